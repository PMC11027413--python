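"""Promoter-proximal pausing metrics.

The pause-release ratio (PRR) of a gene is the read density over its body
(TSS+500 .. TES-500) divided by the density over its promoter (TSS-300 ..
TSS+100), all windows in transcription sense. Higher PRR means more
polymerase released into productive elongation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet
from .coverage import CoverageTrack, StrandedCoverage, _sense_track, interval_density
from .exceptions import SkippedGene, ZERO_PROMOTER
from .genomic import sense_window

PROMOTER_WINDOW = (-300, 100)   # bp relative to TSS, transcription sense
BODY_OFFSET = 500               # bp inset from TSS and from TES


@dataclass(frozen=True)
class PauseReleaseRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    prr: float
    condition: str = ""


@dataclass(frozen=True)
class FoldChangeRecord:
    gene_id: str
    value_a: float
    value_b: float
    log2fc: float


def promoter_interval(gene: GeneModel) -> tuple[int, int]:
    return sense_window(gene.tss, gene.strand, *PROMOTER_WINDOW)


def body_interval(gene: GeneModel) -> tuple[int, int]:
    if gene.length <= 2 * BODY_OFFSET:
        raise ValueError(f"{gene.gene_id}: gene too short for a body window")
    return sense_window(gene.tss, gene.strand, BODY_OFFSET, gene.length - BODY_OFFSET)


def compute_prr(cov, gene: GeneModel, condition: str = "") -> PauseReleaseRecord:
    """Pause-release ratio for one gene.

    Raises :class:`SkippedGene` (reason ``zero_promoter``) when the promoter
    window carries no signal: such genes fail the promoter-occupancy
    precondition and would produce an undefined ratio.
    """
    track = _sense_track(cov, gene.strand)
    p_lo, p_hi = promoter_interval(gene)
    b_lo, b_hi = body_interval(gene)
    prom = interval_density(track, gene.chrom, p_lo, p_hi)
    body = interval_density(track, gene.chrom, b_lo, b_hi)
    if prom <= 0:
        raise SkippedGene(gene.gene_id, ZERO_PROMOTER)
    return PauseReleaseRecord(gene.gene_id, prom, body, body / prom, condition)


def prr_table(cov, genes: Iterable[GeneModel], condition: str = ""
              ) -> tuple[pd.DataFrame, dict[str, str]]:
    """PRR records for many genes; returns (table, skipped gene -> reason)."""
    records, skipped = [], {}
    for g in genes:
        try:
            records.append(compute_prr(cov, g, condition))
        except SkippedGene as exc:
            skipped[g.gene_id] = exc.reason
    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["gene_id", "promoter_density", "body_density",
                               "prr", "condition"])
    return df.set_index("gene_id") if len(df) else df, skipped


def prr_fold_change(records_a: pd.DataFrame, records_b: pd.DataFrame,
                    fc_threshold: float = 1.5) -> tuple[pd.DataFrame, int]:
    """Per-gene PRR fold change b/a plus the count of genes at or above
    ``fc_threshold``-fold increase.

    Only genes with finite positive PRR in both conditions enter; the table
    carries the denominator (`n_compared`) implicitly as its length.
    """
    shared = records_a.index.intersection(records_b.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between conditions")
    a = records_a.loc[shared, "prr"].astype(float)
    b = records_b.loc[shared, "prr"].astype(float)
    ok = (a > 0) & (b > 0) & np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    df = pd.DataFrame({"prr_a": a, "prr_b": b, "log2fc": np.log2(b / a)})
    df = df.sort_index()
    # tolerant comparison: 0.6/0.4 must count as a 1.5-fold change
    n_up = int((df.prr_b / df.prr_a >= fc_threshold * (1 - 1e-9)).sum())
    return df, n_up


def uarna_density(cov: StrandedCoverage, gene: GeneModel,
                  window: tuple[int, int] = (3000, 300)) -> float:
    """Upstream-antisense (uaRNA/PROMPT) density for a gene.

    ``window = (far, near)`` in bp upstream of the TSS; signal is taken on the
    strand opposite the gene over TSS-far .. TSS-near. The near edge must stay
    at least 300 bp upstream, where divergent antisense signal is expected.
    """
    far, near = window
    if near < 300:
        raise ValueError("uaRNA window must start >= 300 bp upstream of the TSS")
    if far <= near:
        raise ValueError("window far edge must exceed near edge")
    track = cov.antisense(gene.strand)
    lo, hi = sense_window(gene.tss, gene.strand, -far, -near)
    return interval_density(track, gene.chrom, lo, hi)


def group_by_quantile(values: Mapping[str, float] | pd.Series, k: int) -> pd.Series:
    """Split genes into ``k`` equal-size groups ordered by the metric.

    Group labels are 1 (lowest metric) .. k (highest); sizes differ by at most
    one; ties are kept adjacent and broken deterministically by gene id.
    """
    s = pd.Series(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(s) < k:
        raise ValueError(f"need at least k={k} values, got {len(s)}")
    if s.nunique() == 1:
        warnings.warn("constant metric: grouping falls back to gene-id order")
    order = sorted(s.index, key=lambda i: (s[i], i))
    labels = pd.Series(0, index=s.index, dtype=int)
    chunks = np.array_split(np.asarray(order, dtype=object), k)
    for grp, ids in enumerate(chunks, start=1):
        labels[list(ids)] = grp
    return labels
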