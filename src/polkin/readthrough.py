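"""Transcriptional readthrough quantification.

The readthrough index (RI) compares nascent-RNA density beyond the TES with a
within-gene reference region: the last exon for protein-coding genes, or the
gene body for independently transcribed snoRNA/snRNA genes (whose downstream
window is twice the gene length starting 100 bp past the TES).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet, SMALL_RNA_BIOTYPES
from .coverage import _sense_track, interval_density
from .exceptions import SkippedGene, ZERO_REFERENCE, NEIGHBOR_TOO_CLOSE
from .genomic import sense_window

LOG2_SIGNIFICANCE = 0.58  # |log2FC| threshold, ~1.5-fold


@dataclass(frozen=True)
class ReadthroughRecord:
    gene_id: str
    biotype: str
    reference_density: float
    downstream_density: float
    ri: float
    condition: str = ""
    window: tuple[int, int] = (0, 0)  # genomic downstream window actually used


def _downstream_limit(gene: GeneModel, gene_set: GeneSet | None,
                      downstream_len: int) -> int:
    """Length of the downstream window after truncation at the nearest
    downstream annotated gene on the same strand."""
    if gene_set is None:
        return downstream_len
    limit = downstream_len
    for other in gene_set:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom \
                or other.strand != gene.strand:
            continue
        if gene.strand == "+":
            d = other.span[0] - gene.tes
        else:
            d = gene.tes - other.span[1]
        if 0 <= d < limit:
            limit = d
    return limit


def compute_ri_coding(cov, gene: GeneModel, last_exon: tuple[int, int] | None = None,
                      downstream_len: int = 10_000, gene_set: GeneSet | None = None,
                      min_window: int = 200, condition: str = "") -> ReadthroughRecord:
    """Readthrough index for a protein-coding gene.

    downstream window = TES .. TES+``downstream_len`` in transcription sense,
    truncated at the nearest downstream same-strand gene; reference = the
    (chosen) last exon. Sense-strand signal only.
    """
    track = _sense_track(cov, gene.strand)
    ex_lo, ex_hi = last_exon if last_exon is not None else gene.last_exon
    ref = interval_density(track, gene.chrom, ex_lo, ex_hi)
    if ref <= 0:
        raise SkippedGene(gene.gene_id, ZERO_REFERENCE)
    limit = _downstream_limit(gene, gene_set, downstream_len)
    if limit < min_window:
        raise SkippedGene(gene.gene_id, NEIGHBOR_TOO_CLOSE)
    lo, hi = sense_window(gene.tes, gene.strand, 0, limit)
    down = interval_density(track, gene.chrom, lo, hi)
    return ReadthroughRecord(gene.gene_id, gene.biotype, ref, down, down / ref,
                             condition, (lo, hi))


def compute_ri_small(cov, gene: GeneModel, offset: int = 100,
                     condition: str = "") -> ReadthroughRecord:
    """Readthrough index for a snoRNA/snRNA gene.

    downstream window = twice the gene length starting ``offset`` bp past the
    TES; reference = the gene body TSS..TES.
    """
    if gene.biotype not in SMALL_RNA_BIOTYPES:
        raise ValueError(f"{gene.gene_id}: biotype {gene.biotype!r} is not a "
                         f"sno/snRNA")
    track = _sense_track(cov, gene.strand)
    b_lo, b_hi = sense_window(gene.tss, gene.strand, 0, gene.length)
    ref = interval_density(track, gene.chrom, b_lo, b_hi)
    if ref <= 0:
        raise SkippedGene(gene.gene_id, ZERO_REFERENCE)
    lo, hi = sense_window(gene.tes, gene.strand, offset, offset + 2 * gene.length)
    down = interval_density(track, gene.chrom, lo, hi)
    return ReadthroughRecord(gene.gene_id, gene.biotype, ref, down, down / ref,
                             condition, (lo, hi))


def ri_table(cov, genes: Iterable[GeneModel], gene_set: GeneSet | None = None,
             downstream_len: int = 10_000, condition: str = ""
             ) -> tuple[pd.DataFrame, dict[str, str]]:
    """RI records for a mixed gene list, dispatching on biotype."""
    records, skipped = [], {}
    for g in genes:
        try:
            if g.biotype in SMALL_RNA_BIOTYPES:
                records.append(compute_ri_small(cov, g, condition=condition))
            else:
                records.append(compute_ri_coding(cov, g, downstream_len=downstream_len,
                                                 gene_set=gene_set, condition=condition))
        except SkippedGene as exc:
            skipped[g.gene_id] = exc.reason
    df = pd.DataFrame([{k: v for k, v in r.__dict__.items() if k != "window"}
                       for r in records],
                      columns=["gene_id", "biotype", "reference_density",
                               "downstream_density", "ri", "condition"])
    return df.set_index("gene_id") if len(df) else df, skipped


def ri_fold_change(records_a: pd.DataFrame, records_b: pd.DataFrame,
                   log2_threshold: float = LOG2_SIGNIFICANCE,
                   fc_threshold: float = 1.5
                   ) -> tuple[pd.DataFrame, set[str], int]:
    """Per-gene RI fold change b/a.

    Returns the table, the set of significant genes (|log2FC| above the
    threshold, direction retained in the table), and the count of genes with a
    >= ``fc_threshold``-fold increase.
    """
    shared = records_a.index.intersection(records_b.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between conditions")
    a = records_a.loc[shared, "ri"].astype(float)
    b = records_b.loc[shared, "ri"].astype(float)
    ok = (a > 0) & (b > 0) & np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    df = pd.DataFrame({"ri_a": a, "ri_b": b, "log2fc": np.log2(b / a)})
    df["significant"] = df.log2fc.abs() > log2_threshold
    df = df.sort_index()
    significant = set(df.index[df.significant])
    # tolerant comparison: exact 1.5-fold ratios must count despite rounding
    n_up = int((df.ri_b / df.ri_a >= fc_threshold * (1 - 1e-9)).sum())
    return df, significant, n_up
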