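"""Peak-summit positioning relative to anchors (TSS, +1 nucleosome dyads).

Each summit is assigned to the nearest anchor within a distance cap; the
signed distance is positive when the summit sits 3' of the anchor in the
anchor gene's transcription sense.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneSet


@dataclass
class AnchorSet:
    """Named per-gene anchor positions with gene strands."""

    name: str
    anchors: pd.DataFrame  # columns: gene_id, chrom, pos, strand

    @classmethod
    def from_tss(cls, genes: GeneSet, name: str = "TSS") -> "AnchorSet":
        rows = [{"gene_id": g.gene_id, "chrom": g.chrom, "pos": g.tss,
                 "strand": g.strand} for g in genes]
        return cls(name, pd.DataFrame(rows))

    @classmethod
    def from_bed(cls, path, genes: GeneSet, name: str) -> "AnchorSet":
        """Anchors from a BED file of positions named by gene_id (e.g. +1
        dyads); strand is taken from the gene annotation."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                gid = f[3].strip()
                rows.append({"gene_id": gid, "chrom": f[0], "pos": int(f[1]),
                             "strand": genes[gid].strand})
        return cls(name, pd.DataFrame(rows))


def read_summit_bed(path) -> list[tuple[str, int]]:
    """BED of peak summit positions (start coordinate used)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1])))
    return out


def summit_distances(summits: Sequence[tuple[str, int]], anchors: AnchorSet,
                     max_dist: int = 1000, bin_width: int = 10
                     ) -> tuple[pd.DataFrame, pd.Series, int]:
    """Signed summit-to-anchor distances plus their histogram.

    Returns (per-summit table, histogram of assigned distances binned at
    ``bin_width`` bp over +-``max_dist``, number of unassigned summits).
    Assignment is to the nearest anchor within ``max_dist``; nearest ties are
    broken by gene_id.
    """
    adf = anchors.anchors
    rows, dists = [], []
    n_unassigned = 0
    by_chrom = {c: sub.sort_values(["pos", "gene_id"]) for c, sub in adf.groupby("chrom")}
    for chrom, pos in summits:
        sub = by_chrom.get(chrom)
        best = None
        if sub is not None:
            absd = (sub.pos - pos).abs()
            m = absd.min()
            if m <= max_dist:
                cand = sub[absd == m].sort_values("gene_id").iloc[0]
                signed = (pos - cand.pos) if cand.strand == "+" else (cand.pos - pos)
                best = (cand.gene_id, int(signed))
        if best is None:
            n_unassigned += 1
            rows.append({"chrom": chrom, "summit": pos, "gene_id": None,
                         "distance": np.nan})
        else:
            rows.append({"chrom": chrom, "summit": pos, "gene_id": best[0],
                         "distance": best[1]})
            dists.append(best[1])
    table = pd.DataFrame(rows, columns=["chrom", "summit", "gene_id", "distance"])
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width)
    counts, _ = np.histogram(dists, bins=edges)
    hist = pd.Series(counts, index=pd.IntervalIndex.from_breaks(edges, closed="left"))
    return table, hist, n_unassigned
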