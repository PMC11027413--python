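"""Gene annotation: GTF parsing, neighbor context, and gene-selection rules.

Internally every coordinate is 0-based half-open; GTF (1-based inclusive) is
converted at the boundary. A :class:`GeneModel` is strand-aware: on the minus
strand the TSS is the genomically *larger* coordinate, so ``tss > tes`` there.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .exceptions import LENGTH_FILTER, NEIGHBOR_FILTER, UNOCCUPIED

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

#: biotypes recognised for the small-gene readthrough index
SMALL_RNA_BIOTYPES = frozenset({"snoRNA", "snRNA"})


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcription unit.

    ``exons`` are half-open genomic intervals ordered 5'->3' along the gene
    (descending genomic start on the minus strand).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tss == self.tes:
            raise ValueError(f"{self.gene_id}: tss == tes")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")
        lo, hi = self.span
        for s, e in self.exons:
            if not (lo <= s < e <= hi):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene span")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic half-open span [start, end)."""
        return min(self.tss, self.tes), max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def last_exon(self) -> tuple[int, int]:
        """Most 3' annotated exon (last element of the 5'->3' ordering)."""
        if not self.exons:
            return self.span
        return self.exons[-1]


class GeneSet:
    """A collection of genes with per-gene nearest-neighbor distances.

    Neighbor distance is the genomic gap between gene spans to the nearest
    other gene on either strand (0 if spans overlap, +inf if the gene is
    alone on its chromosome).
    """

    def __init__(self, genes: Iterable[GeneModel], genome_id: str = ""):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self._genes[g.gene_id] = g
        self.genome_id = genome_id
        self.neighbor_distance: dict[str, float] = self._neighbor_distances()

    def _neighbor_distances(self) -> dict[str, float]:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self._genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        dist = {gid: math.inf for gid in self._genes}
        for genes in by_chrom.values():
            genes = sorted(genes, key=lambda g: g.span)
            # adjacent genes in start order bound the minimal gap; containment
            # cases still yield gap 0 through the max(0, ...) clamp
            for a, b in zip(genes, genes[1:]):
                gap = max(0, b.span[0] - a.span[1])
                dist[a.gene_id] = min(dist[a.gene_id], gap)
                dist[b.gene_id] = min(dist[b.gene_id], gap)
        return dist

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    @property
    def ids(self) -> list[str]:
        return sorted(self._genes)


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_gene_models(path, biotype_filter: set[str] | None = None,
                     genome_id: str = "") -> GeneSet:
    """Load a GTF file into a :class:`GeneSet`.

    Only ``gene`` and ``exon`` features are consumed; attributes must carry
    ``gene_id`` and, optionally, ``gene_type``/``gene_biotype``. A gene without
    exon records is retained with a single exon spanning the gene (warned).
    """
    genes_raw: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: "
                                 f"expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            try:
                s0, e0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
            except ValueError:
                raise ValueError(f"{path}: malformed GTF line {lineno}: "
                                 f"non-integer coordinates") from None
            at = _parse_attributes(attrs)
            gid = at.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing gene_id")
            if feature == "gene":
                biotype = at.get("gene_type", at.get("gene_biotype", "other"))
                genes_raw[gid] = dict(chrom=chrom, strand=strand, start=s0,
                                      end=e0, biotype=biotype)
            else:
                exons.setdefault(gid, []).append((s0, e0))

    models = []
    for gid, info in genes_raw.items():
        if biotype_filter is not None and info["biotype"] not in biotype_filter:
            continue
        ex = exons.get(gid)
        if not ex:
            warnings.warn(f"gene {gid} has no exon records; using gene span")
            ex = [(info["start"], info["end"])]
        ex = sorted(set(ex))
        if info["strand"] == "+":
            tss, tes = info["start"], info["end"]
        else:
            tss, tes = info["end"], info["start"]
            ex = ex[::-1]
        models.append(GeneModel(gene_id=gid, chrom=info["chrom"],
                                strand=info["strand"], tss=tss, tes=tes,
                                exons=tuple(ex), biotype=info["biotype"]))
    return GeneSet(models, genome_id=genome_id)


def write_gtf(genes: GeneSet | Iterable[GeneModel], path) -> None:
    """Write gene and exon features back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            lo, hi = g.span
            fh.write(f"{g.chrom}\tpolkin\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in sorted(g.exons):
                fh.write(f"{g.chrom}\tpolkin\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


def write_bed6(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span, g.gene_id)):
            lo, hi = g.span
            fh.write(f"{g.chrom}\t{lo}\t{hi}\t{g.gene_id}\t0\t{g.strand}\n")


def classify_prr_genes(genes: GeneSet, promoter_occupied: set[str],
                       min_length: int = 2000,
                       min_neighbor: int = 1000) -> dict[str, list[str]]:
    """Per-gene list of pause-release filter failures (empty list = eligible).

    The three filters: gene longer than ``min_length``, farther than
    ``min_neighbor`` from the nearest gene, and promoter occupied by RNAPII.
    """
    out: dict[str, list[str]] = {}
    for g in genes:
        reasons = []
        if g.length <= min_length:
            reasons.append(LENGTH_FILTER)
        if genes.neighbor_distance[g.gene_id] <= min_neighbor:
            reasons.append(NEIGHBOR_FILTER)
        if g.gene_id not in promoter_occupied:
            reasons.append(UNOCCUPIED)
        out[g.gene_id] = reasons
    return out


def select_prr_genes(genes: GeneSet, promoter_occupied: set[str],
                     min_length: int = 2000,
                     min_neighbor: int = 1000) -> list[str]:
    """Gene ids passing all three pause-release eligibility filters, sorted."""
    unknown = set(promoter_occupied) - set(genes.ids)
    if unknown:
        raise ValueError(f"promoter_occupied ids absent from gene set: {sorted(unknown)[:5]}")
    reasons = classify_prr_genes(genes, promoter_occupied, min_length, min_neighbor)
    return sorted(gid for gid, r in reasons.items() if not r)


def resolve_tss(candidates: Sequence[int], occupancy: Sequence[float],
                strand: str = "+") -> int:
    """Pick the TSS candidate with the highest promoter occupancy.

    Ties go to the most 5' candidate along the gene strand.
    """
    if len(candidates) == 0:
        raise ValueError("no TSS candidates")
    if len(candidates) != len(occupancy):
        raise ValueError("candidates and occupancy differ in length")
    for v in occupancy:
        if not (v >= 0 and math.isfinite(v)):
            raise ValueError(f"occupancy values must be finite and >= 0, got {v}")
    best = max(occupancy)
    tied = [p for p, v in zip(candidates, occupancy) if v == best]
    return min(tied) if strand == "+" else max(tied)


def choose_last_exon(gene: GeneModel,
                     exon_expression: Mapping[tuple[int, int], float]) -> tuple[int, int]:
    """Pick the annotated terminal exon with the highest expression.

    Ties go to the exon whose 3' end lies most 3' along the gene.
    """
    if not exon_expression:
        raise ValueError(f"{gene.gene_id}: no terminal exon candidates")
    best = max(exon_expression.values())
    tied = [iv for iv, v in exon_expression.items() if v == best]
    if gene.strand == "+":
        return max(tied, key=lambda iv: iv[1])
    return min(tied, key=lambda iv: iv[0])
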