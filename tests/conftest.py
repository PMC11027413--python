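import numpy as np
import pytest

from polkin.annotation import GeneModel, GeneSet
from polkin.coverage import CoverageTrack, StrandedCoverage


def make_track(arrays, strand=".", library_size=None):
    return CoverageTrack({c: np.asarray(a, dtype=float) for c, a in arrays.items()},
                         strand=strand, library_size=library_size)


@pytest.fixture
def toy_genes():
    """Three genes: two + strand genes 10 kb apart, one - strand gene."""
    a = GeneModel("A", "chr1", "+", 1000, 5000, ((1000, 5000),))
    b = GeneModel("B", "chr1", "+", 15000, 20000, ((15000, 20000),))
    c = GeneModel("C", "chr1", "-", 45000, 40000, ((40000, 45000),))
    return GeneSet([a, b, c])


@pytest.fixture
def uniform_pair():
    """Constant signal 2.0 on both strands of a 60 kb chromosome."""
    arr = np.full(60_000, 2.0)
    return StrandedCoverage(make_track({"chr1": arr}, "+"),
                            make_track({"chr1": arr.copy()}, "-"))


def mirror_gene(gene: GeneModel, m: int) -> GeneModel:
    """Reflect a gene about coordinate m (interval [s,e) -> [m-e, m-s))."""
    flip = {"+": "-", "-": "+"}[gene.strand]
    exons = sorted((m - e, m - s) for s, e in gene.exons)
    if flip == "-":
        exons = exons[::-1]
    return GeneModel(gene.gene_id, gene.chrom, flip, m - gene.tss, m - gene.tes,
                     tuple(exons), gene.biotype)


def mirror_track(track: CoverageTrack) -> CoverageTrack:
    return CoverageTrack({c: a[::-1].copy() for c, a in track.data.items()},
                         strand=track.strand, library_size=track.library_size)
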