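"""Coverage tracks: loading, normalization, binning, metagene views."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polkin.annotation import GeneModel
from polkin.coverage import (CoverageTrack, StrandedCoverage, bin_signal,
                             interval_density, load_bedgraph, load_bigwig,
                             metagene_matrix, normalize_rpm, write_bedgraph)

from conftest import make_track


def brute_density(arr, start, end):
    return float(np.asarray(arr, dtype=float)[start:end].sum() / (end - start))


class TestBedgraphIO:
    def test_single_interval(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t10\t2.0\n")
        t = load_bedgraph(p)
        assert (t.query("chr1", 0, 10) == 2.0).all()

    def test_empty_file_is_zero_track(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        t = load_bedgraph(p, chrom_sizes={"chr1": 100})
        assert t.query("chr1", 0, 100).sum() == 0.0

    def test_adjacent_intervals_mean(self, tmp_path):
        p = tmp_path / "b.bedgraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t10\t20\t3.0\n")
        t = load_bedgraph(p)
        assert interval_density(t, "chr1", 0, 20) == 2.0

    def test_overlapping_intervals_error(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t5\t20\t3.0\n")
        with pytest.raises(ValueError, match="overlap"):
            load_bedgraph(p)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        arr = rng.poisson(1.0, 500).astype(float)
        t = make_track({"chr1": arr})
        p = tmp_path / "rt.bedgraph"
        write_bedgraph(t, p)
        back = load_bedgraph(p, chrom_sizes={"chr1": 500})
        np.testing.assert_array_equal(back.data["chr1"], arr)

    def test_bigwig_round_trip(self, tmp_path):
        pyBigWig = pytest.importorskip("pyBigWig")
        arr = np.array([0, 0, 2.5, 2.5, 1.0, 0, 0, 3.0], dtype=float)
        p = str(tmp_path / "t.bw")
        bw = pyBigWig.open(p, "w")
        bw.addHeader([("chr1", len(arr))])
        starts = list(range(len(arr)))
        bw.addEntries(["chr1"] * len(arr), starts,
                      ends=[s + 1 for s in starts], values=list(arr))
        bw.close()
        t = load_bigwig(p)
        np.testing.assert_allclose(t.data["chr1"], arr)

    def test_unknown_chromosome_named(self):
        t = make_track({"chr1": np.zeros(10)})
        with pytest.raises(KeyError, match="chrX"):
            t.query("chrX", 0, 5)


class TestNormalization:
    def test_rpm_scaling(self):
        t = make_track({"chr1": np.full(10, 5.0)}, library_size=2_000_000)
        n = normalize_rpm(t)
        assert n.data["chr1"][0] == 2.5
        assert n.normalized

    def test_identity_at_one_million(self):
        t = make_track({"chr1": np.full(10, 5.0)}, library_size=1_000_000)
        assert normalize_rpm(t).data["chr1"][0] == 5.0

    def test_double_normalization_refused(self):
        t = make_track({"chr1": np.zeros(5)}, library_size=100)
        n = normalize_rpm(t)
        with pytest.raises(ValueError):
            normalize_rpm(n)

    def test_zero_library_refused(self):
        t = make_track({"chr1": np.zeros(5)}, library_size=0)
        with pytest.raises(ValueError):
            normalize_rpm(t)


class TestIntervalDensity:
    def test_uniform(self):
        t = make_track({"chr1": np.full(100, 3.5)})
        assert interval_density(t, "chr1", 10, 60) == 3.5

    def test_zero_length_error(self):
        t = make_track({"chr1": np.zeros(10)})
        with pytest.raises(ValueError):
            interval_density(t, "chr1", 5, 5)

    def test_clipping_warns(self):
        t = make_track({"chr1": np.full(10, 1.0)})
        with pytest.warns(UserWarning, match="clipped"):
            d = interval_density(t, "chr1", 5, 15)
        assert d == 0.5  # 5 covered bases of 10 requested

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 190), st.integers(1, 60))
    def test_matches_brute_force(self, seed, start, length):
        rng = np.random.default_rng(seed)
        arr = rng.gamma(1.0, 2.0, 250)
        t = make_track({"chr1": arr})
        end = min(start + length, 250)
        if end > start:
            assert interval_density(t, "chr1", start, end) == \
                pytest.approx(brute_density(arr, start, end))


class TestBinSignal:
    def test_constant_track(self):
        t = make_track({"chr1": np.full(2000, 4.0)})
        v = bin_signal(t, "chr1", 500, "+", upstream=0, downstream=1000, bin_size=50)
        assert v.shape == (20,)
        assert (v == 4.0).all()

    def test_step_track(self):
        arr = np.zeros(90_000)
        arr[1000:6000] = 10.0  # TSS at 1000, signal to +5 kb
        t = make_track({"chr1": arr})
        v = bin_signal(t, "chr1", 1000, "+", 0, 80_000, 50)
        assert (v[:100] == 10.0).all() and (v[100:] == 0.0).all()

    def test_minus_strand_mirror(self):
        arr = np.zeros(90_000)
        arr[1000:6000] = 10.0
        plus = bin_signal(make_track({"chr1": arr}), "chr1", 1000, "+", 0, 80_000, 50)
        minus = bin_signal(make_track({"chr1": arr[::-1].copy()}), "chr1",
                           89_000, "-", 0, 80_000, 50)
        np.testing.assert_array_equal(plus, minus)

    def test_indivisible_span_rejected(self):
        t = make_track({"chr1": np.zeros(100)})
        with pytest.raises(ValueError):
            bin_signal(t, "chr1", 0, "+", 0, 99, 50)

    def test_anchor_off_chromosome_error(self):
        t = make_track({"chr1": np.zeros(100)})
        with pytest.raises(ValueError):
            bin_signal(t, "chr1", 500, "+", 0, 50, 50)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 8.0))
    def test_linearity_and_conservation(self, seed, scale):
        rng = np.random.default_rng(seed)
        arr = rng.poisson(2.0, 4000).astype(float)
        t = make_track({"chr1": arr})
        v1 = bin_signal(t, "chr1", 1000, "+", 500, 2000, 50)
        v2 = bin_signal(t.scaled(scale), "chr1", 1000, "+", 500, 2000, 50)
        np.testing.assert_allclose(v2, scale * v1)
        # sum of bin means x bin size equals the per-base sum over the window
        assert v1.sum() * 50 == pytest.approx(arr[500:3000].sum())


class TestMetagene:
    def _gene(self, gid, start):
        return GeneModel(gid, "chr1", "+", start, start + 85_000)

    def test_identical_genes_average_is_row(self):
        arr = np.zeros(300_000)
        arr[1000:6000] = 5.0
        arr[101_000:106_000] = 5.0
        t = make_track({"chr1": arr})
        genes = [self._gene("a", 1000), self._gene("b", 101_000)]
        mat, prof = metagene_matrix(t, genes, "TSS", 0, 80_000, 50)
        np.testing.assert_array_equal(prof, mat.loc["a"].to_numpy())

    def test_mixture_is_hand_average(self):
        arr = np.zeros(300_000)
        arr[1000:6000] = 8.0     # front at +5 kb
        arr[101_000:111_000] = 8.0  # front at +10 kb
        t = make_track({"chr1": arr})
        genes = [self._gene("a", 1000), self._gene("b", 101_000)]
        mat, prof = metagene_matrix(t, genes, "TSS", 0, 80_000, 50)
        expected = (mat.loc["a"].to_numpy() + mat.loc["b"].to_numpy()) / 2
        np.testing.assert_allclose(prof, expected)
        assert prof[:100].mean() == 8.0  # both genes covered to +5 kb
        assert (prof[100:200] == 4.0).all()  # only gene b

    def test_single_gene_identity(self):
        arr = np.zeros(100_000)
        arr[1000:2000] = 1.0
        t = make_track({"chr1": arr})
        mat, prof = metagene_matrix(t, [self._gene("a", 1000)], "TSS", 0, 80_000, 50)
        np.testing.assert_array_equal(prof, mat.loc["a"].to_numpy())

    def test_empty_gene_list_error(self):
        t = make_track({"chr1": np.zeros(10)})
        with pytest.raises(ValueError):
            metagene_matrix(t, [], "TSS", 0, 80_000, 50)

    def test_missing_chromosome_skipped_with_warning(self):
        arr = np.zeros(100_000)
        t = make_track({"chr1": arr})
        genes = [self._gene("a", 1000),
                 GeneModel("b", "chrScaffold", "+", 0, 85_000)]
        with pytest.warns(UserWarning, match="chrScaffold"):
            mat, _ = metagene_matrix(t, genes, "TSS", 0, 80_000, 50)
        assert list(mat.index) == ["a"]
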