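"""Wave-front detection and elongation-rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polkin.annotation import GeneModel
from polkin.coverage import CoverageTrack
from polkin.elongation import (ElongationRateModel, WaveProfile,
                               detect_wave_front, fit_elongation_rate,
                               group_rates, metagene_rate, per_gene_rates)
from polkin.exceptions import MISSING_BINS, NON_MONOTONE

from conftest import make_track


def profile(bins):
    return WaveProfile("g", 0.0, np.asarray(bins, dtype=float))


def brute_force_front(bins, background_mean, background_sd, k_sd=5,
                      run_length=3, sd_floor=1e-6):
    """Exhaustive scan over every bin for the most downstream qualifying run."""
    thr = background_mean + k_sd * max(background_sd, sd_floor)
    best = None
    for b in range(run_length - 1, len(bins)):
        if all(bins[b - j] > thr for j in range(run_length)):
            best = (b + 1) * 50
    return best


class TestDetectWaveFront:
    def test_clean_step(self):
        bins = np.zeros(1600)
        bins[:200] = 10.0
        assert detect_wave_front(profile(bins)) == 10_000.0

    def test_all_background_uncalled(self):
        assert detect_wave_front(profile(np.zeros(1600))) is None

    def test_run_length_one_reproduces_bare_rule(self):
        bins = np.zeros(1600)
        bins[:200] = 10.0
        bins[300] = 10.0  # isolated noise spike
        assert detect_wave_front(profile(bins), run_length=3) == 10_000.0
        assert detect_wave_front(profile(bins), run_length=1) == 15_050.0

    def test_noisy_profile_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        bins = rng.poisson(0.2, 1600).astype(float)
        bins[:500] += 10.0  # true front at 25 kb
        p = profile(bins)
        got = detect_wave_front(p)
        oracle = brute_force_front(bins, p.background_mean, p.background_sd)
        assert got == oracle
        assert abs(got - 25_000) <= 150

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 120))
    def test_oracle_equivalence_randomized(self, seed, front_bins):
        rng = np.random.default_rng(seed)
        bins = rng.poisson(0.3, 1600).astype(float)
        bins[:front_bins] += 8.0
        p = profile(bins)
        assert detect_wave_front(p) == brute_force_front(
            bins, p.background_mean, p.background_sd)

    def test_background_stats_from_declared_window(self):
        bins = np.zeros(1600)
        bins[1200:] = 3.0  # the +60..+80 kb region only
        p = profile(bins)
        assert p.background_mean == 3.0 and p.background_sd == 0.0


class TestFitRate:
    def test_collinear_points(self):
        fit = fit_elongation_rate({0: 0, 5: 10_000, 10: 20_000, 20: 40_000})
        assert fit.rate == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_shift_invariance(self):
        fit = fit_elongation_rate({0: 500, 5: 10_500, 10: 20_500, 20: 40_500})
        assert fit.rate == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(500.0)

    def test_perturbed_point_matches_normal_equations(self):
        fronts = {0: 0.0, 5: 10_400.0, 10: 20_000.0, 20: 40_000.0}
        t = np.array(sorted(fronts))
        y = np.array([fronts[k] for k in sorted(fronts)])
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        fit = fit_elongation_rate(fronts)
        assert fit.rate == pytest.approx(slope / 1000)

    def test_fewer_than_three_points_refused(self):
        with pytest.raises(ValueError, match="3"):
            fit_elongation_rate({0: 0, 5: 10_000})


def wave_tracks(genes, velocities, timepoints=(0, 5, 10, 20), body=10.0,
                chrom_len=400_000, dropout=None):
    """Noiseless square-wave tracks: signal from TSS to the front position."""
    tracks = {}
    for t in timepoints:
        arr = np.zeros(chrom_len)
        for g, v in zip(genes, velocities):
            front = int(v * t * 1000) + 500  # constant 500 bp offset at t=0
            lo, hi = g.tss, min(g.tss + front, g.tss + g.length)
            arr[lo:hi] = body
            arr[g.tss:g.tss + g.length] += 0.05  # ambient floor, below threshold
        if dropout is not None and t == dropout[0]:
            g = dropout[1]
            arr[g.tss:g.tss + g.length] = 0.0
            arr[g.tss:g.tss + int(0.3 * g.length)] = body
        tracks[float(t)] = make_track({"chr1": arr})
    return tracks


def layout(n, L=100_000, gap=20_000):
    return [GeneModel(f"g{i}", "chr1", "+", 5000 + i * (L + gap),
                      5000 + i * (L + gap) + L) for i in range(n)]


class TestPerGeneRates:
    def test_planted_rate_recovered(self):
        genes = layout(3, gap=10_000)
        tracks = wave_tracks(genes, [2.0] * 3, chrom_len=400_000)
        fits, excluded = per_gene_rates(tracks, genes)
        assert not excluded
        for f in fits:
            assert f.rate == pytest.approx(2.0, abs=0.05)

    def test_missing_bin_filter(self):
        genes = layout(2, gap=10_000)
        tracks = wave_tracks(genes, [2.0, 2.0], chrom_len=300_000)
        # zero out 70% of gene g1's bins at t=10
        g = genes[1]
        arr = tracks[10.0].data["chr1"]
        arr[g.tss + 24_000:g.tss + 80_000] = 0.0
        fits, excluded = per_gene_rates(tracks, genes)
        assert excluded == {"g1": MISSING_BINS}
        assert [f.name for f in fits] == ["g0"]

    def test_non_monotone_filter(self):
        genes = layout(2, gap=10_000)
        tracks = wave_tracks(genes, [2.0, 2.0], chrom_len=300_000)
        # plant an artifact: at t=10 the wave of g1 retreats behind its t=5 front
        g = genes[1]
        arr = tracks[10.0].data["chr1"]
        arr[g.tss:g.tss + g.length] = 0.05
        arr[g.tss:g.tss + 6000] = 10.0  # front at 6 kb < t=5 front of 10.5 kb
        fits, excluded = per_gene_rates(tracks, genes)
        assert excluded == {"g1": NON_MONOTONE}

    def test_gene_shorter_than_span_rejected(self):
        short = GeneModel("s", "chr1", "+", 0, 50_000)
        with pytest.raises(ValueError):
            ElongationRateModel({0.0: make_track({"chr1": np.zeros(60_000)})},
                                [short])


class TestMetageneRate:
    def test_single_gene_equals_per_gene_fit(self):
        genes = layout(1)
        tracks = wave_tracks(genes, [2.0], chrom_len=200_000)
        meta = metagene_rate(tracks, genes)
        fits, _ = per_gene_rates(tracks, genes)
        assert meta.rate == fits[0].rate
        assert meta.front_positions == fits[0].front_positions

    def test_mixed_cohort_matches_profile_oracle(self):
        genes = layout(2, gap=10_000)
        tracks = wave_tracks(genes, [1.0, 3.0], chrom_len=300_000)
        meta = metagene_rate(tracks, genes)
        # oracle: exhaustive-scan fronts on the averaged profile, then OLS
        from polkin.coverage import metagene_matrix
        fronts = {}
        for t, track in tracks.items():
            _, prof = metagene_matrix(track, genes, "TSS", 0, 80_000, 50)
            bg = prof[1200:]
            fronts[t] = brute_force_front(prof, bg.mean(), bg.std())
        oracle = fit_elongation_rate(fronts)
        assert meta.front_positions == oracle.front_positions
        assert meta.rate == pytest.approx(oracle.rate)


def test_group_rates_boundaries():
    import pandas as pd
    labels = group_rates(pd.Series({"a": 1.5, "b": 2.0, "c": 3.0,
                                    "lo_edge": 1.87, "hi_edge": 2.36}))
    assert labels["a"] == "low"
    assert labels["b"] == "medium"
    assert labels["c"] == "high"
    # boundary values fall in the lower group
    assert labels["lo_edge"] == "low"
    assert labels["hi_edge"] == "medium"


def test_rate_invariant_to_scaling_and_offset():
    genes = layout(2, gap=10_000)
    tracks = wave_tracks(genes, [2.0, 2.0], chrom_len=300_000)
    base = metagene_rate(tracks, genes).rate
    scaled = {t: tr.scaled(11.0) for t, tr in tracks.items()}
    assert metagene_rate(scaled, genes).rate == pytest.approx(base)
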