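"""Synthetic nascent-transcription data with known ground truth.

The generator lays out well-separated genes on one synthetic chromosome and
emits, per gene, the expected sense-strand signal

``lambda(x) = body [gene body] + pause peak (Gaussian at TSS+30)
            + f * body [TES .. TES+readthrough] + exponential termination decay``

plus constant upstream-antisense (uaRNA) signal over -3000..-300 bp of the
TSS. DRB-release series replace the body term with a sigmoidal wave front
travelling at a planted velocity. Observed signal is either the expectation
itself (``noise="none"``) or per-base Poisson draws of ``depth * lambda``.
The pause-peak amplitude is chosen so that the promoter-window mean density is
exactly ``pause_index`` times the body density, making the planted pausing
index analytic. Truth tables carry window-integrated analytic values so the
analysis stages can be checked like for like.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GeneModel, GeneSet, write_gtf
from .coverage import CoverageTrack, StrandedCoverage, write_bedgraph, write_chrom_sizes
from .genomic import reverse_complement
from .polya import EndRead, write_end_bed

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic locus.

    Defaults mirror the measurement design the analyses assume: genes well
    over 80 kb for wave analysis, 0/5/10/20-min timepoints, and a control-like
    planted elongation velocity of 2.13 kb/min.
    """

    seed: int
    n_genes: int = 20
    gene_length: int = 100_000
    n_small: int = 4                 # snoRNA-like genes for the small-gene RI
    small_gene_length: int = 250
    intergenic_gap: int = 25_000
    flank: int = 5_000
    body_density: float = 0.5        # expected reads/bp in the gene body
    pause_index: float = 5.0         # promoter/body density ratio
    pause_sigma: float = 50.0        # bp; pause peak width
    pause_offset: int = 30           # bp downstream of TSS
    term_decay: float = 1_000.0      # bp; exponential termination decay scale
    readthrough_fraction: float | tuple = 0.0
    readthrough_length: int = 10_000
    ua_density: float = 0.05         # antisense reads/bp over -3000..-300
    bg_density: float = 0.05         # ambient background inside genes (DRB series)
    wave_velocity: float | tuple = 2.13   # kb/min
    wave_front_width: float = 500.0  # bp; sigmoid front width
    timepoints: tuple = (0.0, 5.0, 10.0, 20.0)
    depth: float = 1.0
    polya_site_sigma: float = 10.0   # bp scatter of 3' ends around the site
    reads_per_site: int = 50
    decoy_reads: int = 25
    misprime_decoys: int = 2         # planted A12 runs per coding gene
    noise: str = "none"              # none | poisson
    chrom: str = "chrS"

    def __post_init__(self):
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        for name in ("body_density", "ua_density", "bg_density", "depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for v in np.atleast_1d(self.wave_velocity):
            if v <= 0:
                raise ValueError("wave_velocity must be > 0")
        for f in np.atleast_1d(self.readthrough_fraction):
            if f < 0:
                raise ValueError("readthrough_fraction must be >= 0")


# ---------------------------------------------------------------------------
# layout and analytic helpers

def _per_gene(value, n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    return arr


def _layout(cfg: SimConfig) -> list[GeneModel]:
    """Coding genes then small genes, alternating strands, fixed gaps."""
    genes = []
    pos = cfg.flank
    for i in range(cfg.n_genes):
        start, L = pos, cfg.gene_length
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss, tes = start, start + L
            exons = ((start, start + L - 2000), (start + L - 2000, start + L))
        else:
            tss, tes = start + L, start
            exons = ((start + 2000, start + L), (start, start + 2000))
        genes.append(GeneModel(f"gene{i:03d}", cfg.chrom, strand, tss, tes,
                               exons, "protein_coding"))
        pos += L + cfg.intergenic_gap
    for j in range(cfg.n_small):
        start, L = pos, cfg.small_gene_length
        strand = "+" if j % 2 == 0 else "-"
        if strand == "+":
            tss, tes = start, start + L
        else:
            tss, tes = start + L, start
        genes.append(GeneModel(f"sno{j:03d}", cfg.chrom, strand, tss, tes,
                               ((start, start + L),), "snoRNA"))
        pos += L + 5_000
    return genes


def chrom_length(cfg: SimConfig) -> int:
    return (cfg.flank + cfg.n_genes * (cfg.gene_length + cfg.intergenic_gap)
            + cfg.n_small * (cfg.small_gene_length + 5_000) + cfg.flank)


def pause_amplitude(cfg: SimConfig) -> float:
    """Gaussian mass scale making promoter-window mean = pause_index x body."""
    z = lambda x: (x - cfg.pause_offset) / cfg.pause_sigma
    g_prom = norm.cdf(z(100)) - norm.cdf(z(-300))
    return cfg.body_density * (400 * cfg.pause_index - 100) / g_prom


def analytic_promoter_density(cfg: SimConfig) -> float:
    return cfg.pause_index * cfg.body_density


def analytic_body_density(cfg: SimConfig) -> float:
    L = cfg.gene_length
    z = lambda x: (x - cfg.pause_offset) / cfg.pause_sigma
    leak = pause_amplitude(cfg) * (norm.cdf(z(L - 500)) - norm.cdf(z(500)))
    return cfg.body_density + leak / (L - 1000)


def analytic_prr(cfg: SimConfig) -> float:
    return analytic_body_density(cfg) / analytic_promoter_density(cfg)


def analytic_ri(cfg: SimConfig, f: float, downstream_len: int = 10_000) -> float:
    """Downstream/reference density ratio implied by the generator."""
    rt, td = cfg.readthrough_length, cfg.term_decay
    if downstream_len <= rt:
        mean = f * cfg.body_density
    else:
        tail = td * (1 - math.exp(-(downstream_len - rt) / td))
        mean = f * cfg.body_density * (rt + tail) / downstream_len
    return mean / cfg.body_density if cfg.body_density > 0 else 0.0


def _gene_lambda(cfg: SimConfig, L: int, f: float, pause: bool,
                 rt_len: int | None = None, decay_tail: int | None = None
                 ) -> tuple[int, np.ndarray]:
    """Per-base expected sense signal over offsets [off_lo, off_hi)."""
    off_lo = -400
    if rt_len is None:
        rt_len = cfg.readthrough_length
    if decay_tail is None:
        decay_tail = int(8 * cfg.term_decay)
    off_hi = L + (rt_len + decay_tail if f > 0 else 0)
    x = np.arange(off_lo, off_hi)
    lam = np.zeros(len(x))
    body = (x >= 0) & (x < L)
    lam[body] += cfg.body_density
    if pause:
        edges = (np.arange(off_lo, off_hi + 1) - cfg.pause_offset) / cfg.pause_sigma
        cdf = norm.cdf(edges)
        lam += pause_amplitude(cfg) * np.diff(cdf)
    if f > 0:
        rt = (x >= L) & (x < L + rt_len)
        lam[rt] += f * cfg.body_density
        tail = x >= L + rt_len
        xt = x[tail] - (L + rt_len)
        # exact per-base integral of the exponential decay
        lam[tail] += f * cfg.body_density * cfg.term_decay * (
            np.exp(-xt / cfg.term_decay) - np.exp(-(xt + 1) / cfg.term_decay))
    return off_lo, lam


def _scatter(plus: np.ndarray, minus: np.ndarray, gene: GeneModel,
             off_lo: int, lam: np.ndarray) -> None:
    """Add a transcript-sense lambda vector onto the genomic strand arrays,
    clipping at chromosome edges."""
    n = len(lam)
    if gene.strand == "+":
        g0, vec, target = gene.tss + off_lo, lam, plus
    else:
        g0, vec, target = gene.tss - (off_lo + n), lam[::-1], minus
    lo, hi = max(0, g0), min(len(target), g0 + n)
    target[lo:hi] += vec[lo - g0:hi - g0]


def _ua_window(gene: GeneModel, far: int = 3000, near: int = 300) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - far, gene.tss - near
    return gene.tss + near, gene.tss + far


def _maybe_poisson(arr: np.ndarray, cfg: SimConfig, rng) -> np.ndarray:
    if cfg.noise == "poisson":
        return rng.poisson(cfg.depth * arr).astype(float)
    return arr


# ---------------------------------------------------------------------------
# locus simulation

@dataclass
class SimulatedLocus:
    config: SimConfig
    genes: GeneSet
    genome: dict[str, str]
    coverage: StrandedCoverage
    truth: pd.DataFrame       # per-gene analytic expectations
    decoys: pd.DataFrame      # planted misprime A-run positions

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(self.genes, out / "genes.gtf")
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_chrom_sizes({c: len(s) for c, s in self.genome.items()},
                          out / "chrom.sizes")
        write_bedgraph(self.coverage.plus, out / "cov_plus.bedgraph")
        write_bedgraph(self.coverage.minus, out / "cov_minus.bedgraph")
        self.truth.to_csv(out / "truth_genes.tsv", sep="\t")
        self.decoys.to_csv(out / "truth_decoys.tsv", sep="\t", index=False)


def _decoy_offsets(cfg: SimConfig) -> list[int]:
    m = cfg.misprime_decoys
    return [round(cfg.gene_length * (j + 1) / (m + 1)) for j in range(m)]


def _true_site(gene: GeneModel) -> int:
    """Genomic position of the 3'-most transcribed base."""
    return gene.tes - 1 if gene.strand == "+" else gene.tes


def _plant(seq: np.ndarray, gene: GeneModel, motif: str, offset: int) -> None:
    """Write a transcript-sense motif starting at a sense offset from the TSS."""
    if gene.strand == "+":
        g0 = gene.tss + offset
        seq[g0:g0 + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
    else:
        g0 = gene.tss - offset - len(motif)
        rc = reverse_complement(motif)
        seq[g0:g0 + len(rc)] = np.frombuffer(rc.encode(), dtype="S1")


def _scrub_downstream(seq: np.ndarray, gene: GeneModel, span: int = 60,
                      max_run: int = 6) -> None:
    """Break chance A/T runs just 3' of the true cleavage site so that only
    the deliberately planted decoys trigger the misprime rule."""
    site = _true_site(gene)
    if gene.strand == "+":
        lo, hi, base = site + 1, site + 1 + span, b"A"
    else:
        lo, hi, base = site - span, site, b"T"
    window = seq[lo:hi]
    text = window.tobytes().decode()
    for m in re.finditer((base.decode()) + f"{{{max_run},}}", text):
        # break the run every max_run-1 bases so no sub-run reaches max_run
        for k in range(m.start() + max_run - 1, m.end(), max_run):
            window[k] = b"C"


def simulate_locus(config: SimConfig) -> SimulatedLocus:
    """Synthetic annotation, genome, and stranded coverage with truth tables."""
    cfg = config
    genes = _layout(cfg)
    coding = [g for g in genes if g.biotype == "protein_coding"]
    small = [g for g in genes if g.biotype != "protein_coding"]
    fracs = _per_gene(cfg.readthrough_fraction, len(genes))
    n = chrom_length(cfg)

    # genome with planted polyA signals and misprime decoys
    rng_genome = np.random.default_rng([cfg.seed, 0])
    seq = _BASES[rng_genome.integers(0, 4, n)].copy()
    decoy_rows = []
    for g in genes:
        _plant(seq, g, "AATAAA", g.length - 21)
        _scrub_downstream(seq, g)
    for g in coding:
        for d in _decoy_offsets(cfg):
            _plant(seq, g, "A" * 12, d)
            if g.strand == "+":
                run_start, read_pos = g.tss + d, g.tss + d - 1
            else:
                run_start, read_pos = g.tss - d - 12, g.tss - d
            decoy_rows.append({"gene_id": g.gene_id, "chrom": cfg.chrom,
                               "strand": g.strand, "run_start": run_start,
                               "read_pos": read_pos})
    genome = {cfg.chrom: seq.tobytes().decode()}

    # expected coverage
    plus = np.zeros(n)
    minus = np.zeros(n)
    for g, f in zip(genes, fracs):
        pause = g.biotype == "protein_coding"
        if pause:
            off_lo, lam = _gene_lambda(cfg, g.length, f, pause)
        else:
            # small genes: readthrough only far enough to cover the 2L window
            # at TES+100, short decay, so neighbors stay clean
            off_lo, lam = _gene_lambda(cfg, g.length, f, pause,
                                       rt_len=100 + 2 * g.length,
                                       decay_tail=2000)
        _scatter(plus, minus, g, off_lo, lam)
        if cfg.ua_density > 0:
            lo, hi = _ua_window(g)
            target = minus if g.strand == "+" else plus
            target[lo:hi] += cfg.ua_density
    rng_noise = np.random.default_rng([cfg.seed, 1])
    plus = _maybe_poisson(plus, cfg, rng_noise)
    minus = _maybe_poisson(minus, cfg, rng_noise)
    cov = StrandedCoverage(CoverageTrack({cfg.chrom: plus}, strand="+"),
                           CoverageTrack({cfg.chrom: minus}, strand="-"))

    rows = []
    for g, f in zip(genes, fracs):
        is_coding = g.biotype == "protein_coding"
        rows.append({
            "gene_id": g.gene_id, "biotype": g.biotype, "strand": g.strand,
            "tss": g.tss, "tes": g.tes, "length": g.length,
            "readthrough_fraction": f,
            "promoter_density": analytic_promoter_density(cfg) if is_coding else np.nan,
            "body_density": analytic_body_density(cfg) if is_coding else cfg.body_density,
            "prr": analytic_prr(cfg) if is_coding else np.nan,
            "ri": analytic_ri(cfg, f) if is_coding else f,
            "ua_density": cfg.ua_density,
            "true_polya_site": _true_site(g),
        })
    truth = pd.DataFrame(rows).set_index("gene_id")
    decoys = pd.DataFrame(decoy_rows, columns=["gene_id", "chrom", "strand",
                                               "run_start", "read_pos"])
    return SimulatedLocus(cfg, GeneSet(genes, genome_id="synthetic"), genome,
                          cov, truth, decoys)


# ---------------------------------------------------------------------------
# DRB-release series

@dataclass
class DrbSeries:
    config: SimConfig
    genes: GeneSet
    tracks: dict[float, StrandedCoverage]
    truth: pd.DataFrame  # per-gene planted velocity (kb/min)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(self.genes, out / "genes.gtf")
        rows = []
        for t, cov in sorted(self.tracks.items()):
            for strand, track in (("plus", cov.plus), ("minus", cov.minus)):
                path = out / f"drb_t{t:g}_{strand}.bedgraph"
                write_bedgraph(track, path)
                rows.append({"path": path.name, "minutes": t, "strand": strand})
        pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth_velocity.tsv", sep="\t")


def simulate_drb_series(config: SimConfig) -> DrbSeries:
    """Per-timepoint stranded tracks of a post-DRB-release elongation wave.

    At time t the sense expectation inside a gene is
    ``body * sigmoid((v t 1000 - x) / front_width) + pause peak + background``.
    Velocities taking the front past +80 kb at the latest timepoint only
    trigger a warning (the front leaves the analysed window).
    """
    cfg = config
    if 0 not in cfg.timepoints and 0.0 not in cfg.timepoints:
        raise ValueError("timepoints must include 0")
    genes = [g for g in _layout(cfg) if g.biotype == "protein_coding"]
    vels = _per_gene(cfg.wave_velocity, len(genes))
    t_max = max(cfg.timepoints)
    if (vels * t_max * 1000 > 80_000).any():
        import warnings
        warnings.warn("wave front exceeds +80 kb at the latest timepoint")
    n = chrom_length(cfg)
    amp = pause_amplitude(cfg)

    tracks: dict[float, StrandedCoverage] = {}
    for ti, t in enumerate(cfg.timepoints):
        plus = np.zeros(n)
        minus = np.zeros(n)
        for g, v in zip(genes, vels):
            off_lo = -400
            x = np.arange(off_lo, g.length)
            lam = np.zeros(len(x))
            inside = (x >= 0) & (x < g.length)
            xc = x[inside] + 0.5
            lam[inside] = (cfg.body_density /
                           (1.0 + np.exp(np.clip((xc - v * t * 1000)
                                                 / cfg.wave_front_width, -700, 700)))
                           + cfg.bg_density)
            edges = (np.arange(off_lo, g.length + 1) - cfg.pause_offset) / cfg.pause_sigma
            lam += amp * np.diff(norm.cdf(edges))
            _scatter(plus, minus, g, off_lo, lam)
        rng = np.random.default_rng([cfg.seed, 3, ti])
        plus = _maybe_poisson(plus, cfg, rng)
        minus = _maybe_poisson(minus, cfg, rng)
        tracks[float(t)] = StrandedCoverage(
            CoverageTrack({cfg.chrom: plus}, strand="+"),
            CoverageTrack({cfg.chrom: minus}, strand="-"))
    truth = pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                          "velocity_kb_per_min": vels}).set_index("gene_id")
    return DrbSeries(cfg, GeneSet(genes, genome_id="synthetic"), tracks, truth)


# ---------------------------------------------------------------------------
# c3'-seq end reads

@dataclass
class SimulatedEndReads:
    config: SimConfig
    reads: list[EndRead]
    truth: pd.DataFrame  # true and decoy site positions

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_end_bed(self.reads, out / "c3_ends.bed")
        self.truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)


def simulate_c3_reads(config: SimConfig, locus: SimulatedLocus) -> SimulatedEndReads:
    """3'-end reads at each coding gene's cleavage site plus misprime decoys.

    True-site ends scatter as round(Normal(site, polya_site_sigma)); decoy
    reads sit immediately 5' of each planted A run so the misprime filter must
    flag exactly those peaks.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    reads: list[EndRead] = []
    rows = []
    for g in locus.genes:
        if g.biotype != "protein_coding":
            continue
        site = int(locus.truth.loc[g.gene_id, "true_polya_site"])
        if cfg.polya_site_sigma > 0:
            offs = np.round(rng.normal(0, cfg.polya_site_sigma,
                                       cfg.reads_per_site)).astype(int)
        else:
            offs = np.zeros(cfg.reads_per_site, dtype=int)
        reads.extend(EndRead(g.chrom, g.strand, site + int(o)) for o in offs)
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                     "position": site, "kind": "true"})
    for rec in locus.decoys.itertuples():
        reads.extend(EndRead(rec.chrom, rec.strand, int(rec.read_pos))
                     for _ in range(cfg.decoy_reads))
        rows.append({"gene_id": rec.gene_id, "chrom": rec.chrom,
                     "strand": rec.strand, "position": int(rec.read_pos),
                     "kind": "decoy"})
    truth = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                        "position", "kind"])
    return SimulatedEndReads(cfg, reads, truth)
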