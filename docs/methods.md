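# Methods

This note records the models, window conventions, numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Coordinate and window conventions

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
BED (0-based half-open) are converted at the I/O boundary. On the minus
strand the TSS is the genomically larger coordinate, and every
"upstream/downstream" window is taken in transcription sense: 300 bp upstream
of a minus-strand TSS lies genomically to the right of it. Coverage tracks
are dense per-base arrays per chromosome; an unstranded ChIP track answers
both strand queries, while stranded assays (GRO-seq-like) must supply a
plus/minus pair. Intervals overrunning a chromosome are clipped with a
warning rather than erroring, because fixed 10-kb downstream windows
routinely overrun small scaffolds; genes on chromosomes absent from a track
are skipped with a warning.

Two interpretive choices were genuinely open and are fixed as follows:
"neighboring genes" means the nearest annotated gene on either strand, with
the distance measured between genomic spans (the conservative reading); and
window densities are computed from per-base coverage rather than read
counts, the closest track-level equivalent when inputs are bigWig/bedGraph.

## Pause-release ratio

PRR = body density / promoter density, with promoter = TSS−300 … TSS+100 and
body = TSS+500 … TES−500. Eligibility: length > 2 kb (which also guarantees a
non-empty body window), neighbor distance > 1 kb, and promoter occupancy.
Genes with zero promoter density are excluded with reason `zero_promoter`
rather than pseudocounted — a pseudocount would manufacture ratios for genes
that fail the occupancy precondition. TSS ties (equal occupancy) resolve to
the most 5′ candidate; last-exon expression ties resolve to the most 3′ exon.
Both tie-breaks are arbitrary but deterministic. The upstream-antisense
(uaRNA) window defaults to −3000 … −300 bp of the TSS: divergent antisense
signal is expected beyond 300 bp upstream, and the 3-kb cap keeps the window
out of neighboring genes (configurable). Fold-change summaries use a
relative tolerance of 1e−9 on the 1.5-fold threshold so exact 1.5× ratios
are not lost to binary rounding.

## Elongation rate

Profiles are 1600 bins of 50 bp from the TSS to +80 kb; bins covering
+60 … +80 kb define the background. The front threshold is background mean +
5 × max(SD, 1e−6). The SD floor matters only for noise-free profiles whose
background variance is exactly zero, where the rule degenerates gracefully to
"above background mean"; on any noisy data the measured SD dominates. The
front is reported at the 3′ edge of the most downstream run of
`run_length = 3` consecutive supra-threshold bins; requiring a short run
suppresses single-bin spikes, and `run_length = 1` restores the bare
5-SD-crossing rule. No smoothing is applied before thresholding (an optional
choice deliberately not defaulted). Front granularity is one bin (50 bp),
which bounds noise-free rate recovery at ±0.05 kb/min over a 20-min series.

Rates come from ordinary least squares of front position (bp) on time (min)
over all timepoints including t = 0, reported in kb/min with r². Per-gene
fits require: ≤60% zero-signal bins at every timepoint ("missing" bins are
operationalized as zero-signal; the floor is configurable), a called front at
every timepoint, and strictly increasing fronts over time — violations carry
reason codes `missing>60%`, `uncalled`, `non-monotone`. The metagene fit uses
the column-mean profile without per-gene survival filters. Rate groups split
at 1.87 and 2.36 kb/min, boundaries assigned to the lower group.

Because the sigmoidal wave front decays smoothly, a thresholding front-caller
sits a constant few kb 3′ of the planted front position at every timepoint;
the offset cancels in the regression slope, which is why recovery of the
planted velocity is exact to bin quantization. "Front" and "peak" are treated
as the same quantity throughout.

## Readthrough index

Coding genes: reference = last exon (highest-expressed candidate when
several are annotated), downstream window = TES … TES+10 kb. The 10-kb
default matches the display convention for termination-zone analyses and is
configurable. The window is truncated at the nearest downstream same-strand
gene so neighbor transcription cannot inflate RI; a truncated window under
200 bp excludes the gene (`neighbor_too_close`). sno/snRNA genes: reference =
gene body, window = 2 × gene length starting 100 bp past the TES. Both
variants use sense-strand signal only and are invariant to global track
scaling. Significance of condition changes uses |log2FC| > 0.58 (≈1.5-fold),
direction retained.

## polyA-site calling

Single-linkage clustering per chromosome and strand with "within 30 bp" read
inclusively (gap ≤ 30 joins; configurable). Summit = modal end position, ties
to the 5′-most position in transcript sense, mirroring cleavage-heterogeneity
conventions. Misprime rule: ≥10 consecutive As (transcript sense — Ts on the
minus genomic strand) within the 20 bp downstream of the peak's 3′ edge; the
20-bp window length is a choice — the rule's source states no length, and
20 bp is standard internal-priming practice while comfortably containing a
10-A run. Motif annotation matches IUPAC AWTAAA over −50 … 0 of the summit;
"GT/T-richness" is reported as the plain G/T base fraction over 0 … +30,
deliberately not a positional motif model.

## Summit positioning

Each summit is assigned to the nearest anchor (TSS or externally supplied +1
nucleosome dyads) within 1 kb; the signed distance is positive 3′ of the
anchor in gene sense; histograms use 10-bp bins. Dyad calling is out of
scope — dyads are consumed as BED, and any cross-cell-line mismatch between
dyad and summit sources is the caller's responsibility.

## Synthetic data generator

The generator emulates the data-generating assumptions behind the analyses:
per-base expected sense signal = body density over the gene, a Gaussian pause
peak at TSS+30 (σ = 50 bp), an optional readthrough extension of fraction *f*
over 10 kb past the TES followed by an exponential termination decay
(scale 1 kb), and constant antisense signal over −3000 … −300. The pause-peak
amplitude is solved so the promoter-window mean is exactly `pause_index` ×
body density, making planted PRR analytic (PRR ≈ 1/pause_index). Gaussian
and exponential components are integrated per base (CDF differences), so
window sums in the truth tables are exact, and the truth tables report
window-integrated values — the same quantities the analysis windows measure.

DRB series replace the body term with `body × sigmoid((v·t·1000 − x)/w)`
(front width w = 500 bp) plus the pause peak and a small ambient background
(0.05 reads/bp) inside genes, standing in for the nonspecific ChIP floor;
without it, noise-free-zero backgrounds would make the missing-bin filter
fire on early timepoints for trivial reasons. Noise is per-base Poisson of
`depth × λ`; real coverage is autocorrelated, so Poisson is a lower bound on
realism that still exercises thresholds honestly. The genome is uniform
random ACGT with AATAAA planted 21 bp upstream of each TES, A₁₂ runs planted
at decoy positions inside coding-gene bodies, and chance A/T runs scrubbed
from the 60 bp downstream of each true cleavage site so only deliberate
decoys can trigger the misprime rule. c3′-style reads scatter as
round(Normal(site, 10 bp)), 50 reads per true site, 25 per decoy placed
immediately 5′ of each planted run.

Defaults are the study conditions: 20 genes of 100 kb (wave analyses need
>80 kb), gaps of 25 kb, timepoints 0/5/10/20 min, planted velocities 2.13
(control-like) and 1.39 (knockdown-like) kb/min, pausing index 5, body
density 0.5 reads/bp, depth 1. Where no value was dictated, the choice was
made once on realism grounds and not revisited. All randomness flows from a
single integer seed through named substreams, so identical configurations
produce byte-identical outputs.

### Sampling depth in Poisson recovery checks

The 5% recovery bands for PRR and RI presume well-sampled windows. The
sno/snRNA RI windows span only a few hundred bp; at depth 1 they collect
~600 expected reads and shot noise alone is ~5%, so a depth-1 check would
measure the random number generator rather than the estimator. The Poisson
recovery tests therefore run at depths where window shot noise is ~1%
(depth 10 for PRR, 200 for RI); generator defaults are unchanged. This is a
statement about the precision of the check, not about the estimators, whose
bias the tests show to be negligible.

## What passing tests do and do not show

Recovery of planted PRR/RI/velocity demonstrates that the window arithmetic,
strand handling, front detection, and regressions implement their definitions
correctly, including under Poisson sampling. It does not demonstrate
robustness to features of real data the generator omits: autocorrelated and
batch-varying backgrounds, mappability gaps, overlapping transcription units,
isoform heterogeneity beyond the single planted TSS/TES, antisense leakage
from imperfect strand specificity, or biased fragment recovery in 3′-end
libraries. Distribution-shift statistics (e.g. KS tests on PRR distributions)
are deliberately left to general-purpose libraries rather than re-implemented.
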