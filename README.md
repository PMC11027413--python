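# polkin

RNA polymerase II transcription kinetics from strand-resolved coverage
tracks: promoter-proximal pausing, elongation speed, termination readthrough,
and polyA-site calling — plus a synthetic nascent-transcription generator
with analytic ground truth so every stage can be validated without real
sequencing data.

It is aimed at people analysing ChIP-seq / GRO-seq-style coverage of RNAPII
(bigWig or bedGraph) against a GTF annotation, who want the standard
transcription-kinetics metrics as a tested, scriptable library rather than a
pile of one-off notebook code.

## The quantities it computes

**Pause-release ratio (PRR).** For each gene, read density over the body
(TSS+500 … TES−500) divided by density over the promoter (TSS−300 … TSS+100),
windows in transcription sense:

```
PRR = d(body) / d(promoter),   d(w) = Σ signal / |w|
```

Higher PRR means more polymerase escaping the promoter-proximal pause. Genes
enter the analysis only if they are longer than 2 kb, more than 1 kb from the
nearest gene, and promoter-occupied; for multi-TSS genes the TSS with the
highest promoter occupancy is used.

**Elongation rate from DRB release.** DRB arrests RNAPII at promoters;
after washout the released wave is profiled at 0/5/10/20 min. Coverage is
binned at 50 bp from the TSS to +80 kb; the +60…+80 kb region defines the
background; the wave front is the 3′ edge of the most downstream run of bins
exceeding background mean + 5 SD; ordinary least squares of front position on
time gives the rate in kb/min (`ElongationRateModel.fit()` →
`ElongationRateResults.summary()`). Per-gene fits drop genes with >60% empty
bins or non-monotone fronts, with machine-readable reason codes.

**Readthrough index (RI).** Density downstream of the TES over a reference
density: the last exon for coding genes (downstream window 10 kb, truncated at
the next same-strand gene), or the gene body for sno/snRNA genes (window of
twice the gene length starting 100 bp past the TES). Condition fold changes
are flagged significant at |log2FC| > 0.58 (≈1.5-fold).

**polyA sites from 3′-end reads.** Read 3′-end positions are single-linkage
clustered (≤30 bp gaps), summits taken at the modal end, internal-priming
artifacts flagged when the downstream 20 bp carry ≥10 consecutive genomic As,
and AWTAAA polyadenylation signals annotated upstream of each summit.

Also included: upstream-antisense (uaRNA) density over −3000…−300 bp of the
TSS, quantile grouping of per-gene metrics, and summit-to-anchor (TSS / +1
nucleosome dyad) signed distance distributions.

## Worked example

Simulate a locus of 20 well-separated 100-kb genes with a planted pausing
index of 5, a DRB-release series at 2.13 kb/min, and c3′-style end reads,
then run the stages:

```
polkin simulate --seed 7 --out demo --n-genes 20
polkin prr        --gtf demo/locus/genes.gtf --track demo/locus/cov_plus.bedgraph \
                  --minus demo/locus/cov_minus.bedgraph \
                  --chrom-sizes demo/locus/chrom.sizes --out demo/prr
polkin elongation --gtf demo/drb/genes.gtf --manifest demo/drb/manifest.tsv \
                  --out demo/rates
polkin polya      --ends demo/c3/c3_ends.bed --fasta demo/locus/genome.fa \
                  --out demo/polya
```

The elongation stage prints:

```
Elongation-rate fit
========================================
metagene rate: 2.130 kb/min  (r2=1.0000, n=4 timepoints)
per-gene fits: 20  median rate 2.130 kb/min  IQR [2.130, 2.130]
```

i.e. the planted 2.13 kb/min is recovered exactly on noise-free data (with
Poisson noise it is recovered to within ~0.01 kb/min at metagene depth).
`demo/prr/prr.tsv` lists per-gene promoter density, body density, and PRR =
0.2 (the reciprocal of the planted pausing index), and
`demo/polya/polya_peaks.tsv` shows one clean peak per gene TES with its
AWTAAA signal and `misprime=True` for every planted A-run decoy.

The same operations run on real data by pointing `--track` at rpm-normalized
bigWig/bedGraph files, `--gtf` at e.g. GENCODE, and `--fasta` at the genome.

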