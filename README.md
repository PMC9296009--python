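# loop4c

Allele-specific 4C-seq quantification and single-molecule RNA FISH analysis
for dissecting how enhancer clusters control transcription and chromatin
architecture at a locus — the analysis stack used to ask whether a gene's
contact with its distal enhancer (e.g. *Sox2* and the SCR enhancer cluster
~100 kb downstream in mouse embryonic stem cells) survives deletion of the
very elements that drive its transcription.

It is written for genomicists who have per-allele 4C-seq libraries from
engineered deletion/insertion lines (or want to prototype such an analysis
on synthetic data) and imaging groups counting mRNAs and transcription sites
in smFISH z-stacks.

## What it computes

**4C-seq side.** Reads are counted at restriction *fragment ends* (DpnII /
Csp6I double digest, in-silico fragment maps, engineered-allele coordinate
lifts for deletions and insertions). For each bait, counts within 1 Mb are
quantile-normalized jointly across all replicates and conditions. Two
statistics follow:

- *Interaction calling*: each side of the bait is fitted with a robust
  non-increasing isotonic regression of signal versus distance (the
  distance-decay background); a fragend is called interacting when its
  21-fragment running mean exceeds the background by both an absolute margin
  δ and a fold-change ρ, and per-replicate intervals are intersected into
  consensus regions.
- *Interaction scores*: for a predefined region R the score of library ℓ is
  S_ℓ(R) = Σ_{fragend i ∈ R} x̃_{iℓ}, the sum of quantile-normalized counts.
  Conditions are compared by two-tailed t-tests on per-replicate scores, and
  effects reported as 100·(mean_B − mean_A)/mean_A percent change. TAD
  "leakiness" applies the same score to ~325-kb regions tiling the
  neighbouring domains, rescaled so the wild-type mean is 1.

Deletion alleles are handled throughout: deleted fragends and a flank are
masked from running means, normalization and scores, and edited-axis
coordinates are lifted back to the reference.

**smFISH side.** Cells and nuclei are segmented by Otsu thresholding and
watershed; spots are detected in 3-D by band-pass filtering and localized by
iterative Gaussian-mask fitting with per-plane local background subtraction;
intensities become RNA-equivalents by dividing by the median cytoplasmic
single-molecule intensity; nuclear foci ≥ 2.5 RNA-equivalents are active
transcription sites. Samples are compared by a Wilcoxon rank-sum test on
mRNA/cell and a χ² test on zero / one / more-than-one TS proportions.

**Synthetic data.** Seeded generators produce 4C libraries (power-law decay
λ(d) = A·(d+d₀)^−α, planted peaks, per-allele attenuation, negative-binomial
noise, true re-digestion of edited alleles) and smFISH stacks (cells,
lognormal single-RNA spots, Gamma-load transcription sites, shot + read
noise) with full ground truth, so every stage is testable without external
data.

## Worked example

`examples/simulate_and_score_4c.py` simulates the full study design
(wild-type n = 4, homozygous enhancer-cluster deletion n = 4, heterozygous
alleles n = 3/4; the deletion allele carries a 0.72× attenuation of the
gene-spanning peak and a 1.6× leak into the downstream TAD) and runs the
scoring pipeline:

```text
        region         condition_b  percent_change      t      p
   sox2_region            dSCR_hom           -35.8  30.64 0.0000
   sox2_region  dSCR_het_wt_allele             0.1  -0.09 0.9354
   sox2_region dSCR_het_del_allele           -35.0  28.11 0.0000
downstream_tad            dSCR_hom            38.0 -57.12 0.0000
  upstream_tad            dSCR_hom           -17.5  29.23 0.0000

consensus bait-interacting region(s) across wild-type replicates:
  chrS:1,094,534-1,116,079
```

Read: the deletion allele loses roughly a third of its contact with the
gene region (significant on both the homozygote and the heterozygote's
deleted allele, while the intact allele is indistinguishable from wild
type), contacts leak into the downstream TAD, and the consensus interaction
call recovers the planted gene-spanning peak. The measured −36% for a
planted 28% attenuation, and the −17% shift of the upstream-TAD control,
reflect the compositional coupling quantile normalization introduces when
one condition redistributes substantial signal mass; `docs/methods.md`
quantifies this.

The other examples cover digestion/fragment-end maps, interaction calling,
and smFISH quantification; each prints its result with a short reading.

A thin CLI mirrors the library for shell use:

```bash
loop4c simulate-4c --seed 1 --out ws/   # synthetic workspace
loop4c score ws/                        # normalize, call, score, compare
loop4c demux reads.fastq manifest.yaml --out demux/
loop4c count demux/s1.fastq genome.fa --out counts.tsv
loop4c simulate-smfish --seed 1 --out field.tiff
loop4c smfish field.tiff --out cells.tsv
```

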