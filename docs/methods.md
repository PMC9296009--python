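# Methods

This note records the models, parameter choices and numerical behaviour of
the package — what is computed, which defaults were open choices, and what
the synthetic-data tests do and do not demonstrate about real data.

## Fragment space

4C-seq counts ligation junctions at restriction-fragment ends, so the whole
4C side of the package works in fragment space. Genomes are digested in
silico by literal motif scanning: cut coordinates are site occurrences plus
the enzyme's cut offset (DpnII ^GATC → offset 0, NlaIII CATG^ → 4, Csp6I
G^TAC → 1; any enzyme is expressible as `EnzymeSpec`). N or any non-ACGT
base never matches, the conservative choice over assembly gaps. Zero-length
fragments from coincident cuts are dropped with a logged count. Each
fragment contributes two fragends whose *capture sequence* — the first L
bases read inward from the primary cut site, reverse-complemented on the 3′
side — is the key reads are matched against; L defaults to 36 (a free
parameter: short enough for typical 4C read lengths, long enough that
capture collisions are rare outside repeats). Fragments with no secondary
site are flagged blind (they cannot circularise informatively) but are kept
in the map.

Reads are assigned by exact unique lookup of their leading capture bases
instead of an external aligner. This keeps the fragment-space representation
identical while removing mapping-parameter ambiguity; captures shared by
several fragends are excluded from the dictionary at build time and reads
hitting them are tallied as ambiguous. Externally produced per-fragend count
tables can be imported as TSV when alignment-based assignment is preferred.
Conservation (assigned + ambiguous + unmatched = total) holds at every
stage and is asserted in tests.

Engineered alleles are first-class: deletions/insertions are applied to the
sequence, the edited chromosome is re-digested, and a segment table lifts
edited-axis coordinates back to reference coordinates (inserted sequence
lifts to a named contig, making a foreign insertion usable as a 4C bait).
A deletion therefore genuinely shortens the allele's coordinate map, and
sequence downstream of the scar becomes bait-proximal — the "contiguous
with the bait" signal artifact next to deletion scars emerges from the
geometry rather than being painted in.

## Masking, smoothing, background and calling

Deletion masks cover every fragend whose fragment overlaps the deleted
interval plus `flank_frags` fragends on each side (default 2 — enough to
absorb the broken scar fragments; the exact flank the display convention
requires is a judgement call, and wider flanks only discard data). Masked
positions are excluded from running means, never zeroed, and are written as
no-coverage gaps in bedGraph. The running mean is centered, truncated at
profile ends, and averages only unmasked window members; W defaults to 21
fragments, the same window the interaction caller uses, so display and
statistics share one smoothing scale.

The background model is a non-increasing isotonic least-squares regression
(pool-adjacent-violators) of signal versus distance, fitted independently
on each side of the bait with the 10 bait-proximal fragends excluded
(self-ligation/over-digestion zone). Plain least-squares PAVA has a known
failure mode here: a genuine interaction peak is pooled into a long elevated
plateau, inflating the background under and around the peak — in our
simulations the fitted plateau reached ~half the peak height and the peak
escaped calling entirely. The fit is therefore robustified by exclude-and-
refit: stretches whose 21-fragment smoothed signal exceeds 1.5× the current
fit are removed and the fit recomputed (2 iterations). On peak-free data the
smoothed profile essentially never crosses 1.5× the fit, so the robust fit
coincides with plain PAVA; the PAVA core itself is verified against an
exhaustive contiguous-partition oracle on ≤8-point instances.

Calling uses an explicit two-threshold rule: a fragend is flagged when its
21-fragment running mean exceeds the (equally smoothed) background by at
least δ normalized-count units AND by ρ-fold; maximal flagged runs of at
least `min_frags` fragends become intervals, intervals never span the bait,
and the cross-replicate consensus is the per-position intersection of the
replicate interval sets. The frozen defaults are δ = 2, ρ = 2,
min_frags = 3. They were calibrated once on 200 background-only simulated
replicates at the default study conditions (depth 10⁵, NB dispersion
φ = 10): δ = 2 gives a 0/200 per-replicate false-call rate (δ = 1 admitted
~8%, from smoothed excursions in the low-count far tail), while planted-peak
sensitivity is unaffected — the ~5× gene-spanning peak is recovered by the
wild-type consensus in 20/20 seeds. Raising δ or ρ can only shrink the
called set (asserted as a property).

## Interaction scores and their statistics

Counts within the 1-Mb cis window are quantile-normalized jointly over all
libraries sharing a bait: every column receives the mean-of-sorted-columns
reference distribution, with tied values given the mean of the reference
over their rank span. (This tie rule differs from interpolation-based
implementations for tie runs longer than two; normalization is verified
against limma's `normalizeQuantiles` on tie-free matrices.) The union of
deletion masks over all alleles is removed from *every* column first, so
ranks stay comparable between wild-type and deletion alleles.

A region's interaction score is the sum of normalized counts over fragends
whose primary-cut anchor lies in the region. Conditions are compared by
two-tailed t-tests on per-replicate scores — Welch by default (safe at
n = 2–4; the pooled-variance variant is available and both are pinned by
tests) — with effects reported as percent change of condition means. TAD
scores apply the same machinery to the ~325-kb regions tiling the upstream
and downstream neighbouring domains and are additionally rescaled so the
wild-type mean is 1 per region; raw sums are kept alongside.

**Compositional coupling.** Quantile normalization assumes identical count
distributions; a genuine localized gain or loss is partially redistributed
across the window. Measured on the generator's ground truth: a planted
attenuation of the default 10-kb peak is recovered within ~3–4 percentage
points of truth (biased toward zero); for the paper-locus fixture, whose
gene-region peak is 20 kb wide and whose deletion allele also gains mass
from TAD leakage and scar contiguity, a planted 0.72× attenuation reads as
≈ −35% instead of −28%, and the upstream-TAD control shifts ≈ −18% even
though nothing was planted there. The same coupling necessarily affects any
analysis of real libraries normalized this way; the per-replicate simulated
noise here is far smaller than biological replicate scatter, which is why
the coupling reaches significance in the fixture while the corresponding
control in real data does not.

## smFISH quantification

Nuclei are segmented by Otsu thresholding the smoothed max projection of
the nuclear channel, split by watershed on the distance transform
(seeds = distance-map maxima, min separation 12 px); cells grow from the
nuclei by seeded watershed over the above-background RNA-channel projection,
so each nucleus lies in exactly one cell. Border-touching cells are dropped.

Spot detection band-pass filters the volume (difference of Gaussians at σ
and 2σ) and takes local maxima above median + k·1.4826·MAD of the filtered
values, with the noise floor estimated *inside cells* (the empty field is
quieter than cytoplasm and would let in-cell shot-noise peaks through);
k defaults to 5. Each candidate is refined by iterative Gaussian-mask
localization: per-z-plane local background (median of the ROI's lateral
border ring — a single 3-D shell median leaves a residual offset wherever
background varies along z, which measurably inflates dim-spot intensities)
is subtracted, the Gaussian-weighted centroid is iterated to 10⁻³ voxel, and
the integrated intensity is the least-squares Gaussian amplitude times the
mask sum. A fit that drifts more than 2σ from its candidate voxel is sliding
onto a brighter neighbour: it reverts to the candidate position and is
flagged unconverged (kept). Detections within one PSF width merge, keeping
the brighter. One neighbour-subtraction pass follows: all fitted Gaussians
are subtracted and each spot refitted on its own residual, removing the
~10–20% intensity inflation neighbour tails cause at tens of mRNAs per
cell. The PSF default (σ_z, σ_y, σ_x) = (1.2, 1.3, 1.3) voxels corresponds
to a 1.4-NA 40× objective with 1.6× post-magnification at far-red emission,
0.1-µm pixels and 0.3-µm z-steps; it is fully configurable and the detector
assumes the generator and fitter share it.

RNA-equivalents divide each integrated intensity by the median cytoplasmic
spot intensity pooled over all cells of the sample (scale-invariant by
construction; the median cytoplasmic spot is exactly 1). Per-cell mRNA is
the sum of the cell's RNA-equivalents, so a 3-RNA focus contributes 3 (a
spots-count-as-1 mode exists). Nuclear foci at or above 2.5 RNA-equivalents
(inclusive) are active transcription sites; cells are partitioned into
zero / one / more-than-one TS, with >2 TS cells kept in the last category.
Cells with no detected spot are excluded (segmentation failures in
practice). Samples are compared by a two-sided Wilcoxon rank-sum test
(exact enumeration when both n ≤ 8, tie-corrected normal approximation
otherwise) on mRNA/cell and Pearson χ² on the TS-category table; technical
replicates are concatenated before testing.

## Synthetic-data generators

*4C.* A uniform-random toy chromosome (2.4 Mb, bait centred; DpnII sites
every ~256 bp, matching real 4-cutter density) is digested for real, per
allele, after applying its edits. Expected signal is a power-law decay
λ(d) = A·(d+d₀)^−α with α = 1, d₀ = 2 kb, scaled so the decay alone sums to
the library depth (10⁵ cis reads); planted peaks are plateau-shaped
multiplicative enrichments (default width 10 kb, fold-height ~4 over local
background), per-allele attenuation scales the *total* signal over the peak
footprint (so attenuation f is exactly a 100·(f−1)% ground-truth change),
and region factors plant boundary leakiness. Counts are negative-binomial
with dispersion φ = 10 (variance μ + μ²/φ). The paper-locus fixture mirrors
the study design: wild-type n = 4, homozygous deletion n = 4, heterozygous
alleles n = 3 (intact) and n = 4 (deleted); a 7.3-kb deletion 2 kb
downstream of the bait; a 20-kb gene-spanning peak ~100 kb upstream
attenuated 0.72× on the deletion allele; a 1.6× leak over the 305-kb
downstream-TAD region. Optional FASTQ emission expands counts into capture
reads that round-trip exactly through assignment.

*smFISH.* Cells are soft-edged discs (radius 34 px, nucleus 17 px) on a
jittered grid with margins keeping them clear of the border; optical edges
are smoothed because a hard 1-px rim is a band-pass artifact no real image
has. Cytoplasmic mRNA counts are Poisson (mean 40/cell by default — kept
below typical *Sox2* levels so compact test images remain resolvable);
single-RNA intensity is lognormal (CV 0.2) around I₁ = 3000; each of 2
alleles fires with probability 0.5 and carries a Gamma nascent load
(shape 2, mean 5 RNAs); spots render as 3-D Gaussians at sub-voxel
positions; Poisson shot noise and Gaussian read noise (σ = 6) apply on a
100-count offset, giving single-RNA SNR ≈ 10. An optional
`min_spot_separation` (in PSF σ units) rejection-samples placements, used
by recovery tests to guarantee the planted spots are optically resolvable.

## What the tests show — and do not

Synthetic recovery demonstrates the *implementation*: digestion invariants,
exact worked examples, PAVA-oracle equivalence, null calibration of the
caller (false-call rate ≤ 5% over 200 background-only replicates; t-test
p-values uniform under the null), attenuation recovery within ±8 points in
≥90% of seeds at generator defaults, noiseless localization ≤ 0.05 voxel,
and pooled one-to-one spot recall/precision ≥ 0.95 on resolvable-density
fields. They do not capture: PCR duplicates/jackpotting or ligation biases
in real 4C; biological replicate-to-replicate variability (the simulated
replicate scatter is purely counting noise, so simulated t statistics are
unrealistically large); optical aberrations, uneven illumination or probe
background in real smFISH.

Known limitations worth stating plainly. (1) At study-like spot densities,
molecules closer than ~3 PSF widths blend into single detections; one-to-one
recall is then ~0.87 and per-cell mRNA counts are correspondingly ~10% low.
(2) Because candidates are selected as noise-aligned local maxima, measured
intensities carry a small selection bias that grows with relative noise
(~+7–9% for single RNAs at default noise, ~+2% for bright foci); since the
cytoplasmic median calibrator inherits the single-RNA bias, transcription-
site RNA-equivalents read ~8% low and the effective TS threshold at default
noise is nearer 2.7 true RNAs than 2.5. (3) The quantile-normalization
compositional coupling quantified above applies to any strongly
redistributed allele. None of these affect the package's internal
consistency checks, and all are measured, not guessed, by the acceptance
script and test suite.
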