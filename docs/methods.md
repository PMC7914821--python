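# Methods

## Scope and data model

The unit of analysis is a multi-channel confocal z-stack (`ZStack`):
channel-name → `(z, y, x)` volume, 0-based, section 0 the first acquired
plane, intensities stored as acquired (integer) and converted to floating
point only inside metric computations to keep file round-trips lossless.
Multi-channel TIFFs store planes z-major (for each z, each channel) with
channel names, voxel size and sample labels embedded as JSON in the
ImageDescription tag. Voxel sizes are metadata only — both statistics are
dimensionless — so a missing voxel size is tolerated with a logged warning.

## Background and masking

Background is estimated per channel per stack (not per section: single 2D
sections give noise-prone estimates) as the median intensity outside a
rough foreground segmentation, with a percentile fallback when the
foreground fills the frame, and subtracted as `max(I − b, 0)`.

The pollen region is segmented by Otsu thresholding the **logarithm**
(`log1p`) of the background-subtracted signal channel, pooled over the
stack, then per-section morphological closing, hole filling and
small-object removal. The log transform matters: on a clustered stack the
intensity histogram has a heavy bright tail (foci can be ~50× brighter than
the diffuse cytoplasm), and Otsu on linear intensities places the threshold
between cytoplasm and foci, discarding the cytoplasm the CV is supposed to
measure. On log intensities the background/cytoplasm split dominates the
between-class variance and the whole grain is recovered.

Nuclei are Otsu-segmented on the background-subtracted DAPI channel (linear
scale — there the bright class *is* the target) and dilated by 2 px. A
section is excluded from the CV analysis when nucleus area / pollen area
exceeds τ = 0.01, or when its pollen region is smaller than 256 px; in
retained sections nucleus pixels are additionally removed. The
area-fraction rule plus pixel-level removal is deliberately belt-and-braces:
it is robust to a nucleus grazing a section edge, and exclusion is monotone
in τ. A flag (`section_policy`) disables section exclusion where a user
wants the every-section variant.

## The statistics

Per-section CV uses the population (n-denominator) standard deviation — a
descriptive statistic of a fixed pixel set, and the convention is fixed
repo-wide for reproducibility. Stack aggregation is the unweighted mean
over included sections, for CV and R alike. Sections with fewer than two
pixels, non-positive mean (CV), or zero variance (R) are dropped and
logged, never imputed as zero.

Colocalization thresholds are computed once per stack from pooled in-mask
background-subtracted voxels (per-section thresholds would make R values
incomparable along z); the default method is Otsu on the linear scale,
where separating foci from diffuse signal is exactly the "above threshold"
intent, with a percentile alternative. Pixel selection defaults to the
union rule (above threshold in either channel), configurable to
intersection. Colocalization uses all sections with a usable pollen region
by default while CV uses nucleus-free sections only; both policies are
configurable. A section must select at least `min_pixels = 20` pixels for
its R to be defined: a correlation computed from a handful of
threshold-grazing pixels is an arbitrary number (observed as low as −0.97
from four noise pixels) and would corrupt the unweighted stack mean.

Group comparison is Kruskal–Wallis + Dunn's post hoc, the standard pairing
for a rank ANOVA with pairwise follow-up. Dunn's statistic for groups i, j
is z = (R̄ᵢ − R̄ⱼ) / √((N(N+1)/12 − T)(1/nᵢ + 1/nⱼ)) with tie correction
T = Σ(t³ − t)/(12(N − 1)), two-sided normal p-values, Bonferroni-multiplied
by the number of pairs (adjustment can only raise a p-value, and for two
groups z² equals the tie-corrected Kruskal–Wallis H — a property the tests
exploit as an independent check). When all values are tied across all
groups the omnibus is undefined and reported as p = 1. Significance labels
follow the strict-inequality scheme `***` p < 0.001, `*` p < 0.05, `NS`
otherwise, so the boundary values resolve as 0.001 → `*` and 0.05 → `NS`.
A parametric route (one-way ANOVA + Holm-adjusted Welch t) sits behind
`parametric=True`. Groups below 25 measurements warn rather than error,
mirroring the minimum group sizes the metrics were designed around.

## qPCR

Technical replicates are averaged before anything else; biological
replicates (default n = 4) are the statistical unit. Two-reference
normalization uses the arithmetic mean of the reference Cts — equivalent to
the geometric mean of reference quantities at equal efficiencies.
Amplification efficiency is fixed at 2 (no dilution-series correction is
modelled). Relative expression of a replicate is E^−(ΔCt − mean ΔCt of
matched-timepoint controls); the reference normalization cancels any
per-sample global Ct offset exactly, which the tests verify. Test selection
is normality-gated: Shapiro–Wilk at α = 0.05 on both groups, Welch's t if
both pass, else the Wilcoxon rank-sum (Mann–Whitney) form for independent
treated/control groups; a paired variant exists behind a flag. Identical
zero-variance groups return p = 1 by convention.

## The simulator

The generator emulates mature tricellular pollen: an ellipsoidal grain
(default 16 sections of 256×256 at (1.0, 0.2, 0.2) µm, semi-axes
(6, 90, 90) voxels ≈ a 36 µm grain), one vegetative nucleus (3.5 µm) and
two sperm nuclei (1.5 µm) forming the male germ unit, rendered into the
DAPI channel. Each fluorophore channel is

    B + blur( diffuse·(1−f)·S + foci·f·S ) + noise

where S = amplitude × cytoplasm voxel count is the total expected
in-cytoplasm signal. The clustered-signal fraction f therefore
*redistributes* a fixed total — the CV contrast between conditions encodes
where signal sits, not how much there is — and total signal is invariant to
f by construction (verified to <1%, the residual being boundary
quantization). Focus counts are Poisson (default rate 80); foci are
isotropic Gaussian bumps (default σ 0.35 µm) rather than hard spheres, for
post-PSF realism; a fraction q = 0.5 of foci is placed within three focus
radii of a nucleus surface, mimicking the qualitative enrichment of mRNP
foci around the male germ unit. Shared foci between the two fluorophore
channels are placed first with identical centres; with equal focus rates
the channels share one count draw so the realised shared fraction is
round(ρ·n)/n — exactly ρ within rounding. Noise is Poisson shot noise at
gain g (g = ∞ disables it), additive Gaussian read noise, and a constant
background offset, quantized to the declared bit depth. Nucleus and
spherical radii are specified in micrometres and converted per-axis through
the voxel size, because with anisotropic z spacing a physical radius is the
only self-consistent unit.

One `numpy` Generator seeded from the spec drives every draw, so identical
spec + seed is bit-identical. Condition series derive distinct per-replicate
seeds from a master seed via `SeedSequence`. The geometry fields (ellipsoid,
nuclei, blurred cytoplasm indicator) are cached across stacks sharing a
geometry, which keeps a 75-stack series under half a minute on one CPU.

Ground truth records focus centres and channel assignments, shared count,
nucleus/pollen voxel masks, and per-section flags: a section "has
cytoplasm" when its geometric cytoplasm area is at least 1% of the grain's
maximal cross-section, and "has a nucleus" when geometric nucleus area
exceeds 1% of the pollen cross-section — the same area-fraction form as the
detector, evaluated on geometry instead of images.

**What the simulator does not model**, and hence what passing tests do not
show about real data: pollen wall autofluorescence, spatially varying
background, optically rigorous (Airy/vectorial) PSFs, chromatic offsets
between channels, bleaching along z, and any correlated diffuse component
between fluorophores. The last one is visible in the colocalization
figures: with channel-unique foci fully uncorrelated, the above-threshold R
at low shared fraction ρ goes *negative* (unique foci form anti-correlated
pixel clusters), whereas real two-channel stacks ride on a shared diffuse
background that keeps R positive. R remains strictly increasing in ρ and
reaches ≥ 0.99 at ρ = 1 with low noise, which is the property the pipeline
is validated on; absolute R values from the simulator are not comparable to
measurements on real pollen.

The qPCR generator programs Ct = baseline − log2(fold) + biological noise
(per gene per biological replicate, default sd 0.1 cycles) + technical
noise (per well, default half the biological sd), with an optional
per-sample global offset to exercise the normalization. Reference genes are
forced to fold 1.

## Numerical choices and degenerate inputs

Otsu thresholds on volumes larger than 2¹⁶ voxels are computed on a
stride-4 subsample (the histogram shape is unchanged at these sizes, at a
quarter of the cost); constant volumes short-circuit (background = the
constant; no nuclei). Background subtraction uses float32 on full volumes
and float64 on section-sized inputs; the section statistics themselves are
computed in float64 and match brute-force loop implementations to 1e−12.
Poisson noise is sampled only where expected signal is positive
(Poisson(0) ≡ 0). Pipeline runs exclude unanalyzable stacks with a logged
reason and fail only when a whole condition empties; result tables embed
the config hash (computed over analysis-relevant fields, excluding the
output directory) and master seed, and identically configured runs are
byte-identical.

## Problem sizes

The study-scale designs are those the pipeline defaults encode: 3
conditions × 25 replicate stacks of 16×256×256 for clustering (f = 0.1 /
0.5 / 0.3), 20 replicates per ρ level for colocalization, 500 simulations
for the omnibus-calibration check, 100 seeds for qPCR recovery at n = 4
biological × 2 technical replicates. Unit tests use a scaled-down grain
(10×128×128) with proportionally scaled nuclei.

## Known limitations

Foci are not counted or sized (object-based colocalization, Manders
coefficients and Costes randomization are out of scope); sections are
treated independently (no mixed-effects modelling of section-within-stack
nesting — per-stack aggregates are the statistical unit); the Otsu-based
masks assume one grain per field of view; and the simulator's realism
limits listed above apply to every downstream validation.
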