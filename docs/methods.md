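# Methods

## Polarity scoring

The migration direction of a fixed cell is inferred from its nucleus→Golgi
axis: the Golgi reorients toward the leading edge in directed migration, so
the vector from the nucleus centroid to the Golgi centroid is a proxy for
where the cell is heading. Each Golgi centroid is paired with the nearest
nucleus centroid (Euclidean); when two Golgi claim the same nucleus the
nearer is kept and the other flagged; nuclei without a Golgi (not visible in
the staining) are excluded and counted.

The reference direction is the scratch-rim normal at the rim point nearest
the nucleus, oriented toward an explicitly supplied wound-side point — the
minimal unambiguous encoding of "which side is the wound". When the nearest
rim point is a polyline vertex the normal of the two adjacent segments'
angle bisector is used, which keeps the normal field continuous along the
rim. θ is the signed angle from that normal to the nucleus→Golgi vector,
in (−180°, 180°]; cells whose Golgi coincides with the nucleus are excluded
with a reason code. The scored population defaults to nuclei within 100 µm
of the rim ("cells adjacent to the scratch" is not a standard quantity; the
band width is a reported parameter).

*Classification and test.* Polarized ⇔ |θ| ≤ 60° (boundary inclusive: it
has measure zero for continuous angles; inclusivity gives reproducible
handling of exact-boundary fixtures). The sector spans 120°/360°, so the
uniform null expects one third polarized. The test is a two-class
chi-squared against (n/3, 2n/3), df = 1, upper-tail p, without Yates
correction by default (a correction flag exists; the corrected form matters
only near the rejection boundary). Fields may be pooled before testing or
tested per replicate; pooling is the default.

*Power.* The statistic is asymptotically noncentral χ²(1, λ = n·w²) at
Cohen's w, so power = P(χ²₁(λ) > χ²₁,₁₋α); α defaults to 0.05. The
Monte-Carlo mode simulates the noncentral statistic (Z + √λ)² directly and
agrees with the analytic tail within simulation error. `sector_power_exact`
instead enumerates the binomial distribution of the polarized count under
the proportion shift matching w (p₁ = 1/3 + w/√4.5): discreteness makes the
exact power slightly lower than the asymptotic value (≈ 0.789 vs ≈ 0.801 at
n = 787, w = 0.1, α = 0.05). The asymptotic form is the quantity the power
statement refers to; the exact form is exposed for completeness.

## Infiltration enrichment

Distances are minimum Euclidean distances from each cell to the rim-polygon
boundary (shapely); cells strictly inside the exclusion region (by default
the rim polygon itself, i.e. the needle track) are excluded and counted.
Per section, bin(d) = ceil(10·d/D) with D the section's maximum distance
over both populations pooled (d = 0 → bin 1), making sections with very
different spreads comparable; the per-section D values are reported.
Counts are pooled across sections; ratio[b] = silenced[b]/control[b]; bins
with zero control count are flagged undefined and excluded from the Pearson
correlation of ratio against bin index (two-sided t, df = defined bins − 2;
≥ 3 defined bins required). Zero-control bins are excluded rather than
pseudocounted so the statistic stays a plain count ratio; an optional
pseudocount exists for robustness analyses. Both the signed r and |r| are
reported, because published enrichment analyses differ in sign convention
(a depletion trend may be printed as a positive correlation of a
differently-oriented quantity).

Known limitation: the ratio of two Poisson-like counts is biased upward in
sparse bins (E[S/C] ≈ (ES/EC)(1 + 1/EC)), which tilts the null trend
slightly positive and makes the test mildly anti-conservative when far bins
are sparse. At the default generator geometry the exchangeable-null
rejection rate at α = 0.01 is ≈ 0.8–2.4% depending on the common decay
rate (measured over 500 replicates).

*Composition.* Per-section fraction = silenced/(silenced + control); per
tumour, the mean ± SEM across sections (intra-tumoral variability; SEM = 0
for a single section); the trend is the Pearson correlation of per-tumour
mean fraction against day, two-sided, requiring ≥ 3 tumours at ≥ 2 distinct
days. A constant profile makes r undefined; p = 1 by convention.

## Compartment partitioning

Nuclear mask: global Otsu threshold of the nuclear dye by default (fixed
and local-mean methods configurable; the method name is recorded in the
output for provenance), holes filled, objects under a minimum area removed.
Perinuclear band: pixels outside the nuclear mask whose Euclidean distance
transform (with physical sampling) is ≤ 3 µm — a sub-pixel threshold rather
than integer dilation rounds, so the band width is resolution-consistent.
Cell area: an explicit cell mask when provided, otherwise the Otsu-
thresholded marker channel united with the nuclear mask (the marker is
assumed to fill the cell). Background, the median marker intensity outside
the cell area, is subtracted with negatives clipped (disable with
`subtract_background=False`). The three compartments partition the cell
area exactly (nuclear; band ∩ cell − nuclear; remainder), and fractions are
compartment signal sums over the cell-area sum, summing to 1 by
construction. Quantification is field-level, not per-cell.

Condition comparison: per compartment, Welch's t on per-image fractions by
default (rank-sum optional; the choice is recorded, not asserted as
standard). No multiplicity correction: the three fractions are dependent
views of one signal. Identical zero-variance groups are reported as t = 0,
p = 1.

## Expression stage

2^−ΔΔCt with amplification efficiency fixed at 2 (configurable): replicate
Ct averaged per sample × target, ΔCt = Ct_target − Ct_housekeeping,
referenced to a calibrator sample whose relative expression is exactly 1.
SEM propagates the sample's own replicate Ct variance by the delta method,
treating the calibrator ΔCt as the fixed baseline. Densitometry:
(target/loading)_sample / (target/loading)_reference. The group test
compares log relative expression (fold changes are multiplicative) with
Welch's t by default; rank-sum and label-permutation modes are provided
because the appropriate test for small qPCR panels is genuinely open.

## Synthetic generators

All generators are deterministic in (config, seed) via
`numpy.random.default_rng`.

*Scratch fields.* Angles come from a mixture: with probability ρ uniform in
the ±60° sector, else uniform over the full circle, giving the closed-form
polarized fraction ρ + (1 − ρ)/3 (exactly 1/3 at ρ = 0) — chosen over von
Mises because the closed form enables exact tests; a von Mises sampler is
provided as an alternative. Nuclei occupy a jittered grid in a 100 µm band
behind the rim with minimum spacing 2·(golgi_offset + 1) µm, mimicking
physical cell exclusion and guaranteeing that nearest-nucleus Golgi pairing
is unambiguous, so recorded ground-truth angles are exactly recoverable.
The Golgi offset defaults to 5 µm; it affects geometry only, never angles.

*Brain sections.* Cell positions are drawn as a uniform angle about the
rim-polygon centroid plus a radial offset from the boundary with a
truncated-exponential density (rate 0 → uniform), per population. The ratio
of two exponentials is monotone in distance, the simplest model producing a
monotone enrichment decline. Defaults: silenced rate 0.02/µm, control
0.005/µm, observation window 300 µm — a window spanning several silenced
decay lengths (50 µm scale) while the control population (200 µm scale)
still fills the far bins, consistent with near-injection-site fields at
early timepoints. The rim is a 64-gon of radius 150 µm; placement error
from polygon discretisation is < 0.1 µm.

*Composition.* Per-section silenced counts are binomial around each
tumour's scheduled fraction; the default schedule (day 18: 0.67, day 89:
0.33, day 179: 0.08) mirrors a strongly declining silenced share, with 500
cells/section and 3 sections/tumour.

*Compartment images.* Disjoint disk cells on a grid; the marker is
piecewise-constant per compartment with levels chosen so the noise-free
integral over each ground-truth compartment matches the target fractions
exactly, then scaled so the brightest compartment is 1 and Gaussian noise
added. Not modelled: PSF blur, photobleaching, uneven illumination,
cell-shape variability — so recovery results demonstrate the correctness of
the measurement pipeline, not robustness to real microscopy artefacts.

## Problem sizes

The recovery and calibration analyses use: 10⁶ angles for the uniform-null
fraction; 1000 replicates of n = 787 for type-I error; 10⁵ replicates for
the power cross-check; 100 replicates of 4 sections × (3879 + 1406 cells)
for infiltration detection and null calibration; 20 replicates at 5% noise
for segmentation recovery; 64×64 images for the brute-force band oracle.

## Known limitations

- Pearson-on-ratio inherits heteroscedastic, skewed bin noise; see the
  infiltration note above. A count-based regression (e.g. binomial GLM on
  per-bin proportions) would be better calibrated but would no longer be
  the plain ratio-correlation statistic this pipeline mirrors.
- The polarity analysis assumes a single time point; no tracking or
  velocity estimation.
- Compartment quantification is field-level; images with strongly varying
  per-cell expression conflate cell-to-cell variability with localisation.
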