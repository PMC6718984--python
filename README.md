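# cimquant

Quantification pipeline for contact-inhibition-of-migration (CIM) assays in
glioma cell biology. Tumour cells that have lost CIM migrate regardless of
their neighbours; restoring it shows up in three measurable ways that this
package quantifies:

1. **Scratch-assay polarity** — in a wound-healing assay, each cell's
   migration direction is taken as the vector from its nucleus centroid to
   its Golgi centroid. Expressed as a signed angle θ to the wound-directed
   normal of the scratch rim, a cell is *polarized* when |θ| ≤ 60°. Under a
   uniform direction null this happens with probability 120°/360° = 1/3, so
   bias toward the wound is tested with a two-class goodness-of-fit
   chi-squared test, df = 1:

   χ² = (O_p − n/3)²/(n/3) + (O_np − 2n/3)²/(2n/3)

   Test sensitivity is summarised as power at Cohen's w (noncentrality
   λ = n·w²).

2. **In vivo infiltration enrichment** — silenced (GFP) and control (DsRed)
   cells are co-injected into a brain; per section, each cell's distance to
   the injection-site rim is measured, normalised into 10 equal-width bins
   (bin width = that section's maximum distance / 10, making sections with
   very different spreads comparable), and the silenced/control count ratio
   per bin is tested for a distance trend with Pearson correlation. A
   companion stage follows tumour composition (fraction of silenced cells)
   over days post injection.

3. **Subcellular marker partitioning** — a marker channel (e.g. β-catenin)
   is split into nuclear (thresholded nuclear dye), perinuclear (the 3 µm
   band around the nuclear areas, computed sub-pixel from the Euclidean
   distance transform) and cytoplasmic/membrane (remaining cell area)
   fractions of total signal, which sum to 1.

A thin expression stage provides 2^−ΔΔCt relative qPCR quantification,
densitometry normalisation, and a two-group expression comparison.

Because such studies rarely deposit raw coordinates or images, every stage
ships with a synthetic-data generator with known ground truth (`cimquant.synthetic`):
angular mixtures with a controllable polarized weight ρ (expected polarized
fraction ρ + (1−ρ)/3), two-population point patterns with exponential
distance thinning, binomial composition time courses, and two-channel images
with known compartment fractions. All generators are seed-deterministic, so
every pipeline claim is verified by parameter recovery.

## Worked example

Generate a scratch field of 600 cells with polarized weight ρ = 0.5 and
score it:

```sh
$ cimquant simulate --kind scratch --n-cells 600 --rho 0.5 --seed 7 --out sim
$ cimquant polarity --cells sim/cells.csv --rim sim/rim.csv --band-um 100 --out report
sim-rho0.5-seed7: n=600 polarized=397 chi2=291.07 p=2.91e-65
```

397/600 = 0.66 polarized matches the mixture expectation
0.5 + 0.5/3 = 2/3, and the chi-squared test overwhelmingly rejects the
uniform null (expected 200 polarized). With `--rho 0` the polarized count
settles near 200 and p is uniform on (0,1).

Infiltration, with four sections of 970/351 silenced/control cells and decay
rates 0.02 vs 0.005 /µm (silenced cells concentrated near the rim):

```sh
$ cimquant simulate --kind sections --seed 7 --out simsec
$ cimquant infiltrate --cells simsec/cells.csv --polygons simsec/polygons.csv --out repsec
r=-0.876 (|r|=0.876) p=0.000885 over 10 bins
```

The negative, significant ratio-vs-bin correlation recovers the generated
depletion of the silenced population with distance. Per-bin counts, the
per-cell table, a JSON report and a run manifest land in the `--out`
directory. The same stages are importable (`cimquant.score_field`,
`cimquant.enrichment_profile`, …) for scripted use; see `docs/methods.md`
for the model details and design choices.

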