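# Methods

## Scope and model

`hcsquant` quantifies two endpoint readouts of fixed-cell fluorescence plate
screens: per-cell NF-κB nuclear translocation and per-cell nuclear-GFP
infection, plus the well/donor statistics built on them. The unit of
measurement is one cell; the unit of reporting is one well (percent of
positive cells over its whole measured population, pooled across all
acquired fields); the unit of comparison is one donor (mean ± sd over
replicate wells).

The translocation readout assumes that activation state is encoded in the
ratio of mean signal per pixel between the nucleus and a cytoplasmic
compartment of the same cell, and that the population is a two-class mixture
with a fixed pair of decision thresholds: ratio > 1.2 activated, ratio < 1.0
non-activated, both strict. The band [1.0, 1.2] is not assigned to either
class; by default these intermediate cells stay in the well denominator but
never in the numerator ("percent of the entire population"), and an
alternative policy dropping them from both counts is available and recorded
in every output. Ratios exactly equal to a threshold fall in the
intermediate band — a deliberate reading of the strict inequalities in the
classification rule.

The infection readout uses only nuclear GFP evidence: cells whose mean
nuclear GFP exceeds a positivity threshold count as infected, and the
denominator is the total nucleus count from the DNA counterstain. No
canonical positivity threshold exists for this assay, so the rule is
pluggable: background mean + k·sd (default, k = 3, background estimated from
non-nucleus pixels of the field), Otsu on the per-nucleus mean distribution,
or a fixed cutoff. The default rule intentionally reads non-nucleus pixels —
but only to calibrate the field-wide threshold, never as per-cell evidence;
the invariance of calls to background perturbation is therefore tested under
the fixed and Otsu rules.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2 px) → Otsu global threshold → connected
components (8-connectivity) → optional distance-transform watershed split of
touching objects → removal of objects under 20 px → optional removal of
border-touching nuclei (default on, so every measured cell has a complete
cytoplasm ring). A robustness guard declares a field empty when the Otsu
threshold lies within 5 robust (MAD-based) sigmas of the background median;
without it, thresholding a field that contains only background noise would
hallucinate objects, because Otsu always splits *something*. The guard
constant matches the signal-to-background ≥ 5 regime the pipeline is
qualified for and is configurable (`min_contrast_snr`, 0 disables).

Cytoplasm: a fixed-width perinuclear ring (default 5 px) grown outward from
each nucleus by Euclidean distance; colliding rings are split by
nearest-nucleus assignment (`skimage.segmentation.expand_labels`). Pixels
exactly equidistant from two nuclei are resolved deterministically by the
distance transform's scan order. A ring was preferred over a signal-derived
cell-body mask because the latter would make the measurement compartment
depend on the very signal being quantified. Both compartment masks share one
label set and are pixel-disjoint by construction.

Coordinates are (row, col), 0-based, shared by images and masks end to end.

## The simulator

The generator emulates endpoint two-channel acquisitions of sparsely plated
fibroblasts at low magnification: 47 fields per well covering the well
surface, ~6,000 seeded cells per well (≈128 cells per 512×512 field at a
~1.3 µm/px scale), nuclei as disks (radius 6 ± 0.75 px) inside a concentric
cytoplasm (outer radius 14 ± 1 px — a flat fibroblast's body is much wider
than its nucleus, which is exactly what makes a perinuclear ring a valid
cytoplasm sample). Cells are placed by rejection sampling with no
nucleus–nucleus overlap and, by default, no cell–cell contact; a `clumping`
option allows touching cell bodies for segmentation stress tests. Field-to-
field counts are Poisson (uniform seeding); every field's random stream is
derived from (master seed, well row, well column, field index), so any field
regenerates in isolation and whole plates are reproducible from one seed.

Channel rendering: the DNA channel paints nuclei at a fixed intensity over a
background offset (signal-to-background ≈ 15 by default). In the signal
channel the cytoplasm annulus is painted at `background + 100` a.u. and the
nucleus at `true_ratio ×` that total, so the true ratio refers to the total
measured intensity and a noiseless render-measure round trip returns it
exactly — this is the quantity a ratio-threshold classifier actually sees.
The activated component draws true ratios from N(2.0, 0.2) and the resting
component from N(0.7, 0.1): a well-separated mixture representing clear
pathway activation, chosen so that classification error, not mixture
overlap, is what validation measures. Infected nuclei add N(200, 20) a.u. of
GFP over an 8 a.u. background (~25× contrast). Noise is shot noise (Poisson,
configurable gain, variance ∝ signal) plus additive Gaussian read noise
(σ = 2 a.u.); an optional multiplicative linear ramp (amplitude < 1) models
illumination non-uniformity.

What the simulator does **not** emulate: point-spread-function blur,
chromatic offsets, autofluorescence texture, mitotic/apoptotic morphologies,
multi-nucleated or overlapping 3-D cells, time-lapse kinetics. Passing the
recovery tests therefore shows the measurement and classification chain is
correct and unbiased on geometrically clean input at realistic density and
noise — not that segmentation would survive arbitrary real-image artifacts.

## Statistics

Replicates aggregate as arithmetic mean and sample sd (n−1); a single
replicate yields sd = NaN, flagged rather than 0. The Mann–Whitney U test
enumerates the exact two-sided null over all C(n, n₁) group assignments of
the pooled midranks when combined n ≤ 12 (924 assignments at 6 vs 6, exact
even under ties) and otherwise uses the normal approximation with tie and
continuity correction via scipy. The chi-square reproducibility test runs on
the 2×2 activated/non-activated × experiment counts with the plain
Σ(O−E)²/E statistic; Yates continuity correction is applied (and flagged)
only in the degenerate zero-expected-cell case, where the uncorrected
statistic is undefined. The low/high responder split is either a fixed
percent cutoff or an exhaustive 1-D split of the sorted donor means
minimising within-group sum of squares, ties broken toward the smaller low
group; all-identical means yield a flagged single-group result instead of an
arbitrary split.

## Numerical choices and degenerate inputs

- Threshold comparisons are strict; the flip-scan utility that recovers the
  boundaries rounds its ratio grid to 12 decimals so that grid points like
  1.2 are exact at the printed precision.
- Cells whose cytoplasm mean is ≤ 0 after background subtraction are dropped
  from measurement with a logged count, never silently.
- Zero-cell wells report percent = NaN with a warning, never 0.
- Constant (zero-variance) images segment to an empty mask with a warning.
- CSV outputs use '.' decimal separators, a stable column order, and embed
  the package version, seed and a sha256 configuration hash as `#` header
  lines; all file writes are atomic (temp file + rename).

## Validation problem sizes

The validation suite (`hcsquant.validation`, exercised by
`scripts/acceptance.py` and the end-to-end tests) uses: five wells of 47
fields (~6,000 measured cells each) for translocation recovery across
activated fractions 0.1–0.9 (observed error ≲ 1 percentage point against a
±5-point qualification band); one 47-field well at infected fraction 0.5
for infection recovery (±3-point band); 50 fields for nucleus-count
fidelity (±2% band); 1,000 null repeats at 500 cells/well for chi-square
type-I calibration ([3%, 7%] band at α = 0.05); 200 repeats of 6-vs-6 donor
groups at ~40% vs ~85% for Mann–Whitney power (≥ 95% band); and two full
CLI runs of a small plate byte-compared for determinism. These sizes give
binomial/Monte-Carlo error comfortably inside each band while keeping a full
validation run around half a minute on one CPU.

## Known limitations

- The perinuclear ring under-represents thin cytoplasm far from the nucleus;
  with strong cytoplasmic gradients the ratio is a local, not whole-cell,
  quantity.
- The watershed split handles pairs of touching round nuclei, not dense
  clusters; the pipeline is qualified for non-clumped fields.
- The exact Mann–Whitney path is O(C(n, n₁)) and is capped at combined
  n = 12 before switching to the asymptotic test.
- Donor-specific biological percentages from any particular published screen
  are not reproducible without the original microscope images; validation is
  against simulator ground truth only.
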