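# Methods

## Perimeter profiling

A fiber is represented by a simple closed polygon (≥ 8 vertices) in (x, y)
pixel coordinates plus one raster per channel. Profiles sample the boundary
every `sampling_step_px` (default 1 px) of arc length; arc positions are
fractions of the total perimeter in [0, 1), counterclockwise from the first
vertex. At each sample the reported intensity is the channel mean over a
band extending `band_depth_px` (default 10 px) along the inward normal,
evaluated by bilinear interpolation at one point per pixel of depth. The
inward normal comes from the central-difference tangent of the densely
resampled boundary, which behaves like an angle-bisector normal at polygon
vertices and is stable on irregular outlines. Band averaging (rather than
sampling the boundary curve itself) is a deliberate choice: both myonuclei
and deficiency foci occupy the subsarcolemmal compartment, not the
one-pixel boundary line. A band that would leave the raster is clipped to
the raster with a warning.

Section background is the **modal unsaturated intensity** of the channel
raster: the argmax of a histogram with 1-intensity-unit bins over pixels
strictly below `saturation_level`, ties broken toward the lowest value.
Corrected intensities are `max(raw − background, 0)`; flooring at zero
makes the correction idempotent (the corrected raster's mode is 0).
Line scans ("plot profile" transects) use the same bilinear interpolation
at `ceil(length) + 1` unit-spaced points.

## Domain annotation

Perinuclear domains are perimeter samples whose corrected DAPI intensity
is **strictly greater than** the cohort threshold: the `quantile_q`
(default 0.85) quantile, linear-interpolation definition, of corrected
DAPI pooled over *every sample of every fiber* in the cohort. Pooling
across patients is the default; a per-patient threshold can be obtained by
calling `cohort_dapi_threshold` per subset. By construction the cohort-wide
perinuclear fraction is then ≈ 1 − q of pooled samples, concentrated into
runs around nuclei.

Focal deficiency is taken verbatim from manual interval annotations when
provided. The automated surrogate flags samples where
`MTCOI/(SDHA+ε) < deficiency_fraction × median ratio` (default 0.5) **and**
SDHA exceeds its fiber median — deficiency must co-occur with preserved or
elevated mitochondrial mass, mirroring the COX-negative/SDH-positive
criterion. All masks are circular: runs merge across the arc origin, and
runs shorter than `min_run` samples (default 3) are suppressed as noise.

Whole fibers are classed fully COX-deficient at ≥ 95% deficient coverage,
carry a focus when the deficient fraction is strictly between 0 and 0.5 in
an otherwise positive fiber, and are intermediate in between. Prevalence
summaries report counts, percentages and "1:x" ratios (undefined when no
focus exists).

## Overlap statistic

Per fiber, P, F and O_obs are the means of the perinuclear mask, the focal
mask, and their AND; these identities are enforced by construction, so
O_obs ≤ min(P, F) always. The independence null is the multiplication rule
O_pred = P × F, computed per fiber from that fiber's own fractions. The
cohort test is a one-sample t on the differences O_pred − O_obs, one-tailed
in the direction diff < 0 (a flag flips it). Cohort aggregate fractions
are emitted both as the unweighted mean of per-fiber fractions and as
perimeter-length-weighted pooled fractions; the weighted version is the
headline because longer perimeters contribute more annotated samples. Both
`mean(P_i F_i)` (the per-fiber O_pred mean) and `mean(P)·mean(F)` are
recoverable from the outputs. A cohort whose diffs are constant and
non-zero returns p = 1 with a warning instead of raising; an all-zero
cohort returns t = 0, p = 0.5.

Calibration note: the per-fiber diff distribution is left-skewed (a focus
occasionally lands entirely inside a perinuclear run), so at n = 74 the
one-tailed t test is mildly conservative under the uniform-placement null —
simulated type-I error sits near 3–5% at nominal 5%, within the expected
2–10% band, and power under full enrichment is effectively 1.

## Synthetic fiber sections

Geometry: perturbed-ellipse polygons — a circle of radius
`fiber_radius_px` (default 60 px, per-fiber jitter ±10%) with low-order
radial harmonics (orders 2–5, amplitudes up to jitter/4), 192 vertices.
This is a generic "convex-ish irregular cross-section"; no claim of
histological realism. 1–5 nuclei per fiber are placed uniformly on the
perimeter and rendered as 2-D Gaussian DAPI blobs (σ = 5 px, amplitude
400, centered 5 px inside the boundary). At most one focus per fiber
(probability `foci_per_fiber_prob`, default 1): a contiguous perimeter arc
of `focus_arc_fraction` (default 0.2 of the perimeter) restricted to a
10 px subsarcolemmal band, in which SDHA is multiplied by
`sdha_focus_fold` (default 3.3) and MTCOI by `mtcoi_focus_atten` (default
0.1) relative to the in-fiber baselines (100 each). With probability
`enrichment_rho` the focus center coincides with a nucleus position;
otherwise it is uniform, which is exactly the independence null the
overlap statistic targets. Per-channel additive background (default 40)
and Gaussian noise (default σ = 2) are applied, then values are rounded
and clipped to the unsigned-16-bit saturation level. All randomness flows
through one `numpy` Generator seeded from `seed`, so output is
bit-identical per seed.

What the generator does **not** emulate: point-spread function, uneven
illumination, autofluorescence texture, fiber-to-fiber contact (each fiber
gets its own raster), intermyofibrillar signal structure, or serial
sections. Passing tests therefore demonstrate correctness of the
*measurement pipeline* under controlled conditions, not robustness to
every real-microscopy artifact; the manual-annotation escape hatch exists
for data where the automated deficiency rule is inadequate.

## Synthetic qPCR

Cq values are generated as `intercept + slope·log₁₀(copies) + N(0, σ)`
in triplicate, with a five-point plasmid dilution series (10⁶…10² copies)
per target and no-template controls. The default true slope −3.3834
corresponds to 97.5% amplification efficiency — inside the 95–100%
plate-inclusion gate, as a well-optimized assay would be; replicate noise
defaults to 0.1 cycles; zero template yields no amplification (NaN Cq).
Region ground truth places one focus and two matched COX-positive
subsarcolemmal regions per fiber: matched copy numbers share a per-fiber
lognormal scale (σ = 0.4 between fibers, 0.05 within), and focus
elevations are lognormal with mean fold 2.2 (D-Loop) and 2.5 (ND1)
(σ = 0.25, mean-corrected). Deletion levels are clipped normals — foci
80 ± 10%, matched regions 30 ± 10% — and ND4 copies are derived as
ND1 × (1 − deletion/100), so ND4 ≤ ND1 by construction. Whole-fiber
control groups (8 per arm) use a 20× copy scale and a 1.9-fold
deficient-vs-positive elevation.

## qPCR quantification conventions

Replicate Cq values are **averaged before** the log-linear inversion
(per-replicate quantification is available by calling `quantify_copies`
directly). Efficiency is 10^(−1/slope) − 1; the QC band is [0.95, 1.00]
with a 10⁻⁴ numerical allowance at the upper edge only, so a slope quoted
to printed precision (−3.3219) still reads as 100%. A failed curve blocks
quantification unless explicitly overridden. The NTC gate excludes an
entire fiber group when *any* of its regions has mean ND1 Cq above
NTC − 3 cycles; a sentinel (never-amplifying) NTC passes any region that
itself amplified. Copy numbers are per-region densities — regions are
dissected at matched size, so no area normalization is applied (an area
column is accepted but unused). Deletion level is (1 − ND4/ND1) × 100
clipped to [0, 100] and is undefined (NaN, flagged) at ND1 = 0; the raw
ND4/ND1 and D-Loop/ND1 ratios are both emitted. Paired analysis reports
fold = focus / mean(matched) per metric with a two-tailed paired t on the
within-fiber differences, and two-tailed unpaired t for the whole-fiber
groups.

## Statistics

All tests wrap scipy.stats: one-sample/paired/unpaired t, Mann–Whitney U
(exact null for min(n) ≤ 8 without ties, otherwise normal approximation
with average ranks, tie-corrected variance and continuity correction), and
the exact two-sided binomial test against 0.5 (minlike convention — the
method behind the "Wilson/Brown" label in common graphing software).
Zero-variance inputs return flagged degenerate results instead of NaNs.
No multiple-testing correction is applied anywhere.

## Problem sizes

The simulation-based checks run 200 null cohorts of 74 fibers for
calibration of the overlap test, two full-enrichment cohorts for power,
27 focus/matched-pair plates for fold-change recovery, and a 40-fiber
noise-free cohort for detection fidelity — sizes chosen to match the
study design they emulate (74 profiled fibers; 27 qPCR pairs) while
keeping the whole suite comfortably reproducible on a single CPU.

## Known limitations

* The automated deficiency rule assumes a roughly bimodal MTCOI/SDHA ratio
  along the perimeter; fibers that are globally intermediate need manual
  annotation.
* The cohort quantile threshold ties the cohort-wide perinuclear fraction
  to 1 − q; P is therefore not an independent estimate of nuclear coverage
  but a standardized operational definition.
* Overlap inference treats fibers as independent; serial sections of the
  same fiber would violate this and are not modelled.
* The deletion metric saturates at 0 and 100 and inherits any D-Loop
  triplex artifact only through the separate ratio flag.
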