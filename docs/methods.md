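# Methods

## Segmentation model

A slice is partitioned by combining fixed HU windows with compartment
geometry. The body mask is the largest connected component above −200 HU
with interior holes filled; its boundary is the skin. Muscle candidates are
body pixels in the muscle window [−29, 150] HU; components smaller than
`min_muscle_mm2` (default 20 mm², smaller than any real muscle
cross-section at these levels) are treated as speckle. A morphological
closing with a disk of `closing_mm` (default 3 mm, converted to pixels via
the spacing) bridges gaps between muscle groups; the largest closed
component is the muscle wall, its filled outline the outer muscle contour.
SAT is then SAT-window fat strictly outside that contour, VAT is VAT-window
fat strictly inside the wall's interior cavity, and everything else —
including bone (> 150 HU) and parenchymal organs — is "other". The SAT
and VAT windows overlap in [−150, −50]; the compartment, never the HU,
selects which window applies. Window bounds are inclusive on both ends,
which makes integer-HU fixtures unambiguous. Interior fat whose HU falls in
the SAT-only bands ([−190, −151] or [−49, −30]) is labeled "other", not
VAT.

Two refinements are this module's own design decisions where the region
definitions alone underdetermine an algorithm:

* **Wall connectivity.** Only candidate components connected to the muscle
  wall become muscle. Enhancing organs have boundary voxels whose
  partial-volume HU passes through the muscle window; these form closed
  halo bands inside the visceral cavity that a pure threshold rule would
  call muscle. Discarding wall-disconnected components keeps parenchymal
  organs (and their halos) out of every region of interest, which is also
  what manual review enforces in clinical practice.
* **Closing-artifact reclamation.** Closing a rasterized ring fills
  single-pixel notches along the cavity's stair-stepped boundary. Added
  components that touch only the interior cavity are returned to the
  cavity (so boundary visceral fat is not silently eaten); genuine bridge
  pixels, which touch the outer region as well, stay part of the
  compartment boundary.

The upstream clinical workflow used a trained network plus radiologist
correction; this package deliberately re-implements only the stated
threshold-and-compartment *definitions* with classical morphology, so its
outputs are a transparent reference, not a clone of any learned model.

## Measurement

Area = labeled-pixel count × row spacing × column spacing / 100 (mm² →
cm²), i.e. pixel-center counting with no sub-pixel contour integration —
the convention under which threshold masks are universally measured.
Density = arithmetic mean HU of the labeled pixels; an empty tissue has an
*absent* density, never 0 HU, since 0 HU is a legal density. Height-indexed
variants (e.g. SMI = SMA / height²) are provided as a plain function.

## Phase and level harmonization

The conversion table stores, per (level, parameter, phase), the relative
area (unenhanced = 100) or the additive density shift (unenhanced = 0),
exactly as published — the table is data, not a fit of this package.
Conversion to unenhanced is `value × 100 / relative` for areas and
`value − offset` for densities; phase 0 is an exact identity (short-
circuited so no floating-point division can perturb it); conversion between
two enhanced phases composes through phase 0. Displayed conversions round
to one decimal; chained computation keeps full precision.

Level linkage is a one-parameter regression through the origin, y = βx
with x = L3, y = L1: β = Σxy/Σx², se(β) = √(RSS/(n−1)/Σx²), 95% CI from
the t distribution with n−1 df. R² is uncentered (1 − RSS/Σy²), the
standard definition for no-intercept models; it is systematically higher
than, and not comparable to, the centered R² of a model with an intercept.
The fit is verified in the tests against an exhaustive grid search with
step 10⁻⁶.

## Statistics

Paired phase comparisons use the Wilcoxon signed-rank test, implemented in
the package because its exact conventions matter: zero differences are
dropped (the classical convention), tied magnitudes get average ranks, and
for n ≤ 25 the two-sided p is exact — computed by dynamic programming over
achievable rank sums (doubling ranks keeps tie-averaged ranks integral),
which equals literal enumeration of all 2ⁿ sign assignments and is verified
against such enumeration in the tests. Above n = 25 a normal approximation
with tie-corrected variance and continuity correction is used; the two
methods agree within 0.01 in p at n = 20 across 100 seeded samples.
Level correlations use Spearman's ρ via scipy. Change summaries report
per-subject percent change for areas (defined only for positive baselines)
and absolute HU change for densities, with Tukey box-plot statistics
(median, quartiles, 1.5·IQR whiskers, mean). Pairwise p-values are reported
raw, without multiple-testing correction, and the report notes this.

The `replicate` pipeline runs segmentation → measurement → summaries, all
ten phase-pair tests per parameter and level, and per-parameter/phase level
regressions over a cohort directory; per-slice failures go to an error
ledger and the run aborts only if more than 10% of slices fail.

## The synthetic phantom

Each subject is a 2D scene per vertebral level: an elliptical body whose
nested compartments (subcutaneous fat ring ≈ 200 cm², muscle ring ≈ 80 cm²,
visceral interior ≈ 210 cm² minus 2–4 elliptical organs) are sized from
canonical areas with per-subject lognormal variation (radius sd 6%) and a
per-subject aspect ratio ≈ 0.72. Tissue HU is a frozen per-pixel Gaussian
texture (muscle 45 ± 6, subcutaneous fat −100 ± 8, visceral fat −92 ± 8 HU)
plus a per-subject density shift (sd 4 HU, shared across levels and
phases), plus a per-(tissue, phase) additive enhancement offset, plus fresh
per-phase noise (sd 5 HU), followed by a Gaussian blur of sigma 1 mm
standing in for the scanner's effective in-plane and through-plane partial
volume. Truth masks are recorded before blur and are identical across
phases.

Key modeling choices:

* **Enhancement offsets** default to the published L3 density shifts
  (muscle +2.1/+5.8/+7.8/+9.6; subcutaneous fat +1.2/+3.7/+4.8/+6.2;
  visceral fat +1.5/+4.1/+5.2/+6.1 HU for phases 1–4), so density-change
  recovery has a known target.
* **Organs** enhance from 160 to 310 HU across phases — always above the
  muscle ceiling of 150 HU, so the windows exclude parenchyma outright,
  standing in for the clinical guarantee that no organs enter the regions
  of interest. Only the organs' blurred boundary interacts with the fat
  windows: as organs brighten, the halo band whose blend exceeds −50 HU
  widens and measured VATA falls. Area change is thus *emergent*
  (threshold + blur + enhancement), never injected, which is why the
  package claims only its direction, not its magnitude.
* **Partial-volume rendering.** With blur on, per-pixel tissue means are
  coverage-weighted mixtures from a 4× supersampled rasterization, so
  boundary pixels take continuous sub-pixel blend values the way a real
  detector integrates them. (Binary pixel-center rasterization quantizes
  edge values away from the thresholds and suppresses the threshold-
  crossing behavior that drives area change.) With `blur_sigma = 0` the
  scene is rendered sharp and piecewise constant, giving exact no-noise
  identities for testing.
* **L1 scenes** are the same subject's L3 geometry scaled per parameter
  (defaults: SMA 0.80, SATA 0.70, VATA 0.85 on areas; 1.05/1.00/1.00 on
  muscle/fat baseline densities) with subject-level lognormal jitter
  (sd 3%), so the through-origin L3→L1 slope has a known generating value.
* One seeded `numpy` generator, threaded explicitly, produces every draw;
  no global random state is touched.

What the phantom does *not* emulate: real muscle-group anatomy
(discontinuous muscles, fascia), bone, bowel gas, beam hardening or
reconstruction kernels, inter-phase patient motion, and the true magnitude
of contrast-induced area change. Passing tests therefore demonstrate that
the pipeline's machinery is correct and directionally faithful, not that
real-cohort area-change magnitudes are reproduced — reproducing those would
require the original image data.

## Problem sizes and numerical choices

Validation cohorts use 20 subjects at 320 × 320 px, 1.25 mm spacing (400 mm
field of view); the slope-recovery replicate study uses 100 seeded cohorts
of 8 subjects at 160 × 160 px, 2.5 mm spacing, a grid where measured areas
remain accurate while 100 end-to-end replicates stay desk-scale. At the
default noise and blur, segmentation Dice against truth exceeds 0.95 for
all three tissues; injected density shifts are recovered within 0.5 HU
(blur off) because interior pixels sit many standard deviations from every
window edge, making threshold truncation bias negligible. Records
serialize at 0.01 cm²/0.01 HU precision, the round-trip tolerance the CSV
layer guarantees.

## Known limitations

* The through-origin CI assumes homoscedastic residuals; the generator's
  multiplicative level jitter makes residuals grow with x, so CI coverage
  on measured data runs slightly below nominal (≈ 92/100 in the seeded
  replicate study) — adequate, but a weighted fit would be preferable if
  residual structure mattered downstream.
* Wall connectivity assumes one dominant muscle ring; pathologies that
  split the wall into distant fragments would need a larger closing radius
  or would flag the slice as a segmentation failure (which is the intended
  failure mode, never a silent fat-only labeling).
* DICOM support is deliberately minimal: single-frame reads with rescale
  applied; no series assembly or PACS access.
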