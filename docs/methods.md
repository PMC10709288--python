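# Methods

## Scope

`dgecest` implements desk-scale postprocessing for glucose-enhanced CEST
MRI at 3 T: static glucoCEST mapping from full Z-spectra and dynamic DGE
mapping from interleaved two-offset time series, together with a synthetic
phantom/acquisition simulator that makes every stage verifiable against
known ground truth.  Acquisition (sequence design, k-space readout),
tissue segmentation of real anatomical images, and exchange-level
(Bloch–McConnell) simulation are out of scope.

## Z-spectrum model

All spectra are modeled as sums of Lorentzian saturation pools on the
normalized signal,

    Z(w) = 1 - sum_i A_i (G_i/2)^2 / ((G_i/2)^2 + (w - c_i - d)^2),

with amplitude `A_i` (fraction of S0), FWHM `G_i` (ppm), pool center `c_i`
(ppm from water) and voxel B0 shift `d` (ppm).  This is the standard CEST
parameterization; with `sum A_i <= 1` the model stays in [0, 1].

The simulator's tissue classes carry a direct-water-saturation (DS) pool
and, except CSF, a broad magnetization-transfer (MT) pool fixed at 0 ppm
with 25-ppm width.  Defaults (amplitude / FWHM in ppm): WM 0.85/3.2 +
MT 0.09, GM 0.87/3.0 + MT 0.05, CSF 0.94/2.0, sagittal sinus 0.90/2.8 +
MT 0.02, tumor 0.88/2.6 + MT 0.03.  These are plausible 3-T values chosen
once for the phantom; none of the analysis code depends on them.

## Glucose pool and calibration

Dissolved glucose is modeled as one hydroxyl pool at +1.2 ppm with 1.6-ppm
FWHM whose amplitude is linear in concentration.  The per-mM amplitude is
solved numerically so that a 10-mM increase reduces Z at 2 ppm by exactly
2%, anchoring the simulator's scale to the phantom-study effect size; the
resulting sensitivity is 0.002 per mM at 2 ppm (and 0.004 per mM at
1.2 ppm, the pool center).  Because pools are additive, ground-truth
contrast is exactly linear in concentration, which the tests exploit.

## Bolus kinetics

The venous concentration increase rises piecewise-linearly from the start
of the infusion (duration 200 s = 50 mL at 0.25 mL/s) plus a 100-s
circulation/mixing lag — so the venous peak falls 300 s (5 min) after
infusion start — and then clears exponentially with a 900-s half-life
(venous levels plateau rather than drop on the 10-min horizon).  Tissue
curves are delayed, scaled copies of the venous curve (defaults: sinus
scale 1.0/no delay, GM 0.15/25 s, WM 0.08/30 s, CSF 0.20/40 s, tumor
0.5/20 s).  With the default 8-mM bolus the sinus ground-truth DGE at
2 ppm is roughly 0.5% during infusion and 1.3–1.4% in the two
post-infusion blocks.  The pre-infusion baseline duration is a free
parameter (default 180 s).

## B0 shift mapping

Per voxel, a bounded trust-region least-squares fit of the Z-spectrum is
performed on the offsets in [-1, 1] ppm plus the |w| > 10 ppm wings.  The
model is multi-pool: DS (free amplitude, width, center), MT (fixed at
0 ppm, free amplitude and width), and by default a hydroxyl pool riding
1.2 ppm above the fitted water center with fixed 1.6-ppm width and free
amplitude.  The hydroxyl term matters for post-infusion scans: the glucose
signal's tail inside the ±1-ppm window otherwise drags the fitted water
center upfield by ~0.02 ppm, which propagates into a several-tenths-of-a-
percent error in glucoCEST at 2 ppm.  A strict two-pool variant is
available (`solute_pool=False`).  The fitted water+MT curve (the water
lineshape, excluding solute pools) is evaluated on a uniform grid over
±1 ppm with step 0.0078 ppm (1 Hz at 127.7 MHz, rounded to two significant
figures) and the grid argmin is the B0 shift; exact ties resolve to the
smallest absolute shift, which is unbiased toward zero.  Initialization:
DS (0.9, 2 ppm, raw-spectrum minimum), MT (0.1, 25 ppm), hydroxyl 0.
Voxels whose fit fails carry shift 0 and a per-voxel quality flag; more
than 5% failures raises a warning.

## B0 correction of static spectra

Each voxel's measured spectrum is treated as piecewise-linear in offset
and resampled at the nominal offsets shifted by the voxel's B0 estimate,
referencing the spectrum to the true water frequency.  Shifted sample
positions outside the measured range are left unchanged and counted.
Linear resampling is exact for locally linear spectra; for the calibrated
glucose pool its curvature error at 2 ppm stays below 0.1% of S0 for
shifts up to 0.2 ppm, which bounds the static round-trip error.

## Two-pool amplitude fitting and glucoCEST

On B0-corrected spectra a two-pool fit (DS + MT, centers fixed at 0 ppm,
amplitudes and widths free) is run on the same offset subset, yielding the
amplitude maps used to monitor DS/MT changes.  glucoCEST is the voxel-wise
baseline-minus-postinfusion Z difference at a requested offset (1.2 or
2 ppm).  Values are stored as fractions of S0 and rendered x100 in
reports.

## Dynamic pipeline

Frames are aligned to the second saturation frame (rigid registration),
normalized by the last leading 300-ppm reference image, and split into the
1.2- and 2-ppm series.  Dynamic B0 correction interpolates the baseline
and post-infusion static B0 maps linearly in time at each interleaved-pair
time (the mean of the pair's two frame times), then treats the pair's two
measurements as samples of the local spectrum at true offsets
(1.2 - d, 2.0 - d) and evaluates the line through them at the nominal
offsets.  This two-point linear spectral model is the minimal scheme
consistent with using two consecutive images plus an interpolated shift;
it is exact for affine spectra and leaves a first-order residual
proportional to the mismatch between the local secant and tangent of the
Z-spectrum — see Limitations.

PCA denoising arranges in-mask voxels x time, removes each voxel's
temporal mean, and reconstructs from the first three right-singular
(temporal) directions, reporting cumulative explained variance.  Per-voxel
mean centering preserves the DC level that the DGE difference removes.
PCA runs per offset series by default (DGE is computed per offset); a
joint mode over both series is available.  Three components is the default
empirical trade-off; the optimum may vary per data set, so the count is a
parameter.

DGE(t) is the voxel-wise difference between the pre-infusion mean S/S0
and S/S0(t); block means average DGE over four windows relative to the
infusion start: baseline, [0, 200) s (during infusion), [200, 400) s and
[400, 600) s, using half-open intervals so frames acquired during the
infusion belong to the infusion block.  Frames beyond the last block are
excluded and counted.

## Motion correction

Rigid registration maximizes normalized cross-correlation (insensitive to
the global intensity drop during saturation) with a Nelder–Mead simplex
from three translation starts; rotation (Euler angles about the volume
center) is optional, translation-only is the default.  Resampling is
trilinear with zero fill; the reference frame is passed through untouched.
Recovery of simulated translations, not agreement with any particular
registration package, is the test surface.

## ROI statistics

ROI means/SDs are taken over in-mask, non-missing voxels (missing counts
reported).  Group comparisons use two-sided one-sample and paired t-tests
(`t = mean/(sd/sqrt(n))`, dof `n-1`) at alpha = 0.05 with no
multiple-testing correction by default (a Bonferroni helper exists but is
off), operating on per-subject ROI summary values.  Exactly identical
paired samples raise a zero-variance error rather than returning t = 0.

## Synthetic data: what it does and does not emulate

The default phantom is a 32 x 32 x 8 head: WM core, GM shell, central CSF
compartment, and a small posterior sagittal-sinus cylinder (~48 voxels);
reference intensities differ per tissue.  The B0 field is a fixed
second-order polynomial scaled to a ±0.2-ppm peak, optionally drifting
linearly in time; noise is additive Gaussian on S/S0 (no Rician/magnitude
bias — at the simulated SNRs the distinction is negligible); motion is
per-frame rigid translation.  Not emulated: exchange dynamics and
saturation-power dependence, B1 inhomogeneity, physiological noise and
pulsation, partial-volume mixing at tissue borders, readout artifacts.
Passing tests therefore demonstrate correctness of the processing
algebra and recovery under the modeled degradations, not in-vivo
performance.

## Problem sizes and study conditions used by the tests

Static round trips run on the default 32 x 32 x 8 grid (noiseless, 10-mM
uniform increase, ±0.2-ppm field).  Dynamic recovery uses the volunteer
protocol (128 interleaved time points, 7.2 s per image), Gaussian noise
sigma = 0.002 on S/S0, and a linear drift reaching 0.05 ppm at the end of
the ~15-min scan — the upper end of reported 3-T frequency drift for
scans of this length; endpoint B0 maps come from fitting simulated static
scans at the start and end of the session.  Several unit tests use reduced
grids (down to 20 x 20 x 5) where only algebraic properties are at stake.

## Known limitations

- The two-point dynamic B0 correction leaves a residual proportional to
  the spectrum's curvature between 1.2 and 2 ppm.  Under the 0.05-ppm
  drift condition this biases late-block DGE by roughly -10 to -20% of the
  (small, ~1%) sinus truth even with exact B0 inputs; the correction still
  removes >50% of the drift artifact RMSE (and ~3x in map RMSE against no
  correction).  During-infusion block means are additionally shrunk a few
  percent by PCA when a tissue's temporal signature (the venous rise) is
  rare in the voxel population, so the recovered during-infusion sinus
  mean can sit just past 25% below truth.  Both effects are properties of
  the method under these conditions, not of the implementation; the
  acceptance suite documents them quantitatively.
- B0 mapping assumes the water minimum lies within ±1 ppm (configurable
  window) and shares one fit subset across tissues.
- The simulator's glucose pool is offset-additive; exchange-mediated
  saturation-power dependence and concomitant MT/DS changes during
  infusion (a candidate cause of negative in-vivo glucoCEST) are not
  modeled, so the simulator cannot reproduce negative-contrast scenarios.
- Registration is intensity-based and rigid; it is exercised on simulated
  translations only and makes no claim of equivalence to any specific
  neuroimaging registration tool.
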