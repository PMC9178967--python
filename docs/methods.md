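# Methods

This note documents the models implemented in `wmh_penumbra`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Multi-echo T2 relaxometry

**Signal model.** A voxel's multi-echo spin-echo decay is modelled as a
non-negative superposition of single-T2 decays over a logarithmic grid of
40 T2 values from 10 ms to 2000 ms. Each basis curve is generated with the
extended phase graph (EPG) algorithm: the transverse configuration states
F(k) and phase-stored longitudinal states are propagated through the
refocusing train (excitation 90°, refocusing pulses of a common flip angle
α on the CPMG axis, one crusher-dephasing unit per half echo-spacing), with
T2 decay on transverse states and T1 decay (T1 = 1000 ms assumed; estimates
are insensitive to T1 at these repetition times) on stored states. At
α = 180° the basis reduces exactly to `exp(−nΔTE/T2)`; at lower angles
stimulated-echo pathways redistribute signal along the train, which is the
effect the correction exists for. The implementation is validated against
an independent Bloch rotation-matrix isochromat ensemble to 10⁻³ per echo
and against the closed form at 180° to 10⁻¹². Echo amplitudes are reported
as magnitudes, matching magnitude image reconstruction.

**Flip-angle estimation.** The refocusing angle is unknown per voxel (B1
inhomogeneity). It is estimated by scanning 90°–180° in 2° steps,
computing the unregularized NNLS residual against a coarse 8-bin basis at
each angle, and refining the minimum by parabolic interpolation. A flat
residual profile (no signal) returns 180° flagged low-confidence. For the
final spectrum the refined angle is quantized to 0.25° so the full-grid
basis can be cached across voxels; the quantization is far below the
~1–1.5° estimation noise floor.

**Spectrum fit.** `min ‖Aa − y‖² + μ‖a‖², a ≥ 0`, with μ found by
bisection so the data misfit χ²(μ) lands in [1.02, 1.025] × χ²_min, where
χ²_min comes from the unregularized fit (both factors configurable). When
χ²_min is below 10⁻⁶ of the signal energy (essentially noiseless data —
an off-grid two-pool signal leaves only ~10⁻⁸ relative residual on this
grid) the window is unattainable and μ = 0 is returned with a log notice.

**Metrics.** MWF is the spectral amplitude sum over 10 ≤ T2 ≤ 40 ms divided
by the total; GMT2 is the amplitude-weighted mean of ln T2 over
40 ≤ T2 ≤ 200 ms, exponentiated. Both windows are closed intervals; the
default grid places no bin at exactly 40 ms, so the windows never share a
bin. A zero-amplitude (sub)spectrum yields NaN, not 0. Both metrics are
exactly invariant to overall signal scale.

**Known bias.** χ²-window energy regularization smears the myelin peak
across the 40 ms boundary. At SNR 200 (SNR = S₀/σ, Rician noise, no bias
correction before fitting — a deliberate simplification, documented
limitation) this produces a systematic MWF underestimate of ≈ 0.02–0.03,
growing with the true myelin fraction; the median |ΔMWF| over voxels with
MWF ~ U(0, 0.3) is ≈ 0.03, versus ≈ 0.018 for the unregularized fit. GMT2
(median error ≈ 3 ms) and the flip angle (≈ 1.3°) are essentially
unbiased. Group comparisons and spatial gradients, which difference this
bias away, are unaffected; absolute MWF levels should be interpreted with
it in mind.

## Diffusion tensor metrics

Tensors are fit in log-signal space by ordinary least squares followed by
one weighted pass with weights equal to the squared predicted signal (the
standard correction for log-transform heteroscedasticity). Non-positive
signals are floored at machine tiny; collinear gradient schemes are
rejected. Negative eigenvalues of noisy fits are clamped to zero for FA/MD
with a per-volume count, matching common practice. FA uses
`√(3/2)·‖λ − λ̄‖/‖λ‖` (defined as 0 for a zero tensor), MD is tr D/3.
Noiseless round trips through the simulator recover tensors to 10⁻⁹; FA
and MD are invariant under joint rotation of tensor and gradient table.

## Perilesional ROI geometry

Distances are Euclidean, between voxel centers, in physical millimetres
(anisotropic voxel dimensions respected), computed with an exact distance
transform and verified against an O(N·M) brute-force oracle. Construction
order: (1) NAWM and WMH are trimmed by exclusion guards — CSF dilated 1 mm,
stroke lesions dilated 10 mm; (2) ring k (k = 1..5) collects kept NAWM
voxels with WMH distance in (2(k−1), 2k] — half-open, so a voxel exactly on
a boundary belongs to the inner ring once. WMH connected components use
26-connectivity, and a component is periventricular iff any voxel is
26-adjacent to ventricular CSF ("touching in 3-D"); corner-only contact
counts, a convention the tests pin down explicitly. ROI means ignore
non-finite voxels and rows with zero finite voxels are dropped with a log
entry. The hemisphere split intersects each ROI with a sagittal half-space
and refuses bilateral-stroke subjects, for whom ipsi/contralesional is
undefined.

## Mixed-effects models

One model per metric (FA, MD, MWF, GMT2 as outcome), three families:

1. **distance × group**: fixed effects age, MoCA (both group-mean-centered
   and scaled to unit SD), distance as *orthogonal polynomial* linear +
   quadratic contrasts over the six ordered levels (WMH, 2, 4, 6, 8,
   10 mm), group (stroke = reference), and distance × group; random
   intercepts for scanner and for participant nested within scanner.
   The headline "distance" term is the quadratic column, the shape the
   penumbra is expected to take; the linear column is always estimated and
   reported alongside.
2. **distance × hemisphere**: the same structure within unilateral-stroke
   subjects, hemisphere (ipsilesional = reference) varying within subject.
3. **lesion burden**: WMH-ROI metric on age + MoCA + log WMH volume
   (natural log — the base is a package decision), scanner random
   intercept only (no repeated measures).

Estimation is REML via statsmodels `MixedLM`, with the outcome internally
scaled to unit variance for optimizer health (MD is ~10⁻³ in physical
units) and estimates rescaled afterwards. Reported p-values are Wald tests
as MixedLM provides them; a Satterthwaite small-sample correction is not
available in this backend, and at the row counts involved (≥ ~100 rows per
repeated-measures fit) the difference is small — the programmed-null
simulation below checks the realized type-I rate directly. A fit that
defeats every optimizer (degenerate tiny designs) falls back to OLS and is
flagged non-converged, never silently reported. An independent lme4 fit of
the same model on the same data agrees with the fixed effects to ~10⁻³
(cross-checked in the test suite).

Post hoc pairwise contrasts are model-based cell-mean differences with the
Tukey HSD (studentized-range) adjustment: q = |Δ|/SE(Δ)·√2 referred to the
studentized-range distribution with the family's cell-mean count (6 for
the distance family, 12 for the interaction family of
within-group-across-distance plus between-group-within-distance
contrasts) and residual degrees of freedom. Adjusted p-values are floored
at the raw p.

## The phantom: what it emulates, and what it does not

Geometry is deliberately schematic: an ellipsoidal brain with a sulcal-CSF
rim and grey-matter shell, two lateral ventricles, spherical WMH blobs
(periventricular blobs seeded on the ventricular surface with guaranteed
face contact; deep blobs ≥ 2 mm away), and an optional one-hemisphere
stroke lesion. Voxel grids of 32³–48³ at 1–2 mm keep every study desk-sized.

Programmed structure, with defaults:

* **Penumbra profile** `value(d) = baseline + (lesion − baseline)·max(0, 1 − d/reach)^shape`
  with reach 6 mm and quadratic shape — elevated out to ~4 mm, back to
  baseline well before 10 mm. Applied to IE T2 (80 → ~100 ms), MD
  (0.75 → ~1.1 ×10⁻³ mm²/s) and, inverted, FA (0.45 → 0.30). The FA
  endpoints are fixed package constants; the profile family is shared.
* **Myelin**: MWF is flat (0.10) across NAWM in both groups; inside the
  WMH it is reduced only in the stroke-like group. The deficit deepens
  with lesion burden: WMF_WMH = clip(0.093 − 0.022·z, 0.02, 0.0995) where
  z is the standardized log WMH volume. These values were set by a power
  analysis of the lesion-burden model at the cohort sizes the package
  studies: the stroke-only coupling plus group-standardized predictor
  caps the attainable t-statistic (slope·range is bounded by the
  physiological MWF span, and the group gap itself inflates the residual),
  so gap ≈ 0.02 and slope ≈ 0.022/z balance contrast detectability against
  burden-model power.
* **Severity coupling**: lesion IE T2 and MD rise with z in both groups
  (+6 ms/z, +0.12×10⁻³/z), so fluid metrics track burden across the sample.
* **Cohort covariates**: WMH volumes are log-normal with group medians/IQRs
  patterned on published cohort demographics (older adults ≈ 0.35 mL,
  truncated below 10 mL per the usual exclusion rule; stroke ≈ 2.7 mL,
  truncated above 40 mL — untruncated draws occasionally produce
  physiologically absurd hundreds of millilitres). Ages are uniform 45–80;
  MoCA ≈ N(27, 2) / N(25, 3); scanners alternate within group; every third
  stroke subject is bilateral, the rest alternate left/right.
* **Acquisition**: two scanner configurations differing only in echo train
  (32 echoes @ 10 ms vs 48 @ 8 ms) and the noise draw; HARDI-like
  single-shell DWI, 60 Fibonacci-hemisphere directions at b = 700 s/mm²;
  Rician noise throughout (magnitude of complex Gaussian), echo SNR 200 and
  DWI SNR 40 at S₀. White matter tensors share a principal axis — adequate
  for FA/MD, which are rotation invariant.

Not emulated: realistic anatomy, partial-volume mixing at tissue borders,
registration error between modality spaces (all volumes share one grid —
real data must be resampled upstream), motion/eddy artifacts, any bias
field other than the refocusing flip angle (a smooth random-centered
quadratic over 110°–180°), and T1/FLAIR contrast. Passing tests therefore
demonstrate the *estimation and inference chain* is correct and well
calibrated under the stated noise model — not that it is robust to
real-world artifacts.

A table-level generator (`simulate_roi_table`) draws the long-format ROI
table directly — same profiles, severity coupling, scanner/subject random
intercepts — without image synthesis. It drives the statistical power and
type-I studies (200 replicates at reduced n = 10 + 8), where per-replicate
image synthesis would be pointless cost; the image pipeline and the table
generator produce the same layout, and the end-to-end study runs the full
image path.

## Problem sizes and numerical choices

The end-to-end cohort study uses 20 older-adult-like + 14 stroke-like
subjects on 36³ grids at 1.75 mm, one periventricular and one deep WMH per
subject (radius 3.6 mm). Relaxometry and tensor fitting are restricted to
tissue within 10.5 mm of the WMH — the analysis reads nothing outside the
WMH ROI and its 10 mm ring shell — which keeps a full cohort run to a few
minutes on one CPU; `fit_region_only = False` fits whole brains. Per-stage,
per-subject seeds derive from the master seed via `SeedSequence` spawning,
so any artifact regenerates independently and a fixed-seed run is
bit-reproducible (checksummed in `manifest.json`). Degenerate inputs are
policy, not accident: empty WMH masks raise (zero-lesion subjects are
excluded, as such participants are excluded from the real analysis), empty
rings are kept with a warning and dropped at extraction, all-zero signals
return zero spectra, and zero-variance predictors raise naming the
predictor.
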