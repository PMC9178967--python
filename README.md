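# wmh-penumbra

White matter hyperintensities (WMHs) — bright lesions on T2-weighted MRI of
presumed vascular origin — do not end at their visible border: the
surrounding *normal-appearing white matter* (NAWM) shows graded microstructural
change, a lesion "penumbra". This package is a tested, fully synthetic
re-implementation of the quantitative chain used to characterize that
penumbra with two complementary modalities:

* **Myelin water imaging** — multi-echo spin-echo T2 relaxometry. Each
  voxel's decay is inverted into a T2 spectrum *s*(T2) by regularized
  non-negative least squares over an extended-phase-graph (EPG) basis that
  corrects for stimulated echoes at imperfect refocusing flip angles. Two
  scalar metrics follow:

  - myelin water fraction, `MWF = (∫₁₀⁴⁰ s dT2) / (∫ s dT2)` — specific to
    myelin content;
  - intra/extracellular geometric mean T2,
    `GMT2 = exp( ∫₄₀²⁰⁰ s ln T2 dT2 / ∫₄₀²⁰⁰ s dT2 )` — sensitive to
    interstitial fluid.

* **Diffusion tensor imaging** — `S = S₀ exp(−b gᵀDg)` fit by two-pass
  weighted linear least squares, summarized as fractional anisotropy (FA)
  and mean diffusivity (MD = tr D / 3).

Around each WMH, five concentric 2 mm rings of NAWM (2–10 mm, Euclidean
distance between voxel centers, anisotropic voxels respected) are built
with 1 mm CSF and 10 mm stroke-lesion guard zones. Per-subject ring means
feed linear mixed-effects models — distance (orthogonal quadratic contrast)
× group, distance × hemisphere, and WMH-ROI metrics vs log lesion volume —
with age and MoCA as group-standardized covariates, a scanner random
intercept, participant nested within scanner, and Tukey (studentized-range)
post hoc contrasts.

Because no clinical data ship with the package, a first-class **phantom
module** generates everything the analysis consumes: label volumes
(ventricles, CSF rim, grey matter, NAWM, periventricular/deep WMH blobs,
optional stroke lesion), ground-truth parameter maps with a programmed
quadratic penumbra profile, EPG-simulated multi-echo and tensor-model DWI
signals with Rician noise, and cohort covariate tables. Every estimator can
therefore be validated against known truth.

## A worked example

Fit one two-pool voxel (15 % myelin water, IE pool at 80 ms, 140° actual
refocusing angle, SNR 200):

```bash
$ python examples/01_fit_t2_spectrum.py
estimated MWF        : 0.119   (true 0.150)
estimated GMT2       : 78.3 ms (true IE pool at 80 ms)
estimated flip angle : 145.3 deg (true 140.0)
regularization mu    : 6.41e-04, chi2 = 475.3
```

The flip angle is recovered to a few degrees and GMT2 to ~2 ms; MWF carries
the small negative bias inherent to χ²-window spectral regularization at
this SNR (see `docs/methods.md`). Build a lesioned phantom and read the
programmed penumbra off the distance rings:

```bash
$ python examples/03_phantom_and_rings.py
WMH components: 1 periventricular, 1 deep; lesion volume 0.140 mL
metric              GMT2      MD
distance_level
WMH             100.0000  0.0011
2                91.6839  0.0010
4                84.8677  0.0008
6                80.6644  0.0008
8                80.0000  0.0007
10               80.0000  0.0008
```

GMT2 (ms) and MD (mm²/s) are highest inside the WMH and decay quadratically
to the NAWM baseline (80 ms, 0.75×10⁻³) within ~6 mm — the penumbra the
mixed models then detect (`examples/04_mixed_models.py`,
`examples/05_full_pipeline.py`).

The pipeline is also exposed as a thin CLI:

```bash
wmh-penumbra run-all --config examples/demo_config.toml
wmh-penumbra simulate --seed 7 --out myrun     # individual stages:
wmh-penumbra fit-mwi  --out myrun              # simulate / fit-mwi / fit-dti
wmh-penumbra rois     --out myrun --deep-only  # / rois / stats
```

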