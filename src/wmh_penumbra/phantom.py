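"""Synthetic brain phantoms with WMH lesions and programmed penumbra gradients.

The generator builds small 3-D label volumes (ventricles, CSF rim, grey
matter, NAWM, periventricular and deep WMH blobs, optional stroke lesion),
paints ground-truth parameter maps on them, and synthesizes the two
quantitative acquisitions the analysis consumes: a multi-echo spin-echo
train (via the same EPG physics the fitting stage inverts) and a
single-shell diffusion acquisition, both with Rician noise.

The programmed spatial structure mirrors the phenomenon under study: a
perilesional gradient of interstitial-fluid-linked parameters (IE T2, MD,
and — inversely — FA) decaying quadratically to baseline within ~6 mm of
the WMH boundary, a myelin deficit confined to the WMH and present only in
the stroke-like group, and per-subject lesion severity coupled to the
whole-brain WMH volume covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import relaxometry as rx
from .rois import distance_map_mm, DISTANCE_LEVELS
from .sequences import (
    DiffusionScheme,
    SequenceParams,
    SCANNER_A_32ECHO,
    SCANNER_B_48ECHO,
    make_hardi_scheme,
    write_bvals_bvecs,
)

__all__ = [
    "LABELS",
    "LabelVolume",
    "GroundTruthMaps",
    "SubjectRecord",
    "GradientProfile",
    "CohortConfig",
    "PlacementError",
    "make_label_volume",
    "paint_ground_truth",
    "simulate_echo_train",
    "simulate_echo_volume",
    "simulate_dwi",
    "simulate_dwi_volume",
    "tensor_from_fa_md",
    "simulate_cohort",
    "simulate_roi_table",
    "MYELIN_T2_MS",
]

logger = logging.getLogger(__name__)

MYELIN_T2_MS = 20.0

#: tissue label codes
LABELS = {
    "background": 0,
    "ventricular_csf": 1,
    "sulcal_csf": 2,
    "grey_matter": 3,
    "nawm": 4,
    "wmh": 5,
    "stroke": 6,
}

#: per-tissue ground-truth defaults: (mwf, ie_t2 ms, fa, md mm^2/s)
TISSUE_DEFAULTS = {
    1: dict(mwf=0.0, ie_t2=1800.0, fa=0.02, md=3.0e-3),
    2: dict(mwf=0.0, ie_t2=1800.0, fa=0.02, md=3.0e-3),
    3: dict(mwf=0.03, ie_t2=90.0, fa=0.15, md=0.85e-3),
    4: dict(mwf=0.10, ie_t2=80.0, fa=0.45, md=0.75e-3),
    5: dict(mwf=0.10, ie_t2=100.0, fa=0.30, md=1.10e-3),
    6: dict(mwf=0.04, ie_t2=120.0, fa=0.20, md=1.50e-3),
}

NAWM_MWF = TISSUE_DEFAULTS[4]["mwf"]
NAWM_IE_T2_MS = TISSUE_DEFAULTS[4]["ie_t2"]
NAWM_FA = TISSUE_DEFAULTS[4]["fa"]
NAWM_MD = TISSUE_DEFAULTS[4]["md"]
WMH_FA = TISSUE_DEFAULTS[5]["fa"]
#: WMH myelin water fraction in the stroke-like group (deficit vs NAWM)
WMH_MWF_STROKE = 0.06


class PlacementError(RuntimeError):
    """A requested blob could not be placed on the grid."""


@dataclass
class LabelVolume:
    """Integer tissue classes on a 3-D grid with physical voxel dimensions."""

    labels: np.ndarray
    voxel_size_mm: tuple

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in vs) or len(vs) != 3:
            raise ValueError("voxel_size_mm must be 3 positive components")
        self.voxel_size_mm = vs
        bad = set(np.unique(self.labels)) - set(LABELS.values())
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class GroundTruthMaps:
    """Voxelwise ground truth used by recovery tests."""

    mwf_true: np.ndarray
    ie_t2_true: np.ndarray
    fa_true: np.ndarray
    md_true: np.ndarray
    flip_angle_true: np.ndarray


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # older_adult | stroke
    age: float
    moca: float
    scanner: str  # A_32echo | B_48echo
    hemisphere_of_stroke: str  # left | right | bilateral | none
    wmh_volume_ml: float

    def __post_init__(self) -> None:
        if self.group not in ("older_adult", "stroke"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "stroke" and self.hemisphere_of_stroke == "none":
            raise ValueError("stroke subjects must have a stroke hemisphere")
        if self.group == "older_adult" and self.wmh_volume_ml >= 10.0:
            raise ValueError("older adults must have WMH volume < 10 mL")


@dataclass(frozen=True)
class GradientProfile:
    """Perilesional profile: value(d) = baseline + (lesion-baseline)*(1-d/reach)^shape.

    The support is [0, reach_mm); at and beyond ``reach_mm`` the value equals
    the baseline exactly.  The default quadratic shape with 6 mm reach keeps
    a measurable elevation out to ~4 mm that levels off well before 10 mm.
    """

    baseline: float
    lesion_value: float
    reach_mm: float = 6.0
    shape: float = 2.0

    def __post_init__(self) -> None:
        if self.reach_mm <= 0:
            raise ValueError("reach_mm must be positive")

    def __call__(self, d_mm) -> np.ndarray:
        w = np.clip(1.0 - np.asarray(d_mm, dtype=float) / self.reach_mm, 0.0, None) ** self.shape
        return self.baseline + (self.lesion_value - self.baseline) * w


def _ellipsoid(coords_mm, center_mm, semi_mm) -> np.ndarray:
    x, y, z = coords_mm
    cx, cy, cz = center_mm
    ax, ay, az = semi_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _coords_mm(shape, voxel_size_mm):
    axes = [vs * (np.arange(n) - (n - 1) / 2.0) for n, vs in zip(shape, voxel_size_mm)]
    return np.meshgrid(*axes, indexing="ij")


def make_label_volume(
    shape=(48, 48, 48),
    voxel_size_mm=(1.0, 1.0, 1.0),
    n_deep_wmh: int = 2,
    n_pv_wmh: int = 1,
    with_stroke: bool = False,
    seed: int = 0,
    wmh_radius_mm: float = 3.0,
    stroke_radius_mm: float = 8.0,
    stroke_side: str = "left",
) -> LabelVolume:
    """Generate a deterministic synthetic label volume.

    Geometry: ellipsoidal brain with a sulcal-CSF rim and grey-matter shell,
    a white-matter interior holding two lateral ventricles; periventricular
    WMH blobs are seeded on the ventricular surface (guaranteed face contact
    with ventricular CSF), deep WMH blobs at least 2 mm from it, and an
    optional stroke lesion confined to one hemisphere.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("grid must be at least 32 voxels per axis")
    vs = tuple(float(v) for v in voxel_size_mm)
    rng = np.random.default_rng(seed)
    coords = _coords_mm(shape, vs)
    half_mm = np.array([s * v / 2.0 for s, v in zip(shape, vs)])
    brain_semi = 0.92 * half_mm

    lab = np.zeros(shape, dtype=np.uint8)
    brain = _ellipsoid(coords, (0, 0, 0), brain_semi)
    lab[brain] = LABELS["sulcal_csf"]
    gm_outer = _ellipsoid(coords, (0, 0, 0), brain_semi - 1.5)
    lab[gm_outer] = LABELS["grey_matter"]
    wm = _ellipsoid(coords, (0, 0, 0), brain_semi - 4.5)
    lab[wm] = LABELS["nawm"]

    # two lateral ventricles, elongated along y
    v_semi = np.maximum(brain_semi * np.array([0.14, 0.34, 0.18]), 2.0)
    for sign in (-1.0, +1.0):
        center = (sign * 0.22 * brain_semi[0], 0.0, 0.0)
        vent = _ellipsoid(coords, center, v_semi) & (lab == LABELS["nawm"])
        lab[vent] = LABELS["ventricular_csf"]

    vcsf = lab == LABELS["ventricular_csf"]
    if not vcsf.any():
        raise PlacementError("ventricles: white-matter interior too small")
    dist_vent = distance_map_mm(vcsf, vs)

    def place_sphere(center_idx, radius_mm, allowed) -> np.ndarray:
        c_mm = [coords[a][tuple(center_idx)] for a in range(3)]
        sphere = _ellipsoid(coords, c_mm, (radius_mm,) * 3)
        return sphere & allowed

    wm_mask = lab == LABELS["nawm"]

    # periventricular WMH: seeded on ventricular surface so the blob
    # shares at least one face with ventricular CSF
    for i_blob in range(n_pv_wmh):
        placed = False
        surface = np.argwhere(wm_mask & (dist_vent <= max(vs)))
        order = rng.permutation(len(surface))
        for trial in order[:200]:
            blob = place_sphere(surface[trial], wmh_radius_mm, lab == LABELS["nawm"])
            if blob.sum() >= 4 and _face_adjacent(blob, vcsf):
                lab[blob] = LABELS["wmh"]
                placed = True
                break
        if not placed:
            raise PlacementError(f"periventricular WMH blob {i_blob + 1}")

    # deep WMH: the whole blob stays >= 2 mm from ventricular CSF
    for i_blob in range(n_deep_wmh):
        placed = False
        candidates = np.argwhere(
            (lab == LABELS["nawm"]) & (dist_vent >= 2.0 + wmh_radius_mm + max(vs))
        )
        if len(candidates) == 0:
            raise PlacementError(f"deep WMH blob {i_blob + 1}")
        order = rng.permutation(len(candidates))
        for trial in order[:200]:
            blob = place_sphere(candidates[trial], wmh_radius_mm, lab == LABELS["nawm"])
            if blob.sum() >= 4 and dist_vent[blob].min() >= 2.0:
                lab[blob] = LABELS["wmh"]
                placed = True
                break
        if not placed:
            raise PlacementError(f"deep WMH blob {i_blob + 1}")

    if with_stroke:
        side_sign = -1.0 if stroke_side == "left" else +1.0
        tissue = (lab == LABELS["nawm"]) | (lab == LABELS["grey_matter"])
        hemi = coords[0] * side_sign > 1.0  # stay off the midline
        candidates = np.argwhere(tissue & hemi & (np.abs(coords[0]) > 0.35 * brain_semi[0]))
        placed = False
        if len(candidates):
            order = rng.permutation(len(candidates))
            for trial in order[:200]:
                blob = place_sphere(candidates[trial], stroke_radius_mm, tissue & hemi)
                if blob.sum() >= 8:
                    lab[blob] = LABELS["stroke"]
                    placed = True
                    break
        if not placed:
            raise PlacementError("stroke lesion")

    return LabelVolume(labels=lab, voxel_size_mm=vs)


def _face_adjacent(a: np.ndarray, b: np.ndarray) -> bool:
    """True if any voxel of ``a`` shares a face with a voxel of ``b``."""
    for axis in range(3):
        for shift in (-1, 1):
            if (np.roll(a, shift, axis=axis) & b).any():
                return True
    return False


# ---------------------------------------------------------------------------
# ground truth


def default_gmt2_profile(lesion_value: float = 100.0) -> GradientProfile:
    return GradientProfile(baseline=NAWM_IE_T2_MS, lesion_value=lesion_value)


def default_md_profile(lesion_value: float = 1.10e-3) -> GradientProfile:
    return GradientProfile(baseline=NAWM_MD, lesion_value=lesion_value)


def paint_ground_truth(
    lv: LabelVolume,
    profile_gmt2: GradientProfile | None = None,
    profile_md: GradientProfile | None = None,
    group: str = "older_adult",
    seed: int = 0,
    wmh_mwf: float | None = None,
    flip_range_deg: tuple[float, float] = (110.0, 180.0),
) -> GroundTruthMaps:
    """Paint ground-truth parameter maps on a label volume.

    Fluid-linked maps (IE T2, MD, and inversely FA) follow the perilesional
    profile ``value(d) = baseline + (lesion - baseline) * max(0, 1-d/reach)^shape``
    in NAWM, where d is the distance to the WMH; inside the WMH they take
    the lesion value.  MWF is flat across NAWM for both groups and reduced
    inside the WMH only for the stroke-like group.  The refocusing
    flip-angle field is a smooth quadratic polynomial within
    ``flip_range_deg``.
    """
    profile_gmt2 = default_gmt2_profile() if profile_gmt2 is None else profile_gmt2
    profile_md = default_md_profile() if profile_md is None else profile_md
    if profile_gmt2.baseline != NAWM_IE_T2_MS or profile_md.baseline != NAWM_MD:
        raise ValueError("profile baselines must equal the NAWM defaults")
    if not (40.0 <= profile_gmt2.lesion_value <= 200.0):
        raise ValueError("GMT2 lesion value outside [40, 200] ms")
    if not (0.0 < profile_md.lesion_value <= 4.0e-3):
        raise ValueError("MD lesion value outside (0, 4e-3] mm^2/s")
    if group not in ("older_adult", "stroke"):
        raise ValueError(f"unknown group {group!r}")

    lab = lv.labels
    shape = lab.shape
    maps = {k: np.zeros(shape) for k in ("mwf", "ie", "fa", "md")}
    for code, params in TISSUE_DEFAULTS.items():
        sel = lab == code
        maps["mwf"][sel] = params["mwf"]
        maps["ie"][sel] = params["ie_t2"]
        maps["fa"][sel] = params["fa"]
        maps["md"][sel] = params["md"]

    wmh = lab == LABELS["wmh"]
    nawm = lab == LABELS["nawm"]
    if wmh.any():
        d = distance_map_mm(wmh, lv.voxel_size_mm)
        w = np.clip(1.0 - d / profile_gmt2.reach_mm, 0.0, None) ** profile_gmt2.shape
        maps["ie"][nawm] = profile_gmt2(d)[nawm]
        maps["md"][nawm] = profile_md(d)[nawm]
        maps["fa"][nawm] = NAWM_FA + (WMH_FA - NAWM_FA) * w[nawm]
        maps["ie"][wmh] = profile_gmt2.lesion_value
        maps["md"][wmh] = profile_md.lesion_value
    if wmh_mwf is None:
        wmh_mwf = WMH_MWF_STROKE if group == "stroke" else NAWM_MWF
    maps["mwf"][wmh] = wmh_mwf if group == "stroke" else NAWM_MWF

    # smooth quadratic flip-angle (B1) field: peak near a randomized center,
    # falling off quadratically toward the edges of the volume
    rng = np.random.default_rng(seed)
    coords = _coords_mm(shape, lv.voxel_size_mm)
    half_mm = np.array([s * v / 2.0 for s, v in zip(shape, lv.voxel_size_mm)])
    center = rng.uniform(-0.25, 0.25, size=3) * half_mm
    weights = rng.uniform(0.5, 1.0, size=3)
    r2 = sum(w * ((c - c0) / h) ** 2 for w, c, c0, h in zip(weights, coords, center, half_mm))
    r2 = r2 / r2.max()
    lo, hi = flip_range_deg
    flip = hi - (hi - lo) * r2

    return GroundTruthMaps(
        mwf_true=maps["mwf"],
        ie_t2_true=maps["ie"],
        fa_true=maps["fa"],
        md_true=maps["md"],
        flip_angle_true=flip,
    )


# ---------------------------------------------------------------------------
# signal synthesis


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if sigma == 0:
        return np.abs(clean)
    return np.hypot(
        clean + sigma * rng.standard_normal(clean.shape),
        sigma * rng.standard_normal(clean.shape),
    )


def simulate_echo_train(
    mwf: float,
    ie_t2: float,
    flip_angle: float,
    seq: SequenceParams,
    s0: float = 1.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> rx.EchoTrain:
    """Two-pool multi-echo decay: myelin pool at 20 ms plus an IE pool.

    Noiseless signal is ``s0*(mwf*EPG(20 ms) + (1-mwf)*EPG(ie_t2))``; noise
    is Rician (magnitude of a complex Gaussian perturbation).
    """
    if not 0.0 <= mwf <= 1.0:
        raise ValueError("mwf must be in [0, 1]")
    if not (0.0 < flip_angle <= 180.0):
        raise ValueError("flip angle must be in (0, 180] degrees")
    rng = np.random.default_rng() if rng is None else rng
    clean = s0 * (
        mwf * rx.epg_decay(MYELIN_T2_MS, seq, flip_angle)
        + (1.0 - mwf) * rx.epg_decay(ie_t2, seq, flip_angle)
    )
    return rx.EchoTrain(_rician(clean, noise_sigma, rng), seq)


def simulate_echo_volume(
    gt: GroundTruthMaps,
    mask: np.ndarray,
    seq: SequenceParams,
    s0: float = 800.0,
    snr: float = 200.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized two-pool echo synthesis over all voxels in a mask.

    SNR is defined as s0/sigma; sigma applies per complex channel before the
    magnitude operation (Rician).  Returns a 4-D array (x, y, z, echo) that
    is zero outside the mask.
    """
    rng = np.random.default_rng() if rng is None else rng
    mask = np.asarray(mask, bool)
    mwf = gt.mwf_true[mask]
    ie = np.clip(gt.ie_t2_true[mask], 1.0, None)
    flip = gt.flip_angle_true[mask]
    clean = s0 * (
        mwf[:, None] * rx.epg_decay(np.full_like(ie, MYELIN_T2_MS), seq, flip)
        + (1.0 - mwf[:, None]) * rx.epg_decay(ie, seq, flip)
    )
    sigma = s0 / snr if snr > 0 else 0.0
    noisy = _rician(clean, sigma, rng)
    out = np.zeros(mask.shape + (seq.n_echoes,), dtype=np.float32)
    out[mask] = noisy
    return out


def tensor_from_fa_md(fa: float, md: float, axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Prolate symmetric tensor with prescribed FA and MD, principal ``axis``."""
    fa = float(np.clip(fa, 0.0, 0.999))
    f = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam1 = md * (1.0 + 2.0 * f)
    lam23 = md * (1.0 - f)
    e1 = np.asarray(axis, float)
    e1 = e1 / np.linalg.norm(e1)
    return lam23 * np.eye(3) + (lam1 - lam23) * np.outer(e1, e1)


def simulate_dwi(
    tensor: np.ndarray,
    scheme: DiffusionScheme,
    s0: float = 1.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-tensor DWI signal S_i = s0 * exp(-b_i g_i' D g_i), Rician noise."""
    tensor = np.asarray(tensor, float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T):
        raise ValueError("tensor must be symmetric 3x3")
    if np.linalg.eigvalsh(tensor).min() < -1e-15:
        raise ValueError("tensor must be positive semi-definite")
    rng = np.random.default_rng() if rng is None else rng
    quad = np.einsum("ij,jk,ik->i", scheme.bvecs, tensor, scheme.bvecs)
    clean = s0 * np.exp(-scheme.bvals * quad)
    return _rician(clean, noise_sigma, rng)


def simulate_dwi_volume(
    gt: GroundTruthMaps,
    mask: np.ndarray,
    scheme: DiffusionScheme,
    s0: float = 400.0,
    snr: float = 40.0,
    rng: np.random.Generator | None = None,
    axis=(1.0, 0.0, 0.0),
) -> np.ndarray:
    """Vectorized DWI synthesis from FA/MD ground truth (shared principal axis)."""
    rng = np.random.default_rng() if rng is None else rng
    mask = np.asarray(mask, bool)
    fa = np.clip(gt.fa_true[mask], 0.0, 0.999)
    md = gt.md_true[mask]
    f = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam1 = md * (1.0 + 2.0 * f)
    lam23 = md * (1.0 - f)
    e1 = np.asarray(axis, float)
    e1 = e1 / np.linalg.norm(e1)
    proj = (scheme.bvecs @ e1) ** 2  # (n_volumes,)
    quad = lam23[:, None] + (lam1 - lam23)[:, None] * proj[None, :]
    clean = s0 * np.exp(-scheme.bvals[None, :] * quad)
    sigma = s0 / snr if snr > 0 else 0.0
    noisy = _rician(clean, sigma, rng)
    out = np.zeros(mask.shape + (scheme.n_volumes,), dtype=np.float32)
    out[mask] = noisy
    return out


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    WMH-volume covariates are log-normal with medians/IQRs patterned on the
    two groups' observed distributions (older adults median ~0.35 mL, stroke
    ~2.7 mL with a long tail, truncated below 10 mL for older adults).
    Lesion severity (IE T2 / MD lesion values) scales with the standardized
    log volume, the MWF deficit is group-programmed, and about one stroke
    subject in three has bilateral lesions.
    """

    shape: tuple = (36, 36, 36)
    voxel_size_mm: tuple = (1.75, 1.75, 1.75)
    n_pv_wmh: int = 1
    n_deep_wmh: int = 1
    wmh_radius_mm: float = 3.6
    stroke_radius_mm: float = 7.0
    echo_s0: float = 800.0
    echo_snr: float = 200.0
    dwi_s0: float = 400.0
    dwi_snr: float = 40.0
    n_dwi_directions: int = 60
    b_value: float = 700.0
    age_range: tuple = (45.0, 80.0)
    # log-normal WMH-volume parameters per group: (mu of ln mL, sigma)
    logvol_older: tuple = (np.log(0.352), 1.17)
    logvol_stroke: tuple = (np.log(2.676), 1.48)
    bilateral_every: int = 3  # every k-th stroke subject has bilateral lesions
    stroke_vol_cap_ml: float = 40.0  # upper truncation of the stroke volume draw
    # severity coupling of WMH lesion values to standardized log volume
    gmt2_lesion_base: float = 100.0
    gmt2_lesion_per_z: float = 6.0
    md_lesion_base: float = 1.10e-3
    md_lesion_per_z: float = 0.12e-3
    # WMH myelin deficit (stroke-like group only), deepening with severity
    mwf_lesion_base: float = 0.093
    mwf_lesion_per_z: float = -0.022
    logvol_ref: tuple = (0.0, 1.5)  # standardization reference for ln(mL)


def _draw_wmh_volume(group: str, cfg: CohortConfig, rng: np.random.Generator) -> float:
    mu, sigma = cfg.logvol_older if group == "older_adult" else cfg.logvol_stroke
    cap = 10.0 if group == "older_adult" else cfg.stroke_vol_cap_ml
    for _ in range(100):
        v = float(np.exp(rng.normal(mu, sigma)))
        if v < cap:
            return v
    return 0.95 * cap  # extreme-tail fallback under truncation


def make_subject_records(
    n_older: int, n_stroke: int, cfg: CohortConfig, seed: int
) -> list[SubjectRecord]:
    """Draw the cohort covariate table (deterministic in the seed)."""
    rng = np.random.default_rng(seed)
    records = []
    sides = ("left", "right")
    for i in range(n_older + n_stroke):
        group = "older_adult" if i < n_older else "stroke"
        gi = i if group == "older_adult" else i - n_older
        if group == "stroke":
            if cfg.bilateral_every and (gi + 1) % cfg.bilateral_every == 0:
                hemi = "bilateral"
            else:
                hemi = sides[gi % 2]
        else:
            hemi = "none"
        moca_mu, moca_sd = (27.0, 2.0) if group == "older_adult" else (25.0, 3.0)
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:03d}",
                group=group,
                age=float(np.round(rng.uniform(*cfg.age_range), 1)),
                moca=float(np.clip(np.round(rng.normal(moca_mu, moca_sd)), 0, 30)),
                scanner="A_32echo" if gi % 2 == 0 else "B_48echo",
                hemisphere_of_stroke=hemi,
                wmh_volume_ml=_draw_wmh_volume(group, cfg, rng),
            )
        )
    return records


def subject_profiles(
    record: SubjectRecord, cfg: CohortConfig
) -> tuple[GradientProfile, GradientProfile, float]:
    """Per-subject lesion values, severity-coupled to the volume covariate.

    Fluid-linked lesion values (IE T2, MD) rise with standardized log WMH
    volume in both groups; the WMH myelin deficit exists only in the
    stroke-like group and deepens with severity.  Returns
    ``(gmt2_profile, md_profile, wmh_mwf)``.
    """
    mu, sd = cfg.logvol_ref
    z = (np.log(record.wmh_volume_ml) - mu) / sd
    gmt2_lesion = float(np.clip(cfg.gmt2_lesion_base + cfg.gmt2_lesion_per_z * z, 85.0, 150.0))
    md_lesion = float(np.clip(cfg.md_lesion_base + cfg.md_lesion_per_z * z, 0.85e-3, 1.8e-3))
    if record.group == "stroke":
        wmh_mwf = float(np.clip(cfg.mwf_lesion_base + cfg.mwf_lesion_per_z * z, 0.02, 0.0995))
    else:
        wmh_mwf = NAWM_MWF
    return default_gmt2_profile(gmt2_lesion), default_md_profile(md_lesion), wmh_mwf


def simulate_subject(
    record: SubjectRecord,
    cfg: CohortConfig,
    seed: int,
    fit_region_only: bool = True,
) -> dict:
    """Simulate one subject's volumes; returns arrays keyed by artifact name.

    When ``fit_region_only`` is set, the signal mask is restricted to tissue
    within 10.5 mm of the WMH (covering the WMH ROI and all rings) — the rest
    of the brain plays no role in the downstream analysis.
    """
    ss = np.random.SeedSequence(seed)
    s_geom, s_paint, s_echo, s_dwi = [np.random.default_rng(c) for c in ss.spawn(4)]
    side = record.hemisphere_of_stroke
    lv = make_label_volume(
        shape=cfg.shape,
        voxel_size_mm=cfg.voxel_size_mm,
        n_deep_wmh=cfg.n_deep_wmh + (1 if side == "bilateral" else 0),
        n_pv_wmh=cfg.n_pv_wmh,
        with_stroke=record.group == "stroke",
        seed=int(s_geom.integers(2**31)),
        wmh_radius_mm=cfg.wmh_radius_mm,
        stroke_radius_mm=cfg.stroke_radius_mm,
        stroke_side="left" if side in ("left", "bilateral") else "right",
    )
    p_gmt2, p_md, wmh_mwf = subject_profiles(record, cfg)
    gt = paint_ground_truth(
        lv, p_gmt2, p_md, group=record.group, seed=int(s_paint.integers(2**31)),
        wmh_mwf=wmh_mwf,
    )
    if fit_region_only:
        near_wmh = distance_map_mm(lv.mask("wmh"), lv.voxel_size_mm) <= 10.5
        signal_mask = lv.brain_mask & near_wmh
    else:
        signal_mask = lv.brain_mask
    seq = SCANNER_A_32ECHO if record.scanner == "A_32echo" else SCANNER_B_48ECHO
    echo = simulate_echo_volume(gt, signal_mask, seq, cfg.echo_s0, cfg.echo_snr, s_echo)
    scheme = make_hardi_scheme(cfg.n_dwi_directions, cfg.b_value)
    dwi = simulate_dwi_volume(gt, signal_mask, scheme, cfg.dwi_s0, cfg.dwi_snr, s_dwi)
    return {
        "labels": lv,
        "ground_truth": gt,
        "echo": echo,
        "dwi": dwi,
        "scheme": scheme,
        "seq": seq,
        "signal_mask": signal_mask,
    }


def simulate_cohort(
    n_older: int,
    n_stroke: int,
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectRecord], dict]:
    """Simulate a full cohort; optionally write NIfTI/bval/bvec/TSV to disk.

    Returns ``(records, data)`` where ``data`` maps subject_id to the bundle
    from :func:`simulate_subject`.  Per-subject seeds derive from the master
    seed via ``SeedSequence`` spawning, so any subject can be regenerated
    independently.
    """
    if n_older < 1 or n_stroke < 1:
        raise ValueError("need at least one subject per group")
    cfg = config or CohortConfig()
    master = np.random.SeedSequence(seed)
    rec_seed, *subject_seeds = master.spawn(1 + n_older + n_stroke)
    records = make_subject_records(
        n_older, n_stroke, cfg, seed=int(np.random.default_rng(rec_seed).integers(2**31))
    )
    data = {}
    for record, sseed in zip(records, subject_seeds):
        bundle = simulate_subject(
            record, cfg, seed=int(np.random.default_rng(sseed).integers(2**31))
        )
        data[record.subject_id] = bundle
        logger.info("simulated %s (%s)", record.subject_id, record.group)
    if out_dir is not None:
        write_cohort(records, data, out_dir)
    return records, data


def write_cohort(records, data, out_dir: str | Path) -> None:
    """Write the cohort as NIfTI volumes, FSL gradient tables, and a TSV."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for record in records:
        bundle = data[record.subject_id]
        sdir = out_dir / record.subject_id
        sdir.mkdir(exist_ok=True)
        lv: LabelVolume = bundle["labels"]
        affine = np.diag(list(lv.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(lv.labels.astype(np.uint8), affine), sdir / "labels.nii.gz")
        nib.save(
            nib.Nifti1Image(bundle["echo"].astype(np.float32), affine), sdir / "echo.nii.gz"
        )
        nib.save(nib.Nifti1Image(bundle["dwi"].astype(np.float32), affine), sdir / "dwi.nii.gz")
        write_bvals_bvecs(bundle["scheme"], sdir / "bval", sdir / "bvec")
    table = pd.DataFrame([asdict(r) for r in records])
    table.to_csv(out_dir / "participants.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# table-level simulation (for statistical power / type-I studies)

#: mid-ring distances (mm) used when mapping profiles onto distance levels
LEVEL_DISTANCES_MM = {"WMH": 0.0, "2": 1.0, "4": 3.0, "6": 5.0, "8": 7.0, "10": 9.0}

DEFAULT_TABLE_EFFECTS = {
    "FA": dict(profile=GradientProfile(NAWM_FA, WMH_FA), sd=0.012),
    "MD": dict(profile=default_md_profile(), sd=0.02e-3),
    "GMT2": dict(profile=default_gmt2_profile(), sd=1.0),
    "MWF": dict(profile=GradientProfile(NAWM_MWF, NAWM_MWF), sd=0.004,
                stroke_wmh_value=WMH_MWF_STROKE),
}


def simulate_roi_table(
    n_older: int,
    n_stroke: int,
    effects: dict | None = None,
    seed: int = 0,
    scanner_sd_frac: float = 0.01,
    subject_sd_frac: float = 0.02,
    cfg: CohortConfig | None = None,
) -> pd.DataFrame:
    """Generate a long-format ROI table directly, without image synthesis.

    Each subject contributes one row per distance level per metric.  Row
    values follow the metric's perilesional profile evaluated at mid-ring
    distances, plus scanner and subject random intercepts and residual
    noise.  With flat (zero-amplitude) profiles this generates the
    programmed null used for type-I error studies; the image-based pipeline
    produces the same table layout.
    """
    cfg = cfg or CohortConfig()
    effects = DEFAULT_TABLE_EFFECTS if effects is None else effects
    rng = np.random.default_rng(seed)
    records = make_subject_records(n_older, n_stroke, cfg, seed=int(rng.integers(2**31)))
    scanner_fx = {
        ("A_32echo", m): rng.normal(0.0, scanner_sd_frac * abs(e["profile"].baseline))
        for m, e in effects.items()
    }
    scanner_fx.update(
        {
            ("B_48echo", m): rng.normal(0.0, scanner_sd_frac * abs(e["profile"].baseline))
            for m, e in effects.items()
        }
    )
    rows = []
    for record in records:
        mu, sd_ref = cfg.logvol_ref
        z = (np.log(record.wmh_volume_ml) - mu) / sd_ref
        for metric, eff in effects.items():
            profile: GradientProfile = eff["profile"]
            subj_fx = rng.normal(0.0, subject_sd_frac * abs(profile.baseline))
            for level in DISTANCE_LEVELS:
                d = LEVEL_DISTANCES_MM[level]
                value = float(profile(d))
                if level == "WMH":
                    # severity coupling at the lesion, mirroring the image phantom
                    if metric == "GMT2" and profile.lesion_value != profile.baseline:
                        value = cfg.gmt2_lesion_base + cfg.gmt2_lesion_per_z * z
                    elif metric == "MD" and profile.lesion_value != profile.baseline:
                        value = cfg.md_lesion_base + cfg.md_lesion_per_z * z
                    if metric == "MWF" and record.group == "stroke" and "stroke_wmh_value" in eff:
                        value = float(
                            np.clip(cfg.mwf_lesion_base + cfg.mwf_lesion_per_z * z, 0.02, 0.0995)
                        )
                value += scanner_fx[(record.scanner, metric)] + subj_fx
                value += rng.normal(0.0, eff["sd"])
                rows.append(
                    {
                        "subject_id": record.subject_id,
                        "group": record.group,
                        "scanner": record.scanner,
                        "hemisphere_of_stroke": record.hemisphere_of_stroke,
                        "distance_level": level,
                        "metric": metric,
                        "value": value,
                        "n_voxels": 50,
                        "age": record.age,
                        "moca": record.moca,
                        "wmh_volume_ml": record.wmh_volume_ml,
                    }
                )
    return pd.DataFrame(rows)
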