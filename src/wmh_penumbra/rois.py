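"""Perilesional ROI construction: distance rings around WMH lesions.

The spatial-gradient analysis samples normal-appearing white matter (NAWM)
in five concentric 2 mm rings around the WMH boundary, out to 10 mm.  CSF is
excluded with a 1 mm guard zone (partial-volume protection) and stroke
lesions with a 10 mm guard zone.  All distances are Euclidean distances
between voxel centers in physical millimetres, honoring anisotropic voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

__all__ = [
    "RingSet",
    "distance_map_mm",
    "dilate_mm",
    "make_rings",
    "classify_wmh",
    "extract_roi_means",
    "split_by_hemisphere",
    "wmh_volume_ml",
    "RING_EDGES_MM",
    "DISTANCE_LEVELS",
]

logger = logging.getLogger(__name__)

#: outer edges of the five perilesional rings, mm
RING_EDGES_MM = (2.0, 4.0, 6.0, 8.0, 10.0)
#: ordered distance-level labels used in the long-format table
DISTANCE_LEVELS = ("WMH", "2", "4", "6", "8", "10")

CSF_GUARD_MM = 1.0
STROKE_GUARD_MM = 10.0

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask (e.g. zero-WMH subject)."""


@dataclass
class RingSet:
    """WMH ROI plus five disjoint perilesional NAWM rings (2-10 mm)."""

    wmh_roi: np.ndarray
    rings: list = field(default_factory=list)  # 5 boolean arrays, inner to outer
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def masks(self) -> dict[str, np.ndarray]:
        out = {"WMH": self.wmh_roi}
        for edge, ring in zip(RING_EDGES_MM, self.rings):
            out[str(int(edge))] = ring
        return out

    def to_code_volume(self) -> np.ndarray:
        """Code volume: 10 = WMH ROI, 11..15 = rings (0 elsewhere)."""
        out = np.zeros(self.wmh_roi.shape, dtype=np.uint8)
        out[self.wmh_roi] = 10
        for i, ring in enumerate(self.rings):
            out[ring] = 11 + i
        return out


def distance_map_mm(mask: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the nearest mask voxel.

    Zero inside the mask.  Anisotropic voxel dimensions are honored through
    the sampling argument of the exact Euclidean distance transform.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("distance map requested for an empty mask")
    return ndi.distance_transform_edt(~mask, sampling=np.asarray(voxel_size_mm, float))


def dilate_mm(mask: np.ndarray, d_mm: float, voxel_size_mm) -> np.ndarray:
    """Metric dilation: voxels whose center is within d_mm of the mask."""
    if d_mm < 0:
        raise ValueError("dilation distance must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return distance_map_mm(mask, voxel_size_mm) <= d_mm


def make_rings(
    wmh_mask: np.ndarray,
    nawm_mask: np.ndarray,
    csf_mask: np.ndarray | None = None,
    stroke_mask: np.ndarray | None = None,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> RingSet:
    """Build the WMH ROI and five 2 mm NAWM rings with exclusion guards.

    Order of operations: (1) NAWM and WMH are trimmed by the 1 mm CSF guard
    and the 10 mm stroke guard; (2) ring k collects NAWM voxels whose
    distance to the WMH lies in (2(k-1), 2k] (half-open, so a voxel exactly
    on a boundary belongs to the inner ring).
    """
    wmh_mask = np.asarray(wmh_mask, dtype=bool)
    nawm_mask = np.asarray(nawm_mask, dtype=bool)
    if not wmh_mask.any():
        raise EmptyMaskError("subject has no WMH voxels")
    excl = np.zeros(wmh_mask.shape, dtype=bool)
    if csf_mask is not None and np.asarray(csf_mask).any():
        excl |= dilate_mm(np.asarray(csf_mask, bool), CSF_GUARD_MM, voxel_size_mm)
    if stroke_mask is not None and np.asarray(stroke_mask).any():
        excl |= dilate_mm(np.asarray(stroke_mask, bool), STROKE_GUARD_MM, voxel_size_mm)
    nawm_kept = nawm_mask & ~excl
    wmh_kept = wmh_mask & ~excl
    dist = distance_map_mm(wmh_mask, voxel_size_mm)
    rings = []
    inner = 0.0
    for outer in RING_EDGES_MM:
        ring = (dist > inner) & (dist <= outer) & nawm_kept
        if not ring.any():
            logger.warning("ring (%g, %g] mm is empty", inner, outer)
        rings.append(ring)
        inner = outer
    return RingSet(wmh_roi=wmh_kept, rings=rings, voxel_size_mm=tuple(np.asarray(voxel_size_mm, float)))


def classify_wmh(wmh_mask: np.ndarray, ventricular_csf_mask: np.ndarray) -> np.ndarray:
    """Classify WMH connected components as periventricular or deep.

    Components are found with 26-connectivity; a component is periventricular
    iff any of its voxels is 26-adjacent to (or coincident with the dilation
    of) ventricular CSF.  Returns an integer volume: 0 background,
    1 periventricular WMH, 2 deep WMH.
    """
    wmh_mask = np.asarray(wmh_mask, dtype=bool)
    vcsf = np.asarray(ventricular_csf_mask, dtype=bool)
    labels, n = ndi.label(wmh_mask, structure=_STRUCT26)
    near_vcsf = ndi.binary_dilation(vcsf, structure=_STRUCT26)
    out = np.zeros(wmh_mask.shape, dtype=np.uint8)
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        out[comp_mask] = 1 if (comp_mask & near_vcsf).any() else 2
    return out


def extract_roi_means(
    ring_set: RingSet,
    metric_maps: dict[str, np.ndarray],
    subject: "SubjectRecord | dict | None" = None,
) -> pd.DataFrame:
    """Mean of each metric over the WMH ROI and each ring, long format.

    Rows with zero finite voxels are dropped (logged).  Subject covariates,
    if provided, are attached to every row.
    """
    rows = []
    for level, mask in ring_set.masks().items():
        for metric, vol in metric_maps.items():
            vals = np.asarray(vol, dtype=float)[mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                logger.info("dropping level %s metric %s: no finite voxels", level, metric)
                continue
            rows.append(
                {
                    "distance_level": level,
                    "metric": metric,
                    "value": float(vals.mean()),
                    "n_voxels": int(vals.size),
                }
            )
    df = pd.DataFrame(rows)
    if subject is not None:
        record = subject if isinstance(subject, dict) else vars(subject)
        for key in ("subject_id", "group", "scanner", "hemisphere_of_stroke",
                    "age", "moca", "wmh_volume_ml"):
            if key in record:
                df[key] = record[key]
    return df


def split_by_hemisphere(
    ring_set: RingSet, midline_index: int, stroke_side: str
) -> tuple[RingSet, RingSet]:
    """Split a ring set at a sagittal midline plane (first array axis).

    ``stroke_side`` must be 'left' (x < midline) or 'right'; bilateral or
    lesion-free subjects are rejected — the hemisphere analysis is defined
    only for unilateral stroke.  Returns (ipsilesional, contralesional).
    """
    if stroke_side not in ("left", "right"):
        raise ValueError(
            f"hemisphere split requires unilateral stroke, got {stroke_side!r}"
        )
    shape = ring_set.wmh_roi.shape
    xs = np.arange(shape[0])
    left = (xs < midline_index)[:, None, None] & np.ones(shape, dtype=bool)
    halves = {}
    for side_name, half in (("left", left), ("right", ~left)):
        halves[side_name] = RingSet(
            wmh_roi=ring_set.wmh_roi & half,
            rings=[r & half for r in ring_set.rings],
            voxel_size_mm=ring_set.voxel_size_mm,
        )
    ipsi = halves[stroke_side]
    contra = halves["right" if stroke_side == "left" else "left"]
    return ipsi, contra


def wmh_volume_ml(wmh_mask: np.ndarray, voxel_size_mm) -> float:
    """Lesion volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    voxel_vol = float(np.prod(np.asarray(voxel_size_mm, dtype=float)))
    return float(np.count_nonzero(np.asarray(wmh_mask, bool)) * voxel_vol / 1000.0)
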