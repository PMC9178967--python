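"""Diffusion tensor fitting and FA/MD map computation.

The single-tensor model relates the diffusion-weighted signal to the
gradient direction g and b-value through

    S_i = S0 * exp(-b_i * g_i^T D g_i)

with D a symmetric positive semi-definite 3x3 tensor (mm^2/s).  Fitting is
linear in log-signal space; a two-pass weighted linear least squares (OLS
followed by WLS with weights equal to the squared predicted signal) corrects
for the heteroscedasticity the log transform introduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sequences import DiffusionScheme

__all__ = ["Tensor", "DtiMaps", "fit_tensor", "fa_of", "md_of", "fit_dti_volume"]

logger = logging.getLogger(__name__)

# index pairs for the 6 unique elements: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
_IJ = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class Tensor:
    """Symmetric diffusion tensor (mm^2/s) plus the non-weighted signal S0."""

    d: np.ndarray  # (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    s0: float
    clamped: bool = False  # negative eigenvalues were clamped for FA/MD

    @property
    def matrix(self) -> np.ndarray:
        dxx, dyy, dzz, dxy, dxz, dyz = self.d
        return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending; negatives clamped to 0 with flag."""
        lam = np.linalg.eigvalsh(self.matrix)[::-1]
        if np.any(lam < 0):
            self.clamped = True
            lam = np.clip(lam, 0.0, None)
        return lam


@dataclass
class DtiMaps:
    fa: np.ndarray
    md: np.ndarray
    n_clamped: int = 0


def _design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """Rows: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    b = scheme.bvals
    g = scheme.bvecs
    cols = [np.ones_like(b)]
    for (i, j) in _IJ:
        factor = 1.0 if i == j else 2.0
        cols.append(-factor * b * g[:, i] * g[:, j])
    return np.column_stack(cols)


def fit_tensor(signals: np.ndarray, scheme: DiffusionScheme) -> Tensor:
    """Two-pass weighted linear least-squares tensor fit for one voxel.

    Zero or negative signals are floored at machine epsilon (flagged in the
    log) so the log transform is defined.
    """
    s = np.asarray(signals, dtype=float).ravel()
    if s.size != scheme.n_volumes:
        raise ValueError("signal count does not match scheme")
    floor = np.finfo(float).tiny
    n_floored = int((s < floor).sum())
    if n_floored:
        logger.debug("flooring %d non-positive signals", n_floored)
        s = np.clip(s, floor, None)
    x = _design_matrix(scheme)
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("rank-deficient diffusion design (collinear gradients)")
    y = np.log(s)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    # WLS pass: weights = squared predicted signal
    w = np.exp(x @ beta) ** 2
    xw = x * w[:, None]
    beta = np.linalg.solve(x.T @ xw, xw.T @ y)
    return Tensor(d=beta[1:], s0=float(np.exp(beta[0])))


def fa_of(t: Tensor) -> float:
    """Fractional anisotropy: sqrt(3/2) * ||lambda - mean|| / ||lambda||."""
    lam = t.eigenvalues()
    norm = np.sqrt(np.sum(lam**2))
    if norm == 0:
        return 0.0
    fa = float(np.sqrt(1.5) * np.sqrt(np.sum((lam - lam.mean()) ** 2)) / norm)
    return min(fa, 1.0)


def md_of(t: Tensor) -> float:
    """Mean diffusivity: trace / 3 (mm^2/s)."""
    return float(np.sum(t.eigenvalues()) / 3.0)


def fit_dti_volume(
    dwi: np.ndarray, scheme: DiffusionScheme, mask: np.ndarray
) -> DtiMaps:
    """Voxelwise tensor fit over a 4D volume (x, y, z, volume).

    Returns FA and MD maps with NaN outside the mask; the number of voxels
    whose negative eigenvalues were clamped is logged and returned.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[-1] != scheme.n_volumes:
        raise ValueError(f"expected 4D data with {scheme.n_volumes} volumes")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask shape does not match volume")
    fa = np.full(mask.shape, np.nan)
    md = np.full(mask.shape, np.nan)
    n_clamped = 0
    for i, j, k in np.argwhere(mask):
        sig = dwi[i, j, k]
        if not np.all(np.isfinite(sig)) or not np.any(sig > 0):
            continue
        t = fit_tensor(sig, scheme)
        fa[i, j, k] = fa_of(t)
        md[i, j, k] = md_of(t)
        n_clamped += int(t.clamped)
    if n_clamped:
        logger.info("dti fit: clamped negative eigenvalues in %d voxels", n_clamped)
    return DtiMaps(fa=fa, md=md, n_clamped=n_clamped)
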