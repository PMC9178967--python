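"""Multi-echo T2 relaxometry: EPG-corrected regularized-NNLS spectrum fitting.

The decay of a multi-echo spin-echo train at imperfect refocusing flip angles
is not mono-exponential: stimulated-echo pathways redistribute signal across
echoes.  The extended phase graph (EPG) formalism propagates the transverse
(F) and stored longitudinal (Z) configuration states through the refocusing
train and yields the correct echo amplitudes for any flip angle.  A T2
spectrum is then recovered per voxel by non-negative least squares over a
logarithmic grid of T2 values, with Tikhonov regularization tuned so the
data misfit sits just above the unregularized minimum (a chi-square window),
trading resolution for stability.

Derived metrics:

* **MWF** (myelin water fraction): spectral area with 10 <= T2 <= 40 ms over
  the total spectral area — a proxy for myelin content.
* **GMT2**: amplitude-weighted geometric mean T2 over 40 <= T2 <= 200 ms —
  the intra/extracellular water peak position, a proxy for interstitial
  fluid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.optimize

from .sequences import SequenceParams

__all__ = [
    "T2Grid",
    "T2Spectrum",
    "EchoTrain",
    "MwiFit",
    "FlipAngleEstimate",
    "epg_decay",
    "epg_basis_curve",
    "build_basis",
    "nnls",
    "regularized_nnls",
    "estimate_flip_angle",
    "default_angle_grid",
    "compute_mwf",
    "compute_gmt2",
    "fit_voxel",
    "fit_volume",
]

logger = logging.getLogger(__name__)

MYELIN_WINDOW_MS = (10.0, 40.0)
IE_WINDOW_MS = (40.0, 200.0)
CHI2_WINDOW_DEFAULT = (1.02, 1.025)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class T2Grid:
    """Logarithmically spaced T2 grid (ms) over which spectra are fit."""

    t2_values_ms: np.ndarray

    def __post_init__(self) -> None:
        t2 = np.asarray(self.t2_values_ms, dtype=float)
        object.__setattr__(self, "t2_values_ms", t2)
        if t2.ndim != 1 or t2.size < 2 or np.any(np.diff(t2) <= 0):
            raise ValueError("t2 grid must be a strictly increasing 1-D vector")
        if t2[0] > 10.0 or t2[-1] < 200.0:
            raise ValueError("t2 grid must span at least [10, 200] ms")

    @property
    def n_bins(self) -> int:
        return self.t2_values_ms.size

    @classmethod
    def default(cls, n_bins: int = 40, t2_min_ms: float = 10.0, t2_max_ms: float = 2000.0) -> "T2Grid":
        """40 log-spaced bins from 10 ms to 2000 ms.

        This placement puts no bin at exactly 40 ms, so the myelin and
        intra/extracellular windows (both closed intervals) never share a bin.
        """
        return cls(np.geomspace(t2_min_ms, t2_max_ms, n_bins))


@dataclass
class T2Spectrum:
    """Non-negative amplitudes over a T2 grid."""

    grid: T2Grid
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        if a.shape != (self.grid.n_bins,):
            raise ValueError("amplitudes must match the grid length")
        if np.any(a < -1e-12):
            raise ValueError("amplitudes must be non-negative")
        self.amplitudes = np.clip(a, 0.0, None)


@dataclass
class EchoTrain:
    """One voxel's multi-echo magnitude decay."""

    signal: np.ndarray
    seq: SequenceParams

    def __post_init__(self) -> None:
        s = np.asarray(self.signal, dtype=float).ravel()
        if s.size != self.seq.n_echoes:
            raise ValueError(
                f"signal length {s.size} does not match n_echoes {self.seq.n_echoes}"
            )
        self.signal = s


@dataclass
class FlipAngleEstimate:
    angle_deg: float
    low_confidence: bool = False


@dataclass
class MwiFit:
    """Result of a single-voxel myelin-water fit."""

    spectrum: T2Spectrum
    mwf: float
    gmt2_ms: float
    flip_angle_deg: float
    chi2: float
    regularizer_mu: float
    flip_low_confidence: bool = False


# ---------------------------------------------------------------------------
# EPG decay


def epg_decay(
    t2_ms,
    seq: SequenceParams,
    flip_angle_deg,
    t1_ms: float | None = None,
) -> np.ndarray:
    """Echo amplitudes of a CPMG train for unit initial magnetization.

    Propagates EPG configuration states (transverse F+/F- and stored
    longitudinal Z) through ``seq.n_echoes`` refocusing pulses of the given
    flip angle, with T2 decay on transverse and T1 decay on stored states
    over each half echo-spacing.  Stimulated-echo pathways generated at flip
    angles < 180 deg are thereby included.  At exactly 180 deg the result
    reduces to ``exp(-TE_n / t2)``.

    ``t2_ms`` and ``flip_angle_deg`` may be scalars or broadcastable arrays;
    the output has shape ``broadcast_shape + (n_echoes,)``.
    """
    t2 = np.asarray(t2_ms, dtype=float)
    alpha = np.asarray(flip_angle_deg, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("t2 must be positive")
    if np.any(alpha <= 0) or np.any(alpha > 180.0):
        raise ValueError("flip angle must be in (0, 180] degrees")
    t1 = seq.t1_ms if t1_ms is None else t1_ms

    t2b, ab = np.broadcast_arrays(t2, alpha)
    batch_shape = t2b.shape
    t2f = t2b.ravel()
    af = np.deg2rad(ab.ravel())
    n_b = t2f.size
    n = seq.n_echoes
    half = seq.echo_spacing_ms / 2.0
    e2 = np.exp(-half / t2f)  # (B,)
    e1 = np.exp(-half / t1) * np.ones_like(e2)

    c2 = np.cos(af / 2) ** 2
    s2 = np.sin(af / 2) ** 2
    sa = np.sin(af)
    ca = np.cos(af)

    k_states = n + 1
    fp = np.zeros((k_states, n_b))
    fm = np.zeros((k_states, n_b))
    w = np.zeros((k_states, n_b))  # stored longitudinal states (phase-rotated)
    fp[0] = 1.0
    fm[0] = 1.0  # F(0) is shared between the +/- half-lines

    echoes = np.empty((n, n_b))
    for i in range(n):
        # relax over TE/2 then dephase one unit
        fp *= e2
        fm *= e2
        w *= e1
        _shift_up(fp, fm)
        # refocusing pulse
        fp_new = c2 * fp + s2 * fm + sa * w
        fm_new = s2 * fp + c2 * fm - sa * w
        w_new = -0.5 * sa * fp + 0.5 * sa * fm + ca * w
        fp, fm, w = fp_new, fm_new, w_new
        fm[0] = fp[0]
        # relax over TE/2 then dephase; echo forms at F(0)
        fp *= e2
        fm *= e2
        w *= e1
        _shift_up(fp, fm)
        echoes[i] = fp[0]

    # magnitude acquisition records |F0|; the signed state can dip slightly
    # negative for very short T2 at late echoes
    return np.abs(np.moveaxis(echoes, 0, -1)).reshape(batch_shape + (n,))


def _shift_up(fp: np.ndarray, fm: np.ndarray) -> None:
    """In-place dephasing shift F(k) -> F(k+1) of the configuration line."""
    fp[1:] = fp[:-1]
    fp[0] = fm[1] if fm.shape[0] > 1 else 0.0
    fm[:-1] = fm[1:]
    fm[-1] = 0.0
    fm[0] = fp[0]


def epg_basis_curve(t2_ms: float, seq: SequenceParams, flip_angle_deg: float) -> np.ndarray:
    """Unit-amplitude EPG decay curve for one T2 value (vector of n_echoes)."""
    return epg_decay(float(t2_ms), seq, float(flip_angle_deg))


def build_basis(grid: T2Grid, seq: SequenceParams, flip_angle_deg: float) -> np.ndarray:
    """Basis matrix (n_echoes x n_bins); column j is the decay at grid T2_j."""
    return epg_decay(grid.t2_values_ms, seq, float(flip_angle_deg)).T


@lru_cache(maxsize=2048)
def _cached_basis_stack(
    seq_key: tuple, grid_key: tuple, angle_key: tuple
) -> np.ndarray:
    """Stack of basis matrices over an angle grid: (n_angles, n_echoes, n_bins)."""
    seq = SequenceParams(*seq_key)
    t2 = np.array(grid_key)
    angles = np.array(angle_key)
    out = epg_decay(t2[None, :], seq, angles[:, None])  # (n_angles, n_bins, n_echoes)
    return np.swapaxes(out, 1, 2)


def _basis_stack(seq: SequenceParams, t2_values: np.ndarray, angles: np.ndarray) -> np.ndarray:
    return _cached_basis_stack(
        (seq.n_echoes, seq.echo_spacing_ms, seq.tr_ms, seq.t1_ms),
        tuple(float(v) for v in t2_values),
        tuple(float(a) for a in angles),
    )


# ---------------------------------------------------------------------------
# NNLS machinery


def nnls(basis: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Solve min ||basis @ a - signal||^2 subject to a >= 0."""
    basis = np.asarray(basis, dtype=float)
    signal = np.asarray(signal, dtype=float).ravel()
    if basis.shape[0] != signal.size:
        raise ValueError("basis and signal are dimensionally inconsistent")
    if not np.any(signal):
        return np.zeros(basis.shape[1])
    a, _ = scipy.optimize.nnls(basis, signal)
    return a


def _chi2(basis: np.ndarray, a: np.ndarray, signal: np.ndarray) -> float:
    r = basis @ a - signal
    return float(r @ r)


def regularized_nnls(
    basis: np.ndarray,
    signal: np.ndarray,
    chi2_window: tuple[float, float] = CHI2_WINDOW_DEFAULT,
    max_iter: int = 60,
) -> tuple[np.ndarray, float, float]:
    """Tikhonov-regularized NNLS with a chi-square misfit window.

    Solves ``min ||A a - y||^2 + mu ||a||^2, a >= 0`` with ``mu`` chosen by
    bisection so the *data* misfit chi2(mu) lies within
    ``[low, high] * chi2_min``, where chi2_min is the unregularized optimum.
    If the window is unattainable (noiseless data, chi2_min ~ 0) the
    unregularized solution is returned with mu = 0.

    Returns ``(amplitudes, mu, chi2)``.
    """
    low, high = chi2_window
    if not (1.0 < low < high):
        raise ValueError("chi2 window must satisfy 1 < low < high")
    basis = np.asarray(basis, dtype=float)
    signal = np.asarray(signal, dtype=float).ravel()
    a0 = nnls(basis, signal)
    chi2_min = _chi2(basis, a0, signal)
    y_norm2 = float(signal @ signal)
    # essentially-noiseless data: the residual of an off-grid two-pool
    # signal against a 40-bin basis is ~1e-8 of the signal energy, orders of
    # magnitude below any realistic noise floor (SNR 2000 gives ~2.5e-6)
    if chi2_min <= 1e-6 * max(y_norm2, 1.0):
        logger.debug("chi2 window unattainable (chi2_min ~ 0); returning mu = 0")
        return a0, 0.0, chi2_min

    n_bins = basis.shape[1]
    aug_y = np.concatenate([signal, np.zeros(n_bins)])
    eye = np.eye(n_bins)

    def solve(mu: float) -> tuple[np.ndarray, float]:
        aug_a = np.vstack([basis, np.sqrt(mu) * eye])
        a, _ = scipy.optimize.nnls(aug_a, aug_y)
        return a, _chi2(basis, a, signal)

    # bracket: grow mu until chi2 exceeds the window top
    scale = float(np.trace(basis.T @ basis)) / n_bins
    mu_lo, mu_hi = 0.0, 1e-6 * scale
    a_hi, c_hi = solve(mu_hi)
    grow = 0
    while c_hi < high * chi2_min and grow < 60:
        mu_lo = mu_hi
        mu_hi *= 4.0
        a_hi, c_hi = solve(mu_hi)
        grow += 1
    best_a, best_mu, best_c = a_hi, mu_hi, c_hi
    for _ in range(max_iter):
        if low * chi2_min <= best_c <= high * chi2_min:
            break
        mu_mid = 0.5 * (mu_lo + mu_hi)
        a_mid, c_mid = solve(mu_mid)
        if c_mid < low * chi2_min:
            mu_lo = mu_mid
        else:
            mu_hi = mu_mid
            best_a, best_mu, best_c = a_mid, mu_mid, c_mid
        if mu_hi - mu_lo <= 1e-12 * max(mu_hi, 1.0):
            break
    return best_a, best_mu, best_c


# ---------------------------------------------------------------------------
# flip-angle estimation


def default_angle_grid(step_deg: float = 2.0) -> np.ndarray:
    """Refocusing-angle search grid, 90-180 degrees inclusive."""
    return np.arange(90.0, 180.0 + 1e-9, step_deg)


_COARSE_GRID_BINS = 8


def estimate_flip_angle(
    echo: EchoTrain,
    grid: T2Grid | None = None,
    angle_grid: np.ndarray | None = None,
) -> FlipAngleEstimate:
    """Estimate the refocusing flip angle from the decay shape.

    For each candidate angle, the unregularized NNLS residual of the signal
    against a coarse (8-bin) EPG basis is computed; the angle minimizing the
    residual is refined by parabolic interpolation around the grid minimum.
    A flat residual profile (pure-noise voxel) returns 180 degrees flagged
    as low confidence.
    """
    angle_grid = default_angle_grid() if angle_grid is None else np.asarray(angle_grid, float)
    if angle_grid[0] > 90.0 or angle_grid[-1] < 180.0:
        raise ValueError("angle grid must cover [90, 180] degrees")
    if grid is None:
        grid = T2Grid.default()
    coarse_t2 = np.geomspace(grid.t2_values_ms[0], grid.t2_values_ms[-1], _COARSE_GRID_BINS)
    stack = _basis_stack(echo.seq, coarse_t2, angle_grid)
    y = echo.signal
    resid = np.empty(angle_grid.size)
    for i in range(angle_grid.size):
        a, r = scipy.optimize.nnls(stack[i], y)
        resid[i] = r
    i_min = int(np.argmin(resid))
    spread = resid.max() - resid.min()
    if spread <= 1e-9 * max(resid.max(), 1e-30):
        return FlipAngleEstimate(180.0, low_confidence=True)
    if i_min == 0 or i_min == angle_grid.size - 1:
        return FlipAngleEstimate(float(angle_grid[i_min]), low_confidence=False)
    # parabolic refinement on the residual profile
    x0, x1, x2 = angle_grid[i_min - 1 : i_min + 2]
    y0, y1, y2 = resid[i_min - 1 : i_min + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom <= 0:
        angle = float(angle_grid[i_min])
    else:
        angle = float(x1 + 0.5 * (y0 - y2) / denom * (x1 - x0))
        angle = float(np.clip(angle, angle_grid[0], angle_grid[-1]))
    return FlipAngleEstimate(angle, low_confidence=False)


# ---------------------------------------------------------------------------
# spectral metrics


def compute_mwf(spec: T2Spectrum, window_ms: tuple[float, float] = MYELIN_WINDOW_MS) -> float:
    """Myelin water fraction: windowed spectral area / total area.

    Returns NaN when the spectrum has zero total amplitude (undefined).
    """
    a = spec.amplitudes
    total = a.sum()
    if total <= 0:
        return float("nan")
    t2 = spec.grid.t2_values_ms
    in_win = (t2 >= window_ms[0]) & (t2 <= window_ms[1])
    return float(a[in_win].sum() / total)


def compute_gmt2(spec: T2Spectrum, window_ms: tuple[float, float] = IE_WINDOW_MS) -> float:
    """Geometric mean T2 (ms) of the spectrum restricted to a window.

    Amplitude-weighted mean of ln(T2) over the window, exponentiated.
    Returns NaN when the window holds no amplitude (undefined).
    """
    a = spec.amplitudes
    t2 = spec.grid.t2_values_ms
    in_win = (t2 >= window_ms[0]) & (t2 <= window_ms[1])
    wsum = a[in_win].sum()
    if wsum <= 0:
        return float("nan")
    return float(np.exp(np.sum(a[in_win] * np.log(t2[in_win])) / wsum))


# ---------------------------------------------------------------------------
# voxel / volume fits


def fit_voxel(
    echo: EchoTrain,
    grid: T2Grid | None = None,
    chi2_window: tuple[float, float] = CHI2_WINDOW_DEFAULT,
    angle_grid: np.ndarray | None = None,
    flip_angle_deg: float | None = None,
) -> MwiFit:
    """Full single-voxel myelin-water fit.

    Pipeline: estimate the refocusing flip angle (unless given), build the
    EPG basis at that angle, solve the regularized NNLS, derive MWF and GMT2.
    """
    if not np.all(np.isfinite(echo.signal)):
        raise ValueError("echo train contains non-finite values")
    grid = T2Grid.default() if grid is None else grid
    if flip_angle_deg is None:
        est = estimate_flip_angle(echo, grid, angle_grid)
        # quantize to 0.25 deg so the basis cache is shared across voxels;
        # well below the angle-estimation noise floor
        basis_angle = round(est.angle_deg * 4.0) / 4.0
    else:
        est = FlipAngleEstimate(float(flip_angle_deg))
        basis_angle = est.angle_deg
    basis = _basis_stack(echo.seq, tuple(grid.t2_values_ms), (basis_angle,))[0]
    a, mu, chi2 = regularized_nnls(basis, echo.signal, chi2_window)
    spec = T2Spectrum(grid, a)
    return MwiFit(
        spectrum=spec,
        mwf=compute_mwf(spec),
        gmt2_ms=compute_gmt2(spec),
        flip_angle_deg=est.angle_deg,
        chi2=chi2,
        regularizer_mu=mu,
        flip_low_confidence=est.low_confidence,
    )


def fit_volume(
    echo_data: np.ndarray,
    mask: np.ndarray,
    seq: SequenceParams,
    grid: T2Grid | None = None,
    chi2_window: tuple[float, float] = CHI2_WINDOW_DEFAULT,
    angle_grid: np.ndarray | None = None,
    log_every: int = 5000,
) -> dict[str, np.ndarray]:
    """Voxelwise myelin-water fit over a 4D volume (x, y, z, echo).

    Returns float maps ``mwf``, ``gmt2``, ``flip`` (NaN outside the mask or
    where the voxel was rejected).
    """
    echo_data = np.asarray(echo_data, dtype=float)
    if echo_data.ndim != 4 or echo_data.shape[-1] != seq.n_echoes:
        raise ValueError(
            f"expected 4D data with {seq.n_echoes} echoes, got shape {echo_data.shape}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != echo_data.shape[:3]:
        raise ValueError("mask shape does not match volume")
    grid = T2Grid.default() if grid is None else grid
    maps = {k: np.full(mask.shape, np.nan) for k in ("mwf", "gmt2", "flip")}
    idx = np.argwhere(mask)
    n_bad = 0
    for count, (i, j, k) in enumerate(idx):
        sig = echo_data[i, j, k]
        if not np.all(np.isfinite(sig)) or not np.any(sig):
            n_bad += 1
            continue
        fit = fit_voxel(EchoTrain(sig, seq), grid, chi2_window, angle_grid)
        maps["mwf"][i, j, k] = fit.mwf
        maps["gmt2"][i, j, k] = fit.gmt2_ms
        maps["flip"][i, j, k] = fit.flip_angle_deg
        if log_every and (count + 1) % log_every == 0:
            logger.info("mwi fit: %d / %d voxels", count + 1, len(idx))
    if n_bad:
        logger.warning("mwi fit: rejected %d non-finite/empty voxels", n_bad)
    return maps
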