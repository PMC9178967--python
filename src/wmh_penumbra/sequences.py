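"""Acquisition descriptions: multi-echo spin-echo trains and diffusion schemes.

Two "scanner" configurations are bundled, mirroring a two-site study design
in which one scanner runs a 32-echo GRASE sequence (10 ms echo spacing) and
the other a 48-echo sequence (8 ms echo spacing).  The diffusion scheme is a
single-shell HARDI acquisition with 60 non-collinear gradients at
b = 700 s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SequenceParams",
    "DiffusionScheme",
    "SCANNER_A_32ECHO",
    "SCANNER_B_48ECHO",
    "make_hardi_scheme",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]


@dataclass(frozen=True)
class SequenceParams:
    """Multi-echo spin-echo (CPMG/GRASE) timing parameters.

    The first echo is assumed to occur at ``echo_spacing_ms`` and subsequent
    echoes at integer multiples thereof.  ``t1_ms`` is the longitudinal
    relaxation time assumed when propagating stored magnetization through the
    refocusing train; estimates are insensitive to it at typical TRs.
    """

    n_echoes: int
    echo_spacing_ms: float
    tr_ms: float = 1000.0
    t1_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_echoes < 8:
            raise ValueError(f"n_echoes must be >= 8, got {self.n_echoes}")
        if self.echo_spacing_ms <= 0:
            raise ValueError("echo_spacing_ms must be positive")
        if self.t1_ms <= 0:
            raise ValueError("t1_ms must be positive")

    @property
    def echo_times_ms(self) -> np.ndarray:
        """Echo times TE_n = n * echo spacing, n = 1..n_echoes, in ms."""
        return self.echo_spacing_ms * np.arange(1, self.n_echoes + 1)


#: 32-echo configuration (TR/TE = 1000/10 ms).
SCANNER_A_32ECHO = SequenceParams(n_echoes=32, echo_spacing_ms=10.0, tr_ms=1000.0)
#: 48-echo configuration (TR/TE = 1073/8 ms).
SCANNER_B_48ECHO = SequenceParams(n_echoes=48, echo_spacing_ms=8.0, tr_ms=1073.0)


@dataclass
class DiffusionScheme:
    """Single-shell diffusion gradient table.

    bvals are in s/mm^2; bvecs are unit 3-vectors (one row per volume).
    Non-unit weighted directions are normalized on construction with a
    warning, matching common scanner-export tolerance.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    _normalized: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, self.bvals.size) and self.bvecs.shape[0] != self.bvecs.shape[1]:
            self.bvecs = self.bvecs.T
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} inconsistent with {self.bvals.size} bvals"
            )
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-6):
            import logging

            logging.getLogger(__name__).warning(
                "normalizing %d non-unit diffusion directions", int((np.abs(norms - 1) > 1e-6).sum())
            )
            self.bvecs = self.bvecs.copy()
            self.bvecs[weighted] /= norms[:, None]
            self._normalized = True
        n_weighted = int(weighted.sum())
        if n_weighted < 6 or (~weighted).sum() < 1:
            raise ValueError("scheme needs >= 6 weighted directions and >= 1 b=0 volume")

    @property
    def n_volumes(self) -> int:
        return self.bvals.size


def make_hardi_scheme(
    n_directions: int = 60, b_value: float = 700.0, n_b0: int = 1
) -> DiffusionScheme:
    """Build a single-shell scheme with near-uniform directions.

    Directions are placed on a spherical Fibonacci lattice (restricted to a
    hemisphere, as diffusion encoding is antipodally symmetric), which
    guarantees non-collinearity for any ``n_directions`` >= 6.
    """
    i = np.arange(n_directions)
    golden = (1 + 5**0.5) / 2
    # hemisphere: z in (0, 1]
    z = (i + 0.5) / n_directions
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvals=bvals, bvecs=bvecs)


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    """Read FSL-style gradient tables (1 row of bvals; 3 rows of bvecs)."""
    bvals = np.loadtxt(bval_path)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionScheme(bvals=bvals, bvecs=bvecs)


def write_bvals_bvecs(scheme: DiffusionScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write FSL-style gradient tables."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")
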