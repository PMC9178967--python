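"""Fit a single voxel's multi-echo decay and read off MWF and GMT2.

Simulates a two-pool voxel (15% myelin water at T2 = 20 ms, the rest at
80 ms) acquired with a 32-echo train at an imperfect 140-degree refocusing
angle and SNR 200, then runs the full estimation chain: flip-angle search,
EPG basis construction, chi-square-windowed regularized NNLS.
"""

import numpy as np

from wmh_penumbra.phantom import simulate_echo_train
from wmh_penumbra.relaxometry import fit_voxel
from wmh_penumbra.sequences import SCANNER_A_32ECHO

rng = np.random.default_rng(3)
train = simulate_echo_train(
    mwf=0.15, ie_t2=80.0, flip_angle=140.0, seq=SCANNER_A_32ECHO,
    s0=800.0, noise_sigma=4.0, rng=rng,
)
fit = fit_voxel(train)

print(f"estimated MWF        : {fit.mwf:.3f}   (true 0.150)")
print(f"estimated GMT2       : {fit.gmt2_ms:.1f} ms (true IE pool at 80 ms)")
print(f"estimated flip angle : {fit.flip_angle_deg:.1f} deg (true 140.0)")
print(f"regularization mu    : {fit.regularizer_mu:.2e}, chi2 = {fit.chi2:.1f}")
# MWF is the spectral area in 10-40 ms over the total area; GMT2 is the
# log-scale amplitude-weighted mean T2 of the 40-200 ms (intra/extra-
# cellular water) band.  MWF carries a small negative bias from the
# regularization's spectral smoothing -- see docs/methods.md.
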