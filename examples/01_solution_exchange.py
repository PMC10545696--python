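"""Calibrate the solution-exchange time constant from a K+-jump trace.

Builds a synthetic current relaxation for a 150 -> 120 mM jump of the
permeant K+ concentration at fully open channels, fits the
delayed-exponential exchange model to it, and rescales the fitted tau to
the ligand (cGMP) through the ratio of diffusion coefficients.
"""

import numpy as np

import gatefit as gf
from gatefit.exchange import T0_OVER_TAU
from gatefit.trace import Trace

# synthetic K+-jump current: tau = 1.1 ms (a fast patch), 1% noise
tau_true = 1.1e-3
dt = 1e-4
t = np.arange(int(15 * tau_true / dt)) * dt
t0 = tau_true * T0_OVER_TAU
current = -250.0 - 50.0 * np.exp(-np.maximum(t - t0, 0.0) / tau_true)
rng = np.random.default_rng(1)
trace = Trace(time=t, current=current + rng.normal(0, 0.5, t.size))

fit = gf.fit_exchange_tau(trace)
tau_cgmp = fit.ligand_tau()  # K+ -> cGMP via D_K / D_cGMP

print(f"true tau_K      : {tau_true * 1e3:.3f} ms")
print(f"fitted tau_K    : {fit.tau * 1e3:.3f} ms  (delay t0 = {fit.t0 * 1e3:.3f} ms)")
print(f"t0 / tau        : {fit.t0 / fit.tau:.4f}  (= ln(4/pi) ~ 0.24)")
print(f"tau for cGMP    : {tau_cgmp * 1e3:.3f} ms  (slower: D_cGMP < D_K)")
print()
print("The K+ jump measures how fast ANY solute reaches the patch; the")
print("ligand is slower by the ratio of diffusion coefficients, and this")
print("tau is what deforms every nominal concentration step at the patch.")
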