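"""Discriminate binding mechanisms with a complex concentration protocol.

Generates a noisy (1000-channel) response of a cooperative two-step
scheme to a multi-level pulse train, fits competing schemes (one binding
step; two independent identical sites; two cooperative steps) and ranks
them by reduced SSR, counting each concentration jump as one degree of
freedom.
"""

import numpy as np

import gatefit as gf

UM = 1e-6
truth = np.array([2e7, 100.0, 1e6, 1000.0])
m44 = gf.build_sequential_model(2, True, 990, 10)

levels = [0.5, 4, 100, 1, 16, 0.0, 50, 2, 25, 8, 100, 6]
proto = gf.complex_protocol([(l * UM, 0.25) for l in levels])
conc = gf.correct_protocol(proto, 1.1e-3, dt=5e-4)
data = gf.simulate_stochastic(m44, truth, conc, n_channels=1000, seed=11)
nj = proto.n_jumps()

fits = [
    gf.global_fit(gf.build_sequential_model(1, True, 990, 10), conc, data,
                  theta0=[1e6, 300.0], n_jumps=nj),
    gf.global_fit(gf.build_sequential_model(2, False, 990, 10), conc, data,
                  theta0=[1e6, 300.0], n_jumps=nj),
    gf.global_fit(m44, conc, data, theta0=truth * [0.5, 2, 0.5, 2], n_jumps=nj),
]
ranking = gf.rank_models(fits)
print(ranking.table().to_string(index=False))
print()
best = ranking.best
print(f"best model: {best.model_label}")
for name, val, sd in zip(best.param_names, best.theta_hat, best.sd):
    print(f"  {name:>4s} = {val:.4g}  (SD {sd:.2g})")
for a, b, rho in gf.underdetermination_report(best, threshold=0.99):
    print(f"  note: {a} and {b} are strongly correlated "
          f"(rho = {rho:+.4f}; their ratio is far better determined)")
K1 = best.theta_hat[0] / best.theta_hat[1]
print(f"  K1 = k1/k-1 = {K1:.3g} /M  (truth {truth[0] / truth[1]:.3g} /M)")
print()
print("Only the cooperative two-step scheme reaches the noise floor;")
print("forcing identical independent sites fits no better than a single")
print("binding step, so the data demand step-specific (cooperative) rates.")
print("The fast first binding step equilibrates within each pulse, so the")
print("noisy data mainly pin its equilibrium constant K1; the correlation")
print("report shows which individual rates to distrust.")
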