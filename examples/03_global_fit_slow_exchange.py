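"""Rate constants survive a 50-fold slower solution exchange.

Simulates the open-probability response of a two-state C-O scheme to a
concentration step whose exchange time constant is 50x the channel's
activation time constant, then fits both rate constants with the
exchange time course embedded in the forward model.
"""

import numpy as np

import gatefit as gf

k_open, k_close = 9e6, 100.0  # 1/(M s), 1/s
truth = np.array([k_open, k_close])
model = gf.build_co_model(k_open, k_close)

c_step = 1e-4  # 100 uM
tau_a = 1.0 / (k_open * c_step + k_close)   # activation time constant
tau_s = 50 * tau_a                          # much slower exchange
print(f"activation tau_a = {tau_a * 1e3:.2f} ms, exchange tau_s = {tau_s * 1e3:.1f} ms")

proto = gf.complex_protocol([(0.0, 0.02), (c_step, 0.3), (0.0, 0.3)])
conc = gf.correct_protocol(proto, tau_s, dt=5e-4)
data = gf.simulate_deterministic(model, truth, conc)

fit = gf.global_fit(model, conc, data, theta0=truth * [3, 0.3],
                    n_jumps=proto.n_jumps())
err = np.abs(fit.theta_hat / truth - 1)
print(f"fitted k_open  = {fit.theta_hat[0]:.6g} /M/s  (rel. error {err[0]:.1e})")
print(f"fitted k_close = {fit.theta_hat[1]:.6g} /s    (rel. error {err[1]:.1e})")
print(f"converged after {fit.n_iter} iterations, S = {fit.S:.3e}")
print()
print("Although the concentration step at the patch is 50x slower than the")
print("gating it probes, embedding the exchange model in the fit recovers")
print("both rate constants to machine precision on noiseless data.")
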