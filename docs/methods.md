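# Methods

This note records the models implemented in `gatefit`, their
assumptions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Gating schemes

Channels are modelled as continuous-time Markov chains. The sequential
activation schemes are chains `C0 <-> ... <-> Cm <-> O` with `m`
ligand-binding steps (m = 1..4) followed by one conformational opening
step; there is exactly one conducting state. Every binding rate is
strictly linear in ligand concentration (no saturation of the binding
step itself), rates are concentration-independent otherwise, and voltage
dependence, desensitised states and single-channel dwell-time structure
are out of scope.

*Cooperative* schemes give each step its own microscopic pair
(k_j, k_-j), so a scheme with `s = m + 2` states has `p = 2m` free
parameters (labels 3s2p, 4s4p, 5s6p, 6s8p). *Independent* schemes
assume `m` identical, independent sites sharing one microscopic pair
(k_on, k_off); the aggregated occupancy chain then carries statistical
factors `(m - j + 1)` forward and `j` backward. This aggregation is an
exact lumping of the `2^m`-microstate site model, which the test suite
verifies by brute-force enumeration. The opening/closing rates e+/e-
are treated as known and fixed (990/10 1/s by default, the literature
range for CNGA2-class channels) — freeing them as well is possible via
the same interface but is not the default analysis.

The two-state C-O scheme (ligand-dependent opening `k_open·c`, constant
closing) is the minimal model used throughout the robustness studies;
its activation time constant at concentration c is
`tau_a = 1/(k_open·c + k_close)`.

## Propagation

The master equation `dp/dt = p·Q(c, θ)` is solved exactly on
piecewise-constant concentration segments by the eigenvalue method:
`p(t + Δ) = p(t)·V·exp(ΛΔ)·V⁻¹`. Because `Q` is affine in
concentration, `Q(c) = A + c·B`, the propagators for a whole trace are
built in one batched eigendecomposition over the distinct concentration
values. When the eigenvector matrix is ill-conditioned (condition
number > 1e12, as happens for near-defective generators at extreme
parameter values during optimisation) the implementation falls back to
scaling-and-squaring (`scipy.linalg.expm`), which is unconditionally
stable; rows of each propagator are checked to sum to one within 1e-9.
Probability mass is renormalised after each step (drift is at the
1e-12 level) and any violation beyond 1e-8 raises an error naming the
segment.

Continuous concentration time courses are discretised
piecewise-constant at 0.5 ms (the standard concentration step width)
using the interval-midpoint value; the midpoint rule halves the
discretisation bias of a left-edge rule. State probabilities are
carried continuously across pulse boundaries — no re-equilibration —
and the first segment starts at the stationary distribution of its own
concentration (for protocols beginning at zero ligand this is the
resting state; whether real recordings start exactly at rest is an
assumption, and a caller can supply any initial distribution).

## Solution exchange

The ligand concentration at a patch located a distance `L` inside the
pipette follows the diffusion solution for a cylindrical column with a
reflecting membrane, an alternating Fourier series with time constant
`τ = 4L²/(Dπ²)`. The series is summed until the next term falls below
1e-10 of the step amplitude (a rigorous bound for an alternating
series; cap 1e4 terms). After an initial sigmoid onset the series is
approximated by its first term: a monoexponential with delay
`t0 = τ·ln(4/π) ≈ 0.24 τ`. For `t < t0` the implementation holds the
concentration at its starting value `c1`, which keeps the curve
continuous at `t0` and reduces to the published zero branch when
`c1 = 0`; a strict zero-branch mode is available for reproduction.
Convection outside the pipette is ignored (lumped into τ), as are 2-D
and 3-D geometries.

τ is calibrated per patch by fitting the delayed exponential to a
K⁺-jump current (150 → 120 mM at saturating ligand). The delay is
constrained to `t0 = τ·ln(4/π)` because the diffusion solution fixes
that ratio; a free-delay variant exists for robustness checks. A fitted
amplitude below three residual RMS flags the calibration as
low-confidence. The fitted τ transfers to the ligand via
`τ_ligand = τ_K · D_K / D_ligand` (L is geometry, not chemistry);
shipped coefficients are D_K = 1.96e-5 and D_cAMP = D_cGMP = 4.4e-6
cm²/s, extensible through a user table.

Protocol correction chains delayed exponentials across segments: each
nominal step relaxes from the *effective* concentration reached at the
switch toward the new level, so incomplete relaxations compose
correctly and the output is always bounded by the nominal levels.

## Synthetic data

The stochastic generator models a macropatch as `N` independent
channels (default 1000, the population used in the robustness
simulations). Per sampling interval the channels in each state are
redistributed by one multinomial draw from the exact interval
transition matrix `exp(QΔ)` — the true conditional law on the sampling
grid — rather than by event-by-event simulation; this is exact at the
sample times and fast at millisecond resolution. Currents are
`I = N·i·Po + leak` plus optional seeded Gaussian recording noise.
Default sampling is 2 kHz for complex-protocol fixtures and 10 kHz
where activation is fast.

What the generator does *not* emulate: amplifier/Bessel filtering,
capacitive and vibration artefacts, run-down, desensitisation, channel
number drift, and correlated (non-shot) noise. Passing tests therefore
demonstrate correctness of the inference chain under idealised
macropatch statistics, not robustness to every artefact of real
recordings.

Fixture rate sets are demonstration choices, not published constants
(the underlying recordings and their fitted rates are not publicly
tabulated). The model-discrimination fixture uses a cooperative
two-step truth with a kinetically distinct second step
(k1 = 2e7 /M/s, k-1 = 100 /s, k2 = 1e6 /M/s, k-2 = 1000 /s): the
second site binds more slowly and releases faster than the first, which
no identical-site scheme with statistical factors can imitate. This is
the regime in which reduced-SSR ranking separates binding mechanisms
most cleanly; with nearly identical or on-rate-amplified steps the
independent schemes absorb most of the c² character and the contrast
against single-step binding shrinks.

## Global fitting

The objective is the summed squared residual
`S = Σ (Po,m(t_i) − Po,c(t_i, θ))²`; under the constant-variance
assumption the weighted χ² is `S/σ̄²` with `σ̄² = S/(n − k − 1)`, so
only S needs minimising (per-point weights are accepted optionally).
Minimisation is Levenberg–Marquardt in log-parameter space, which
enforces positivity and makes steps scale-free:

- forward-difference Jacobian, step 1e-6 in log space;
- damping initialised at 1e-3, ×10 on rejection, ÷10 on acceptance;
- convergence when the relative S change stays below 1e-9 for three
  consecutive iterations (or the gradient vanishes); default cap 100
  iterations;
- default log-space bounds at ±ln(1e15) keep trial rates finite; a
  trial step that breaks the propagator is treated as rejected.

The covariance is `σ̄²·(JᵀJ)⁻¹` with J evaluated in *linear* parameter
space at the optimum (chain rule from the log-space Jacobian), standard
errors are its diagonal roots, and the correlation matrix follows.
Determinacy is judged on the correlation-normalised Hessian — the raw
condition number is inflated by rate-magnitude disparity alone — with
fits beyond condition 1e10 flagged underdetermined and inverted by
pseudo-inverse. `underdetermination_report` lists parameter pairs with
|ρ| above a threshold (default 0.999): such pairs are determined only
in combination (typically their ratio).

Model ranking uses the reduced SSR `S/(n_jumps − k)`. Successive
samples of a relaxation are strongly correlated, so the number of
*concentration jumps* — every non-calibration segment whose level
differs from its predecessor, the first always counting — is used as
the degrees of freedom, a deliberately conservative choice. Fits that
did not converge, are flagged underdetermined, or have `n_jumps ≤ k`
are reported but never ranked. When fitting nested expansions of a
scheme, the extra binding step is initialised near-transparent (fast
and tight) so the larger model starts from the smaller model's
behaviour instead of a remote local minimum.

Identifiability in practice: fitting rectangular (uncorrected)
protocols to exchange-smoothed data does not reproduce the generating
rates — the optimiser compensates the missing smoothing with a slow
binding cascade (small k-1, k1 ≈ k2), a biased but locally
well-conditioned solution whose S is orders of magnitude above the
corrected-protocol fit. Embedding the corrected time course removes
both the bias and that compensation. Genuine |ρ| → 1 ridges arise
whenever a binding step is kinetically invisible at the probed
concentrations (fleeting or pre-equilibrated intermediates); the
correlation report exists precisely to expose them.

## Hill fits and trace summaries

Quasi-equilibrium concentration–response points are the mean signal
over the terminal window of each pulse (last 5% of the step by default;
a fixed last-0.6-ms window is available for fast-channel work). The
Hill fit `I/Imax = 1/(1 + (EC50/c)^n)` uses the zero-concentration
response for offset correction and the saturating (highest, latest
occurring) concentration for normalisation, excluding both from the
fit; at least three points must remain. The hysteresis index is the
signed area between normalised decremental and incremental branches on
the log-concentration axis; positive when deactivation lags, and
shrinking toward zero as pulse duration approaches equilibration.

## Problem sizes

Tests and the acceptance script use scaled-down protocols chosen for
desk-scale runtimes while preserving the study conditions: 12×250 ms
multi-level pulse trains (0–100 µM, 2 kHz, 0.5 ms concentration steps)
for model discrimination; two-segment step protocols of ~30 exchange
time constants for the C–O robustness studies; 10 seeded replicates at
N = 1000 for stochastic recovery; τ-miscalibration is assessed at an
exchange-to-activation ratio of 2, representative of fast patches —
the 10%/25% error bands widen roughly linearly with that ratio, which
the sensitivity table in the test suite makes explicit.

## Units

Rates are stored in 1/s and 1/(M·s), concentrations in molar, lengths
in cm and diffusion coefficients in cm²/s. Files (traces, reports) are
SI; configuration files accept µM (the bench convention) but must name
the unit explicitly.
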