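"""Deterministic and stochastic simulation of macropatch responses.

Deterministic traces are the exact solution of the master equation under
the (possibly exchange-corrected) piecewise-constant concentration trace.
Stochastic traces model a finite population of N independent channels:
per sampling interval the channels in each state are redistributed by a
multinomial draw from the exact interval transition matrix expm(Q*dt) —
the true conditional law on the sampling grid, so no Gillespie event loop
is needed.  Currents are obtained by scaling Po with the channel count and
single-channel amplitude, plus optional leak and Gaussian recording noise.
"""

from __future__ import annotations

import numpy as np

from .models import KineticModel, ModelError
from .propagate import (
    PropagationError,
    _batched_expm,
    propagate_piecewise,
    stationary_distribution,
)
from .trace import Trace

__all__ = ["simulate_deterministic", "simulate_stochastic", "to_current"]


def _conc_and_dt(conc_trace: Trace) -> tuple[np.ndarray, float]:
    if conc_trace.conc is None:
        raise ValueError("conc_trace must carry a concentration array")
    return conc_trace.conc, conc_trace.dt


def simulate_deterministic(
    model: KineticModel,
    theta,
    conc_trace: Trace,
    dt_state: float | None = None,
    p0: np.ndarray | None = None,
) -> Trace:
    """Exact open-probability response to a concentration trace.

    The initial state is the stationary distribution at the first
    concentration unless ``p0`` is given.  ``dt_state`` may refine the
    propagation grid but must divide the sampling interval; because the
    piecewise-constant propagator is exact it only matters for callers
    wanting sub-sample state output and defaults to the sampling interval.
    """
    conc, dt = _conc_and_dt(conc_trace)
    if dt_state is not None:
        ratio = dt / dt_state
        if abs(ratio - round(ratio)) > 1e-9:
            raise ModelError("dt_state must divide the sampling interval")
    try:
        po, _ = propagate_piecewise(model, theta, conc, dt, p0=p0)
    except PropagationError as err:
        raise PropagationError(f"deterministic simulation failed: {err}") from err
    return conc_trace.replace(po=po, meta={**conc_trace.meta, "model": model.label})


def simulate_stochastic(
    model: KineticModel,
    theta,
    conc_trace: Trace,
    n_channels: int,
    seed: int,
    p0: np.ndarray | None = None,
) -> Trace:
    """Finite-population gating noise: N channels, multinomial updates.

    ``po[i]`` is the open fraction at sample time i; the initial channel
    counts are a multinomial draw from the stationary distribution at the
    first concentration.  Fully reproducible under a fixed seed.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    conc, dt = _conc_and_dt(conc_trace)
    rng = np.random.default_rng(seed)

    if p0 is None:
        p0 = stationary_distribution(model, theta, conc[0])
    A, B = model.split_matrices(theta)
    levels, inverse = np.unique(conc, return_inverse=True)
    props = _batched_expm(A[None] + levels[:, None, None] * B[None], dt)
    # clip tiny negative round-off and renormalise rows for sampling
    props = np.clip(props, 0.0, None)
    props /= props.sum(axis=2, keepdims=True)

    s = model.n_states
    open_idx = list(model.open_states)
    counts = rng.multinomial(n_channels, p0 / p0.sum())
    po = np.empty(conc.size)
    for i in range(conc.size):
        po[i] = counts[open_idx].sum() / n_channels
        P = props[inverse[i]]
        new = np.zeros(s, dtype=np.int64)
        for state in np.nonzero(counts)[0]:
            new += rng.multinomial(counts[state], P[state])
        counts = new
    meta = {**conc_trace.meta, "model": model.label, "n_channels": n_channels,
            "seed": seed}
    return conc_trace.replace(po=po, meta=meta)


def to_current(
    po_trace: Trace,
    n_channels: int,
    i_single: float,
    leak: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Trace:
    """Scale Po to macroscopic current: I = N * i * Po + leak + noise (pA)."""
    if po_trace.po is None:
        raise ValueError("po_trace must carry open probabilities")
    if i_single < 0:
        raise ValueError("single-channel amplitude must be non-negative")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when adding recording noise")
    current = n_channels * i_single * po_trace.po + leak
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=current.shape)
    meta = {**po_trace.meta, "n_channels": n_channels, "i_single_pA": i_single,
            "leak_pA": leak, "noise_sd_pA": noise_sd}
    if seed is not None:
        meta["noise_seed"] = seed
    return po_trace.replace(current=current, meta=meta)
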