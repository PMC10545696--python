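"""Shared fixtures: small models, protocols and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg

import gatefit as gf

UM = 1e-6


@pytest.fixture(scope="session")
def co_model():
    """Two-state C-O model with activation time constant 1 ms at 100 uM."""
    return gf.build_co_model(9e6, 100.0)


@pytest.fixture(scope="session")
def co_truth():
    return np.array([9e6, 100.0])


@pytest.fixture(scope="session")
def m44():
    """Cooperative two-binding-step scheme with e+/e- = 990/10 1/s."""
    return gf.build_sequential_model(2, True, 990.0, 10.0)


@pytest.fixture(scope="session")
def m44_truth():
    """Well-determined symmetric rate set used for recovery tests."""
    return np.array([5e6, 500.0, 5e6, 500.0])


@pytest.fixture(scope="session")
def pulse_protocol():
    """Short multi-level pulse train spanning 0-100 uM."""
    levels = [0.5, 4, 100, 1, 16, 0.0, 50, 2, 25, 8, 100, 6]
    return gf.complex_protocol([(l * UM, 0.25) for l in levels])


def dense_ode_po(model, theta, conc, dt, p0, substep=1e-6):
    """Independent oracle: fixed-step RK4 integration of dp/dt = p Q(c).

    Integrates the master equation densely (step <= 1 us) through the
    piecewise-constant concentration sequence and returns Po at the sample
    times, matching the convention of ``propagate_piecewise``.
    """
    open_idx = list(model.open_states)
    p = np.asarray(p0, float).copy()
    po = np.empty(len(conc))
    n_sub = int(round(dt / substep))
    for i, c in enumerate(conc):
        po[i] = p[open_idx].sum()
        Q = gf.q_matrix(model, theta, c)
        h = dt / n_sub
        for _ in range(n_sub):
            k1 = p @ Q
            k2 = (p + 0.5 * h * k1) @ Q
            k3 = (p + 0.5 * h * k2) @ Q
            k4 = (p + h * k3) @ Q
            p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return po


def microstate_independent_po(m, k_on, k_off, e_plus, e_minus, conc, dt):
    """Independent oracle: explicit 2^m-site microstate chain, aggregated.

    Enumerates every subset of bound sites as its own state (plus one open
    state reachable from the fully liganded microstate) and propagates with
    scipy's expm; equivalent by symmetry to the (m+2)-state aggregated
    scheme with statistical factors.
    """
    n_micro = 1 << m
    n = n_micro + 1  # + open state
    full = n_micro - 1
    Po = np.empty(len(conc))
    # start unliganded closed
    p = np.zeros(n)
    p[0] = 1.0
    for i, c in enumerate(conc):
        Po[i] = p[-1]
        Q = np.zeros((n, n))
        for s in range(n_micro):
            for site in range(m):
                if not s & (1 << site):
                    Q[s, s | (1 << site)] += k_on * c
                else:
                    Q[s, s & ~(1 << site)] += k_off
        Q[full, n_micro] += e_plus
        Q[n_micro, full] += e_minus
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        p = p @ scipy.linalg.expm(Q * dt)
    return Po


def sequential_stationary_po(theta, e_plus, e_minus, conc):
    """Closed-form stationary Po of the cooperative sequential scheme.

    Detailed balance along the chain gives p(Cj) proportional to the
    product of the equilibrium constants K_i * c up to step j, and
    p(O) = p(Cm) * e+/e-.
    """
    m = len(theta) // 2
    weights = [1.0]
    for j in range(m):
        K = theta[2 * j] / theta[2 * j + 1]
        weights.append(weights[-1] * K * conc)
    weights.append(weights[-1] * e_plus / e_minus)
    return weights[-1] / sum(weights)
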