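"""Exact propagation of state probabilities on piecewise-constant segments.

The master equation dp/dt = p Q(c) is solved segment-wise by the eigenvalue
method: on an interval of constant concentration the exact update is
p(t+dt) = p(t) expm(Q dt), with expm evaluated through the eigendecomposition
of Q.  When the eigenvector matrix is ill-conditioned (near-defective Q at
extreme parameters) the propagator falls back to scipy's scaling-and-squaring
expm, which is unconditionally stable.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .models import KineticModel, ModelError, q_matrix

__all__ = [
    "PropagationError",
    "transition_matrix",
    "propagate",
    "propagate_piecewise",
    "stationary_distribution",
]

#: eigenvector condition number beyond which expm falls back to
#: scaling-and-squaring
_COND_LIMIT = 1e12


class PropagationError(RuntimeError):
    """Numerical failure while propagating state probabilities."""


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """expm(Q*dt) via eigendecomposition with a conditioning guard."""
    w, V = np.linalg.eig(Q)
    if np.linalg.cond(V) > _COND_LIMIT:
        return scipy.linalg.expm(Q * dt)
    P = (V * np.exp(w * dt)) @ np.linalg.inv(V)
    return P.real


def propagate(model: KineticModel, theta, p0, conc: float, dt: float) -> np.ndarray:
    """Advance a state distribution by ``dt`` seconds at constant ligand.

    Returns p0 @ expm(Q(conc, theta) * dt).  Probability mass is conserved
    to 1e-10; violation or a non-finite result raises PropagationError.
    """
    if dt < 0:
        raise ModelError("dt must be non-negative")
    p0 = _check_distribution(p0, model.n_states)
    P = transition_matrix(q_matrix(model, theta, conc), dt)
    p = p0 @ P
    if not np.all(np.isfinite(p)) or abs(p.sum() - 1.0) > 1e-10:
        raise PropagationError(
            f"propagation failed at conc={conc:g} M, dt={dt:g} s "
            f"(mass {p.sum():.3e})"
        )
    if p.min() < 0:
        p = np.clip(p, 0.0, None)
        p = p / p.sum()
    return p


def propagate_piecewise(
    model: KineticModel,
    theta,
    conc: np.ndarray,
    dt: float,
    p0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate over a piecewise-constant concentration sequence.

    ``conc[i]`` is held constant over the i-th interval of width ``dt``.
    Returns ``(po, p_final)`` where ``po[i]`` is the open probability at
    sample time ``i * dt`` (so ``po[0]`` reflects ``p0``) and ``p_final``
    is the distribution after the last interval.

    The generator is affine in concentration, Q(c) = A + c B, so the
    interval propagators are built in one batched eigendecomposition over
    the unique concentration values.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.ndim != 1 or conc.size == 0:
        raise ModelError("concentration sequence must be a non-empty 1-D array")
    if np.any(conc < 0):
        raise ModelError("negative concentration in sequence")
    if dt <= 0:
        raise ModelError("dt must be positive")
    if p0 is None:
        p0 = stationary_distribution(model, theta, conc[0])
    p0 = _check_distribution(p0, model.n_states)

    A, B = model.split_matrices(theta)
    levels, inverse = np.unique(conc, return_inverse=True)
    Qs = A[None, :, :] + levels[:, None, None] * B[None, :, :]
    props = _batched_expm(Qs, dt)

    open_idx = list(model.open_states)
    po = np.empty(conc.size)
    p = p0
    for i in range(conc.size):
        po[i] = p[open_idx].sum()
        p = p @ props[inverse[i]]
        s = p.sum()
        if not np.isfinite(s) or abs(s - 1.0) > 1e-8:
            raise PropagationError(
                f"probability mass lost at segment {i} (conc {conc[i]:g} M)"
            )
        if p.min() < 0:
            p = np.clip(p, 0.0, None)
        p = p / p.sum()
    return po, p


def _batched_expm(Qs: np.ndarray, dt: float) -> np.ndarray:
    """expm(Q*dt) for a stack of generators, eigen-method with guard."""
    w, V = np.linalg.eig(Qs)
    conds = np.linalg.cond(V)
    good = np.isfinite(conds) & (conds <= _COND_LIMIT)
    props = np.empty_like(Qs)
    if good.any():
        Vg = V[good]
        props[good] = np.real(
            (Vg * np.exp(w[good] * dt)[:, None, :]) @ np.linalg.inv(Vg)
        )
        rowsum_err = np.abs(props[good].sum(axis=2) - 1.0).max(axis=1)
        if np.any(rowsum_err > 1e-9):
            idx = np.nonzero(good)[0][rowsum_err > 1e-9]
            good[idx] = False
    for i in np.nonzero(~good)[0]:
        props[i] = scipy.linalg.expm(Qs[i] * dt)
    return props


def stationary_distribution(model: KineticModel, theta, conc: float) -> np.ndarray:
    """Stationary distribution of Q(conc, theta).

    Solves p Q = 0 with the normalisation sum(p) = 1.  At zero ligand a
    sequential scheme is reducible (the unliganded closed state absorbs all
    mass); the degenerate distribution is still returned and the chain of
    callers treats it as the resting state.
    """
    Q = q_matrix(model, theta, conc)
    s = model.n_states
    # append the normalisation row; lstsq tolerates the reducible c=0 case
    M = np.vstack([Q.T, np.ones(s)])
    b = np.zeros(s + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(M, b, rcond=None)
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if total <= 0 or not np.all(np.isfinite(p)):
        raise PropagationError(f"no stationary distribution at conc={conc:g} M")
    return p / total


def _check_distribution(p, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ModelError(f"distribution has shape {p.shape}, expected ({n},)")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ModelError("p0 is not a probability distribution")
    return p
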