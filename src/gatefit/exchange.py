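"""Diffusion-limited solution exchange between pipette tip and patch.

An excised patch sits a distance ``L`` inside the pipette; when the bath
solution at the tip is switched, the new ligand concentration reaches the
membrane only by diffusion through that column.  For a cylindrical column
with a reflecting membrane the concentration at the patch follows the
Fourier series

    c(L, t) = c2 + (c1 - c2) * (4/pi) * sum_n (-1)^(n+1) / (2n-1)
              * exp[-(2n-1)^2 * t / tau],        tau = 4 L^2 / (D pi^2)

which after an initial sigmoid onset is well approximated by a single
delayed exponential with delay t0 = tau * ln(4/pi) (about 0.24 tau).

The exchange time constant is calibrated per patch from a jump of the
permeant K+ concentration (150 -> 120 mM) at maximally open channels, and
rescaled to the ligand of interest through the ratio of diffusion
coefficients (L is a property of the patch geometry, not of the molecule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit

from .protocols import Protocol
from .trace import Trace

__all__ = [
    "DIFFUSION_COEFFICIENTS",
    "ExchangeModel",
    "tau_from_geometry",
    "length_from_tau",
    "rescale_tau",
    "series_concentration",
    "approx_concentration",
    "fit_exchange_tau",
    "ExchangeFit",
    "correct_protocol",
]

#: delay-to-time-constant ratio t0 / tau of the first-term approximation
T0_OVER_TAU = math.log(4.0 / math.pi)

#: published diffusion coefficients, cm^2 / s.  cGMP is taken equal to the
#: structurally near-identical cAMP.
DIFFUSION_COEFFICIENTS: dict[str, float] = {
    "K+": 1.96e-5,
    "cAMP": 4.4e-6,
    "cGMP": 4.4e-6,
}


def tau_from_geometry(L: float, D: float) -> float:
    """Exchange time constant (s) for column length L (cm) and D (cm^2/s)."""
    if L <= 0 or D <= 0:
        raise ValueError("L and D must be positive")
    return 4.0 * L * L / (D * math.pi**2)


def length_from_tau(tau: float, D: float) -> float:
    """Invert ``tau_from_geometry``: patch position L (cm) from tau (s)."""
    if tau <= 0 or D <= 0:
        raise ValueError("tau and D must be positive")
    return 0.5 * math.pi * math.sqrt(D * tau)


def rescale_tau(tau_ref: float, D_ref: float, D_target: float) -> float:
    """Transfer a fitted tau to another molecule at the same patch.

    L is fixed by the patch, so tau scales inversely with the diffusion
    coefficient: tau_target = tau_ref * D_ref / D_target.
    """
    if tau_ref <= 0 or D_ref <= 0 or D_target <= 0:
        raise ValueError("all inputs must be positive")
    return tau_ref * D_ref / D_target


@dataclass(frozen=True)
class ExchangeModel:
    """Concentration step c1 -> c2 filtered by diffusion with constant tau.

    Attributes are in SI-cgs mixed units as conventional in the field:
    concentrations in M, L in cm, D in cm^2/s, tau and t0 in s.
    """

    c1: float
    c2: float
    tau: float
    t0: float
    L: float | None = None
    D: float | None = None

    @classmethod
    def from_geometry(cls, c1: float, c2: float, L: float, D: float) -> "ExchangeModel":
        tau = tau_from_geometry(L, D)
        return cls(c1=c1, c2=c2, tau=tau, t0=tau * T0_OVER_TAU, L=L, D=D)

    @classmethod
    def from_tau(cls, c1: float, c2: float, tau: float) -> "ExchangeModel":
        if tau <= 0:
            raise ValueError("tau must be positive")
        return cls(c1=c1, c2=c2, tau=tau, t0=tau * T0_OVER_TAU)


def series_concentration(em: ExchangeModel, t, tol: float = 1e-10):
    """Full Fourier-series concentration at the patch at time(s) t (s).

    Terms are accumulated until the next term's magnitude falls below
    ``tol * |c1 - c2|`` (the alternating series makes this a rigorous
    truncation bound), with a hard cap of 1e4 terms.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    amp = em.c1 - em.c2
    out = np.zeros_like(t_arr, dtype=float)
    zero = t_arr == 0
    pos = ~zero
    if np.any(pos):
        tp = t_arr[pos]
        total = np.zeros_like(tp)
        pending = np.ones(tp.shape, dtype=bool)
        scale = abs(amp) if amp != 0 else 1.0
        for n in range(1, 10_001):
            q = 2 * n - 1
            term = ((-1) ** (n + 1) / q) * np.exp(-q * q * tp[pending] / em.tau)
            total[pending] += term
            done = np.abs(amp) * (4.0 / math.pi) * np.abs(term) < tol * scale
            idx = np.nonzero(pending)[0]
            pending[idx[done]] = False
            if not pending.any():
                break
        out[pos] = em.c2 + amp * (4.0 / math.pi) * total
    out[zero] = em.c1
    return out if np.ndim(t) else float(out)


def approx_concentration(em: ExchangeModel, t, strict_zero_branch: bool = False):
    """Delayed-exponential (first series term) concentration at time(s) t.

    For t < t0 the concentration is held at c1, which keeps the curve
    continuous at t0 and reduces to the published zero branch when c1 = 0;
    ``strict_zero_branch`` forces the literal 0 before the delay instead.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    c = em.c2 + (em.c1 - em.c2) * np.exp(-np.maximum(t_arr - em.t0, 0.0) / em.tau)
    if strict_zero_branch:
        c = np.where(t_arr < em.t0, 0.0, c)
    return c if np.ndim(t) else float(c)


@dataclass(frozen=True)
class ExchangeFit:
    """Result of calibrating tau from a K+-jump relaxation."""

    tau: float
    amplitude: float
    offset: float
    t0: float
    tau_sd: float
    residual_rms: float
    success: bool
    low_confidence: bool
    n_points: int

    def ligand_tau(self, D_ref: float = DIFFUSION_COEFFICIENTS["K+"],
                   D_target: float = DIFFUSION_COEFFICIENTS["cGMP"]) -> float:
        return rescale_tau(self.tau, D_ref, D_target)


def fit_exchange_tau(
    trace: Trace,
    window: tuple[float, float] | None = None,
    free_delay: bool = False,
    signal: str = "current",
) -> ExchangeFit:
    """Fit the delayed-exponential relaxation of a K+-jump current.

    The switch is assumed to occur at the start of ``window`` (whole trace
    if omitted).  The delay is constrained to t0 = tau * ln(4/pi) as fixed
    by the diffusion solution; ``free_delay`` releases it for robustness
    checks.  A fitted amplitude smaller than three times the residual RMS
    is flagged low-confidence.
    """
    y_full = getattr(trace, signal)
    if y_full is None:
        raise ValueError(f"trace has no {signal!r} samples")
    t = trace.time
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < 5:
            raise ValueError("window contains fewer than 5 samples")
        t, y = t[sel] - window[0], y_full[sel]
    else:
        t, y = t - t[0], y_full

    def residual(params):
        tau = params["tau"].value
        t0 = params["t0"].value if free_delay else tau * T0_OVER_TAU
        model = params["offset"].value + params["amplitude"].value * np.exp(
            -np.maximum(t - t0, 0.0) / tau
        )
        return model - y

    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    params = lmfit.Parameters()
    params.add("tau", value=span / 5.0, min=1e-7, max=100 * span)
    params.add("amplitude", value=y[0] - y[-1])
    params.add("offset", value=y[-1])
    if free_delay:
        params.add("t0", value=span / 20.0, min=0.0, max=span)
    result = lmfit.minimize(residual, params, method="leastsq")

    tau = result.params["tau"].value
    amp = result.params["amplitude"].value
    rms = float(np.sqrt(np.mean(result.residual**2)))
    tau_sd = result.params["tau"].stderr or float("nan")
    return ExchangeFit(
        tau=tau,
        amplitude=amp,
        offset=result.params["offset"].value,
        t0=(result.params["t0"].value if free_delay else tau * T0_OVER_TAU),
        tau_sd=tau_sd,
        residual_rms=rms,
        success=bool(result.success),
        low_confidence=abs(amp) < 3.0 * rms,
        n_points=t.size,
    )


def correct_protocol(
    protocol: Protocol,
    tau_ligand: float,
    dt: float = 5e-4,
    strict_zero_branch: bool = False,
) -> Trace:
    """Turn a nominal step protocol into the effective concentration trace.

    Each nominal step relaxes from the effective concentration reached at
    the switch toward the new level along the delayed exponential, so
    incomplete relaxations chain correctly across segment boundaries.  The
    output is piecewise-constant at ``dt`` (default 0.5 ms) using the
    interval-midpoint value.
    """
    if tau_ligand <= 0:
        raise ValueError("tau_ligand must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    for seg in protocol.segments:
        if seg.duration < dt:
            raise ValueError(
                f"segment of {seg.duration:g} s is shorter than dt={dt:g} s"
            )

    t0 = tau_ligand * T0_OVER_TAU
    bounds = np.concatenate([[0.0], np.cumsum([s.duration for s in protocol.segments])])
    n = int(round(protocol.total_duration / dt))
    t_mid = (np.arange(n) + 0.5) * dt
    seg_idx = np.clip(np.searchsorted(bounds, t_mid, side="right") - 1,
                      0, len(protocol.segments) - 1)

    # effective concentration at each segment start, chained in closed form
    c_starts = np.empty(len(protocol.segments))
    c_eff = protocol.segments[0].level  # assume pre-equilibration at first level
    for i, seg in enumerate(protocol.segments):
        c_starts[i] = c_eff
        decay = math.exp(-max(seg.duration - t0, 0.0) / tau_ligand)
        c_eff = seg.level + (c_eff - seg.level) * decay

    levels = np.array([s.level for s in protocol.segments])
    t_rel = t_mid - bounds[seg_idx]
    target = levels[seg_idx]
    start = c_starts[seg_idx]
    conc = target + (start - target) * np.exp(
        -np.maximum(t_rel - t0, 0.0) / tau_ligand
    )
    if strict_zero_branch:
        conc = np.where(t_rel < t0, 0.0, conc)
    time = np.arange(n) * dt
    return Trace(time=time, conc=conc,
                 meta={"tau_ligand_s": tau_ligand, "protocol": protocol.label,
                       "corrected": True})
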