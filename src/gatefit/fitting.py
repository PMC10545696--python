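"""Global fitting of gating schemes to Po traces and model ranking.

The forward model is the exact piecewise propagation of the scheme under
the exchange-corrected concentration trace; the objective is the summed
squared residual S between measured and computed open probability (the
weighted chi^2 collapses to S under the constant-variance assumption).
Minimisation uses a Levenberg-Marquardt iteration in log-parameter space,
which enforces positivity and makes the finite-difference Jacobian scale
free.  Parameter uncertainty comes from the final Jacobian: the covariance
is sigma2_bar * (J^T J)^-1 with sigma2_bar = S / (n - k - 1), standard
errors are the square roots of its diagonal, and the correlation matrix
exposes jointly unidentifiable parameter pairs (|rho| -> 1).

Competing schemes fitted to the same data are ranked by the reduced SSR,
S / (n_jumps - k): because successive samples of a relaxation are strongly
correlated, the degrees of freedom are counted conservatively as the
number of concentration jumps in the protocol rather than the number of
samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .models import KineticModel, ModelError
from .propagate import PropagationError, propagate_piecewise
from .protocols import Protocol
from .trace import Trace

__all__ = [
    "FitResult",
    "HillFit",
    "ModelRanking",
    "objective_ssr",
    "global_fit",
    "correlation_matrix",
    "reduced_ssr",
    "rank_models",
    "hill_fit",
    "underdetermination_report",
]


class FitError(RuntimeError):
    """Fit did not produce a usable result."""


def objective_ssr(po_measured, po_computed) -> float:
    """Summed squared residual between two aligned Po series."""
    if isinstance(po_measured, Trace):
        if isinstance(po_computed, Trace):
            if po_measured.n != po_computed.n or not np.allclose(
                po_measured.time, po_computed.time, rtol=1e-9, atol=1e-12
            ):
                raise FitError("traces are not on the same time grid")
            po_computed = po_computed.po
        po_measured = po_measured.po
    elif isinstance(po_computed, Trace):
        po_computed = po_computed.po
    a = np.asarray(po_measured, float)
    b = np.asarray(po_computed, float)
    if a.shape != b.shape:
        raise FitError("residual arrays have different lengths")
    d = a - b
    return float(d @ d)


@dataclass(eq=False)
class FitResult:
    """Outcome of a global fit, including uncertainty and ranking inputs."""

    model_label: str
    param_names: tuple[str, ...]
    theta_hat: np.ndarray
    sd: np.ndarray
    cov: np.ndarray
    corr: np.ndarray
    S: float
    sigma2_bar: float
    chi2: float
    n_points: int
    k: int
    n_jumps: int | None
    reduced_ssr: float | None
    converged: bool
    n_iter: int
    s_history: list[float] = field(default_factory=list)
    underdetermined: bool = False
    message: str = ""
    data_hash: str = ""
    fixed: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model_label,
            "params": {
                name: {"value": float(v), "sd": float(s)}
                for name, v, s in zip(self.param_names, self.theta_hat, self.sd)
            },
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "cov": self.cov.tolist(),
            "corr": self.corr.tolist(),
            "S": self.S,
            "sigma2_bar": self.sigma2_bar,
            "chi2": self.chi2,
            "n_points": self.n_points,
            "k": self.k,
            "n_jumps": self.n_jumps,
            "reduced_ssr": self.reduced_ssr,
            "converged": self.converged,
            "underdetermined": self.underdetermined,
            "n_iter": self.n_iter,
            "s_history": [float(s) for s in self.s_history],
            "message": self.message,
            "data_hash": self.data_hash,
        }


def _data_hash(conc: np.ndarray, po: np.ndarray, n_jumps) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(conc).tobytes())
    h.update(np.ascontiguousarray(po).tobytes())
    h.update(str(n_jumps).encode())
    return h.hexdigest()


# LM hyper-parameters; the damping schedule and stopping rule follow common
# practice for this optimiser.
_FD_STEP = 1e-6          # forward-difference step in log-parameter space
_LAMBDA0 = 1e-3          # initial damping
_REL_TOL = 1e-9          # relative S change counted as "no progress"
_STREAK = 3              # consecutive no-progress iterations to converge
_LAMBDA_MAX = 1e12
_LOG_LIMIT = 34.5        # default |log rate| bound (~1e15), keeps exp finite


def global_fit(
    model: KineticModel,
    protocol_corrected: Trace,
    data: Trace,
    theta0,
    fixed: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    max_iter: int = 100,
    n_jumps: int | None = None,
    protocol: Protocol | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Fit a gating scheme's free rates to a measured Po trace.

    Parameters
    ----------
    protocol_corrected
        Concentration trace at the patch (exchange-corrected or nominal),
        on the same grid as ``data``.
    theta0
        Initial values for the model's free parameters (full length; any
        entries named in ``fixed`` are clamped).
    fixed
        Parameter name -> value pairs excluded from optimisation.
    bounds
        Optional per-parameter (lo, hi) bounds, enforced by clipping the
        log-space steps.
    n_jumps, protocol
        Degrees of freedom for the reduced SSR; give the jump count
        directly or a Protocol to count it from.
    """
    conc, dt = protocol_corrected.conc, protocol_corrected.dt
    if conc is None:
        raise FitError("protocol_corrected must carry a concentration array")
    if data.po is None:
        raise FitError("data must carry an open-probability array")
    if data.n != conc.size:
        raise FitError("data and concentration traces have different lengths")
    if n_jumps is None and protocol is not None:
        n_jumps = protocol.n_jumps()

    fixed = dict(fixed or {})
    names = list(model.free_params)
    theta0 = np.asarray(theta0, float)
    if theta0.shape != (len(names),):
        raise FitError(f"theta0 must have length {len(names)}")
    if np.any(theta0 <= 0):
        raise FitError("theta0 entries must be positive")
    free_idx = [i for i, nm in enumerate(names) if nm not in fixed]
    if not free_idx:
        raise FitError("no free parameters left to fit")
    free_names = [names[i] for i in free_idx]
    k = len(free_idx)
    y = data.po
    w = np.sqrt(np.asarray(weights, float)) if weights is not None else None

    lo = np.full(k, -_LOG_LIMIT)
    hi = np.full(k, _LOG_LIMIT)
    for j, nm in enumerate(free_names):
        if bounds and nm in bounds:
            lo[j], hi[j] = np.log(bounds[nm][0]), np.log(bounds[nm][1])

    theta_full = theta0.copy()
    for i, nm in enumerate(names):
        if nm in fixed:
            theta_full[i] = fixed[nm]

    def residual(x: np.ndarray) -> np.ndarray:
        th = theta_full.copy()
        th[free_idx] = np.exp(x)
        po, _ = propagate_piecewise(model, th, conc, dt)
        r = po - y
        return r * w if w is not None else r

    x = np.log(theta_full[free_idx].astype(float))
    x = np.clip(x, lo, hi)
    try:
        r = residual(x)
    except PropagationError as err:
        raise FitError(f"forward model failed at theta0: {err}") from err
    S = float(r @ r)
    s_history = [S]
    lam = _LAMBDA0
    streak = 0
    last_rel = None
    converged = False
    underdetermined = False
    message = ""
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        J = _fd_jacobian(residual, x, r)
        g = J.T @ r
        H = J.T @ J
        if S < 1e-28 or np.linalg.norm(g) < 1e-14 * max(1.0, S):
            converged = True
            message = "gradient vanished"
            break
        accepted = False
        while lam <= _LAMBDA_MAX:
            D = np.diag(np.maximum(np.diag(H), 1e-300))
            try:
                delta = np.linalg.solve(H + lam * D, -g)
            except np.linalg.LinAlgError:
                underdetermined = True
                lam *= 10.0
                continue
            if not np.all(np.isfinite(delta)):
                underdetermined = True
                lam *= 10.0
                continue
            x_try = np.clip(x + delta, lo, hi)
            try:
                r_try = residual(x_try)
            except (PropagationError, ModelError):
                lam *= 10.0
                continue
            S_try = float(r_try @ r_try)
            if S_try < S:
                last_rel = (S - S_try) / max(S, 1e-300)
                x, r, S = x_try, r_try, S_try
                lam = max(lam / 10.0, 1e-14)
                streak = streak + 1 if last_rel < _REL_TOL else 0
                accepted = True
                break
            lam *= 10.0
        s_history.append(S)
        if accepted and streak >= _STREAK:
            converged = True
            message = f"relative S change below {_REL_TOL:g} for {_STREAK} iterations"
            break
        if not accepted:
            # damping exhausted: a minimum if progress had already stalled
            converged = S < 1e-20 or streak > 0 or (
                last_rel is not None and last_rel < 1e-6
            )
            message = "no downhill step found (damping exhausted)"
            break
    else:
        message = f"did not converge to a minimum ({max_iter} iterations)"

    theta_hat_free = np.exp(x)
    theta_full[free_idx] = theta_hat_free

    # covariance in linear parameter space from the final log-space Jacobian
    J = _fd_jacobian(residual, x, r)
    J_lin = J / theta_hat_free[None, :]
    H_lin = J_lin.T @ J_lin
    n = y.size
    sigma2_bar = S / max(n - k - 1, 1)
    # determinacy is judged on the scale-invariant (correlation-normalised)
    # Hessian, otherwise disparate rate magnitudes alone would trip the flag
    d = np.sqrt(np.clip(np.diag(H_lin), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        H_norm = H_lin / np.outer(d, d)
    H_norm[~np.isfinite(H_norm)] = 0.0
    cond = np.linalg.cond(H_norm)
    if not np.isfinite(cond) or cond > 1e10 or np.any(d == 0):
        underdetermined = True
        cov = sigma2_bar * np.linalg.pinv(H_lin)
    else:
        cov = sigma2_bar * np.linalg.inv(H_lin)
    corr = correlation_matrix(cov)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    chi2 = S / sigma2_bar if sigma2_bar > 0 else 0.0

    if n_jumps is not None and n_jumps > k:
        red = S / (n_jumps - k)
    else:
        red = None
        if n_jumps is not None:
            underdetermined = True
            message += "; n_jumps <= k: reduced SSR undefined"

    return FitResult(
        model_label=model.label,
        param_names=tuple(free_names),
        theta_hat=theta_hat_free,
        sd=sd,
        cov=cov,
        corr=corr,
        S=S,
        sigma2_bar=sigma2_bar,
        chi2=chi2,
        n_points=n,
        k=k,
        n_jumps=n_jumps,
        reduced_ssr=red,
        converged=converged,
        n_iter=n_iter,
        s_history=s_history,
        underdetermined=underdetermined,
        message=message.lstrip("; "),
        data_hash=_data_hash(conc, y, n_jumps),
        fixed=fixed,
    )


def _fd_jacobian(residual, x: np.ndarray, r0: np.ndarray) -> np.ndarray:
    J = np.empty((r0.size, x.size))
    for j in range(x.size):
        xj = x.copy()
        xj[j] += _FD_STEP
        try:
            J[:, j] = (residual(xj) - r0) / _FD_STEP
        except (PropagationError, ModelError):
            xj[j] = x[j] - _FD_STEP
            J[:, j] = (r0 - residual(xj)) / _FD_STEP
    return J


def correlation_matrix(cov: np.ndarray) -> np.ndarray:
    """Correlation matrix rho_ij = cov_ij / (sigma_i sigma_j).

    Entries involving a zero variance are undefined and returned as NaN;
    the diagonal is exactly 1 wherever the variance is positive.
    """
    cov = np.asarray(cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be square")
    sig = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sig, sig)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sig > 0, 1.0, np.nan))
    return corr


def reduced_ssr(S: float, n_jumps: int, k: int) -> float:
    """S normalised by (concentration jumps - free parameters)."""
    if n_jumps <= k:
        raise FitError(
            f"underdetermined: n_jumps={n_jumps} <= k={k} free parameters"
        )
    return S / (n_jumps - k)


@dataclass
class ModelRanking:
    ranked: list[FitResult]
    unranked: list[FitResult]

    def table(self) -> pd.DataFrame:
        rows = []
        for f in self.ranked:
            rows.append({"model": f.model_label, "k": f.k, "S": f.S,
                         "reduced_ssr": f.reduced_ssr, "converged": f.converged,
                         "ranked": True})
        for f in self.unranked:
            rows.append({"model": f.model_label, "k": f.k, "S": f.S,
                         "reduced_ssr": f.reduced_ssr, "converged": f.converged,
                         "ranked": False})
        return pd.DataFrame(rows)

    @property
    def best(self) -> FitResult:
        if not self.ranked:
            raise FitError("no rankable fits")
        return self.ranked[0]


def rank_models(fits: list[FitResult]) -> ModelRanking:
    """Order fits of competing schemes by reduced SSR (ascending).

    All fits must be on identical data with the same jump count.
    Underdetermined or non-converged fits are reported separately and
    never ranked.
    """
    if not fits:
        raise FitError("no fits to rank")
    ref = fits[0].data_hash
    if any(f.data_hash != ref for f in fits):
        raise FitError("fits were not performed on identical data")
    rankable = [f for f in fits
                if f.reduced_ssr is not None and f.converged and not f.underdetermined]
    rankable_ids = {id(f) for f in rankable}
    rest = [f for f in fits if id(f) not in rankable_ids]
    rankable.sort(key=lambda f: f.reduced_ssr)
    return ModelRanking(ranked=rankable, unranked=rest)


@dataclass(frozen=True)
class HillFit:
    """Hill-equation fit of a concentration-activation relationship."""

    ec50: float
    hill_n: float
    ec50_sd: float
    hill_n_sd: float
    residual_norm: float
    n_used: int

    def response(self, conc) -> np.ndarray:
        conc = np.asarray(conc, float)
        return 1.0 / (1.0 + (self.ec50 / conc) ** self.hill_n)


def hill_fit(concs, responses, exclude_zero_and_sat: bool = True) -> HillFit:
    """Fit I/Imax = 1 / (1 + (EC50/c)^n) to late-response data.

    With ``exclude_zero_and_sat`` (the default convention) the response at
    zero concentration is used for offset correction, the response at the
    saturating (highest, latest-occurring) concentration for normalisation,
    and both points are excluded from the fit itself.
    """
    c = np.asarray(concs, float)
    y = np.asarray(responses, float)
    if c.shape != y.shape or c.ndim != 1:
        raise FitError("concs and responses must be matching 1-D arrays")

    if exclude_zero_and_sat:
        zero_mask = c == 0
        offset = float(y[zero_mask].mean()) if zero_mask.any() else 0.0
        pos = np.nonzero(~zero_mask)[0]
        if pos.size == 0:
            raise FitError("no positive concentrations")
        cmax = c[pos].max()
        sat_candidates = pos[c[pos] == cmax]
        sat = sat_candidates[-1]  # latest occurrence breaks ties
        imax = y[sat] - offset
        if imax <= 0:
            raise FitError("saturating response not above offset")
        use = np.array([i for i in pos if i != sat])
        c_fit, y_fit = c[use], (y[use] - offset) / imax
    else:
        keep = c > 0
        c_fit, y_fit = c[keep], y[keep]
    if c_fit.size < 3:
        raise FitError("need at least 3 usable points for a Hill fit")

    def resid(params):
        ec50 = params["ec50"].value
        nh = params["hill_n"].value
        return 1.0 / (1.0 + (ec50 / c_fit) ** nh) - y_fit

    params = lmfit.Parameters()
    params.add("ec50", value=float(np.exp(np.mean(np.log(c_fit)))),
               min=c_fit.min() / 1e3, max=c_fit.max() * 1e3)
    params.add("hill_n", value=1.0, min=1e-3, max=20.0)
    out = lmfit.minimize(resid, params, method="leastsq")
    return HillFit(
        ec50=out.params["ec50"].value,
        hill_n=out.params["hill_n"].value,
        ec50_sd=out.params["ec50"].stderr or float("nan"),
        hill_n_sd=out.params["hill_n"].stderr or float("nan"),
        residual_norm=float(np.sqrt(np.sum(out.residual**2))),
        n_used=c_fit.size,
    )


def underdetermination_report(
    fit: FitResult, threshold: float = 0.999
) -> list[tuple[str, str, float]]:
    """Parameter pairs whose correlation magnitude reaches ``threshold``.

    A |rho| of ~1 means the data constrain only a combination (typically
    the ratio) of the two rates, not their individual values.
    """
    pairs = []
    k = len(fit.param_names)
    for i in range(k):
        for j in range(i + 1, k):
            rho = fit.corr[i, j]
            if np.isfinite(rho) and abs(rho) >= threshold:
                pairs.append((fit.param_names[i], fit.param_names[j], float(rho)))
    return pairs
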