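"""Markov gating schemes for ligand-gated ion channels.

A kinetic model is a continuous-time Markov chain over channel conformations.
The sequential activation schemes used here are chains

    C0  <->  C1  <->  ...  <-> Cm  <->  O

with ``m`` ligand-binding steps followed by a single opening step; every
binding rate is linear in the ligand concentration, the gating rates e+/e-
are concentration independent.  Models are labelled ``"<s>s<p>p"`` after
their state count ``s`` and free-parameter count ``p`` (e.g. ``4s4p`` for
two cooperative binding steps).

With *cooperative* binding every step has its own microscopic on/off rate
(free parameters ``k1, k-1, ..., km, k-m``).  With *independent* binding all
``m`` sites share one microscopic pair ``k_on, k_off`` and the macroscopic
rates carry statistical occupancy factors: step ``j`` proceeds forward at
``(m - j + 1) * k_on * c`` and backward at ``j * k_off``.

The two-state C-O model has a single ligand-dependent opening step; it is
the minimal scheme used in the robustness simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateLaw",
    "KineticModel",
    "build_sequential_model",
    "build_co_model",
    "q_matrix",
    "open_probability",
]


class ModelError(ValueError):
    """Invalid model topology or parameters."""


@dataclass(frozen=True)
class RateLaw:
    """One directed transition: rate = multiplier * parameter * (conc or 1)."""

    source: int
    target: int
    param: str
    multiplier: float = 1.0
    ligand_dependent: bool = False


@dataclass(frozen=True)
class KineticModel:
    label: str
    n_states: int
    binding_steps: int
    cooperative: bool
    open_states: tuple[int, ...]
    rate_laws: tuple[RateLaw, ...]
    fixed_params: dict[str, float] = field(default_factory=dict)
    free_params: tuple[str, ...] = ()
    state_names: tuple[str, ...] = ()
    default_theta: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.open_states:
            raise ModelError("model must declare at least one open state")
        for law in self.rate_laws:
            if law.multiplier <= 0:
                raise ModelError(f"non-positive multiplier on edge {law}")
            if law.param not in self.free_params and law.param not in self.fixed_params:
                raise ModelError(f"rate law references unknown parameter {law.param!r}")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_params)

    def split_matrices(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """Decompose Q(c) = A + c * B for a fixed parameter vector.

        Every ligand-dependent rate is linear in concentration, so the
        generator at any concentration is an affine function of ``c``; the
        split lets piecewise-constant protocols be propagated in batch.
        The diagonals of A and B each hold the negated row sums of their
        own off-diagonal parts, so row sums of Q vanish for every ``c``.
        """
        theta = _validate_theta(self, theta)
        values = dict(zip(self.free_params, theta))
        values.update(self.fixed_params)
        s = self.n_states
        A = np.zeros((s, s))
        B = np.zeros((s, s))
        for law in self.rate_laws:
            rate = law.multiplier * values[law.param]
            M = B if law.ligand_dependent else A
            M[law.source, law.target] += rate
            M[law.source, law.source] -= rate
        return A, B


def _validate_theta(model: KineticModel, theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.k,):
        raise ModelError(
            f"theta has length {theta.size}, model {model.label} expects {model.k}"
        )
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        raise ModelError("all rate parameters must be positive and finite")
    return theta


def build_sequential_model(
    m: int,
    cooperative: bool,
    e_plus: float,
    e_minus: float,
) -> KineticModel:
    """Build a sequential activation scheme with ``m`` binding steps.

    Parameters
    ----------
    m
        Number of ligand-binding steps (1-4).
    cooperative
        If True every step has its own on/off rate pair (2m free
        parameters); if False all sites are identical and share one
        microscopic ``k_on``/``k_off`` pair with statistical factors.
    e_plus, e_minus
        Fixed opening and closing rates in 1/s of the final gating step.
    """
    if m not in (1, 2, 3, 4):
        raise ModelError(f"unsupported number of binding steps: {m}")
    if e_plus <= 0 or e_minus <= 0:
        raise ModelError("gating rates e_plus and e_minus must be positive")

    s = m + 2
    laws: list[RateLaw] = []
    if cooperative:
        free: list[str] = []
        for j in range(1, m + 1):
            free += [f"k{j}", f"k-{j}"]
            laws.append(RateLaw(j - 1, j, f"k{j}", 1.0, ligand_dependent=True))
            laws.append(RateLaw(j, j - 1, f"k-{j}", 1.0))
        p = 2 * m
    else:
        free = ["k_on", "k_off"]
        for j in range(1, m + 1):
            laws.append(RateLaw(j - 1, j, "k_on", float(m - j + 1), ligand_dependent=True))
            laws.append(RateLaw(j, j - 1, "k_off", float(j)))
        p = 2
    laws.append(RateLaw(m, m + 1, "e+"))
    laws.append(RateLaw(m + 1, m, "e-"))

    label = f"{s}s{p}p" if cooperative else f"{s}s{p}p-independent"
    if m == 1 and cooperative:
        label = "3s2p"
    names = tuple(f"C{i}" for i in range(m + 1)) + ("O",)
    return KineticModel(
        label=label,
        n_states=s,
        binding_steps=m,
        cooperative=cooperative,
        open_states=(m + 1,),
        rate_laws=tuple(laws),
        fixed_params={"e+": float(e_plus), "e-": float(e_minus)},
        free_params=tuple(free),
        state_names=names,
    )


def build_co_model(k_open_per_conc: float, k_close: float) -> KineticModel:
    """Two-state C-O model with a single ligand-dependent opening step.

    ``k_open_per_conc`` (1/(M s)) scales linearly with ligand concentration;
    ``k_close`` (1/s) is constant.  Both are free parameters; the supplied
    values become the model's default parameter vector.
    """
    if k_open_per_conc <= 0 or k_close <= 0:
        raise ModelError("C-O rates must be positive")
    laws = (
        RateLaw(0, 1, "k_open", 1.0, ligand_dependent=True),
        RateLaw(1, 0, "k_close", 1.0),
    )
    return KineticModel(
        label="C-O",
        n_states=2,
        binding_steps=0,
        cooperative=False,
        open_states=(1,),
        rate_laws=laws,
        free_params=("k_open", "k_close"),
        state_names=("C", "O"),
        default_theta=(float(k_open_per_conc), float(k_close)),
    )


def q_matrix(model: KineticModel, theta, conc: float) -> np.ndarray:
    """Assemble the generator Q (1/s) at one ligand concentration (M).

    Off-diagonal entries are transition rates, rows sum to zero; entries
    are exactly zero where the scheme has no edge.
    """
    if conc < 0:
        raise ModelError(f"negative concentration: {conc}")
    A, B = model.split_matrices(theta)
    return A + float(conc) * B


def open_probability(p, model: KineticModel) -> float:
    """Total probability mass in the conducting state(s)."""
    p = np.asarray(p, dtype=float)
    return float(p[..., list(model.open_states)].sum(axis=-1))
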