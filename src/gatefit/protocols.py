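"""Concentration protocols and per-pulse trace summaries.

A protocol is an ordered list of (level, duration) segments applied at the
pipette tip.  Builders cover the designs used for fast functional mapping:
logarithmic staircases run up and/or down, series spaced to give
approximately equal response increments given a known EC50 and Hill
coefficient, and free-form complex pulse trains.  Summaries extract the
late (quasi-equilibrium) response of each pulse and quantify hysteresis
between incremental and decremental staircases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = [
    "Segment",
    "Protocol",
    "staircase_protocol",
    "response_equidistant_protocol",
    "complex_protocol",
    "standard_complex_protocol",
    "nominal_concentration",
    "late_response",
    "hysteresis_index",
]

SEGMENT_KINDS = ("ligand", "k_jump", "zero")


@dataclass(frozen=True)
class Segment:
    level: float      # concentration in M
    duration: float   # s
    kind: str = "ligand"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.level < 0:
            raise ValueError("segment level must be non-negative")
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")


@dataclass(frozen=True)
class Protocol:
    segments: tuple[Segment, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def levels(self) -> np.ndarray:
        return np.array([s.level for s in self.segments])

    def ligand_segments(self) -> list[tuple[int, Segment]]:
        """Segments relevant for dose-response summaries (K+ jumps excluded)."""
        return [(i, s) for i, s in enumerate(self.segments) if s.kind != "k_jump"]

    def n_jumps(self) -> int:
        """Number of concentration jumps, the degrees of freedom used when
        ranking models: each non-K+-jump segment whose level differs from
        the preceding one counts as one jump (the first always counts)."""
        count = 0
        prev = None
        for _, seg in self.ligand_segments():
            if prev is None or seg.level != prev:
                count += 1
            prev = seg.level
        return count

    def segment_bounds(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])


def staircase_protocol(
    c_min: float,
    c_max: float,
    n_steps: int,
    duration: float,
    direction: str = "up",
) -> Protocol:
    """Log-equidistant concentration staircase.

    ``direction`` is ``"up"``, ``"down"`` or ``"updown"``; the latter
    concatenates the incremental and decremental runs (2 * n_steps
    segments).  A zero-concentration baseline is not representable on the
    log grid; prepend an explicit zero segment if needed.
    """
    if c_min <= 0:
        raise ValueError(
            "c_min must be positive (log spacing undefined at 0; "
            "prepend an explicit zero segment instead)"
        )
    if c_max <= c_min:
        raise ValueError("need c_min < c_max")
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    levels = np.geomspace(c_min, c_max, n_steps)
    if direction == "up":
        seq = levels
    elif direction == "down":
        seq = levels[::-1]
    elif direction == "updown":
        seq = np.concatenate([levels, levels[::-1]])
    else:
        raise ValueError(f"unknown direction {direction!r}")
    segs = tuple(Segment(float(c), duration) for c in seq)
    return Protocol(segs, label=f"staircase-{direction}-{n_steps}")


def response_equidistant_protocol(
    ec50: float,
    hill_n: float,
    n_steps: int,
    duration: float,
) -> Protocol:
    """Concentration series giving approximately equal response steps.

    Target fractional responses f_i = i / (n_steps + 1) are inverted
    through the Hill equation: c_i = ec50 * (f / (1 - f))^(1 / hill_n).
    """
    if ec50 <= 0 or hill_n <= 0:
        raise ValueError("ec50 and hill_n must be positive")
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    f = np.arange(1, n_steps + 1) / (n_steps + 1)
    levels = ec50 * (f / (1.0 - f)) ** (1.0 / hill_n)
    segs = tuple(Segment(float(c), duration) for c in levels)
    return Protocol(segs, label=f"response-equidistant-{n_steps}")


def complex_protocol(spec, label: str = "complex") -> Protocol:
    """Verbatim protocol from a list of (level_M, duration_s) pairs."""
    spec = list(spec)
    if not spec:
        raise ValueError("empty protocol specification")
    segs = tuple(
        Segment(float(level), float(dur),
                kind="zero" if level == 0 else "ligand")
        for level, dur in spec
    )
    return Protocol(segs, label=label)


def standard_complex_protocol() -> Protocol:
    """Synthetic 23-pulse complex protocol fixture.

    23 pulses of 500 ms (11.5 s total) spanning zero to a saturating
    100 uM, with a zero-concentration pulse between 6.5 and 7 s — the
    shape typically used to probe activation and deactivation across the
    full response range in a single short recording.  The pulse levels
    are a synthetic log-spanning stand-in, not measured data.
    """
    uM = 1e-6
    levels_uM = [
        0.5, 2, 8, 32, 100, 16, 1, 64, 4, 0.25, 50, 12,
        25, 0.0, 6, 100, 0.75, 20, 3, 40, 1.5, 80, 10,
    ]
    assert len(levels_uM) == 23 and levels_uM[13] == 0.0
    return complex_protocol(
        [(c * uM, 0.5) for c in levels_uM], label="complex-23x500ms"
    )


def nominal_concentration(protocol: Protocol, dt: float = 5e-4) -> Trace:
    """Sample the uncorrected rectangular protocol on a uniform grid.

    The value of each ``dt`` interval is the nominal level at the interval
    midpoint, mirroring the discretisation used for corrected protocols.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bounds = protocol.segment_bounds()
    n = int(round(protocol.total_duration / dt))
    t_mid = (np.arange(n) + 0.5) * dt
    idx = np.clip(np.searchsorted(bounds, t_mid, side="right") - 1,
                  0, len(protocol.segments) - 1)
    conc = protocol.levels[idx]
    return Trace(time=np.arange(n) * dt, conc=conc,
                 meta={"protocol": protocol.label, "corrected": False})


def late_response(
    trace: Trace,
    protocol: Protocol,
    rule: dict | None = None,
    signal: str | None = None,
) -> pd.DataFrame:
    """Mean signal over the terminal window of each ligand pulse.

    ``rule`` is ``{"last_ms": x}`` or ``{"last_fraction": f}`` (default:
    last 5% of each step).  Returns a frame with columns ``segment``,
    ``conc``, ``response``.
    """
    rule = rule or {"last_fraction": 0.05}
    if signal is None:
        signal = "po" if trace.po is not None else "current"
    y = getattr(trace, signal)
    if y is None:
        raise ValueError(f"trace has no {signal!r} samples")
    if trace.time[-1] + trace.dt < protocol.total_duration - 1e-9:
        raise ValueError("trace does not cover the protocol")

    bounds = protocol.segment_bounds()
    rows = []
    for i, seg in protocol.ligand_segments():
        if "last_ms" in rule:
            win = rule["last_ms"] * 1e-3
        elif "last_fraction" in rule:
            win = rule["last_fraction"] * seg.duration
        else:
            raise ValueError("rule must contain 'last_ms' or 'last_fraction'")
        if win > seg.duration:
            raise ValueError(
                f"window {win:g} s longer than segment {i} ({seg.duration:g} s)"
            )
        t_end = bounds[i + 1]
        sel = (trace.time >= t_end - win - 1e-12) & (trace.time < t_end - 1e-12)
        if not sel.any():
            raise ValueError(f"no samples in terminal window of segment {i}")
        rows.append({"segment": i, "conc": seg.level,
                     "response": float(y[sel].mean())})
    return pd.DataFrame(rows)


def hysteresis_index(up_summary: pd.DataFrame, down_summary: pd.DataFrame) -> float:
    """Signed area between incremental and decremental dose-response curves.

    Both summaries (from :func:`late_response`) are normalised by the
    common maximum response and integrated against log10 concentration;
    a decremental branch lying above the incremental one (activation
    persisting at lower ligand, the usual non-equilibrium signature)
    gives a positive index.
    """
    up = up_summary.sort_values("conc").reset_index(drop=True)
    down = down_summary.sort_values("conc").reset_index(drop=True)
    if len(up) != len(down) or not np.allclose(up["conc"], down["conc"], rtol=1e-9):
        raise ValueError("up and down branches must share the concentration grid")
    if (up["conc"] <= 0).any():
        raise ValueError("hysteresis index requires positive concentrations")
    norm = max(up["response"].max(), down["response"].max())
    if norm <= 0:
        raise ValueError("responses are non-positive; cannot normalise")
    x = np.log10(up["conc"].to_numpy())
    diff = (down["response"].to_numpy() - up["response"].to_numpy()) / norm
    return float(np.trapezoid(diff, x))
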