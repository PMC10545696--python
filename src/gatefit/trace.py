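"""Uniformly sampled time-series container for concentration/Po/current."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """A uniformly sampled recording.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, uniform grid.
    conc : ndarray, optional
        Ligand concentration in M at the patch, piecewise-constant per
        sampling interval.
    po : ndarray, optional
        Open probability, in [0, 1].
    current : ndarray, optional
        Macroscopic current in pA.
    meta : dict
        Free-form metadata (sampling rate, channel count N, single-channel
        amplitude, seed, leak offset, ...).
    """

    time: np.ndarray
    conc: np.ndarray | None = None
    po: np.ndarray | None = None
    current: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1:
            raise ValueError("time must be a 1-D array")
        for name in ("conc", "po", "current"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.time.shape:
                    raise ValueError(
                        f"{name} has length {arr.size}, time has {self.time.size}"
                    )
                setattr(self, name, arr)
        if self.time.size >= 2:
            steps = np.diff(self.time)
            bad = np.nonzero(~np.isclose(steps, steps[0], rtol=1e-6, atol=0.0))[0]
            if bad.size:
                raise ValueError(
                    f"non-uniform time grid: first offending index {bad[0] + 1}"
                )
        if self.po is not None and self.po.size:
            if self.po.min() < -1e-9 or self.po.max() > 1 + 1e-9:
                raise ValueError("po values outside [0, 1]")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        if self.time.size < 2:
            raise ValueError("dt undefined for traces with fewer than 2 samples")
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def replace(self, **kwargs) -> "Trace":
        """Copy of the trace with some fields swapped out."""
        return replace(self, **kwargs)
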