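"""File I/O: delimited-text traces, YAML/JSON configs, JSON fit reports.

Traces are stored as tab-separated text with SI units in the header
(``time_s``, ``conc_M``, ``po``, ``current_pA``) and metadata in a single
``# meta`` comment line.  Configs accept concentrations in uM or M but must
name the unit explicitly, which prevents silent thousand-fold errors at the
user boundary (rates are always 1/s and 1/(M s)).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exchange import DIFFUSION_COEFFICIENTS
from .fitting import FitResult
from .models import KineticModel, build_co_model, build_sequential_model
from .protocols import Protocol, Segment
from .trace import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "load_config",
    "model_from_config",
    "protocol_from_config",
    "protocol_to_config",
    "load_diffusion_table",
    "write_fit_report",
]

_COLUMNS = {"time_s": "time", "conc_M": "conc", "po": "po", "current_pA": "current"}
_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


def write_trace(trace: Trace, path) -> None:
    """Write a trace as tab-separated text, 17 significant digits."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_s": trace.time}
    if trace.conc is not None:
        cols["conc_M"] = trace.conc
    if trace.po is not None:
        cols["po"] = trace.po
    if trace.current is not None:
        cols["current_pA"] = trace.current
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        if trace.meta:
            fh.write("# meta " + json.dumps(trace.meta, default=str) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trace(path) -> Trace:
    """Read a delimited-text trace; the time grid must be uniform."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty input file")
        if first.startswith("# meta"):
            meta = json.loads(first[len("# meta"):])
            body_start = 1
        else:
            body_start = 0
    df = pd.read_csv(path, sep="\t", skiprows=body_start,
                     float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column time_s")
    unknown = [c for c in df.columns if c not in _COLUMNS]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")
    if len(df) == 0:
        warnings.warn(f"{path}: header-only file, returning zero-length trace")
    kwargs = {attr: df[col].to_numpy() for col, attr in _COLUMNS.items()
              if col in df.columns}
    return Trace(meta=meta, **kwargs)


def load_config(path) -> dict:
    """Load a YAML-or-JSON config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _conc_scale(cfg: dict, context: str) -> float:
    unit = cfg.get("concentration_unit")
    if unit is None:
        raise ValueError(f"{context}: concentration_unit (M/mM/uM/nM) is required")
    if unit not in _UNIT_SCALE:
        raise ValueError(f"{context}: unknown concentration unit {unit!r}")
    return _UNIT_SCALE[unit]


def model_from_config(cfg: dict) -> tuple[KineticModel, np.ndarray | None, dict | None]:
    """Build a model from a config mapping.

    Returns (model, theta0, bounds); theta0/bounds are None when the
    config does not provide them.  Example::

        type: sequential          # or "co"
        binding_steps: 2
        cooperative: true
        e_plus: 990.0             # 1/s
        e_minus: 10.0
        theta0: {k1: 1.0e6, k-1: 100.0, k2: 1.0e7, k-2: 50.0}
        bounds: {k1: [1.0e3, 1.0e10]}
    """
    kind = cfg.get("type", "sequential")
    if kind == "sequential":
        model = build_sequential_model(
            int(cfg["binding_steps"]),
            bool(cfg.get("cooperative", True)),
            float(cfg["e_plus"]),
            float(cfg["e_minus"]),
        )
    elif kind == "co":
        model = build_co_model(float(cfg["k_open"]), float(cfg["k_close"]))
    else:
        raise ValueError(f"unknown model type {kind!r}")

    theta0 = None
    if "theta0" in cfg:
        missing = [p for p in model.free_params if p not in cfg["theta0"]]
        if missing:
            raise ValueError(f"theta0 missing parameters {missing}")
        theta0 = np.array([float(cfg["theta0"][p]) for p in model.free_params])
    elif model.default_theta is not None:
        theta0 = np.array(model.default_theta)
    bounds = None
    if "bounds" in cfg:
        bounds = {p: (float(lo), float(hi)) for p, (lo, hi) in cfg["bounds"].items()}
    return model, theta0, bounds


def protocol_from_config(cfg: dict) -> Protocol:
    """Build a protocol from a config mapping.

    Example::

        label: staircase
        concentration_unit: uM
        segments:
          - {level: 0.1, duration: 0.5}
          - {level: 1.0, duration: 0.5, kind: ligand}
    """
    scale = _conc_scale(cfg, "protocol config")
    segs = tuple(
        Segment(float(s["level"]) * scale, float(s["duration"]),
                s.get("kind", "ligand"))
        for s in cfg["segments"]
    )
    return Protocol(segs, label=cfg.get("label", ""))


def protocol_to_config(protocol: Protocol, unit: str = "uM") -> dict:
    scale = _UNIT_SCALE[unit]
    return {
        "label": protocol.label,
        "concentration_unit": unit,
        "segments": [
            {"level": s.level / scale, "duration": s.duration, "kind": s.kind}
            for s in protocol.segments
        ],
    }


def load_diffusion_table(path=None) -> dict[str, float]:
    """Diffusion coefficients (cm^2/s); built-ins merged with a user table."""
    table = dict(DIFFUSION_COEFFICIENTS)
    if path is not None:
        user = load_config(path)
        for name, value in user.items():
            value = float(value)
            if value <= 0:
                raise ValueError(f"diffusion coefficient {name!r} must be positive")
            table[name] = value
    return table


def write_fit_report(fit: FitResult, path, extra: dict | None = None) -> None:
    """Serialize a FitResult (plus provenance fields) as JSON."""
    payload = fit.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
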