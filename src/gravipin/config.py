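"""Run configuration and file I/O.

A run is described by a flat TOML file with one table per model block;
defaults reproduce the wheat-coleoptile parameter set (statocyte
10 x 25 d with a 4 d pile, R = 25, A = 1.3, tau_PIN = 13 min,
tau_aux/tau_PIN = 1/2000).  Unknown keys are rejected so that typos
fail loudly before any computation.  CSV files carry a header row,
UTF-8, '.' decimals, 12 significant digits (lossless round-trip at that
precision).
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gravipin import __version__
from gravipin.fitting import ResponseCurve
from gravipin.geometry import StatocyteGeometry
from gravipin.pin import PinParameters
from gravipin.response import OrganParameters, Protocol, Trajectory
from gravipin.transport import TransportParameters

__all__ = [
    "RunConfig",
    "load_config",
    "read_curve",
    "write_curve",
    "write_trajectory",
    "run_log",
]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Validated parameter blocks for a reproducible run."""

    geometry: StatocyteGeometry = field(default_factory=StatocyteGeometry)
    pin: PinParameters = field(
        default_factory=lambda: PinParameters.from_reduced(25.0, 1e-4, 13.0))
    transport: TransportParameters = field(
        default_factory=lambda: TransportParameters.from_tau_aux(13.0 / 2000.0))
    organ: OrganParameters = field(default_factory=OrganParameters)
    protocol: Protocol = field(default_factory=Protocol)
    A: float = 1.3
    pin_scheme: str = "patch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.pin_scheme not in ("patch", "pooled"):
            raise ValueError("pin_scheme must be 'patch' or 'pooled'")


_KNOWN = {
    "geometry": {"W", "H", "H_stato", "binding_mode"},
    "pin": {"R", "P", "tau_pin", "k_off_0", "k_off_1", "kappa_0", "kappa_1",
            "N_tot", "binding_mode"},
    "transport": {"N", "tau_aux", "D_star", "w_ratio", "P_in"},
    "organ": {"R_organ", "tau_g", "L_gz"},
    "protocol": {"theta_deg", "delta_T_min", "t_end_min", "gravity_multiple"},
    "response": {"A", "pin_scheme"},
}
_TOP = set(_KNOWN) | {"seed"}


def _check_keys(block: str, given: dict) -> None:
    unknown = set(given) - _KNOWN[block]
    if unknown:
        raise ValueError(f"unknown key(s) in [{block}]: {sorted(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a (TOML-parsed) mapping, rejecting unknown keys."""
    unknown = set(raw) - _TOP
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kw: dict = {}

    g = dict(raw.get("geometry", {}))
    _check_keys("geometry", g)
    kw["geometry"] = StatocyteGeometry(**g)

    p = dict(raw.get("pin", {}))
    _check_keys("pin", p)
    if "R" in p or "P" in p or "tau_pin" in p:
        bad = {"k_off_0", "k_off_1", "kappa_0", "kappa_1"} & set(p)
        if bad:
            raise ValueError("give either reduced (R, P, tau_pin) or raw rates, "
                             f"not both: {sorted(bad)}")
        kw["pin"] = PinParameters.from_reduced(
            R=p.get("R", 25.0), P=p.get("P", 1e-4), tau_pin=p.get("tau_pin", 13.0),
            N_tot=p.get("N_tot", 1.0),
            binding_mode=p.get("binding_mode", kw["geometry"].binding_mode),
        )
    elif p:
        kw["pin"] = PinParameters(**p)
    else:
        kw["pin"] = PinParameters.from_reduced(
            25.0, 1e-4, 13.0, binding_mode=kw["geometry"].binding_mode)

    t = dict(raw.get("transport", {}))
    _check_keys("transport", t)
    if "tau_aux" in t:
        if "D_star" in t:
            raise ValueError("give tau_aux or D_star, not both")
        tau = t.pop("tau_aux")
        kw["transport"] = TransportParameters.from_tau_aux(tau, **t)
    else:
        kw["transport"] = TransportParameters(**t) if t else (
            TransportParameters.from_tau_aux(13.0 / 2000.0))

    o = dict(raw.get("organ", {}))
    _check_keys("organ", o)
    kw["organ"] = OrganParameters(**o)

    pr = dict(raw.get("protocol", {}))
    _check_keys("protocol", pr)
    kw["protocol"] = Protocol(
        theta_0=pr.get("theta_deg", 45.0),
        delta_T=pr.get("delta_T_min", math.inf),
        t_end=pr.get("t_end_min", 208.0),
        gravity_multiple=pr.get("gravity_multiple", 1.0),
    )

    r = dict(raw.get("response", {}))
    _check_keys("response", r)
    kw["A"] = r.get("A", 1.3)
    kw["pin_scheme"] = r.get("pin_scheme", "patch")
    kw["seed"] = int(raw.get("seed", 0))
    return RunConfig(**kw)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        return config_from_dict(tomllib.load(fh))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = {
    "steady": ("angle_deg", "response"),
    "dose": ("duration_min", "response"),
}


def write_curve(curve: ResponseCurve, path: str | Path, kind: str = "steady"
                ) -> None:
    """Write a response curve as CSV with the standard column names."""
    xcol, ycol = _CURVE_COLUMNS[kind]
    df = pd.DataFrame({xcol: curve.x, ycol: curve.y})
    if curve.sigma is not None:
        df["sigma"] = curve.sigma
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curve(path: str | Path, kind: str = "steady") -> ResponseCurve:
    """Read a response curve CSV, checking the expected header."""
    xcol, ycol = _CURVE_COLUMNS[kind]
    df = pd.read_csv(path)
    for col in (xcol, ycol):
        if col not in df.columns:
            raise ValueError(
                f"missing column '{col}' in {path} "
                f"(found {list(df.columns)}); expected a '{kind}' curve")
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return ResponseCurve(x=df[xcol].to_numpy(), y=df[ycol].to_numpy(), sigma=sigma)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a simulated trajectory as CSV (times in minutes)."""
    pd.DataFrame({
        "time_min": traj.t,
        "u0": traj.u0,
        "u1": traj.u1,
        "Pe": traj.Pe,
        "delta_tilde": traj.delta_tilde,
        "curvature_per_mm": traj.curvature,
        "tip_angle_deg": traj.tip_angle,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_log(config_text: str, seed: int, t_start: float) -> dict:
    """Reproducibility record: config hash, seed, version, wall-clock."""
    return {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "gravipin_version": __version__,
        "numpy_version": np.__version__,
        "wall_clock_s": round(time.perf_counter() - t_start, 3),
    }


def dump_log(log: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2) + "\n")


def config_text(cfg: RunConfig) -> str:
    """Canonical text rendering of a config (used for hashing)."""
    def enc(o):
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        return str(o)
    return json.dumps(asdict(cfg), default=enc, sort_keys=True)
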