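"""Configuration, serialization and reproducibility plumbing.

Run configuration is a flat, human-diffable TOML file with a required
``[parameters]`` table (the 17 model constants, romanized lowercase names)
and an optional ``[run]`` table (initial state, horizon, solver tolerances,
seed). Trajectories are written as CSV (full float precision, exact
round-trip) with a JSON sidecar recording parameters and solver metadata;
stability reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .model import GameParameters, StrategyState, validate_parameters
from .dynamics import DEFAULT_ABS_TOL, DEFAULT_HORIZON, DEFAULT_REL_TOL, Trajectory
from .stability import classify_equilibrium, CORNER_LABELS, proposition_check

__all__ = [
    "RunConfig",
    "ConfigError",
    "read_config",
    "write_trajectory",
    "read_trajectory",
    "report_stability",
]

logger = logging.getLogger("trigame")

PathLike = Union[str, Path]


class ConfigError(ValueError):
    """Raised for unreadable or invalid run-configuration files."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults for omitted fields."""

    parameters: GameParameters
    init: StrategyState = StrategyState(0.5, 0.5, 0.5)
    horizon: float = DEFAULT_HORIZON
    rel_tol: float = DEFAULT_REL_TOL
    abs_tol: float = DEFAULT_ABS_TOL
    seed: int = 0
    source: Optional[str] = None
    config_hash: Optional[str] = None
    extras: dict = field(default_factory=dict)


def read_config(path: PathLike) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Requires a ``[parameters]`` table; ``[run]`` keys ``init`` (3-list),
    ``horizon``, ``rel_tol``, ``abs_tol`` and ``seed`` are optional with the
    documented defaults.
    """
    path = Path(path)
    raw_bytes = path.read_bytes()
    try:
        doc = tomllib.loads(raw_bytes.decode("utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if "parameters" not in doc:
        raise ConfigError(f"{path} is missing the required [parameters] block")
    try:
        params = validate_parameters(doc["parameters"])
    except ValueError as exc:
        raise ConfigError(f"invalid [parameters] in {path}: {exc}") from exc

    run = doc.get("run", {})
    init_values = run.get("init", (0.5, 0.5, 0.5))
    try:
        init = StrategyState.from_iterable(init_values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [run].init in {path}: {exc}") from exc

    config = RunConfig(
        parameters=params,
        init=init,
        horizon=float(run.get("horizon", DEFAULT_HORIZON)),
        rel_tol=float(run.get("rel_tol", DEFAULT_REL_TOL)),
        abs_tol=float(run.get("abs_tol", DEFAULT_ABS_TOL)),
        seed=int(run.get("seed", 0)),
        source=str(path),
        config_hash=hashlib.sha256(raw_bytes).hexdigest(),
        extras={k: v for k, v in doc.items() if k not in ("parameters", "run")},
    )
    logger.info(
        "trigame %s loaded config %s (sha256=%s, seed=%d)",
        __version__, path, config.config_hash[:12], config.seed,
    )
    return config


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trajectory(traj: Trajectory, path: PathLike, seed: Optional[int] = None) -> None:
    """Write a trajectory as CSV (time,delta,eta,zeta) plus a JSON sidecar.

    Floats are written in shortest round-trip representation, so reading the
    CSV back reproduces the stored states exactly.
    """
    path = Path(path)
    frame = pd.DataFrame({
        "time": traj.times,
        "delta": traj.delta,
        "eta": traj.eta,
        "zeta": traj.zeta,
    })
    # repr gives the shortest exact round-trip decimal for every float
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    meta = {
        "package_version": __version__,
        "params": traj.params.as_dict() if traj.params is not None else None,
        "solver_meta": traj.solver_meta,
        "seed": seed,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    logger.info("trigame %s wrote trajectory %s (%d rows, seed=%s)",
                __version__, path, len(frame), seed)


def read_trajectory(path: PathLike) -> Trajectory:
    """Read back a trajectory CSV written by :func:`write_trajectory`.

    Restores the parameters from the JSON sidecar when present.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    params = None
    solver_meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("params"):
            params = GameParameters(**meta["params"])
        solver_meta = meta.get("solver_meta", {})
    return Trajectory(
        times=frame["time"].to_numpy(),
        states=frame[["delta", "eta", "zeta"]].to_numpy(),
        params=params,
        solver_meta=solver_meta,
    )


def report_stability(params: GameParameters, path: PathLike, tol: float = 1e-9) -> dict:
    """Write (and return) the full JSON stability report.

    Contains all eight corner reports (eigenvalues, sign pattern,
    classification) plus the sufficient-condition proposition block.
    """
    reports = [classify_equilibrium(label, params, tol) for label in CORNER_LABELS]
    check = proposition_check(params)
    doc = {
        "package_version": __version__,
        "parameters": params.as_dict(),
        "equilibria": [
            {
                "label": r.label,
                "state": list(r.state.as_tuple()),
                "eigenvalues": list(r.eigenvalues),
                "sign_pattern": "".join(r.sign_pattern),
                "classification": r.classification,
            }
            for r in reports
        ],
        "ess": [r.label for r in reports if r.classification == "ESS"],
        "proposition_check": {
            "cond1_holds": check.cond1_holds,
            "cond2_holds": check.cond2_holds,
            "auxiliary_signs": check.auxiliary_signs,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    logger.info("trigame %s wrote stability report %s (ESS=%s)",
                __version__, path, ",".join(doc["ess"]) or "none")
    return doc
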