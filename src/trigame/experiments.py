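"""Parameter sweeps, critical-threshold scans, sensitivity indices, and the
random-parameter sampler used by property tests.

The sensitivity analysis is a transparent Monte-Carlo variance decomposition
(Saltelli-style first-order indices) of the long-run compliance rate with
respect to the medical risk, penalty intensity and exposure rate, plus
one-at-a-time local elasticities around the reference parameterization. It
deliberately replaces any machine-learned surrogate: the quantity ranked is
the model's own output, computed by integrating the replicator system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .model import (
    BASELINE,
    PARAMETER_NAMES,
    GameParameters,
    ParameterValidationError,
    StrategyState,
)
from .stability import proposition_check
from .dynamics import DEFAULT_HORIZON, detect_convergence, integrate, time_to_threshold

__all__ = [
    "SweepResult",
    "SensitivityReport",
    "sweep",
    "threshold_scan",
    "sensitivity_indices",
    "sample_parameters",
    "DEFAULT_INIT",
    "SENSITIVITY_DEFAULT_RANGES",
]

#: Default initial condition for all experiments (maximum-entropy midpoint).
DEFAULT_INIT = StrategyState(0.5, 0.5, 0.5)

METRICS = ("final_delta", "final_eta", "final_zeta", "attractor_label", "time_to_eta_0.9")

#: Default sampling ranges for the sensitivity analysis, bracketing the
#: reference values (vm2=20, theta=0.6, mu=0.8).
SENSITIVITY_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "vm2": (10.0, 30.0),
    "theta": (0.2, 0.8),
    "mu": (0.1, 0.9),
}

#: Uniform sampling ranges for the random-parameter fixture generator:
#: payoffs/costs on [1, 100], probabilities/intensities on [0.05, 0.95].
_SAMPLER_RANGES: dict[str, tuple[float, float]] = {
    name: ((0.05, 0.95) if name in ("mu", "theta") else (1.0, 100.0))
    for name in PARAMETER_NAMES
}


@dataclass(frozen=True)
class SweepResult:
    """Grid of a trajectory-derived metric over one or two parameters."""

    swept_names: tuple[str, ...]
    grids: tuple[tuple[float, ...], ...]
    metric_name: str
    values: np.ndarray
    base_params: GameParameters
    init: StrategyState
    horizon: float

    def as_records(self) -> list[dict]:
        """Long-format records (one per grid point), convenient for CSV."""
        records = []
        if len(self.swept_names) == 1:
            for i, v in enumerate(self.grids[0]):
                records.append({self.swept_names[0]: v, self.metric_name: self.values[i]})
        else:
            for i, v1 in enumerate(self.grids[0]):
                for j, v2 in enumerate(self.grids[1]):
                    records.append({
                        self.swept_names[0]: v1,
                        self.swept_names[1]: v2,
                        self.metric_name: self.values[i, j],
                    })
        return records


@dataclass(frozen=True)
class SensitivityReport:
    """First-order variance indices and local elasticities of final eta."""

    names: tuple[str, ...]
    first_order_indices: dict[str, float]
    elasticities: dict[str, float]
    n_samples: int
    seed: int
    output_variance: float = 0.0
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


def _check_range(name: str, value: float) -> None:
    if name in ("mu", "theta"):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"grid value {value} out of range for {name!r} (must be in [0, 1])")
    elif value < 0:
        raise ValueError(f"grid value {value} out of range for {name!r} (must be >= 0)")


def _metric_from_trajectory(traj, metric: str):
    if metric == "final_delta":
        return traj.final_state().delta
    if metric == "final_eta":
        return traj.final_state().eta
    if metric == "final_zeta":
        return traj.final_state().zeta
    if metric == "attractor_label":
        return detect_convergence(traj)
    if metric == "time_to_eta_0.9":
        return time_to_threshold(traj, "eta", 0.9)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def sweep(
    base: GameParameters,
    names: Sequence[str],
    grids: Sequence[Sequence[float]],
    metric: str = "final_eta",
    init: StrategyState = DEFAULT_INIT,
    horizon: float = DEFAULT_HORIZON,
) -> SweepResult:
    """Integrate once per grid point and extract a trajectory metric.

    ``names`` holds one or two parameter names; ``grids`` the matching value
    lists. For two parameters the metric array is shaped (len(grid1),
    len(grid2)).
    """
    names = tuple(names)
    if not 1 <= len(names) <= 2 or len(grids) != len(names):
        raise ValueError("sweep takes one or two parameter names with matching grids")
    for name in names:
        if name not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter name {name!r}")
    grids = tuple(tuple(float(v) for v in g) for g in grids)
    for name, grid in zip(names, grids):
        for v in grid:
            _check_range(name, v)

    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")

    shape = tuple(len(g) for g in grids)
    values = np.empty(shape, dtype=object)
    for idx in np.ndindex(shape):
        overrides = {name: grids[k][idx[k]] for k, name in enumerate(names)}
        traj = integrate(init, base.replace(**overrides), horizon=horizon)
        values[idx] = _metric_from_trajectory(traj, metric)
    if metric != "attractor_label":
        values = values.astype(float)
    return SweepResult(
        swept_names=names,
        grids=grids,
        metric_name=metric,
        values=values,
        base_params=base,
        init=init,
        horizon=horizon,
    )


def _e8_stable(params: GameParameters) -> bool:
    # Sign of E8's eta-eigenvalue: cm1 - cm2 + im2 - cc - mu*bm.
    p = params
    return (p.cm1 - p.cm2 + p.im2 - p.cc - p.mu * p.bm) < 0


def threshold_scan(
    base: GameParameters,
    name: str,
    lo: float,
    hi: float,
    criterion: str = "e8_stability",
    tol: float = 1e-3,
    init: StrategyState = DEFAULT_INIT,
    horizon: float = DEFAULT_HORIZON,
) -> float:
    """Bisect for the critical parameter value where a criterion flips.

    ``e8_stability`` uses the sign of the fully cooperative corner's second
    eigenvalue (closed form, no integration); ``attractor_flip`` uses the
    integrated attractor label from the default initial state. The criterion
    must differ at the two endpoints; the returned value brackets the flip
    to within ``tol``.
    """
    if name not in PARAMETER_NAMES:
        raise KeyError(f"unknown parameter name {name!r}")
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")

    if criterion == "e8_stability":
        probe = lambda v: _e8_stable(base.replace(**{name: v}))
    elif criterion == "attractor_flip":
        probe = lambda v: detect_convergence(
            integrate(init, base.replace(**{name: v}), horizon=horizon)
        )
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    f_lo, f_hi = probe(lo), probe(hi)
    if f_lo == f_hi:
        raise ValueError(
            f"criterion {criterion!r} takes the same value ({f_lo!r}) at both endpoints"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if probe(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _final_eta(params: GameParameters, init: StrategyState, horizon: float) -> float:
    return integrate(init, params, horizon=horizon).final_state().eta


def sensitivity_indices(
    base: GameParameters = BASELINE,
    names: Sequence[str] = ("vm2", "theta", "mu"),
    ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    n: int = 256,
    seed: int = 0,
    init: StrategyState = DEFAULT_INIT,
    horizon: float = DEFAULT_HORIZON,
) -> SensitivityReport:
    """Monte-Carlo first-order variance indices of the long-run compliance.

    Uses the Saltelli pick-and-freeze scheme: two independent n-by-k sample
    matrices A and B on the given uniform ranges, plus one hybrid matrix per
    parameter; S1_i = Cov(f(B), f(AB_i) - f(A)) / Var estimated from the
    pooled outputs, clipped to [0, 1] (the raw estimator can dip slightly
    negative at finite n). Elasticities are central-difference local
    derivatives of final eta at ``base``, scaled to relative (percent per
    percent) units. Deterministic for a fixed seed; cost is n*(k+2)
    integrations.
    """
    if n < 16:
        raise ValueError(f"n must be >= 16, got {n}")
    names = tuple(names)
    bounds: dict[str, tuple[float, float]] = {}
    for name in names:
        if name not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter name {name!r}")
        lo, hi = (ranges or SENSITIVITY_DEFAULT_RANGES)[name]
        if not lo < hi:
            raise ValueError(f"invalid range for {name!r}: [{lo}, {hi}]")
        _check_range(name, lo)
        _check_range(name, hi)
        bounds[name] = (float(lo), float(hi))

    rng = np.random.default_rng(seed)
    k = len(names)
    lo = np.array([bounds[name][0] for name in names])
    hi = np.array([bounds[name][1] for name in names])
    A = lo + rng.random((n, k)) * (hi - lo)
    B = lo + rng.random((n, k)) * (hi - lo)

    def evaluate(matrix: np.ndarray) -> np.ndarray:
        out = np.empty(matrix.shape[0])
        for row_i, row in enumerate(matrix):
            params = base.replace(**dict(zip(names, row)))
            out[row_i] = _final_eta(params, init, horizon)
        return out

    f_a = evaluate(A)
    f_b = evaluate(B)
    pooled = np.concatenate([f_a, f_b])
    variance = float(np.var(pooled))
    indices: dict[str, float] = {}
    for i, name in enumerate(names):
        AB = A.copy()
        AB[:, i] = B[:, i]
        f_ab = evaluate(AB)
        if variance == 0.0:
            indices[name] = 0.0
        else:
            s1 = float(np.mean(f_b * (f_ab - f_a)) / variance)
            indices[name] = min(1.0, max(0.0, s1))

    eta0 = _final_eta(base, init, horizon)
    elasticities: dict[str, float] = {}
    for name in names:
        v0 = getattr(base, name)
        h = 0.01 * v0 if v0 != 0 else 0.01
        hi_v = min(v0 + h, 1.0) if name in ("mu", "theta") else v0 + h
        lo_v = max(v0 - h, 0.0)
        d_eta = _final_eta(base.replace(**{name: hi_v}), init, horizon) - _final_eta(
            base.replace(**{name: lo_v}), init, horizon
        )
        derivative = d_eta / (hi_v - lo_v)
        elasticities[name] = derivative * v0 / eta0 if eta0 != 0 else derivative * v0

    return SensitivityReport(
        names=names,
        first_order_indices=indices,
        elasticities=elasticities,
        n_samples=n,
        seed=seed,
        output_variance=variance,
        ranges=bounds,
    )


def sample_parameters(
    constraint: str = "any",
    n: int = 1,
    seed: int = 0,
    max_tries: Optional[int] = None,
) -> list[GameParameters]:
    """Rejection-sample valid random parameter sets.

    Payoffs/costs are uniform on [1, 100], mu and theta on [0.05, 0.95];
    the cm2 < cm1 ordering is enforced by swapping the two draws. With
    ``constraint='cond1'`` or ``'cond2'`` only sets satisfying the
    corresponding sufficient-condition inequality pair are kept.
    """
    if constraint not in ("any", "cond1", "cond2"):
        raise ValueError(f"unknown constraint {constraint!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    budget = max_tries if max_tries is not None else 1000 + 500 * n
    out: list[GameParameters] = []
    tries = 0
    while len(out) < n:
        if tries >= budget:
            raise RuntimeError(
                f"rejection budget exceeded ({budget} draws) for constraint {constraint!r}"
            )
        tries += 1
        draw = {
            name: rng.uniform(lo, hi) for name, (lo, hi) in _SAMPLER_RANGES.items()
        }
        if draw["cm2"] >= draw["cm1"]:
            draw["cm1"], draw["cm2"] = draw["cm2"], draw["cm1"]
        try:
            params = GameParameters(**draw)
        except ParameterValidationError:  # pragma: no cover - ranges preclude it
            continue
        if constraint != "any":
            check = proposition_check(params)
            ok = check.cond1_holds if constraint == "cond1" else check.cond2_holds
            if not ok:
                continue
        out.append(params)
    return out
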