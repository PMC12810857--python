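"""Numerical integration of the replicator system and attractor detection.

The replicator flow preserves the unit cube and leaves every face invariant.
To respect that structure exactly, integration works in log-odds coordinates
y = logit(x), in which each replicator equation collapses to dy/dt = G(x) —
the payoff-difference bracket itself. This keeps trajectories strictly
inside the cube, retains sub-floating-point distances from the faces (so a
transient visit near a saddle face does not numerically glue the trajectory
onto it), and makes components that start exactly on a face stay there
exactly. Default horizon is 200 model-time units, long enough that
trajectories under the reference parameterization settle at a corner to well
below the 1e-3 corner tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .model import GameParameters, StrategyState, _brackets, _rhs
from .stability import CORNER_LABELS, corner_equilibria

__all__ = [
    "Trajectory",
    "BasinSummary",
    "SolverError",
    "integrate",
    "detect_convergence",
    "basin_sample",
    "time_to_threshold",
]

DEFAULT_HORIZON = 200.0
DEFAULT_REL_TOL = 1e-8
DEFAULT_ABS_TOL = 1e-10
_MIN_SAMPLES = 201  # dense enough for time-to-threshold interpolation

StateLike = Union[StrategyState, Sequence[float]]


class SolverError(RuntimeError):
    """Raised when the ODE solver fails (e.g. step underflow)."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped solution of the replicator system.

    ``times`` is strictly increasing starting at 0; ``states`` is the
    matching (n, 3) array of (delta, eta, zeta) rows, clipped to [0, 1].
    """

    times: np.ndarray
    states: np.ndarray
    params: GameParameters
    solver_meta: dict = field(default_factory=dict)

    @property
    def delta(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def eta(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def zeta(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def initial_state(self) -> StrategyState:
        return StrategyState.clipped(*self.states[0])

    def final_state(self) -> StrategyState:
        return StrategyState.clipped(*self.states[-1])


@dataclass(frozen=True)
class BasinSummary:
    """Tally of detected attractors over random initial conditions."""

    n_samples: int
    attractor_counts: dict[Optional[str], int]
    seed: int


def _as_state(init: StateLike) -> StrategyState:
    if isinstance(init, StrategyState):
        return init
    return StrategyState.from_iterable(init)


def integrate(
    init: StateLike,
    params: GameParameters,
    horizon: float = DEFAULT_HORIZON,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
    n_points: int = _MIN_SAMPLES,
) -> Trajectory:
    """Integrate the replicator system over [0, horizon] with adaptive RK45.

    Integration runs in log-odds coordinates, where the replicator equation
    for each component reduces to dy/dt = G (the payoff-difference bracket
    evaluated at the current state). Components that start exactly at 0 or 1
    lie on an invariant face and are held there exactly. At least
    ``n_points`` (default 201) equispaced samples are stored for
    time-to-threshold queries.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    state0 = _as_state(init)
    x0 = np.asarray(state0.as_tuple(), dtype=float)
    frozen = (x0 == 0.0) | (x0 == 1.0)
    free = np.nonzero(~frozen)[0]
    t_eval = np.linspace(0.0, horizon, max(int(n_points), _MIN_SAMPLES))
    meta = {
        "method": "RK45",
        "coordinates": "log-odds",
        "rel_tol": rel_tol,
        "abs_tol": abs_tol,
        "horizon": float(horizon),
        "n_points": int(t_eval.size),
    }

    if free.size == 0:
        states = np.tile(x0, (t_eval.size, 1))
        return Trajectory(times=t_eval, states=states, params=params, solver_meta=meta)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        x = x0.copy()
        x[free] = expit(y)
        g = _brackets(x[0], x[1], x[2], params)
        return [g[i] for i in free]

    y0 = np.log(x0[free] / (1.0 - x0[free]))
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method="RK45",
        rtol=rel_tol,
        atol=abs_tol,
        t_eval=t_eval,
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise SolverError(f"integration failed at t={reached:g}: {sol.message}")
    states = np.tile(x0, (t_eval.size, 1))
    states[:, free] = expit(sol.y.T)
    states[0] = x0  # exact requested initial condition (logit round-trip is 1-ulp lossy)
    return Trajectory(times=sol.t, states=states, params=params, solver_meta=meta)


def detect_convergence(traj: Trajectory, corner_tol: float = 1e-3) -> Optional[str]:
    """Label of the corner the trajectory has settled at, or ``None``.

    A corner qualifies when (a) the final stored state is within
    ``corner_tol`` of it in max-norm, (b) the replicator field at that final
    state has max-norm below ``corner_tol`` (the trajectory is genuinely
    parked, not merely passing nearby), and (c) no bracket drives the state
    away from the corner — a trajectory dwelling beside a saddle face at
    sub-precision distance moves slowly but has not converged and is
    reported as ``None``.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    final = traj.states[-1]
    d, e, z = (float(v) for v in final)
    speed = max(abs(v) for v in _rhs(d, e, z, traj.params))
    if speed >= corner_tol:
        return None
    brackets = _brackets(d, e, z, traj.params)
    for label, corner in corner_equilibria():
        coords = corner.as_tuple()
        dist = max(abs(v - c) for v, c in zip((d, e, z), coords))
        if dist >= corner_tol:
            continue
        outward = any(
            (c == 1.0 and g < 0.0) or (c == 0.0 and g > 0.0)
            for c, g in zip(coords, brackets)
        )
        return None if outward else label
    return None


def basin_sample(
    params: GameParameters,
    n: int,
    seed: int,
    horizon: float = DEFAULT_HORIZON,
    corner_tol: float = 1e-3,
) -> BasinSummary:
    """Integrate from ``n`` random initial states and tally attractors.

    Initial states are drawn uniformly from (0.01, 0.99)^3 — a margin off
    the boundary, since every face of the cube is invariant and corners are
    absorbing. Reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    counts: dict[Optional[str], int] = {}
    for _ in range(n):
        init = rng.uniform(0.01, 0.99, size=3)
        traj = integrate(init, params, horizon=horizon)
        label = detect_convergence(traj, corner_tol=corner_tol)
        counts[label] = counts.get(label, 0) + 1
    return BasinSummary(n_samples=n, attractor_counts=counts, seed=seed)


_VARIABLE_INDEX = {"delta": 0, "eta": 1, "zeta": 2}


def time_to_threshold(traj: Trajectory, variable: str, level: float) -> Optional[float]:
    """Normalized first-crossing time of ``variable`` above ``level``.

    Returns t*/horizon where t* is the first time the variable reaches the
    level (linear interpolation between stored samples); 0.0 if the initial
    value is already at or above it; ``None`` if never reached.
    """
    if variable not in _VARIABLE_INDEX:
        raise KeyError(f"variable must be one of {sorted(_VARIABLE_INDEX)}, got {variable!r}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    values = traj.states[:, _VARIABLE_INDEX[variable]]
    times = traj.times
    if values[0] >= level:
        return 0.0
    above = np.nonzero(values >= level)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    v0, v1 = values[i - 1], values[i]
    t0, t1 = times[i - 1], times[i]
    t_star = t0 if v1 == v0 else t0 + (level - v0) * (t1 - t0) / (v1 - v0)
    return float(t_star / traj.horizon)
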