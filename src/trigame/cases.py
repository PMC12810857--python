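"""Case-study fixtures and model-vs-observation comparison.

Three supervision programs are bundled as fixtures: TB treatment adherence
in Saudi Arabia, COVID-19 vaccination compliance in Guangdong (China), and
antibiotic prescription supervision in rural Vietnam. Each fixture carries
the observed population means (delta, eta, zeta) and the three parameters
reported for that program (exposure rate mu, medical risk vm2, penalty
intensity theta). The remaining payoff constants are not reported for the
cases, so simulation falls back to the package's reference
parameterization — case-level conclusions therefore depend on that fill-in,
which callers can override.

Observed means are used as *initial conditions* of the replicator system,
not as calibration targets; no parameter fitting is attempted.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .model import BASELINE, GameParameters, StrategyState
from .dynamics import DEFAULT_HORIZON, Trajectory, integrate

__all__ = ["CaseStudy", "CASE_NAMES", "load_case", "simulate_case", "compare_cases"]

CASE_NAMES = ("saudi_tb", "guangdong_covid", "vietnam_antibiotics")


@dataclass(frozen=True)
class CaseStudy:
    """One supervision-program fixture."""

    name: str
    observed_delta: float
    observed_eta: float
    observed_zeta: float
    overrides: dict[str, float]
    provenance: str

    def observed_state(self) -> StrategyState:
        return StrategyState(self.observed_delta, self.observed_eta, self.observed_zeta)


def _case_table() -> dict:
    data = resources.files("trigame").joinpath("data/cases.toml").read_bytes()
    return tomllib.loads(data.decode("utf-8"))


def load_case(name: str) -> CaseStudy:
    """Load one of the bundled case fixtures by name."""
    table = _case_table()
    if name not in table:
        raise KeyError(f"unknown case {name!r}; available: {sorted(table)}")
    entry = table[name]
    case = CaseStudy(
        name=name,
        observed_delta=float(entry["observed_delta"]),
        observed_eta=float(entry["observed_eta"]),
        observed_zeta=float(entry["observed_zeta"]),
        overrides={k: float(v) for k, v in entry["overrides"].items()},
        provenance=str(entry["description"]),
    )
    case.observed_state()  # validates the [0, 1] bounds
    return case


def simulate_case(
    case: CaseStudy,
    base: GameParameters = BASELINE,
    horizon: float = DEFAULT_HORIZON,
) -> Trajectory:
    """Integrate the replicator system for a case.

    Parameters are ``base`` merged with the case's reported overrides; the
    initial condition is the observed (delta, eta, zeta) means.
    """
    params = base.replace(**case.overrides)
    return integrate(case.observed_state(), params, horizon=horizon)


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        return None
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def compare_cases(
    cases: Sequence[CaseStudy],
    base: GameParameters = BASELINE,
    horizon: float = DEFAULT_HORIZON,
) -> dict:
    """Cross-case comparison of observed means and simulated end states.

    Returns per-case gaps (simulated final minus observed, per coordinate)
    and the Pearson correlation of observed delta vs observed eta across the
    cases (``None`` when either series has zero variance). With fewer than
    10 cases the correlation is flagged as descriptive: it characterizes the
    fixtures at hand, not a population.
    """
    if len(cases) < 2:
        raise ValueError("compare_cases needs at least two cases")
    per_case = []
    for case in cases:
        final = simulate_case(case, base=base, horizon=horizon).final_state()
        per_case.append({
            "name": case.name,
            "observed": case.observed_state().as_tuple(),
            "simulated_final": final.as_tuple(),
            "gap": (
                final.delta - case.observed_delta,
                final.eta - case.observed_eta,
                final.zeta - case.observed_zeta,
            ),
        })
    deltas = np.array([c.observed_delta for c in cases])
    etas = np.array([c.observed_eta for c in cases])
    return {
        "cases": per_case,
        "pearson_r_delta_eta": _pearson(deltas, etas),
        "n_cases": len(cases),
        "descriptive_only": len(cases) < 10,
    }
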