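"""Corner equilibria, Jacobian, and Lyapunov first-method classification.

The replicator system has eight fixed points at the cube corners (every
component of the field carries a factor x(1-x)). At a corner the Jacobian is
diagonal, so its eigenvalues are the three diagonal partials; the corner is
an evolutionarily stable strategy (ESS) exactly when all three are strictly
negative. Two sufficient-condition propositions single out the
"participate / defect / supervise" corner E6(1,0,1) and the fully
cooperative corner E8(1,1,1); both inequality pairs are exposed via
:func:`proposition_check` together with the auxiliary third-eigenvalue signs
the propositions leave implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GameParameters, StrategyState, _brackets

__all__ = [
    "CORNER_LABELS",
    "EquilibriumReport",
    "PropositionCheck",
    "corner_equilibria",
    "jacobian",
    "classify_equilibrium",
    "ess_set",
    "proposition_check",
]

#: Fixed label <-> corner mapping, in the conventional reporting order.
_CORNERS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("E1", (0.0, 0.0, 0.0)),
    ("E2", (1.0, 0.0, 0.0)),
    ("E3", (0.0, 1.0, 0.0)),
    ("E4", (0.0, 0.0, 1.0)),
    ("E5", (1.0, 1.0, 0.0)),
    ("E6", (1.0, 0.0, 1.0)),
    ("E7", (0.0, 1.0, 1.0)),
    ("E8", (1.0, 1.0, 1.0)),
)

CORNER_LABELS = tuple(label for label, _ in _CORNERS)
_CORNER_STATES = {label: state for label, state in _CORNERS}

#: Default eigenvalue tolerance: |lambda| <= tol is treated as a zero real
#: part, where the linearization is inconclusive (center manifold).
DEFAULT_EIGENVALUE_TOL = 1e-9


@dataclass(frozen=True)
class EquilibriumReport:
    """Stability report for one corner equilibrium.

    ``eigenvalues`` are the Jacobian's diagonal entries at the corner, in
    (delta, eta, zeta) order; ``sign_pattern`` uses '+', '-', '0';
    ``classification`` is 'ESS', 'unstable' or 'indeterminate'.
    """

    label: str
    state: StrategyState
    eigenvalues: tuple[float, float, float]
    sign_pattern: tuple[str, str, str]
    classification: str


@dataclass(frozen=True)
class PropositionCheck:
    """The two sufficient-condition inequality pairs and auxiliary signs.

    cond1: cm2 - cm1 - im2 + theta*vm2 + mu*bm < 0 and ip2 - ip1 < 0
    (E6's eta- and delta-eigenvalues negative); cond2: cm1 - cm2 + im2 - cc
    - mu*bm < 0 and ip2 - ip1 < 0 (E8's). ``auxiliary_signs`` carries the
    third eigenvalue at each corner (ig2 - w - theta*vm2 - mu*bg at E6, -w
    at E8), whose negativity the propositions implicitly assume.
    """

    cond1_holds: bool
    cond2_holds: bool
    auxiliary_signs: dict[str, float]


def corner_equilibria() -> list[tuple[str, StrategyState]]:
    """The eight corner fixed points as (label, state) pairs, E1..E8."""
    return [(label, StrategyState(*coords)) for label, coords in _CORNERS]


def jacobian(state: StrategyState, params: GameParameters) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator field at ``state``.

    Derived by differentiating x(1-x)*Gx directly: diagonal entries are
    (1-2x)*Gx; each off-diagonal entry carries the factor x(1-x) times the
    partial of that bracket, so at every corner the matrix is diagonal.
    """
    d, e, z = state.delta, state.eta, state.zeta
    p = params
    gp, gm, gg = _brackets(d, e, z, p)
    dd = d * (1 - d)
    ee = e * (1 - e)
    zz = z * (1 - z)
    return np.array([
        [
            (1 - 2 * d) * gp,
            -dd * (1 - z) * p.mu * p.bp,
            -dd * (1 - e) * p.mu * p.bp,
        ],
        [
            ee * p.mu * p.bm,
            (1 - 2 * e) * gm,
            ee * (p.theta * p.vm2 - p.cc),
        ],
        [
            zz * (1 - e) * p.mu * p.bg,
            -zz * (p.theta * p.vm2 + d * p.mu * p.bg - p.ig2),
            (1 - 2 * z) * gg,
        ],
    ])


def _sign(value: float, tol: float) -> str:
    if value > tol:
        return "+"
    if value < -tol:
        return "-"
    return "0"


def classify_equilibrium(
    label: str,
    params: GameParameters,
    tol: float = DEFAULT_EIGENVALUE_TOL,
) -> EquilibriumReport:
    """Classify one corner by the eigenvalues of the Jacobian there.

    ESS when all three eigenvalues are strictly below ``-tol``; unstable
    when any eigenvalue exceeds ``+tol`` (a positive direction dominates any
    zero one); indeterminate otherwise (some eigenvalue within ``tol`` of
    zero and none positive — Lyapunov's first method is inconclusive).
    """
    if label not in _CORNER_STATES:
        raise KeyError(f"unknown equilibrium label {label!r}; expected one of {CORNER_LABELS}")
    state = StrategyState(*_CORNER_STATES[label])
    eigenvalues = tuple(float(v) for v in np.diag(jacobian(state, params)))
    pattern = tuple(_sign(v, tol) for v in eigenvalues)
    if any(v > tol for v in eigenvalues):
        classification = "unstable"
    elif all(v < -tol for v in eigenvalues):
        classification = "ESS"
    else:
        classification = "indeterminate"
    return EquilibriumReport(
        label=label,
        state=state,
        eigenvalues=eigenvalues,  # type: ignore[arg-type]
        sign_pattern=pattern,  # type: ignore[arg-type]
        classification=classification,
    )


def ess_set(params: GameParameters, tol: float = DEFAULT_EIGENVALUE_TOL) -> set[str]:
    """Labels of all corners classified ESS under ``params``."""
    return {
        label
        for label in CORNER_LABELS
        if classify_equilibrium(label, params, tol).classification == "ESS"
    }


def proposition_check(params: GameParameters) -> PropositionCheck:
    """Evaluate both sufficient-condition inequality pairs.

    Note the two conditions are not mutually exclusive: when cc exceeds
    theta*vm2 there is a window of exposure rates in which both corners E6
    and E8 are simultaneously ESS (bistability), despite the propositions'
    uniqueness phrasing. ``ess_set`` is the authoritative classification.
    """
    p = params
    cond1 = (p.cm2 - p.cm1 - p.im2 + p.theta * p.vm2 + p.mu * p.bm < 0) and (p.ip2 - p.ip1 < 0)
    cond2 = (p.cm1 - p.cm2 + p.im2 - p.cc - p.mu * p.bm < 0) and (p.ip2 - p.ip1 < 0)
    return PropositionCheck(
        cond1_holds=cond1,
        cond2_holds=cond2,
        auxiliary_signs={
            "e6_lambda3": p.ig2 - p.w - p.theta * p.vm2 - p.mu * p.bg,
            "e8_lambda3": -p.w,
        },
    )
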