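"""Core model of the tripartite healthcare-safety supervision game.

Three bounded-rational populations interact: the public (participate in
safety supervision or not, frequency ``delta``), medical institutions
(compliant or non-compliant care, frequency ``eta``), and government
regulators (strict or lax supervision, frequency ``zeta``). Each strategy's
frequency evolves by replicator dynamics: its growth rate is proportional to
the payoff advantage of that strategy over its population's mean payoff,

    d(delta)/dt = delta (1 - delta) Gp(eta, zeta)
    d(eta)/dt   = eta (1 - eta)     Gm(delta, zeta)
    d(zeta)/dt  = zeta (1 - zeta)   Gg(delta, eta)

where each bracket G is the payoff difference between the two pure
strategies of that population. This module houses the parameter container,
the strategy state, the expected utilities, the brackets, and the vector
field; stability analysis and integration live in :mod:`trigame.stability`
and :mod:`trigame.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace as _dc_replace
from typing import Iterable, Mapping

__all__ = [
    "PARAMETER_NAMES",
    "BASELINE",
    "GameParameters",
    "StrategyState",
    "PayoffTriple",
    "ExpectedUtilities",
    "FieldVector",
    "ParameterValidationError",
    "MissingParameterError",
    "ParameterRangeError",
    "ParameterSignError",
    "ParameterOrderingError",
    "validate_parameters",
    "expected_utilities",
    "bracket_terms",
    "replicator_field",
    "payoff_cell",
]


class ParameterValidationError(ValueError):
    """Base class for invalid game-parameter inputs."""


class MissingParameterError(ParameterValidationError):
    """A required parameter name is absent from the input mapping."""


class ParameterRangeError(ParameterValidationError):
    """A probability/intensity parameter lies outside [0, 1]."""


class ParameterSignError(ParameterValidationError):
    """A payoff or cost parameter is negative."""


class ParameterOrderingError(ParameterValidationError):
    """The non-compliant care cost is not below the compliant care cost."""


#: Canonical (romanized, lowercase) order of the 17 model constants.
PARAMETER_NAMES = (
    "ip1", "ip2", "mu", "bp",
    "im1", "cm1", "im2", "cm2", "theta", "vm2", "bm", "cc",
    "ig1", "w", "cg1", "ig2", "bg",
)

_UNIT_INTERVAL = ("mu", "theta")


@dataclass(frozen=True)
class GameParameters:
    """The 17 payoff, cost and probability constants of the game.

    All payoffs are in normalized units (the model works on a common unit
    scale; no currency calibration is attempted).

    Public: ``ip1``/``ip2`` are the payoffs of participating / not
    participating in supervision; ``mu`` is the exposure rate, the
    probability that participation reveals non-compliant behaviour; ``bp``
    is the health loss the public bears when violations go unchecked.

    Institutions: ``im1``/``cm1`` are the revenue and cost of compliant
    care; ``im2``/``cm2`` the extra revenue and (lower) cost of
    non-compliant care; ``theta`` the penalty intensity scaling the medical
    risk ``vm2`` into the fine ``theta * vm2`` levied under strict
    supervision; ``bm`` the reputational damage when exposed; ``cc`` the
    cost of capturing (bribing) a lax regulator.

    Regulators: ``ig1`` base benefit, ``w`` reward for strict supervision,
    ``cg1`` supervision cost, ``ig2`` side income from regulatory capture
    under lax supervision, ``bg`` the superior-authority penalty when lax
    capture is exposed by the public.
    """

    ip1: float
    ip2: float
    mu: float
    bp: float
    im1: float
    cm1: float
    im2: float
    cm2: float
    theta: float
    vm2: float
    bm: float
    cc: float
    ig1: float
    w: float
    cg1: float
    ig2: float
    bg: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if value < 0:
                raise ParameterSignError(f"parameter {name!r} must be >= 0, got {value}")
        for name in _UNIT_INTERVAL:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterRangeError(
                    f"parameter {name!r} is a probability/intensity and must lie in [0, 1], got {value}"
                )
        if not self.cm2 < self.cm1:
            raise ParameterOrderingError(
                f"non-compliant care cost cm2 ({self.cm2}) must be strictly below compliant cost cm1 ({self.cm1})"
            )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def replace(self, **overrides: float) -> "GameParameters":
        """Return a copy with the given fields overridden (re-validated)."""
        unknown = set(overrides) - set(PARAMETER_NAMES)
        if unknown:
            raise MissingParameterError(f"unknown parameter name(s): {sorted(unknown)}")
        return _dc_replace(self, **overrides)


def validate_parameters(raw: Mapping[str, float]) -> GameParameters:
    """Validate a mapping of the 17 parameter names into a `GameParameters`.

    Raises a distinct error per defect: `MissingParameterError`,
    `ParameterRangeError` (mu/theta outside [0,1]), `ParameterSignError`
    (negative value), `ParameterOrderingError` (cm2 >= cm1).
    """
    lowered = {str(k).lower(): v for k, v in raw.items()}
    missing = [name for name in PARAMETER_NAMES if name not in lowered]
    if missing:
        raise MissingParameterError(f"missing parameter(s): {missing}")
    return GameParameters(**{name: lowered[name] for name in PARAMETER_NAMES})


#: Reference parameterization used throughout the package's examples and
#: default experiments (normalized units; exposure rate 0.8, penalty
#: intensity 0.6). Under it the all-ones corner (participate, comply,
#: strictly supervise) is the unique evolutionarily stable strategy.
BASELINE = GameParameters(
    ip1=30, ip2=20, mu=0.8, bp=15,
    im1=40, cm1=30, im2=20, cm2=15, theta=0.6, vm2=20, bm=70, cc=15,
    ig1=30, w=25, cg1=15, ig2=20, bg=25,
)


@dataclass(frozen=True)
class StrategyState:
    """A point (delta, eta, zeta) in the unit cube.

    delta: public participation frequency; eta: institutional compliance
    frequency; zeta: strict-supervision frequency.
    """

    delta: float
    eta: float
    zeta: float

    def __post_init__(self) -> None:
        for name in ("delta", "eta", "zeta"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")

    @classmethod
    def clipped(cls, delta: float, eta: float, zeta: float) -> "StrategyState":
        """Construct after clamping each component to [0, 1] (floating-point
        overshoot from numerical steps)."""
        clamp = lambda x: min(1.0, max(0.0, float(x)))
        return cls(clamp(delta), clamp(eta), clamp(zeta))

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "StrategyState":
        d, e, z = values
        return cls(d, e, z)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta, self.eta, self.zeta)


@dataclass(frozen=True)
class PayoffTriple:
    """One cell of the 2x2x2 payoff matrix (normalized payoff units)."""

    regulator_payoff: float
    institution_payoff: float
    public_payoff: float


@dataclass(frozen=True)
class ExpectedUtilities:
    """Per-strategy expected payoffs and population means.

    ``hp1``/``hp2`` are the public's expected payoffs when participating /
    abstaining, ``hp_mean`` the delta-weighted population mean; likewise for
    institutions (``hm*``, weighted by eta) and regulators (``hg*``, zeta).
    """

    hp1: float
    hp2: float
    hp_mean: float
    hm1: float
    hm2: float
    hm_mean: float
    hg1: float
    hg2: float
    hg_mean: float


@dataclass(frozen=True)
class FieldVector:
    """Replicator time-derivatives plus the three payoff-difference brackets."""

    d_delta: float
    d_eta: float
    d_zeta: float
    gp: float
    gm: float
    gg: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d_delta, self.d_eta, self.d_zeta)


def expected_utilities(state: StrategyState, params: GameParameters) -> ExpectedUtilities:
    """Expected payoffs of each pure strategy and the population means.

    The public participating catches non-compliance with probability mu, so
    only the unexposed share (1-mu) of lax/non-compliant episodes still costs
    it bp; a non-participant bears the full bp whenever care is non-compliant
    and supervision lax. Institutions choosing non-compliance pay the capture
    cost cc under lax supervision, the fine theta*vm2 under strict
    supervision, and the reputational loss mu*bm scaled by public
    participation. Strict regulators collect fines from the non-compliant
    share; lax regulators take capture income but risk the superior penalty
    bg when exposed by participating citizens.
    """
    d, e, z = state.delta, state.eta, state.zeta
    p = params
    hp1 = p.ip1 - (1 - e) * (1 - z) * (1 - p.mu) * p.bp
    hp2 = p.ip2 - (1 - e) * (1 - z) * p.bp
    hm1 = p.im1 - p.cm1
    hm2 = p.im1 + p.im2 - p.cm2 - (1 - z) * p.cc - z * p.theta * p.vm2 - d * p.mu * p.bm
    hg1 = p.w + p.ig1 - p.cg1 + (1 - e) * p.theta * p.vm2
    hg2 = p.ig1 + (1 - e) * p.ig2 - p.cg1 - (1 - e) * d * p.mu * p.bg
    return ExpectedUtilities(
        hp1=hp1, hp2=hp2, hp_mean=d * hp1 + (1 - d) * hp2,
        hm1=hm1, hm2=hm2, hm_mean=e * hm1 + (1 - e) * hm2,
        hg1=hg1, hg2=hg2, hg_mean=z * hg1 + (1 - z) * hg2,
    )


def bracket_terms(state: StrategyState, params: GameParameters) -> tuple[float, float, float]:
    """The three payoff-difference brackets (Gp, Gm, Gg).

    Each bracket is the expected-payoff advantage of the 'active' strategy
    (participate / comply / supervise strictly) over its alternative; it
    equals ``Hx1 - Hx2`` from :func:`expected_utilities` and is written here
    in expanded closed form.
    """
    return _brackets(state.delta, state.eta, state.zeta, params)


def _brackets(d: float, e: float, z: float, p: GameParameters) -> tuple[float, float, float]:
    gp = p.ip1 - p.ip2 + (1 - e) * (1 - z) * p.mu * p.bp
    gm = -p.cm1 - p.im2 + p.cm2 + (1 - z) * p.cc + d * p.mu * p.bm + z * p.theta * p.vm2
    gg = p.w + (1 - e) * p.theta * p.vm2 + (1 - e) * d * p.mu * p.bg - (1 - e) * p.ig2
    return (gp, gm, gg)


def _rhs(d: float, e: float, z: float, p: GameParameters) -> tuple[float, float, float]:
    """Replicator right-hand side on raw floats (fast path for the solver)."""
    gp, gm, gg = _brackets(d, e, z, p)
    return (d * (1 - d) * gp, e * (1 - e) * gm, z * (1 - z) * gg)


def replicator_field(state: StrategyState, params: GameParameters) -> FieldVector:
    """The replicator vector field at ``state``: x(1-x) times each bracket."""
    gp, gm, gg = bracket_terms(state, params)
    d, e, z = state.delta, state.eta, state.zeta
    return FieldVector(
        d_delta=d * (1 - d) * gp,
        d_eta=e * (1 - e) * gm,
        d_zeta=z * (1 - z) * gg,
        gp=gp, gm=gm, gg=gg,
    )


def payoff_cell(
    regulator_strict: bool,
    compliant: bool,
    participates: bool,
    params: GameParameters,
    reconciled: bool = False,
) -> PayoffTriple:
    """One cell of the 2x2x2 payoff matrix.

    With ``reconciled=False`` the cells reproduce the published payoff table
    verbatim, including its deduction of the fine ``theta*vm2`` from the
    non-compliant institution's payoff even under lax regulation. With
    ``reconciled=True`` the institution cells are made consistent with the
    expected-utility equations that define the dynamics: the fine applies
    only under strict supervision, and the capture cost ``cc`` applies under
    lax supervision. Regulator and public cells are identical in both modes.
    All dynamics elsewhere in the package are built from the expected-utility
    equations, never from the verbatim table.
    """
    p = params
    if regulator_strict:
        if compliant:
            reg = p.ig1 + p.w - p.cg1
            inst = p.im1 - p.cm1
        else:
            reg = p.w + p.ig1 + p.theta * p.vm2 - p.cg1
            inst = p.im1 + p.im2 - p.cm2 - p.theta * p.vm2
            if participates:
                inst -= p.mu * p.bm
        pub = p.ip1 if participates else p.ip2
    else:
        if compliant:
            reg = p.ig1 - p.cg1
            inst = p.im1 - p.cm1
            pub = p.ip1 if participates else p.ip2
        else:
            reg = p.ig1 + p.ig2 - p.cg1
            if participates:
                reg -= p.mu * p.bg
            inst = p.im1 + p.im2 - p.cm2
            inst -= p.cc if reconciled else p.theta * p.vm2
            if participates:
                inst -= p.mu * p.bm
            pub = (p.ip1 - (1 - p.mu) * p.bp) if participates else (p.ip2 - p.bp)
    return PayoffTriple(regulator_payoff=reg, institution_payoff=inst, public_payoff=pub)
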