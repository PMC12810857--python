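"""Unit and property tests for the payoff/utility layer and the vector field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trigame import (
    BASELINE,
    PARAMETER_NAMES,
    MissingParameterError,
    ParameterOrderingError,
    ParameterRangeError,
    ParameterSignError,
    StrategyState,
    bracket_terms,
    expected_utilities,
    payoff_cell,
    replicator_field,
    validate_parameters,
)
from conftest import random_states

BASELINE_DICT = BASELINE.as_dict()


class TestValidation:
    def test_reference_set_is_valid_and_roundtrips(self):
        params = validate_parameters(BASELINE_DICT)
        assert params == BASELINE
        assert params.as_dict() == BASELINE_DICT

    def test_uppercase_keys_accepted(self):
        params = validate_parameters({k.upper(): v for k, v in BASELINE_DICT.items()})
        assert params == BASELINE

    @pytest.mark.parametrize(
        "mutation, error",
        [
            ({"mu": None}, MissingParameterError),  # None marks deletion below
            ({"mu": 1.2}, ParameterRangeError),
            ({"theta": 1.5}, ParameterRangeError),
            ({"cm2": 35}, ParameterOrderingError),
            ({"cm2": 30}, ParameterOrderingError),  # equality is rejected too
            ({"bp": -1}, ParameterSignError),
            ({"theta": -0.2}, ParameterSignError),
        ],
    )
    def test_each_defect_raises_its_own_error(self, mutation, error):
        raw = dict(BASELINE_DICT)
        for key, value in mutation.items():
            if value is None:
                del raw[key]
            else:
                raw[key] = value
        with pytest.raises(error):
            validate_parameters(raw)

    def test_state_bounds_enforced(self):
        with pytest.raises(ValueError):
            StrategyState(1.2, 0.5, 0.5)
        clipped = StrategyState.clipped(1.0 + 1e-12, -1e-12, 0.5)
        assert clipped == StrategyState(1.0, 0.0, 0.5)


class TestExpectedUtilities:
    def test_inaction_loss_hits_nonparticipants_hardest(self, baseline):
        # With no compliance and no supervision the participant still catches
        # violations with probability mu, so only (1-mu)*bp hits them.
        u = expected_utilities(StrategyState(0.5, 0.0, 0.0), baseline)
        assert u.hp1 == pytest.approx(27.0)
        assert u.hp2 == pytest.approx(5.0)

    def test_full_compliance_removes_public_losses(self, baseline, rng):
        for state in random_states(rng, 10):
            u = expected_utilities(StrategyState(state.delta, 1.0, state.zeta), baseline)
            assert u.hp1 == pytest.approx(30.0)
            assert u.hp2 == pytest.approx(20.0)

    def test_noncompliance_pays_badly_under_full_scrutiny(self, baseline):
        u = expected_utilities(StrategyState(1.0, 0.5, 1.0), baseline)
        assert u.hm1 == pytest.approx(10.0)
        assert u.hm2 == pytest.approx(-23.0)

    def test_means_are_weighted_averages(self, random_param_sets, rng):
        for params in random_param_sets[:40]:
            for state in random_states(rng, 5):
                u = expected_utilities(state, params)
                d, e, z = state.as_tuple()
                assert u.hp_mean == pytest.approx(d * u.hp1 + (1 - d) * u.hp2, abs=1e-12)
                assert u.hm_mean == pytest.approx(e * u.hm1 + (1 - e) * u.hm2, abs=1e-12)
                assert u.hg_mean == pytest.approx(z * u.hg1 + (1 - z) * u.hg2, abs=1e-12)


class TestBrackets:
    def test_midpoint_values(self, baseline):
        gp, gm, gg = bracket_terms(StrategyState(0.5, 0.5, 0.5), baseline)
        assert (gp, gm, gg) == pytest.approx((13.0, 6.5, 26.0))

    def test_compliant_supervised_limit(self, random_param_sets):
        # At eta = zeta = 1 every conditional term vanishes from Gp.
        for params in random_param_sets[:50]:
            gp, _, _ = bracket_terms(StrategyState(0.3, 1.0, 1.0), params)
            assert gp == pytest.approx(params.ip1 - params.ip2)

    def test_unsupervised_noncompliant_participation_bonus(self, baseline):
        gp, _, _ = bracket_terms(StrategyState(0.7, 0.0, 0.0), baseline)
        assert gp == pytest.approx(22.0)  # 10 + 0.8 * 15

    def test_brackets_equal_payoff_differences(self, random_param_sets, rng):
        # 1000 random (state, params) draws: Gx == Hx1 - Hx2 to 1e-12.
        states = random_states(rng, 1000)
        for i, state in enumerate(states):
            params = random_param_sets[i % len(random_param_sets)]
            gp, gm, gg = bracket_terms(state, params)
            u = expected_utilities(state, params)
            assert gp == pytest.approx(u.hp1 - u.hp2, abs=1e-12)
            assert gm == pytest.approx(u.hm1 - u.hm2, abs=1e-12)
            assert gg == pytest.approx(u.hg1 - u.hg2, abs=1e-12)


class TestReplicatorField:
    def test_all_corners_are_exact_fixed_points(self, random_param_sets):
        corners = [
            StrategyState(d, e, z) for d in (0.0, 1.0) for e in (0.0, 1.0) for z in (0.0, 1.0)
        ]
        for params in random_param_sets[:50]:
            for corner in corners:
                assert replicator_field(corner, params).as_tuple() == (0.0, 0.0, 0.0)

    def test_midpoint_field(self, baseline):
        f = replicator_field(StrategyState(0.5, 0.5, 0.5), baseline)
        assert f.as_tuple() == pytest.approx((3.25, 1.625, 6.5))

    @settings(max_examples=200, derandomize=True)
    @given(
        delta=st.floats(0, 1), eta=st.floats(0, 1), zeta=st.floats(0, 1),
        pick=st.integers(0, 499),
    )
    def test_two_replicator_forms_agree(self, delta, eta, zeta, pick, random_param_sets):
        # x(1-x)(Hx1-Hx2) equals x(Hx1 - Hx_mean): the textbook and the
        # expanded form of the replicator equation coincide.
        params = random_param_sets[pick]
        state = StrategyState(delta, eta, zeta)
        u = expected_utilities(state, params)
        f = replicator_field(state, params)
        scale = max(1.0, abs(u.hp1), abs(u.hm1), abs(u.hg2))
        assert f.d_delta == pytest.approx(delta * (u.hp1 - u.hp_mean), abs=1e-12 * scale)
        assert f.d_eta == pytest.approx(eta * (u.hm1 - u.hm_mean), abs=1e-12 * scale)
        assert f.d_zeta == pytest.approx(zeta * (u.hg1 - u.hg_mean), abs=1e-12 * scale)

    def test_participation_monotone_when_it_pays(self, random_param_sets, rng):
        # ip1 > ip2 makes Gp positive everywhere, so delta never decreases.
        for params in random_param_sets[:100]:
            if not params.ip1 > params.ip2:
                continue
            for state in random_states(rng, 5):
                f = replicator_field(state, params)
                assert f.gp > 0
                assert f.d_delta >= 0


class TestPayoffCells:
    def test_cooperative_cell(self, baseline):
        cell = payoff_cell(True, True, True, baseline)
        assert (cell.regulator_payoff, cell.institution_payoff, cell.public_payoff) == (40, 10, 30)

    def test_lax_compliant_nonparticipating_cell(self, baseline):
        cell = payoff_cell(False, True, False, baseline)
        assert (cell.regulator_payoff, cell.institution_payoff, cell.public_payoff) == (15, 10, 20)

    def test_reconciliation_changes_only_lax_noncompliant_institution(self, baseline):
        # Verbatim table fines the institution theta*vm2 even under lax
        # regulation; the utility equations charge the capture cost cc there.
        verbatim = payoff_cell(False, False, False, baseline, reconciled=False)
        fixed = payoff_cell(False, False, False, baseline, reconciled=True)
        assert verbatim.institution_payoff == pytest.approx(33.0)
        assert fixed.institution_payoff == pytest.approx(30.0)
        assert verbatim.regulator_payoff == fixed.regulator_payoff
        assert verbatim.public_payoff == fixed.public_payoff

    @pytest.mark.parametrize("strict", [True, False])
    @pytest.mark.parametrize("compliant", [True, False])
    @pytest.mark.parametrize("participates", [True, False])
    def test_reconciled_cells_reproduce_expected_utilities(
        self, baseline, strict, compliant, participates
    ):
        # Plugging a pure-strategy profile into the expected utilities must
        # give back the corresponding reconciled payoff cell.
        state = StrategyState(float(participates), float(compliant), float(strict))
        u = expected_utilities(state, baseline)
        cell = payoff_cell(strict, compliant, participates, baseline, reconciled=True)
        assert cell.public_payoff == pytest.approx(u.hp1 if participates else u.hp2)
        assert cell.institution_payoff == pytest.approx(u.hm1 if compliant else u.hm2)
        assert cell.regulator_payoff == pytest.approx(u.hg1 if strict else u.hg2)
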