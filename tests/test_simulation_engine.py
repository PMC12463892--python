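"""Engine behaviour: conservation, determinism, oracle agreement, CRN."""

import numpy as np
import pytest

import ckdsim as ck
from ckdsim.states import STATE_INDEX, STATE_ORDER, State

from conftest import make_individual

FROZEN = ck.TransitionParameters(
    r_gen_mort=0.0, p_esrd_mort=0.0, p_esrd_base=0.0, p_ckd_incidence=0.0
)


def mixed_cohort(n_at_risk=80, n_undet=40, n_diag=30, n_treated=30, n_esrd=20):
    cohort, i = [], 0
    for count, state, stage in [
        (n_at_risk, State.AT_RISK, "NONE"),
        (n_undet, State.CKD_UNDETECTED, "I-IV"),
        (n_diag, State.CKD_DIAGNOSED, "I-IV"),
        (n_treated, State.CKD_TREATED, "I-IV"),
        (n_esrd, State.ESRD, "V"),
    ]:
        for _ in range(count):
            cohort.append(make_individual(id=i, age=70, state=state, stage=stage))
            i += 1
    return cohort


class TestRunArm:
    def test_frozen_dynamics_constant_counts(self, small_cohort):
        ledgers = ck.run_arm(small_cohort, FROZEN, None, 2024, 5, 1)
        first = ledgers[0].state_counts
        for l in ledgers[1:]:
            assert l.state_counts == first
            assert l.new_esrd == 0 and l.deaths == 0

    def test_all_esrd_one_year_death_count(self):
        n = 4000
        cohort = [
            make_individual(id=i, age=70, state=State.ESRD, stage="V")
            for i in range(n)
        ]
        ledgers = ck.run_arm(cohort, ck.TransitionParameters(), None, 2024, 1, 13)
        p = 0.0338
        assert abs(ledgers[0].deaths - n * p) <= 4 * np.sqrt(n * p * (1 - p))

    def test_deterministic_given_seed(self, small_cohort, default_params,
                                      combined_strategy):
        a = ck.run_arm(small_cohort, default_params, combined_strategy, 2024, 5, 21)
        b = ck.run_arm(small_cohort, default_params, combined_strategy, 2024, 5, 21)
        assert a == b

    def test_input_cohort_not_mutated(self, small_cohort, default_params):
        import copy

        before = copy.deepcopy(small_cohort)
        ck.run_arm(small_cohort, default_params, None, 2024, 3, 2)
        assert small_cohort == before

    def test_conservation_every_year(self, small_cohort, default_params,
                                     combined_strategy):
        ledgers = ck.run_arm(small_cohort, default_params, combined_strategy,
                             2024, 10, 3)
        for l in ledgers:
            assert sum(l.state_counts.values()) == len(small_cohort)
            assert 0.0 <= l.qalys_per_capita <= 1.0

    def test_qaly_trajectory_non_increasing(self, small_cohort, default_params):
        ledgers = ck.run_arm(small_cohort, default_params, None, 2024, 10, 4)
        pc = [l.qalys_per_capita for l in ledgers]
        assert all(a >= b for a, b in zip(pc, pc[1:]))

    def test_perfect_health_accrues_unit_qaly(self, small_cohort):
        utilities = ck.UtilityParams(u_at_risk=1.0, u_ckd=1.0, u_esrd=1.0)
        ledgers = ck.run_arm(small_cohort, FROZEN, None, 2024, 5, 5,
                             utilities=utilities)
        for l in ledgers:
            assert l.qalys_per_capita == pytest.approx(1.0)

    def test_survivors_age_one_year_per_cycle(self, default_params):
        cohort = [make_individual(id=0, age=70, state=State.AT_RISK)]
        params = ck.TransitionParameters(r_gen_mort=0.0)
        # no mortality: the lone member survives and ages each cycle
        ledgers = ck.run_arm(cohort, params, None, 2024, 3, 6)
        assert ledgers[-1].state_counts[State.AT_RISK] == 1

    def test_horizon_and_empty_cohort_rejected(self, small_cohort, default_params):
        with pytest.raises(ck.ParameterError):
            ck.run_arm(small_cohort, default_params, None, 2024, 0, 1)
        with pytest.raises(ck.ParameterError):
            ck.run_arm([], default_params, None, 2024, 5, 1)

    def test_all_dead_cohort_warns(self, default_params):
        cohort = [make_individual(id=0, state=State.DEAD)]
        with pytest.warns(UserWarning):
            ledgers = ck.run_arm(cohort, default_params, None, 2024, 2, 1)
        assert ledgers[0].state_counts[State.DEAD] == 1


class TestExpectedOccupancy:
    def test_identity_matrix_constant(self):
        m = ck.build_transition_matrix(FROZEN)
        init = [10, 5, 3, 2, 1, 0]
        occ = ck.expected_occupancy(init, m, 4)
        assert np.allclose(occ, np.tile(init, (4, 1)))

    def test_two_year_esrd_death_mass(self, default_params):
        m = ck.build_transition_matrix(default_params)
        init = np.zeros(len(STATE_ORDER))
        init[STATE_INDEX[State.ESRD]] = 1.0
        occ = ck.expected_occupancy(init, m, 2)
        assert occ[1, STATE_INDEX[State.DEAD]] == pytest.approx(1 - 0.9662**2)

    def test_conserves_total(self, default_params):
        m = ck.build_transition_matrix(default_params)
        init = [100, 50, 25, 25, 10, 0]
        occ = ck.expected_occupancy(init, m, 10)
        assert np.allclose(occ.sum(axis=1), sum(init))

    def test_micro_mean_matches_oracle(self, default_params):
        """Micro-simulation means agree with the matrix-power expectation
        (small replicate version; the full check runs in the acceptance
        suite)."""
        params = ck.TransitionParameters(p_ckd_incidence=0.02)
        cohort = mixed_cohort()
        m = ck.build_transition_matrix(params, treated_variant=True)
        reps, horizon = 100, 3
        occ = np.zeros((reps, horizon, len(STATE_ORDER)))
        for r in range(reps):
            ledgers = ck.run_arm(cohort, params, None, 2024, horizon, r,
                                 matrix=m)
            for t, l in enumerate(ledgers):
                occ[r, t] = [l.state_counts[s] for s in STATE_ORDER]
        init = np.bincount(
            [STATE_INDEX[i.state] for i in cohort], minlength=len(STATE_ORDER)
        )
        expected = ck.expected_occupancy(init, m, horizon)
        mean = occ.mean(axis=0)
        se = occ.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - expected) <= 5 * np.maximum(se, 1e-9))


class TestRunPaired:
    def test_zero_participation_arms_identical(self, small_cohort, default_params):
        strategy = ck.get_strategy("hypertension_diabetes_age65", participation=0.0)
        comp = ck.run_paired(small_cohort, default_params, strategy, 2024, 5, 8)
        assert comp.intervention == comp.control
        assert comp.esrd_reduction == [0] * 5
        assert comp.cost_savings == pytest.approx([0.0] * 5)

    def test_crn_dominance(self, small_cohort, default_params, combined_strategy):
        """Common random numbers: the intervention arm never has more
        cumulative ESRD cases or deaths, nor lower per-capita QALYs."""
        comp = ck.run_paired(small_cohort, default_params, combined_strategy,
                             2024, 10, 17)
        ci = comp.cumulative_esrd("intervention")
        cc = comp.cumulative_esrd("control")
        assert all(i <= c for i, c in zip(ci, cc))
        di = comp.cumulative_deaths("intervention")
        dc = comp.cumulative_deaths("control")
        assert all(i <= c for i, c in zip(di, dc))
        assert all(g >= 0 for g in comp.qaly_gain_per_capita)

    def test_esrd_reduction_definition(self, small_cohort, default_params,
                                       combined_strategy):
        comp = ck.run_paired(small_cohort, default_params, combined_strategy,
                             2024, 6, 9)
        ci = comp.cumulative_esrd("intervention")
        cc = comp.cumulative_esrd("control")
        assert comp.esrd_reduction == [c - i for c, i in zip(cc, ci)]

    def test_paired_determinism(self, small_cohort, default_params,
                                combined_strategy):
        a = ck.run_paired(small_cohort, default_params, combined_strategy,
                          2024, 5, 10)
        b = ck.run_paired(small_cohort, default_params, combined_strategy,
                          2024, 5, 10)
        assert a.intervention == b.intervention
        assert a.control == b.control
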