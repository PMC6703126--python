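"""Discounting, accrual, ICER, PSA, CEAC and sensitivity analyses."""

import numpy as np
import pytest

import copdcf as cf
from copdcf.economics import CEPair, pairs_to_array
from copdcf.states import N_STATES, HealthState


class TestDiscounting:
    @pytest.mark.parametrize(
        "cycle, rate, cy, expected",
        [
            (0, 0.035, 0.25, 1.0),
            (7, 0.0, 0.25, 1.0),
            (4, 0.035, 0.25, 1 / 1.035),
            (8, 0.035, 0.25, 1 / 1.035**2),
        ],
    )
    def test_discount_factor(self, cycle, rate, cy, expected):
        assert cf.discount_factor(cycle, rate, cy) == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            cf.discount_factor(1, -0.01, 0.25)

    def test_zero_rate_discounted_equals_undiscounted(self, base_params, inputs):
        lt, pr = inputs
        ps = base_params.copy()
        ps.analysis.discount_rate = 0.0
        ps.analysis.horizon_years = 10.0
        trace = cf.run_cohort(ps, ps.case_finding, lt, pr)
        assert trace.total_cost == trace.total_cost_undiscounted
        assert trace.total_qaly == trace.total_qaly_undiscounted

    def test_discounted_totals_below_undiscounted(self, base_traces):
        for trace in base_traces:
            assert trace.total_cost < trace.total_cost_undiscounted
            assert trace.total_qaly < trace.total_qaly_undiscounted


class TestCycleAccrual:
    def test_all_dead_accrues_screening_costs_only(self, base_params):
        occ = np.zeros(N_STATES)
        occ[HealthState.DEAD] = 1.0
        cost, qaly = cf.cycle_accrual(occ, np.zeros(N_STATES), base_params, 12.5)
        assert (cost, qaly) == (12.5, 0.0)

    def test_treated_gold1_cycle_accrual(self, base_params):
        occ = np.zeros(N_STATES)
        occ[HealthState.TREAT_GOLD1] = 1.0
        cost, qaly = cf.cycle_accrual(occ, np.zeros(N_STATES), base_params, 0.0)
        assert qaly == pytest.approx((0.7197 + 0.0367) * 0.25, abs=1e-9)
        assert cost == pytest.approx((164.56 + 485.16) / 4, abs=1e-9)

    def test_asymptomatic_cycle_accrual(self, base_params):
        occ = np.zeros(N_STATES)
        occ[HealthState.ASYMPTOMATIC] = 1.0
        cost, qaly = cf.cycle_accrual(occ, np.zeros(N_STATES), base_params, 0.0)
        assert qaly == pytest.approx(0.8394 * 0.25, abs=1e-9)
        assert cost == 0.0

    def test_undiagnosed_states_accrue_no_routine_cost(self, base_params):
        occ = np.zeros(N_STATES)
        occ[HealthState.UNDIAG_GOLD3] = 1.0
        cost, _ = cf.cycle_accrual(occ, np.zeros(N_STATES), base_params, 0.0)
        assert cost == 0.0

    def test_exacerbation_event_charges_episode_and_disutility(self, base_params):
        occ = np.zeros(N_STATES)
        occ[HealthState.DIAG_GOLD3] = 1.0
        exac = np.zeros(N_STATES)
        exac[HealthState.DIAG_GOLD3] = 0.1
        cost, qaly = cf.cycle_accrual(occ, exac, base_params, 0.0)
        assert cost == pytest.approx(394.01 / 4 + 0.1 * 2263.0, abs=1e-9)
        assert qaly == pytest.approx(0.6798 * 0.25 - 0.1 * 0.2265 / 12, abs=1e-9)


class TestIcer:
    def test_ratio_from_rounded_published_style_totals(self):
        res = cf.icer((1473.51, 14.2048), (1007.64, 14.1767))
        assert res.delta_cost == pytest.approx(465.87, abs=1e-9)
        assert res.delta_qaly == pytest.approx(0.0281, abs=1e-9)
        assert res.value == pytest.approx(465.87 / 0.0281, rel=1e-9)
        assert res.label == "icer"

    def test_dominant_and_dominated_labels(self):
        assert cf.icer((-1.0, 0.01), (0.0, 0.0)).label == "dominant"
        assert cf.icer((100.0, -0.01), (0.0, 0.0)).label == "dominated"

    def test_zero_qaly_difference_undefined(self):
        res = cf.icer((100.0, 1.0), (0.0, 1.0))
        assert res.label == "undefined"
        assert np.isnan(res.value)
        assert cf.icer((0.0, 1.0), (0.0, 1.0)).label == "equivalent"

    def test_invariant_to_shared_constant_cost_stream(self, base_traces):
        ti, tc = base_traces
        base = cf.icer(ti, tc).value
        shift = 123.45
        shifted = cf.icer(
            (ti.total_cost + shift, ti.total_qaly),
            (tc.total_cost + shift, tc.total_qaly),
        ).value
        assert shifted == pytest.approx(base, rel=1e-12)


class TestPsa:
    def test_same_seed_identical_pairs(self, base_params, inputs):
        lt, pr = inputs
        ps = base_params.copy()
        ps.analysis.horizon_years = 5.0
        a = cf.run_psa(ps, 3, seed=5, life_table=lt, profiles=pr)
        b = cf.run_psa(ps, 3, seed=5, life_table=lt, profiles=pr)
        assert a == b
        c = cf.run_psa(ps, 3, seed=6, life_table=lt, profiles=pr)
        assert a != c

    def test_degenerate_distributions_reproduce_deterministic_increments(
        self, base_params, inputs
    ):
        lt, pr = inputs
        ps = base_params.copy()
        ps.analysis.horizon_years = 10.0
        ps.distributions = {}
        (pair,) = cf.run_psa(ps, 1, seed=0, life_table=lt, profiles=pr)
        ti = cf.run_cohort(ps, ps.case_finding, lt, pr)
        tc = cf.run_cohort(ps, cf.routine_care(ps.case_finding), lt, pr)
        assert pair.delta_cost == pytest.approx(ti.total_cost - tc.total_cost, abs=1e-9)
        assert pair.delta_qaly == pytest.approx(ti.total_qaly - tc.total_qaly, abs=1e-9)

    def test_n_below_one_rejected(self, base_params):
        with pytest.raises(ValueError):
            cf.run_psa(base_params, 0, seed=1)


class TestCeac:
    def test_single_pair_steps_at_its_icer(self):
        pair = CEPair(465.87, 0.0281)
        ratio = 465.87 / 0.0281
        curve = cf.ceac([pair], wtp_grid=[0, ratio - 1, ratio + 1, 50_000])
        assert list(curve.probability) == [0.0, 0.0, 1.0, 1.0]

    def test_zero_wtp_with_positive_costs(self):
        pairs = [CEPair(10.0, 0.01), CEPair(20.0, 0.02)]
        assert cf.ceac(pairs, wtp_grid=[0.0]).probability[0] == 0.0

    def test_large_wtp_with_positive_qalys(self):
        pairs = [CEPair(10.0, 0.01), CEPair(20.0, 0.02)]
        assert cf.ceac(pairs, wtp_grid=[1e9]).probability[0] == 1.0

    def test_monotone_when_all_pairs_gain_qalys(self, psa_pairs):
        arr = pairs_to_array(psa_pairs)
        assert np.all(arr[:, 1] > 0)
        curve = cf.ceac(psa_pairs)
        assert np.all(np.diff(curve.probability) >= 0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            cf.ceac([])
        with pytest.raises(ValueError):
            cf.ceac([CEPair(1.0, 0.1)], wtp_grid=[])


class TestOneWaySensitivity:
    def test_base_value_reproduces_base_case(self, base_params, inputs, base_traces):
        lt, pr = inputs
        ti, tc = base_traces
        table = cf.one_way_sensitivity(
            base_params, "treatment.utility_gain", [0.0367], lt, pr
        )
        row = table.iloc[0]
        assert row["cost_difference"] == pytest.approx(
            ti.total_cost - tc.total_cost, abs=1e-9
        )
        assert row["qaly_difference"] == pytest.approx(
            ti.total_qaly - tc.total_qaly, abs=1e-9
        )

    def test_removing_utility_gain_raises_icer(self, base_params, inputs):
        lt, pr = inputs
        table = cf.one_way_sensitivity(
            base_params, "treatment.utility_gain", [0.0, 0.0367], lt, pr
        )
        assert table["qaly_difference"].iloc[0] < table["qaly_difference"].iloc[1]
        assert table["icer"].iloc[0] > table["icer"].iloc[1]

    def test_unresolvable_path_errors(self, base_params, inputs):
        lt, pr = inputs
        with pytest.raises(KeyError):
            cf.one_way_sensitivity(base_params, "treatment.nope", [1.0], lt, pr)


class TestThresholdSearch:
    def test_no_sign_change_reports_endpoint_icers(self, base_params, inputs):
        lt, pr = inputs
        with pytest.raises(ValueError, match="ICER"):
            cf.threshold_search(
                base_params,
                "treatment.utility_gain",
                wtp=1.0,  # ICER far above 1 across the whole bracket
                bracket=(0.0, 0.05),
                life_table=lt,
                profiles=pr,
            )

    def test_utility_gain_threshold_hits_wtp(self, base_params, inputs):
        lt, pr = inputs
        wtp = base_icer = None
        ti_c = cf.one_way_sensitivity(
            base_params, "treatment.utility_gain", [0.0367], lt, pr
        )
        base_icer = ti_c["icer"].iloc[0]
        wtp = 1.5 * base_icer  # crossed somewhere below the base gain
        value = cf.threshold_search(
            base_params,
            "treatment.utility_gain",
            wtp=wtp,
            bracket=(0.0, 0.0367),
            tol=1.0,
            life_table=lt,
            profiles=pr,
        )
        assert 0.0 < value < 0.0367
        check = cf.one_way_sensitivity(
            base_params, "treatment.utility_gain", [value], lt, pr
        )
        assert check["icer"].iloc[0] == pytest.approx(wtp, abs=1.0)


class TestTreatmentInertness:
    def test_fully_inert_treatment_yields_equal_qalys(self, base_params, inputs):
        """Switching every treatment effect off — odds ratios to 1, utility
        gain to 0, and the treated-only stage-improvement entries of the
        annual matrix to 0 — with free case-finding contacts makes diagnosis
        clinically inert: both strategies accrue identical QALYs."""
        lt, pr = inputs
        ps = base_params.copy()
        ps.analysis.horizon_years = 20.0
        ps.treatment.or_mortality = 1.0
        ps.treatment.or_exacerbation = 1.0
        ps.treatment.or_progression = 1.0
        ps.treatment.utility_gain = 0.0
        ps.case_finding.cost_questionnaire = 0.0
        ps.case_finding.cost_spirometry = 0.0
        gm = ps.natural_history.gold_matrix.copy()
        gm[1, 0] = gm[2, 1] = gm[3, 2] = 0.0
        ps.natural_history.gold_matrix = gm
        ti = cf.run_cohort(ps, ps.case_finding, lt, pr)
        tc = cf.run_cohort(ps, cf.routine_care(ps.case_finding), lt, pr)
        assert abs(ti.total_qaly - tc.total_qaly) < 1e-9
        # diagnosis still moves people into costed states
        assert ti.total_cost > tc.total_cost

    def test_improvement_alone_still_benefits_treated(self, base_params, inputs):
        """With odds ratios at 1 and no utility gain, the treated-only
        stage-improvement pathway keeps case-finding QALY-positive."""
        lt, pr = inputs
        ps = base_params.copy()
        ps.analysis.horizon_years = 20.0
        ps.treatment.or_mortality = 1.0
        ps.treatment.or_exacerbation = 1.0
        ps.treatment.or_progression = 1.0
        ps.treatment.utility_gain = 0.0
        ti = cf.run_cohort(ps, ps.case_finding, lt, pr)
        tc = cf.run_cohort(ps, cf.routine_care(ps.case_finding), lt, pr)
        assert ti.total_qaly > tc.total_qaly
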