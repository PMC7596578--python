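"""Transition-matrix construction, cohort iteration and accrual."""

import numpy as np
import pytest

from hbocscreen import draw_psa_sample
from hbocscreen.decision_tree import Subgroup
from hbocscreen.epi import CurveTable
from hbocscreen.markov import (N_STATES, S, accrue_outcomes, accrue_trace,
                               build_transition_matrices, run_cohort,
                               run_markov, subgroup_outcomes)

from _oracles import microsimulate_toy

SUBGROUPS = [
    Subgroup("BRCA1", True, "mammo_mri"),
    Subgroup("BRCA2", True, "mammo_only"),
    Subgroup("CHEK2", True, "mammo_only"),
    Subgroup("TP53", False, "mammo_only"),
    Subgroup("noncarrier", False, "mammo_only"),
]


def zero_cancer_curves(curves):
    """Curve bundle with no cancer incidence anywhere."""
    out = dict(curves)
    ages = curves["bc_pop"].ages
    flat = CurveTable(ages, np.zeros(ages.size))
    for k in ("bc_pop", "oc_pop", "bc_BRCA1", "bc_BRCA2", "oc_BRCA1",
              "oc_BRCA2"):
        out[k] = flat
    return out


class TestMatrixConstruction:
    def test_dead_row_is_identity(self, base_params, curves):
        M = build_transition_matrices(30, SUBGROUPS[0], base_params, curves)
        assert np.all(M[:, S["DEAD"], S["DEAD"]] == 1.0)
        assert np.all(M[:, S["DEAD"], :S["DEAD"]] == 0.0)

    def test_no_breast_cancer_after_mastectomy(self, base_params, curves):
        for sub in SUBGROUPS:
            M = build_transition_matrices(30, sub, base_params, curves)
            assert np.all(M[:, S["POST_RRM"], S["BC_E1"]] == 0.0)
            assert np.all(M[:, S["POST_RRM"], S["BC_L1"]] == 0.0)

    def test_unidentified_carriers_never_take_surgery(self, base_params,
                                                      curves):
        M = build_transition_matrices(
            30, Subgroup("BRCA1", False, "mammo_only"), base_params, curves)
        for mon in (S["MON1"], S["MON2"]):
            assert np.all(M[:, mon, S["RRM1"]] == 0.0)
            assert np.all(M[:, mon, S["RRSO1"]] == 0.0)

    def test_tunnel_states_have_no_self_transition(self, base_params, curves):
        M = build_transition_matrices(30, SUBGROUPS[0], base_params, curves)
        for tun in (S["BC_E1"], S["BC_L1"], S["OC_E1"], S["OC_L1"],
                    S["RRM1"], S["RRSO1"]):
            assert np.all(M[:, tun, tun] == 0.0)

    def test_rows_sum_to_one_over_random_draws(self, base_params, curves):
        """Construction property: every row of every matrix sums to 1
        within 1e-9 across random parameter draws, ages and subgroups."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            s = draw_psa_sample(base_params, rng)
            age = int(rng.integers(20, 95))
            sub = SUBGROUPS[int(rng.integers(len(SUBGROUPS)))]
            M = build_transition_matrices(age, sub, s, curves)
            assert np.allclose(M.sum(axis=2), 1.0, atol=1e-9)
            assert np.all(M >= -1e-15)


class TestCohortIteration:
    def test_two_state_geometric_decay(self):
        """Toy alive->dead chain with p=0.5: occupancy halves each cycle."""
        M = np.broadcast_to(np.array([[0.5, 0.5], [0.0, 1.0]]),
                            (10, 2, 2)).copy()
        trace = run_markov(M, np.array([1.0, 0.0]))
        assert np.allclose(trace.occupancy[:, 0], 0.5 ** np.arange(11))

    def test_static_cohort_without_risks(self, base_params, curves):
        M = np.broadcast_to(np.eye(N_STATES), (10, N_STATES, N_STATES)).copy()
        init = np.zeros(N_STATES)
        init[S["MON2"]] = 1.0
        trace = run_markov(M, init)
        assert np.allclose(trace.occupancy, init)

    def test_all_dead_cohort_is_inert(self, base_params, curves):
        M = build_transition_matrices(30, SUBGROUPS[0], base_params, curves)
        init = np.zeros(N_STATES)
        init[S["DEAD"]] = 1.0
        trace = run_markov(M, init)
        assert trace.incident_early.sum() == 0.0
        assert trace.rrso_events.sum() == 0.0
        assert np.allclose(trace.occupancy[:, S["DEAD"]], 1.0)

    def test_trace_conserves_mass_over_random_draws(self, base_params,
                                                    curves):
        rng = np.random.default_rng(29)
        for _ in range(10):
            s = draw_psa_sample(base_params, rng)
            sub = SUBGROUPS[int(rng.integers(len(SUBGROUPS)))]
            trace = run_cohort(int(rng.integers(20, 60)), sub, s, curves)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_trace_ends_fully_dead(self, base_params, curves):
        trace = run_cohort(30, SUBGROUPS[0], base_params, curves)
        assert trace.occupancy[-1, S["DEAD"]] == pytest.approx(1.0, abs=1e-9)


class TestAccrual:
    def test_annuity_closed_form(self):
        """Deathless single-state cohort at utility 1: discounted QALYs
        follow the annuity formula."""
        M = np.broadcast_to(np.eye(2), (3, 2, 2)).copy()
        trace = run_markov(M, np.array([1.0, 0.0]))
        _, qaly, ly = accrue_trace(trace, np.zeros(2), np.array([1.0, 0.0]),
                                   np.zeros((2, 2)), None, 0.03)
        assert qaly == pytest.approx(2.8286114, abs=1e-6)
        assert ly == pytest.approx(qaly)

    def test_zero_rate_counts_cycles(self):
        M = np.broadcast_to(np.eye(2), (7, 2, 2)).copy()
        trace = run_markov(M, np.array([1.0, 0.0]))
        _, qaly, _ = accrue_trace(trace, np.zeros(2), np.array([1.0, 0.0]),
                                  np.zeros((2, 2)), None, 0.0)
        assert qaly == pytest.approx(7.0)

    def test_utility_weights_bound_qalys_by_life_years(self, base_params,
                                                       curves):
        """Zeroing cancer utilities pulls QALYs strictly below life-years
        for a carrier; perfect health weights make them equal."""
        sub = Subgroup("BRCA1", False, "mammo_only")
        worst = base_params.copy()
        for k in list(worst.values):
            if k.startswith("utility."):
                worst.values[k] = 0.0
        b_worst = subgroup_outcomes(30, sub, worst, curves)
        assert b_worst.qaly < b_worst.ly

        perfect = base_params.copy()
        for k in list(perfect.values):
            if k.startswith(("utility.", "disutility.")):
                perfect.values[k] = 1.0 if k.startswith("utility.") else 0.0
        b_perfect = subgroup_outcomes(30, sub, perfect, curves)
        assert b_perfect.qaly == pytest.approx(b_perfect.ly, abs=1e-9)

    def test_life_expectancy_identity_without_cancer(self, base_params,
                                                     curves):
        """With zero cancer risk, unit utilities and no discounting, the
        engine's QALYs equal life expectancy from the life table."""
        p = base_params.copy()
        p.values["discount_rate"] = 0.0
        flat = zero_cancer_curves(curves)
        bundle = subgroup_outcomes(30, SUBGROUPS[4], p, flat)
        le = curves["life_table"].life_expectancy(30)
        assert bundle.qaly == pytest.approx(le, abs=1e-6)
        assert bundle.cases_total == 0.0

    def test_more_rrso_uptake_never_raises_ovarian_cases(self, base_params,
                                                         curves):
        sub = Subgroup("BRCA1", True, "mammo_mri")
        lo = dict(curves)
        hi = dict(curves)
        base_uptake = curves["uptake_rrso"]
        hi["uptake_rrso"] = CurveTable(base_uptake.ages,
                                       np.minimum(base_uptake.values * 1.3,
                                                  0.999))
        def oc_cases(cv):
            trace = run_cohort(30, sub, base_params, cv)
            return (trace.inflow(S["OC_E1"]) + trace.inflow(S["OC_L1"])).sum()
        assert oc_cases(hi) <= oc_cases(lo) + 1e-12


class TestEngineOracle:
    def test_cohort_matches_microsimulation(self, toy):
        """Matrix-based cohort outcomes on the frozen toy chain agree with
        an independent 1e5-path individual microsimulation within 3 Monte
        Carlo standard errors."""
        n = 100_000
        cost_i, qaly_i, had_cancer = microsimulate_toy(toy, n, seed=42)
        trace = run_markov(toy.matrices(), np.array([1.0, 0.0, 0.0]))
        cost, qaly, _ = accrue_trace(trace, toy.state_costs(),
                                     toy.state_utilities(), toy.flow_costs(),
                                     None, toy.discount_rate)
        cases = trace.flows[:, 0, 1].sum()
        for engine, sample in ((cost, cost_i), (qaly, qaly_i),
                               (cases, had_cancer.astype(float))):
            se = sample.std(ddof=1) / np.sqrt(n)
            assert abs(engine - sample.mean()) < 3 * se
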