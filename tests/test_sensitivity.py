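"""One-way (tornado) and probabilistic sensitivity machinery.

Model-independent behaviour is exercised with a cheap analytic runner so
these tests stay fast; full-pipeline sensitivity runs live in the
acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbocscreen import compute_ceac, run_one_way, run_psa
from hbocscreen.parameters import load_parameter_set

TOY_CONFIG = """
schema_version: 1
parameters:
  gene_proportion.BRCA1: {value: 0.5, low: 0.4, high: 0.6, dist: dirichlet, kind: proportion, block: gene_proportion}
  gene_proportion.BRCA2: {value: 0.5, low: 0.4, high: 0.6, dist: dirichlet, kind: proportion, block: gene_proportion}
  cost.assay: {value: 200, low: 160, high: 240, dist: normal, kind: cost}
  effect: {value: 0.5, low: 0.4, high: 0.6, dist: beta, kind: proportion}
  frozen: {value: 3.0, dist: fixed, kind: ratio}
"""


@pytest.fixture()
def toy_params():
    return load_parameter_set(TOY_CONFIG)


def analytic_runner(params):
    """Closed-form toy pipeline: cost rises with the assay price, QALYs
    with the effect parameter."""
    return {
        "d_cost": params["cost.assay"] * 2.0,
        "d_qaly": 0.01 * params["effect"],
        "d_ly": 0.01 * params["effect"],
        "d_cases_early": 1.0,
        "d_cases_late": -2.0,
        "d_cases_total": -1.0,
    }


class TestOneWay:
    def test_degenerate_bounds_give_zero_width(self, toy_params):
        table = run_one_way(toy_params, ["frozen"], analytic_runner)
        assert table.loc["frozen", "width"] == 0.0

    def test_icer_increases_with_assay_cost(self, toy_params):
        table = run_one_way(toy_params, ["cost.assay"], analytic_runner)
        assert (table.loc["cost.assay", "icer_high"]
                > table.loc["cost.assay", "icer_low"])

    def test_bar_widths_match_brute_force(self, toy_params):
        """Tornado entries equal independent re-evaluation at each bound."""
        from hbocscreen import perturb_one_way
        table = run_one_way(toy_params, ["cost.assay", "effect"],
                            analytic_runner)
        for name in ("cost.assay", "effect"):
            lo = analytic_runner(perturb_one_way(toy_params, name, "low"))
            hi = analytic_runner(perturb_one_way(toy_params, name, "high"))
            assert table.loc[name, "icer_low"] == pytest.approx(
                lo["d_cost"] / lo["d_qaly"])
            assert table.loc[name, "icer_high"] == pytest.approx(
                hi["d_cost"] / hi["d_qaly"])
        assert list(table["width"]) == sorted(table["width"], reverse=True)

    def test_unknown_parameter_raises(self, toy_params):
        with pytest.raises(KeyError):
            run_one_way(toy_params, ["nope"], analytic_runner)


class TestPSA:
    def test_same_seed_is_bit_identical(self, toy_params):
        a = run_psa(toy_params, n=20, seed=9, runner=analytic_runner)
        b = run_psa(toy_params, n=20, seed=9, runner=analytic_runner)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_stream_discipline_prefix_property(self, toy_params):
        """The first half of a 2n-draw run equals the n-draw run exactly."""
        short = run_psa(toy_params, n=10, seed=4, runner=analytic_runner)
        long = run_psa(toy_params, n=20, seed=4, runner=analytic_runner)
        pd.testing.assert_frame_equal(long.draws.iloc[:10], short.draws)

    def test_single_draw_collapses_credible_range(self, toy_params):
        res = run_psa(toy_params, n=1, seed=2, runner=analytic_runner)
        lo, hi = res.credible_range("d_cost")
        assert lo == hi == res.draws["d_cost"].iloc[0]

    def test_point_mass_distributions_reproduce_base(self, toy_params):
        frozen = toy_params.copy()
        for name, spec in list(frozen.specs.items()):
            frozen.specs[name] = type(spec)(
                family="fixed", base=spec.base, low=spec.base,
                high=spec.base, kind=spec.kind, block=None)
        res = run_psa(frozen, n=5, seed=1, runner=analytic_runner)
        base = analytic_runner(toy_params)
        assert (res.draws["d_cost"] == base["d_cost"]).all()
        assert (res.draws["d_qaly"] == base["d_qaly"]).all()

    def test_failed_draws_are_counted_not_dropped(self, toy_params):
        calls = {"n": 0}

        def flaky(params):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("numerical failure")
            return analytic_runner(params)

        res = run_psa(toy_params, n=9, seed=6, runner=flaky)
        assert len(res.failed_draws) == 3
        assert res.n_effective == 6


class TestCEAC:
    def test_all_cost_saving_draws_give_unit_curve(self):
        draws = pd.DataFrame({"d_cost": [-1.0, -2.0], "d_qaly": [0.1, 0.2]})
        assert (compute_ceac(draws, [0, 50_000, 1e6]) == 1.0).all()

    def test_zero_wtp_counts_cost_saving_fraction(self):
        draws = pd.DataFrame({"d_cost": [-1.0, 2.0, 3.0, -4.0],
                              "d_qaly": [0.1, 0.1, 0.1, 0.1]})
        assert compute_ceac(draws, [0.0]).iloc[0] == 0.5

    def test_monotone_when_qalys_nonnegative(self):
        rng = np.random.default_rng(12)
        draws = pd.DataFrame({"d_cost": rng.normal(100, 50, 500),
                              "d_qaly": np.abs(rng.normal(0.01, 0.005, 500))})
        curve = compute_ceac(draws, np.linspace(0, 60_000, 25))
        assert (np.diff(curve.to_numpy()) >= 0).all()

    def test_matches_normal_orthant_probability(self):
        """For independent Gaussian (cost, QALY) draws the CEAC equals the
        closed-form probability P(lambda*dq - dc >= 0) within 3 Monte Carlo
        standard errors."""
        rng = np.random.default_rng(77)
        n = 40_000
        mu_c, sd_c, mu_q, sd_q = 1000.0, 300.0, 0.01, 0.004
        draws = pd.DataFrame({"d_cost": rng.normal(mu_c, sd_c, n),
                              "d_qaly": rng.normal(mu_q, sd_q, n)})
        for lam in (50_000.0, 100_000.0, 200_000.0):
            mean = lam * mu_q - mu_c
            sd = np.hypot(lam * sd_q, sd_c)
            exact = stats.norm.sf(0.0, loc=mean, scale=sd)
            est = compute_ceac(draws, [lam]).iloc[0]
            se = np.sqrt(exact * (1 - exact) / n)
            assert abs(est - exact) < 3 * se
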