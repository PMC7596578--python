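"""Cascade testing of first-degree relatives."""

import numpy as np
import pytest

from hbocscreen import (OutcomeBundle, combine_outcomes, expected_relatives,
                        run_cascade)
from hbocscreen.epi import LifeTable
from hbocscreen.synthetic import make_life_table


def unit_survival_table():
    """Everyone survives to the terminal age."""
    ages = np.arange(20, 101)
    qx = np.zeros(ages.size)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


class TestExpectedRelatives:
    def test_unit_survival_counts(self):
        asm = {"maternal_gap": 27, "n_sisters": 1.0, "n_daughters": 1.0}
        prof = expected_relatives(47, unit_survival_table(), asm)
        by = {r.relation: r for r in prof.relatives}
        assert by["mother"].expected_count == 1.0
        assert by["mother"].age == 74
        assert by["sister"].expected_count == 1.0
        assert by["daughter"].expected_count == 1.0
        assert by["daughter"].age == 20
        assert prof.total == 3.0

    def test_young_index_has_no_daughters(self):
        prof = expected_relatives(25, unit_survival_table(),
                                  {"maternal_gap": 27})
        assert {r.relation for r in prof.relatives} == {"mother", "sister"}

    def test_everyone_dead_table_gives_no_relatives(self):
        ages = np.arange(20, 25)
        dead = LifeTable(ages, np.ones(ages.size))
        prof = expected_relatives(22, dead, {"maternal_gap": 27})
        assert prof.total == 0.0

    def test_survival_products_from_parametric_table(self):
        life = make_life_table()
        prof = expected_relatives(45, life, {"maternal_gap": 27,
                                             "n_sisters": 2.0})
        by = {r.relation: r for r in prof.relatives}
        assert by["mother"].expected_count == pytest.approx(
            np.prod(1.0 - life.qx[: 72 - life.min_age]))
        assert by["sister"].expected_count == pytest.approx(
            2.0 * np.prod(1.0 - life.qx[: 45 - life.min_age]))
        # daughter aged 18 is below the table start: certain survival
        assert by["daughter"].expected_count == 1.0


class TestRunCascade:
    @staticmethod
    def flat_outcome_fn(gene, identified, age):
        # identified carriers gain a known constant benefit
        return (OutcomeBundle(cost=10.0, qaly=2.0) if identified
                else OutcomeBundle(cost=4.0, qaly=1.0))

    def _params(self, base_params, **overrides):
        p = base_params.copy()
        p.values.update(overrides)
        return p.validate()

    def test_no_informing_no_cascade(self, base_params, curves):
        p = self._params(base_params, cascade_inform=0.0)
        inc = run_cascade({"BRCA1": 1.0}, 47, p, curves,
                          outcome_fn=self.flat_outcome_fn)
        assert inc.tested_count == 0.0
        assert inc.delta == OutcomeBundle()

    def test_detected_carriers_per_index(self, base_params):
        """Three surviving relatives -> 3 x 0.70 x 0.20 x 0.5 x 0.991
        newly detected carriers per index carrier."""
        curves = {"life_table": unit_survival_table()}
        inc = run_cascade({"BRCA1": 1.0}, 47, base_params, curves,
                          outcome_fn=self.flat_outcome_fn)
        assert inc.detected_count == pytest.approx(0.20811, abs=1e-10)
        assert inc.tested_count == pytest.approx(3 * 0.70 * 0.20)

    def test_certain_cascade_detects_all_carrier_relatives(self,
                                                           base_params):
        p = self._params(base_params, cascade_inform=1.0, cascade_test=1.0,
                         test_sensitivity=1.0)
        p.settings["cascade"]["n_daughters"] = 0.0
        curves = {"life_table": unit_survival_table()}
        inc = run_cascade({"BRCA2": 1.0}, 47, p, curves,
                          outcome_fn=self.flat_outcome_fn)
        # two relatives (mother + sister), each carrying with probability 0.5
        assert inc.detected_count == pytest.approx(1.0)

    def test_deltas_scale_linearly_in_identified_mass(self, base_params,
                                                      curves):
        one = run_cascade({"BRCA1": 1e-3}, 35, base_params, curves,
                          outcome_fn=self.flat_outcome_fn)
        three = run_cascade({"BRCA1": 3e-3}, 35, base_params, curves,
                            outcome_fn=self.flat_outcome_fn)
        assert three.delta.qaly == pytest.approx(3 * one.delta.qaly,
                                                 rel=1e-12)
        assert three.testing_cost == pytest.approx(3 * one.testing_cost,
                                                   rel=1e-12)

    def test_positive_identification_benefit_gives_positive_delta(
            self, base_params, curves):
        inc = run_cascade({"BRCA1": 1e-3}, 35, base_params, curves,
                          outcome_fn=self.flat_outcome_fn)
        assert inc.delta.qaly > 0


class TestCombineOutcomes:
    def test_printed_incremental_case_components_age_30(self):
        """Primary-model and cascade case increments add to the combined
        published counts for 30-year-olds (early +138, total -75)."""
        base = OutcomeBundle(cases_early=117, cases_late=-184)
        cascade = OutcomeBundle(cases_early=21, cases_late=-29)
        combined = combine_outcomes(base, cascade)
        assert combined.cases_early == 138
        assert combined.cases_late == -213
        assert combined.cases_total == -75

    def test_printed_incremental_case_components_age_45(self):
        base = OutcomeBundle(cases_early=138, cases_late=-154)
        cascade = OutcomeBundle(cases_early=21, cases_late=-29)
        combined = combine_outcomes(base, cascade)
        assert combined.cases_early == 159
        assert combined.cases_late == -183
        assert combined.cases_total == -24

    def test_zero_cascade_is_identity(self):
        base = OutcomeBundle(cost=1.5, qaly=2.5, cases_early=3)
        assert combine_outcomes(base, OutcomeBundle()) == base

    def test_scale_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            combine_outcomes(OutcomeBundle(), OutcomeBundle(),
                             base_scale=100_000, cascade_scale=1.0)
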