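"""Model and Results objects for the population-screening analysis.

:class:`PopulationScreeningModel` bundles a parameter set, an input-curve
bundle and a screening age; :meth:`~PopulationScreeningModel.run` evaluates
both strategy arms through the decision tree and Markov engine, attaches
the cascade-testing increment, and returns a :class:`ScreeningResults`
carrying incremental costs, QALYs, case counts and the ICER, with a
``summary()`` table.

Per-subgroup lifetime outcomes are memoized on the model instance, so the
two arms (and the cascade module's relatives) share subgroup evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov
from .cascade import CascadeIncrement, run_cascade
from .cea import CEResult, apply_harm_scenario, summarize_per_100k
from .decision_tree import MAMMO_MRI, MAMMO_ONLY, Subgroup, allocate_cohort
from .epi import discount_factor
from .markov import OutcomeBundle
from .parameters import GENES, ParameterSet, base_parameter_set
from .synthetic import default_curves

__all__ = ["PopulationScreeningModel", "ScreeningResults", "sweep_ages"]

SCENARIOS = ("base", "no-cascade", "harm")


class PopulationScreeningModel:
    """Decision-tree + Markov cohort model of population genomic screening
    for hereditary breast and ovarian cancer versus family-history-based
    testing, for one cohort of women entering at a single age.

    Parameters
    ----------
    params : ParameterSet, optional
        Model parameters; defaults to the packaged base case.
    curves : dict, optional
        Input bundle with per-gene cumulative incidence, cumulative surgical
        uptake and a ``life_table``; defaults to the packaged synthetic
        stand-ins (see :mod:`hbocscreen.synthetic`).
    age : int
        Age of the screened cohort at entry.
    cohort_size : float
        Number of women, used only for per-cohort scaling of results.
    include_cascade : bool
        Attach the cascade-testing module's increment in the base scenario.
    """

    def __init__(self, params: ParameterSet | None = None,
                 curves: dict | None = None, age: int = 30,
                 cohort_size: float = 100_000.0,
                 include_cascade: bool = True) -> None:
        self.params = params if params is not None else base_parameter_set()
        self.curves = curves if curves is not None else default_curves()
        self.age = int(age)
        self.cohort_size = float(cohort_size)
        self.include_cascade = include_cascade
        life = self.curves["life_table"]
        if not life.min_age <= self.age < life.max_age:
            raise ValueError(f"screening age {age} outside modeled range "
                             f"[{life.min_age}, {life.max_age})")
        self._memo: dict[tuple, OutcomeBundle] = {}

    @classmethod
    def from_config(cls, config_path, curves: dict | None = None,
                    **kwargs) -> "PopulationScreeningModel":
        from .parameters import load_parameter_set
        return cls(params=load_parameter_set(config_path), curves=curves,
                   **kwargs)

    # -- subgroup evaluation (memoized) -----------------------------------
    def subgroup_bundle(self, subgroup: Subgroup, age: int) -> OutcomeBundle:
        key = (subgroup.gene, subgroup.identified, subgroup.surveillance, age)
        if key not in self._memo:
            self._memo[key] = markov.subgroup_outcomes(
                age, subgroup, self.params, self.curves)
        return self._memo[key]

    def _carrier_bundle(self, gene: str, identified: bool,
                        age: int) -> OutcomeBundle:
        """Per-unit-mass outcomes for a carrier, averaging over MRI choice
        and charging the knowledge disutility when identified."""
        if not identified:
            return self.subgroup_bundle(Subgroup(gene, False, MAMMO_ONLY), age)
        p = self.params
        mri = p["mri_uptake"]
        b = (mri * self.subgroup_bundle(Subgroup(gene, True, MAMMO_MRI), age)
             + (1.0 - mri)
             * self.subgroup_bundle(Subgroup(gene, True, MAMMO_ONLY), age))
        df1 = float(discount_factor(1, p.discount_rate))
        return b - OutcomeBundle(qaly=p["disutility.knowledge"] * df1)

    # -- arms --------------------------------------------------------------
    def arm_bundle(self, arm: str) -> OutcomeBundle:
        """Per-woman lifetime outcomes of one strategy arm, including
        upfront testing costs and the knowledge disutility."""
        alloc = allocate_cohort(arm, self.params)
        total = OutcomeBundle()
        for sub, mass in alloc.masses.items():
            if mass == 0.0:
                continue
            total = total + mass * self.subgroup_bundle(sub, self.age)
        df1 = float(discount_factor(1, self.params.discount_rate))
        return total + OutcomeBundle(
            cost=alloc.upfront_cost,
            qaly=-alloc.upfront_disutility * df1)

    def cascade_increment(self) -> CascadeIncrement:
        """Increment from cascade testing of relatives of carriers detected
        by the screening assay, per woman in the primary cohort."""
        p = self.params
        part = 1.0 - p["avoid_screening"]
        detected = {g: p.carrier_prevalence * p.gene_proportions[g]
                    * part * p["test_sensitivity"] for g in GENES}
        return run_cascade(detected, self.age, p, self.curves,
                           outcome_fn=self._carrier_bundle)

    # -- main entry --------------------------------------------------------
    def run(self, scenario: str = "base") -> "ScreeningResults":
        """Evaluate both arms and return a results object.

        Scenarios: ``base`` (with cascade testing unless the model was
        built with ``include_cascade=False``), ``no-cascade``, and ``harm``
        (base plus the noncarrier screening-harm decrement).
        """
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; "
                             f"expected one of {SCENARIOS}")
        screen = self.arm_bundle("screening")
        comparator = self.arm_bundle("family_history")

        cascade = None
        with_cascade = self.include_cascade and scenario != "no-cascade"
        if with_cascade:
            cascade = self.cascade_increment()
            screen = screen + cascade.total

        cea = summarize_per_100k(screen, comparator,
                                 cohort_size=self.cohort_size,
                                 scenario=scenario)
        if scenario == "harm":
            cea = apply_harm_scenario(cea, self.params)
        return ScreeningResults(model=self, scenario=scenario, cea=cea,
                                cascade=cascade)


@dataclass
class ScreeningResults:
    """Results of one model evaluation: two arm bundles, the cascade
    increment (if attached) and derived incremental cost-effectiveness."""

    model: PopulationScreeningModel
    scenario: str
    cea: CEResult
    cascade: CascadeIncrement | None = None

    # convenience passthroughs
    @property
    def icer(self):
        return self.cea.icer

    @property
    def d_cost(self) -> float:
        return self.cea.d_cost

    @property
    def d_qaly(self) -> float:
        return self.cea.d_qaly

    def incremental_per_100k(self) -> dict[str, float]:
        c = self.cea
        return {
            "cases_early": c.per_100k("cases_early"),
            "cases_late": c.per_100k("cases_late"),
            "cases_total": c.per_100k("cases_early") + c.per_100k("cases_late"),
            "cost": c.d_cost * 1e5,
            "qaly": c.d_qaly * 1e5,
            "ly": c.d_ly * 1e5,
        }

    def to_frame(self) -> pd.DataFrame:
        return self.cea.to_frame()

    def summary(self) -> str:
        m = self.model
        icer = self.icer
        icer_txt = f"{icer:,.0f} $/QALY" if isinstance(icer, float) else icer
        lines = [
            "Population genomic screening for HBOC vs family-history testing",
            f"  screening age: {m.age}   cohort: {m.cohort_size:,.0f} women"
            f"   scenario: {self.scenario}",
            f"  discount rate: {m.params.discount_rate:.1%}/y"
            f"   cascade testing: "
            f"{'included' if self.cascade is not None else 'excluded'}",
            "",
            self.cea.to_frame().to_string(float_format=lambda v: f"{v:,.4f}"),
            "",
            f"  incremental cost per woman: ${self.d_cost:,.2f}",
            f"  incremental QALYs per woman: {self.d_qaly:.6f}",
            f"  ICER: {icer_txt}",
        ]
        if self.cascade is not None:
            k = m.cohort_size
            lines += [
                "",
                "  cascade testing module (per cohort):",
                f"    relatives tested: {self.cascade.tested_count * k:,.1f}",
                f"    new carriers identified: "
                f"{self.cascade.detected_count * k:,.1f}",
                f"    testing cost: ${self.cascade.testing_cost * k:,.0f}",
                f"    QALY increment: {self.cascade.delta.qaly * k:,.1f}",
            ]
        return "\n".join(lines)


def sweep_ages(ages, params: ParameterSet | None = None,
               curves: dict | None = None, scenario: str = "base",
               include_cascade: bool = True) -> pd.DataFrame:
    """ICER and incremental outcomes across screening ages.

    Returns one row per age with per-woman incrementals and the ICER
    (dominance flags become +/-inf for plotting convenience).
    """
    params = params if params is not None else base_parameter_set()
    curves = curves if curves is not None else default_curves()
    rows = []
    for age in ages:
        res = PopulationScreeningModel(
            params=params, curves=curves, age=int(age),
            include_cascade=include_cascade).run(scenario)
        icer = res.icer
        rows.append({
            "age": int(age),
            "d_cost": res.d_cost,
            "d_qaly": res.d_qaly,
            "icer": icer if isinstance(icer, float)
            else (np.inf if icer == "dominated" else -np.inf),
            "icer_flag": icer if isinstance(icer, str) else "ratio",
        })
    return pd.DataFrame(rows).set_index("age")
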