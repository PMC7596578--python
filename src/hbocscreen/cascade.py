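"""Cascade testing of first-degree relatives of screen-identified carriers.

Each carrier identified by the population screening assay has an expected
set of surviving female first-degree relatives (mother, sisters,
daughters), determined by the index woman's age, an assumed maternal age
gap, and background survival.  Informed relatives (70%) who choose testing
(20%) carry the family variant with probability 0.5 under autosomal
dominance and are detected with the assay's sensitivity.  Each newly
identified carrier is run through the Markov engine at her own age, and the
difference against her unidentified counterfactual self - plus the testing
costs - forms the cascade increment that is added back into the primary
model's incremental results.

Family structure is handled in expectation (no realized pedigrees), which
keeps the module deterministic.  Relatives identified through the
status-quo family-history route are assumed to behave identically in both
strategy arms and therefore cancel from all incrementals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import markov
from .decision_tree import MAMMO_MRI, MAMMO_ONLY, Subgroup
from .epi import LifeTable, discount_factor
from .markov import OutcomeBundle
from .parameters import ParameterSet

__all__ = ["Relative", "FamilyProfile", "CascadeIncrement",
           "expected_relatives", "run_cascade", "combine_outcomes"]


@dataclass(frozen=True)
class Relative:
    relation: str   # "mother" | "sister" | "daughter"
    age: int        # current age at the index woman's screening
    expected_count: float

    def __post_init__(self) -> None:
        if self.expected_count < 0:
            raise ValueError("expected relative count must be nonnegative")


@dataclass(frozen=True)
class FamilyProfile:
    """Expected surviving female first-degree relatives per index carrier."""

    index_age: int
    relatives: tuple[Relative, ...]

    @property
    def total(self) -> float:
        return sum(r.expected_count for r in self.relatives)


@dataclass
class CascadeIncrement:
    """Per-cohort cascade results: tested relatives, their testing costs,
    and the summed outcome deltas of newly identified carriers."""

    tested_count: float = 0.0
    detected_count: float = 0.0
    testing_cost: float = 0.0
    delta: OutcomeBundle = field(default_factory=OutcomeBundle)

    @property
    def total(self) -> OutcomeBundle:
        """Outcome deltas with testing costs folded into cost."""
        return self.delta + OutcomeBundle(cost=self.testing_cost)

    def scaled(self, k: float) -> "CascadeIncrement":
        return CascadeIncrement(self.tested_count * k, self.detected_count * k,
                                self.testing_cost * k, self.delta * k)


def expected_relatives(index_age: int, life_table: LifeTable,
                       assumptions: dict) -> FamilyProfile:
    """Expected surviving mother/sisters/daughters of an index carrier.

    The mother is ``maternal_gap`` years older, sisters the same age,
    daughters ``maternal_gap`` years younger (none if the index woman is
    younger than the gap).  Survival to each age comes from the life table;
    ages below its first age are treated as certain survival.
    """
    gap = int(assumptions.get("maternal_gap", 27))
    n_sis = float(assumptions.get("n_sisters", 1.0))
    n_dau = float(assumptions.get("n_daughters", 1.0))

    rels = [Relative("mother", index_age + gap,
                     life_table.survival_to(index_age + gap)),
            Relative("sister", index_age,
                     n_sis * life_table.survival_to(index_age))]
    if index_age >= gap:
        dau_age = index_age - gap
        rels.append(Relative("daughter", dau_age,
                             n_dau * life_table.survival_to(dau_age)))
    return FamilyProfile(index_age=index_age, relatives=tuple(rels))


def _default_outcome_fn(params: ParameterSet, curves: dict):
    def fn(gene: str, identified: bool, age: int) -> OutcomeBundle:
        if identified:
            mri = params["mri_uptake"]
            b = (mri * markov.subgroup_outcomes(
                     age, Subgroup(gene, True, MAMMO_MRI), params, curves)
                 + (1.0 - mri) * markov.subgroup_outcomes(
                     age, Subgroup(gene, True, MAMMO_ONLY), params, curves))
            df1 = float(discount_factor(1, params.discount_rate))
            return b - OutcomeBundle(qaly=params["disutility.knowledge"] * df1)
        return markov.subgroup_outcomes(
            age, Subgroup(gene, False, MAMMO_ONLY), params, curves)
    return fn


def run_cascade(identified_by_gene: dict[str, float], index_age: int,
                params: ParameterSet, curves: dict,
                outcome_fn=None) -> CascadeIncrement:
    """Cascade increment generated by the given screen-identified carrier
    masses (per unit cohort), all entering at ``index_age``.

    ``outcome_fn(gene, identified, age) -> OutcomeBundle`` supplies
    per-unit-mass lifetime outcomes (the model object passes its memoized
    evaluator); relatives younger than the modeled age range enter at its
    lower bound with their deltas discounted back over the waiting years.
    """
    if outcome_fn is None:
        outcome_fn = _default_outcome_fn(params, curves)
    life: LifeTable = curves["life_table"]
    profile = expected_relatives(index_age, life,
                                 params.settings.get("cascade", {}))
    inform = params["cascade_inform"]
    test = params["cascade_test"]
    sens = params["test_sensitivity"]
    specificity = params["test_specificity"]
    rate = params.discount_rate

    index_mass = sum(identified_by_gene.values())
    inc = CascadeIncrement()
    if index_mass <= 0 or profile.total == 0:
        return inc

    tested_per_index = profile.total * inform * test
    inc.tested_count = index_mass * tested_per_index
    # every tested relative pays the assay; positives (true detections plus
    # the tiny false-positive mass among noncarrier relatives) pay the
    # confirmation
    positives_per_tested = 0.5 * sens + 0.5 * (1.0 - specificity)
    inc.testing_cost = inc.tested_count * (
        params["cost.assay"]
        + positives_per_tested * params["cost.confirmation"])

    delta = OutcomeBundle()
    detected = 0.0
    for rel in profile.relatives:
        if rel.expected_count == 0:
            continue
        tested_r = rel.expected_count * inform * test
        eval_age = min(max(rel.age, life.min_age), life.max_age - 1)
        wait = max(life.min_age - rel.age, 0)
        offset = float(discount_factor(wait, rate))
        for gene, mass in identified_by_gene.items():
            det = mass * tested_r * 0.5 * sens
            if det == 0:
                continue
            detected += det
            d = outcome_fn(gene, True, eval_age) - outcome_fn(gene, False,
                                                              eval_age)
            # discounted quantities shift back to the index screening date;
            # case counts are undiscounted and pass through unchanged
            delta = delta + OutcomeBundle(
                cost=det * d.cost * offset,
                qaly=det * d.qaly * offset,
                ly=det * d.ly * offset,
                cases_early=det * d.cases_early,
                cases_late=det * d.cases_late,
                deaths_cancer=det * d.deaths_cancer,
            )
    inc.detected_count = detected
    inc.delta = delta
    return inc


def combine_outcomes(base: OutcomeBundle, cascade: OutcomeBundle, *,
                     base_scale: float = 100_000.0,
                     cascade_scale: float = 100_000.0) -> OutcomeBundle:
    """Element-wise sum of primary-model and cascade incremental outcomes.

    Both inputs must be expressed per the same cohort size; a mismatch
    raises rather than silently rescaling.
    """
    if base_scale != cascade_scale:
        raise ValueError(
            f"cohort scale mismatch: {base_scale} vs {cascade_scale}")
    return base + cascade
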