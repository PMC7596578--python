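"""Decision tree: distributes the entering cohort across starting states.

For each strategy arm the tree resolves, in order: screening participation,
carrier status, test result (sensitivity/specificity), family-history-based
identification (the status-quo route, available in both arms and applied to
those not identified by screening), specific gene, and choice of intensive
surveillance (MRI) among identified carriers.  The output is a mass
distribution over (gene, identified, surveillance) subgroups plus the
upfront testing costs and the one-year disutility of learning one's carrier
status.

Family-history testing is applied only to screening-arm non-participants
and false negatives, so nobody is identified twice.  The assay cost is
charged per screening participant and the confirmation cost per positive
result (true or false); false-positive noncarriers return to the noncarrier
path after confirmation.  The status-quo family-history testing route
itself is not costed (it is identical in both arms and cancels from every
incremental result).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import GENES, ParameterSet

__all__ = ["NONCARRIER", "MAMMO_MRI", "MAMMO_ONLY", "Subgroup",
           "InitialAllocation", "allocate_cohort"]

NONCARRIER = "noncarrier"
MAMMO_MRI = "mammo_mri"
MAMMO_ONLY = "mammo_only"
ARMS = ("screening", "family_history")


@dataclass(frozen=True)
class Subgroup:
    """A homogeneous stratum of the cohort: gene (or noncarrier),
    identification status, and surveillance modality."""

    gene: str
    identified: bool
    surveillance: str

    def __post_init__(self) -> None:
        if self.gene not in GENES and self.gene != NONCARRIER:
            raise ValueError(f"unknown gene {self.gene!r}")
        if self.surveillance not in {MAMMO_MRI, MAMMO_ONLY}:
            raise ValueError(f"unknown surveillance {self.surveillance!r}")
        if self.gene == NONCARRIER and self.identified:
            raise ValueError("noncarriers cannot be identified carriers")
        if self.surveillance == MAMMO_MRI and not self.identified:
            raise ValueError("MRI surveillance requires identified carrier status")


@dataclass
class InitialAllocation:
    """First-cycle distribution of one strategy arm.

    ``masses`` are cohort fractions summing to 1; ``upfront_cost`` is the
    expected testing cost per woman (assay + confirmations) and
    ``upfront_disutility`` the expected one-year QALY loss per woman from
    learning a positive result (applied in the first cycle).
    """

    arm: str
    masses: dict[Subgroup, float]
    upfront_cost: float = 0.0
    upfront_disutility: float = 0.0
    false_positive_fraction: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        total = sum(self.masses.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {total}, expected 1 within 1e-9")
        if any(m < -1e-15 for m in self.masses.values()):
            raise ValueError("masses must be nonnegative")

    @property
    def identified_mass(self) -> float:
        return sum(m for s, m in self.masses.items() if s.identified)


def allocate_cohort(arm: str, params: ParameterSet) -> InitialAllocation:
    """Distribute a unit cohort of previously undiagnosed women across
    Markov starting subgroups for one strategy arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    prev = params["carrier_prevalence"]
    props = params.gene_proportions
    fh = params["fh_identification"]
    sens = params["test_sensitivity"]
    specificity = params["test_specificity"]
    mri = params["mri_uptake"]
    knowledge = params["disutility.knowledge"]

    masses: dict[Subgroup, float] = {}
    if arm == "screening":
        part = 1.0 - params["avoid_screening"]
        # identified = screen-detected among participants, plus
        # family-history identification of non-participants and false
        # negatives (status-quo route, no double counting)
        p_identified = part * sens + (part * (1.0 - sens) + (1.0 - part)) * fh
        false_pos = part * (1.0 - prev) * (1.0 - specificity)
        upfront_cost = (part * params["cost.assay"]
                        + (part * prev * sens + false_pos)
                        * params["cost.confirmation"])
    else:
        p_identified = fh
        false_pos = 0.0
        upfront_cost = 0.0

    for gene in GENES:
        prev_g = prev * props[gene]
        ident = prev_g * p_identified
        masses[Subgroup(gene, True, MAMMO_MRI)] = ident * mri
        masses[Subgroup(gene, True, MAMMO_ONLY)] = ident * (1.0 - mri)
        masses[Subgroup(gene, False, MAMMO_ONLY)] = prev_g - ident
    masses[Subgroup(NONCARRIER, False, MAMMO_ONLY)] = 1.0 - prev

    identified_total = prev * p_identified
    return InitialAllocation(
        arm=arm,
        masses=masses,
        upfront_cost=upfront_cost,
        upfront_disutility=identified_total * knowledge,
        false_positive_fraction=false_pos,
    )
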