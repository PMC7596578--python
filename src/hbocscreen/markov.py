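"""Annual-cycle Markov cohort engine over the screening model's state space.

The state space has two precancer monitoring states (mammography + MRI, or
mammography only), single-cycle tunnel states for incident early/late-stage
breast and ovarian cancer and for the two risk-reducing surgeries,
after-cancer and after-surgery states, and absorbing death:

    MON1 (mammo+MRI), MON2 (mammo), BC_E1, BC_L1, OC_E1, OC_L1,
    POST_BC_E, POST_BC_L, POST_OC_E, POST_OC_L, RRM1, RRSO1,
    POST_RRM, POST_RRSO, POST_RRM_RRSO, DEAD

Transition rows are built so they sum to 1 exactly: background death is
applied first (probability qx), and the competing events among survivors
(surgical uptake, breast/ovarian cancer incidence) are decomposed on the
rate scale into mutually exclusive first events.  Rows are verified, never
renormalized.  Accrual is end-of-cycle with no half-cycle correction: the
cohort occupying a state at the start of cycle t accrues that state's cost
and utility at discount factor (1 + r)^-(t+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import epi
from .decision_tree import MAMMO_MRI, NONCARRIER, Subgroup
from .epi import CurveTable, LifeTable, annual_excess_mortality, \
    apply_hazard_ratio, apply_odds_ratio
from .parameters import ParameterSet

__all__ = [
    "STATES", "EngineError", "CohortTrace", "OutcomeBundle",
    "build_transition_matrices", "run_markov", "run_cohort",
    "accrue_trace", "accrue_outcomes", "subgroup_outcomes",
]

STATES = (
    "MON1", "MON2", "BC_E1", "BC_L1", "OC_E1", "OC_L1",
    "POST_BC_E", "POST_BC_L", "POST_OC_E", "POST_OC_L",
    "RRM1", "RRSO1", "POST_RRM", "POST_RRSO", "POST_RRM_RRSO", "DEAD",
)
S = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)

_CANCER_Y1 = (S["BC_E1"], S["BC_L1"], S["OC_E1"], S["OC_L1"])
_POST_CANCER = (S["POST_BC_E"], S["POST_BC_L"], S["POST_OC_E"], S["POST_OC_L"])
_CANCER_STATES = _CANCER_Y1 + _POST_CANCER
_BC_STATES = (S["BC_E1"], S["BC_L1"], S["POST_BC_E"], S["POST_BC_L"])
_OC_STATES = (S["OC_E1"], S["OC_L1"], S["POST_OC_E"], S["POST_OC_L"])
_ALIVE = tuple(i for i in range(N_STATES) if i != S["DEAD"])

_ROW_TOL = 1e-9


class EngineError(RuntimeError):
    """Raised when a transition matrix or cohort trace violates conservation."""


@dataclass(frozen=True)
class OutcomeBundle:
    """Discounted lifetime outcomes plus undiscounted event counts, all per
    unit of starting cohort mass."""

    cost: float = 0.0
    qaly: float = 0.0
    ly: float = 0.0
    cases_early: float = 0.0
    cases_late: float = 0.0
    deaths_cancer: float = 0.0

    @property
    def cases_total(self) -> float:
        return self.cases_early + self.cases_late

    def __add__(self, other: "OutcomeBundle") -> "OutcomeBundle":
        return OutcomeBundle(*(a + b for a, b in
                               zip(self._tuple(), other._tuple())))

    def __sub__(self, other: "OutcomeBundle") -> "OutcomeBundle":
        return OutcomeBundle(*(a - b for a, b in
                               zip(self._tuple(), other._tuple())))

    def __mul__(self, k: float) -> "OutcomeBundle":
        return OutcomeBundle(*(a * k for a in self._tuple()))

    __rmul__ = __mul__

    def _tuple(self):
        return (self.cost, self.qaly, self.ly, self.cases_early,
                self.cases_late, self.deaths_cancer)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and transition flows for one subgroup.

    ``occupancy[t]`` is the start-of-cycle-t distribution (cycle 0 = model
    entry); ``flows[t, i, j]`` the mass moving i -> j during cycle t.
    """

    start_age: int
    occupancy: np.ndarray  # (T+1, n)
    flows: np.ndarray      # (T, n, n)

    @property
    def n_cycles(self) -> int:
        return self.flows.shape[0]

    def inflow(self, state: int) -> np.ndarray:
        """Per-cycle mass entering ``state`` (event counter)."""
        return self.flows[:, :, state].sum(axis=1) - self.flows[:, state, state]

    @property
    def incident_early(self) -> np.ndarray:
        return self.inflow(S["BC_E1"]) + self.inflow(S["OC_E1"])

    @property
    def incident_late(self) -> np.ndarray:
        return self.inflow(S["BC_L1"]) + self.inflow(S["OC_L1"])

    @property
    def rrm_events(self) -> np.ndarray:
        return self.inflow(S["RRM1"]) + self.flows[:, S["POST_RRSO"],
                                                   S["POST_RRM_RRSO"]]

    @property
    def rrso_events(self) -> np.ndarray:
        return self.inflow(S["RRSO1"]) + self.flows[:, S["POST_RRM"],
                                                    S["POST_RRM_RRSO"]]

    @property
    def cancer_deaths(self) -> np.ndarray:
        return self.flows[:, list(_CANCER_STATES), S["DEAD"]].sum(axis=1)


# ---------------------------------------------------------------------------
# transition-matrix construction
# ---------------------------------------------------------------------------

def _gene_group(gene: str) -> str:
    return gene if gene in ("BRCA1", "BRCA2") else "nonBRCA"

def _annual_incidence(gene: str, cancer: str, params: ParameterSet,
                      curves: dict, ages: np.ndarray) -> np.ndarray:
    """Annual incidence probability among the event-free, by current age.

    BRCA1/2 use their own cumulative curves; other genes use the
    general-population curve odds-adjusted by the gene's odds ratio (genes
    without a published odds ratio for a cancer keep baseline risk);
    noncarriers use the population curve directly.
    """
    if gene in ("BRCA1", "BRCA2"):
        curve: CurveTable = curves[f"{cancer}_{gene}"]
        return epi.annual_prob_from_cumulative(curve, ages)
    p0 = epi.annual_prob_from_cumulative(curves[f"{cancer}_pop"], ages)
    if gene == NONCARRIER:
        return p0
    key = {"bc": "breast_or", "oc": "ovarian_or"}[cancer]
    or_map = params.group(key)
    if gene not in or_map:
        return p0
    return apply_odds_ratio(p0, or_map[gene])


def _band_values(params: ParameterSet, prefix: str, ages: np.ndarray) -> np.ndarray:
    """Age-banded parameter lookup (<45, 45-54, 55-64, 65-74, >=75)."""
    bands = params.group(prefix)
    out = np.empty(ages.shape, dtype=float)
    out[ages < 45] = bands["lt45"]
    out[(ages >= 45) & (ages < 55)] = bands["45_54"]
    out[(ages >= 55) & (ages < 65)] = bands["55_64"]
    out[(ages >= 65) & (ages < 75)] = bands["65_74"]
    out[ages >= 75] = bands["ge75"]
    return out


def _competing(surviving: np.ndarray, probs: list[np.ndarray]):
    """First-event decomposition on the rate scale among survivors.

    Returns (per-event probabilities, stay probability); the pieces sum to
    ``surviving`` exactly."""
    rates = [epi.prob_to_rate(np.clip(p, 0.0, 1.0 - 1e-12)) for p in probs]
    total = np.sum(rates, axis=0)
    any_event = -np.expm1(-total)
    safe = np.where(total > 0, total, 1.0)
    shares = [r / safe for r in rates]
    events = [surviving * any_event * sh for sh in shares]
    stay = surviving - surviving * any_event
    return events, stay


def build_transition_matrices(start_age: int, subgroup: Subgroup,
                              params: ParameterSet, curves: dict) -> np.ndarray:
    """Age-specific transition matrices for one subgroup, shape (T, n, n),
    covering cycles from ``start_age`` to the life table's terminal age
    (whose qx = 1 closes every trace)."""
    life: LifeTable = curves["life_table"]
    last = life.max_age
    if not life.min_age <= start_age < last:
        raise ValueError(f"start age {start_age} outside life table")
    ages = np.arange(start_age, last + 1)
    T = ages.size
    qx = life.qx_at(ages)

    # event probabilities by current age; the terminal cycle has qx = 1 and
    # no events (curves define increments only below their last age)
    ev_ages = ages[:-1]
    zeros = np.zeros(T)

    def padded(vals: np.ndarray) -> np.ndarray:
        out = zeros.copy()
        out[:-1] = vals
        return out

    p_bc = padded(_annual_incidence(subgroup.gene, "bc", params, curves, ev_ages))
    p_oc = padded(_annual_incidence(subgroup.gene, "oc", params, curves, ev_ages))

    if subgroup.identified and subgroup.gene != NONCARRIER:
        group = _gene_group(subgroup.gene)
        rr_rrm = 1.0 if group != "nonBRCA" else params["nonbrca_rrm_rate_ratio"]
        rr_rrso = 1.0 if group != "nonBRCA" else params["nonbrca_rrso_rate_ratio"]
        p_rrm = padded(epi.annual_uptake_prob(curves["uptake_rrm"], ev_ages, rr_rrm))
        p_rrso = padded(epi.annual_uptake_prob(curves["uptake_rrso"], ev_ages, rr_rrso))
    else:
        p_rrm = p_rrso = zeros

    # stage split at diagnosis by surveillance intensity
    policy = params.settings["stage_policy"]
    if subgroup.identified:
        pe = (policy["p_early_mammo_mri"] if subgroup.surveillance == MAMMO_MRI
              else policy["p_early_mammo"])
    else:
        pe = policy["p_early_undetected_carrier"]

    # cancer-specific excess mortality (annualized 5-y relative mortality)
    ex_bc = annual_excess_mortality(_band_values(params, "bc_rel_mort", ages))
    ex_oc = annual_excess_mortality(_band_values(params, "oc_rel_mort", ages))
    red = params["early_stage_mortality_reduction"]
    if params.settings.get("early_stage_reduction_as_multiplier", False):
        ex_bc_early = ex_bc * red
    else:
        ex_bc_early = ex_bc * (1.0 - red)

    d_bc_e = np.minimum(qx + ex_bc_early, 1.0)
    d_bc_l = np.minimum(qx + ex_bc, 1.0)
    d_oc = np.minimum(qx + ex_oc, 1.0)
    if not params.settings.get("excess_mortality_persists", True):
        d_post_bc_e = d_post_bc_l = d_post_oc = qx
    else:
        d_post_bc_e, d_post_bc_l, d_post_oc = d_bc_e, d_bc_l, d_oc

    group = _gene_group(subgroup.gene) if subgroup.gene != NONCARRIER else "nonBRCA"
    hr_bc_rrm = params[f"hr_bc_post_rrm.{group}"]
    hr_bc_rrso = params[f"hr_bc_post_rrso.{group}"]
    hr_oc_rrso = params[f"hr_oc_post_rrso.{group}"]

    M = np.zeros((T, N_STATES, N_STATES))

    def fill_risk_state(idx: int, bc: np.ndarray, oc: np.ndarray,
                        extra: list[tuple[int, np.ndarray]]) -> None:
        """Row for a precancer state with competing incidence/uptake/death."""
        surv = 1.0 - qx
        probs = [bc, oc] + [p for _, p in extra]
        events, stay = _competing(surv, probs)
        M[:, idx, S["DEAD"]] = qx
        M[:, idx, S["BC_E1"]] = events[0] * pe
        M[:, idx, S["BC_L1"]] = events[0] * (1.0 - pe)
        M[:, idx, S["OC_E1"]] = events[1] * pe
        M[:, idx, S["OC_L1"]] = events[1] * (1.0 - pe)
        for (dest, _), ev in zip(extra, events[2:]):
            M[:, idx, dest] += ev
        M[:, idx, idx] = stay

    for mon in (S["MON1"], S["MON2"]):
        fill_risk_state(mon, p_bc, p_oc,
                        [(S["RRM1"], p_rrm), (S["RRSO1"], p_rrso)])

    # surgery years: tunnel states, no further events modeled within the year
    for tun, post in ((S["RRM1"], S["POST_RRM"]), (S["RRSO1"], S["POST_RRSO"])):
        M[:, tun, S["DEAD"]] = qx
        M[:, tun, post] = 1.0 - qx

    # after mastectomy: breast risk removed (HR 0), ovarian risk unchanged,
    # oophorectomy may still follow
    fill_risk_state(S["POST_RRM"], apply_hazard_ratio(p_bc, hr_bc_rrm), p_oc,
                    [(S["POST_RRM_RRSO"], p_rrso)])
    # after oophorectomy: both risks hazard-reduced, mastectomy may follow
    fill_risk_state(S["POST_RRSO"], apply_hazard_ratio(p_bc, hr_bc_rrso),
                    apply_hazard_ratio(p_oc, hr_oc_rrso),
                    [(S["POST_RRM_RRSO"], p_rrm)])
    # after both surgeries: hazard ratios compose on the rate scale
    fill_risk_state(S["POST_RRM_RRSO"],
                    apply_hazard_ratio(p_bc, hr_bc_rrm * hr_bc_rrso),
                    apply_hazard_ratio(p_oc, hr_oc_rrso), [])

    # incident-cancer tunnel years and after-cancer states
    for y1, post, death in ((S["BC_E1"], S["POST_BC_E"], d_bc_e),
                            (S["BC_L1"], S["POST_BC_L"], d_bc_l),
                            (S["OC_E1"], S["POST_OC_E"], d_oc),
                            (S["OC_L1"], S["POST_OC_L"], d_oc)):
        M[:, y1, S["DEAD"]] = death
        M[:, y1, post] = 1.0 - death
    for post, death in ((S["POST_BC_E"], d_post_bc_e),
                        (S["POST_BC_L"], d_post_bc_l),
                        (S["POST_OC_E"], d_post_oc),
                        (S["POST_OC_L"], d_post_oc)):
        M[:, post, S["DEAD"]] = death
        M[:, post, post] = 1.0 - death

    M[:, S["DEAD"], S["DEAD"]] = 1.0

    rowsums = M.sum(axis=2)
    if not np.allclose(rowsums, 1.0, rtol=0.0, atol=_ROW_TOL):
        worst = float(np.abs(rowsums - 1.0).max())
        raise EngineError(f"transition rows deviate from 1 by {worst:.2e}")
    if np.any(M < -1e-15):
        raise EngineError("negative transition probability constructed")
    return M


# ---------------------------------------------------------------------------
# cohort iteration and accrual
# ---------------------------------------------------------------------------

def run_markov(matrices: np.ndarray, init: np.ndarray,
               start_age: int = 0) -> CohortTrace:
    """Advance a cohort through per-cycle transition matrices, recording
    occupancy and flows; raises :class:`EngineError` on mass leakage."""
    T, n, _ = matrices.shape
    init = np.asarray(init, dtype=float)
    occ = np.zeros((T + 1, n))
    occ[0] = init
    flows = np.zeros((T, n, n))
    total0 = init.sum()
    for t in range(T):
        flows[t] = occ[t][:, None] * matrices[t]
        occ[t + 1] = flows[t].sum(axis=0)
        if abs(occ[t + 1].sum() - total0) > 1e-9 * max(total0, 1.0):
            raise EngineError(f"mass not conserved at cycle {t}")
    return CohortTrace(start_age=start_age, occupancy=occ, flows=flows)


def run_cohort(start_age: int, subgroup: Subgroup, params: ParameterSet,
               curves: dict) -> CohortTrace:
    """Build this subgroup's matrices and run a unit cohort through them."""
    M = build_transition_matrices(start_age, subgroup, params, curves)
    init = np.zeros(N_STATES)
    start = S["MON1"] if subgroup.surveillance == MAMMO_MRI else S["MON2"]
    init[start] = 1.0
    return run_markov(M, init, start_age=start_age)


def accrue_trace(trace: CohortTrace, state_costs: np.ndarray,
                 state_utilities: np.ndarray, flow_costs: np.ndarray,
                 flow_disutilities: np.ndarray | None,
                 discount_rate: float) -> tuple[float, float, float]:
    """Generic end-of-cycle accrual: returns (disc_cost, disc_qaly, disc_ly).

    ``state_costs``/``state_utilities`` may be (n,) or per-cycle (T, n);
    ``flow_costs``/``flow_disutilities`` may be (n, n) or (T, n, n).
    Life-years count every alive state at weight 1.
    """
    T = trace.n_cycles
    occ = trace.occupancy[:T]
    df = epi.discount_factor(np.arange(1, T + 1), discount_rate)

    sc = np.broadcast_to(np.asarray(state_costs, float),
                         (T, occ.shape[1]) if np.ndim(state_costs) == 1
                         else np.shape(state_costs))
    su = np.broadcast_to(np.asarray(state_utilities, float),
                         (T, occ.shape[1]) if np.ndim(state_utilities) == 1
                         else np.shape(state_utilities))
    cost = float(np.einsum("t,ts,ts->", df, occ, sc))
    qaly = float(np.einsum("t,ts,ts->", df, occ, su))

    fc = np.asarray(flow_costs, float)
    if fc.ndim == 2:
        fc = np.broadcast_to(fc, trace.flows.shape)
    cost += float(np.einsum("t,tij,tij->", df, trace.flows, fc))
    if flow_disutilities is not None:
        fd = np.asarray(flow_disutilities, float)
        if fd.ndim == 2:
            fd = np.broadcast_to(fd, trace.flows.shape)
        qaly -= float(np.einsum("t,tij,tij->", df, trace.flows, fd))

    alive = np.ones(occ.shape[1])
    alive[-1] = 0.0  # by convention the last state is absorbing death
    ly = float(np.einsum("t,ts,s->", df, occ, alive))
    return cost, qaly, ly


def accrue_outcomes(trace: CohortTrace, params: ParameterSet,
                    subgroup: Subgroup) -> OutcomeBundle:
    """Discounted costs/QALYs/life-years and undiscounted case counts for
    one subgroup trace, per unit of starting mass."""
    T = trace.n_cycles
    ages = np.arange(trace.start_age, trace.start_age + T)
    old = ages >= 65

    u = np.ones(N_STATES)
    u[S["BC_E1"]] = u[S["BC_L1"]] = params["utility.bc"]
    u[S["OC_E1"]] = u[S["OC_L1"]] = params["utility.oc"]
    u[S["POST_BC_E"]] = u[S["POST_BC_L"]] = params["utility.post_bc"]
    u[S["POST_OC_E"]] = u[S["POST_OC_L"]] = params["utility.post_oc"]
    u[S["RRM1"]] = 1.0 - params["disutility.mastectomy"]
    u[S["RRSO1"]] = 1.0 - params["disutility.oophorectomy"]
    u[S["DEAD"]] = 0.0

    sc = np.zeros((T, N_STATES))
    mammo = params["cost.mammography"]
    mri = params["cost.mri"]
    sc[:, S["MON1"]] = mammo + mri
    sc[:, S["MON2"]] = mammo
    # after oophorectomy alone, breast surveillance continues
    sc[:, S["POST_RRSO"]] = mammo + (
        mri if subgroup.surveillance == MAMMO_MRI else 0.0)
    sc[:, S["RRM1"]] = params["cost.mastectomy"]
    sc[:, S["RRSO1"]] = params["cost.oophorectomy"]

    def banded(young_key: str, old_key: str) -> np.ndarray:
        return np.where(old, params[old_key], params[young_key])

    bc_init = banded("cost.bc_initial_lt65", "cost.bc_initial_ge65")
    bc_cont = banded("cost.bc_continuing_lt65", "cost.bc_continuing_ge65")
    bc_last = banded("cost.bc_lastyear_lt65", "cost.bc_lastyear_ge65")
    oc_init = banded("cost.oc_initial_lt65", "cost.oc_initial_ge65")
    oc_cont = banded("cost.oc_continuing_lt65", "cost.oc_continuing_ge65")
    oc_last = banded("cost.oc_lastyear_lt65", "cost.oc_lastyear_ge65")
    sc[:, S["BC_E1"]] = sc[:, S["BC_L1"]] = bc_init
    sc[:, S["OC_E1"]] = sc[:, S["OC_L1"]] = oc_init
    sc[:, S["POST_BC_E"]] = sc[:, S["POST_BC_L"]] = bc_cont
    sc[:, S["POST_OC_E"]] = sc[:, S["POST_OC_L"]] = oc_cont

    fc = np.zeros((T, N_STATES, N_STATES))
    for s_ in _BC_STATES:
        fc[:, s_, S["DEAD"]] = bc_last   # palliative care in the last year
    for s_ in _OC_STATES:
        fc[:, s_, S["DEAD"]] = oc_last
    # second surgery, charged on the flow into the combined post state
    fc[:, S["POST_RRM"], S["POST_RRM_RRSO"]] = params["cost.oophorectomy"]
    fc[:, S["POST_RRSO"], S["POST_RRM_RRSO"]] = params["cost.mastectomy"]

    fd = np.zeros((N_STATES, N_STATES))
    fd[S["POST_RRM"], S["POST_RRM_RRSO"]] = params["disutility.oophorectomy"]
    fd[S["POST_RRSO"], S["POST_RRM_RRSO"]] = params["disutility.mastectomy"]

    cost, qaly, ly = accrue_trace(trace, sc, u, fc, fd, params.discount_rate)
    return OutcomeBundle(
        cost=cost, qaly=qaly, ly=ly,
        cases_early=float(trace.incident_early.sum()),
        cases_late=float(trace.incident_late.sum()),
        deaths_cancer=float(trace.cancer_deaths.sum()),
    )


def subgroup_outcomes(start_age: int, subgroup: Subgroup,
                      params: ParameterSet, curves: dict) -> OutcomeBundle:
    """Outcomes per unit mass for one subgroup entering at ``start_age``."""
    trace = run_cohort(start_age, subgroup, params, curves)
    return accrue_outcomes(trace, params, subgroup)
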