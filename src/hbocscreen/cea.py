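"""Incremental cost-effectiveness computation and scenario adjustments.

The incremental cost-effectiveness ratio (ICER) is the difference in
lifetime discounted cost between the two strategies divided by the
difference in discounted QALYs.  Dominance is handled explicitly: a
strategy that is no more expensive and strictly better is "dominant"; one
that loses QALYs at nonnegative extra cost is "dominated".  When both
differences are negative the ratio is still returned (savings per QALY
forgone, the southwest quadrant) and callers should interpret it from the
signs of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .markov import OutcomeBundle
from .parameters import ParameterSet

__all__ = ["DOMINANT", "DOMINATED", "EQUIVALENT", "compute_icer",
           "CEResult", "summarize_per_100k", "apply_harm_scenario",
           "harm_decrement_per_woman"]

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"


def compute_icer(delta_cost: float, delta_qaly: float):
    """ICER in USD per QALY, or a dominance flag.

    Returns a float when a ratio is defined (including the southwest
    quadrant, where both differences are negative), otherwise one of the
    string flags ``dominant``, ``dominated`` or ``equivalent``.  Zero QALY
    gain at positive cost counts as dominated by convention.
    """
    if not (abs(delta_cost) < float("inf") and abs(delta_qaly) < float("inf")):
        raise ValueError("incremental outcomes must be finite")
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return EQUIVALENT
    if delta_qaly > 0.0:
        return delta_cost / delta_qaly if delta_cost > 0.0 else DOMINANT
    if delta_qaly == 0.0:
        return DOMINANT if delta_cost < 0.0 else DOMINATED
    # delta_qaly < 0
    return delta_cost / delta_qaly if delta_cost < 0.0 else DOMINATED


@dataclass
class CEResult:
    """Two-arm comparison on a common cohort.

    ``screen`` and ``comparator`` are per-woman outcome bundles (the
    screening arm already including any cascade increment and scenario
    adjustment); per-cohort and per-100 000 views are derived.
    """

    screen: OutcomeBundle
    comparator: OutcomeBundle
    cohort_size: float = 100_000.0
    scenario: str = "base"

    # -- incrementals, per woman -----------------------------------------
    @property
    def d_cost(self) -> float:
        return self.screen.cost - self.comparator.cost

    @property
    def d_qaly(self) -> float:
        return self.screen.qaly - self.comparator.qaly

    @property
    def d_ly(self) -> float:
        return self.screen.ly - self.comparator.ly

    @property
    def icer(self):
        return compute_icer(self.d_cost, self.d_qaly)

    def per_100k(self, field: str) -> float:
        """Incremental quantity scaled to a 100 000-woman cohort."""
        d = getattr(self.screen, field) - getattr(self.comparator, field)
        return d * 100_000.0

    def cases_per_100k(self, arm: str) -> dict[str, float]:
        b = self.screen if arm == "screen" else self.comparator
        return {"early": b.cases_early * 100_000.0,
                "late": b.cases_late * 100_000.0,
                "total": b.cases_total * 100_000.0}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, b in (("population_screening", self.screen),
                         ("family_history", self.comparator)):
            rows.append({
                "strategy": label,
                "cases_early_per_100k": b.cases_early * 1e5,
                "cases_late_per_100k": b.cases_late * 1e5,
                "cases_total_per_100k": b.cases_total * 1e5,
                "cost_per_woman": b.cost,
                "qaly_per_woman": b.qaly,
                "ly_per_woman": b.ly,
            })
        icer = self.icer
        rows.append({
            "strategy": "incremental",
            "cases_early_per_100k": self.per_100k("cases_early"),
            "cases_late_per_100k": self.per_100k("cases_late"),
            "cases_total_per_100k": self.per_100k("cases_early")
            + self.per_100k("cases_late"),
            "cost_per_woman": self.d_cost,
            "qaly_per_woman": self.d_qaly,
            "ly_per_woman": self.d_ly,
            "icer": icer if isinstance(icer, float) else icer,
        })
        return pd.DataFrame(rows).set_index("strategy")


def summarize_per_100k(screen: OutcomeBundle, comparator: OutcomeBundle,
                       cohort_size: float = 100_000.0,
                       scenario: str = "base") -> CEResult:
    """Package two per-woman arm bundles into a :class:`CEResult`."""
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    return CEResult(screen=screen, comparator=comparator,
                    cohort_size=float(cohort_size), scenario=scenario)


def harm_decrement_per_woman(params: ParameterSet,
                             screen_disc_ly: float | None = None) -> float:
    """Expected QALY loss per woman in the screening arm from noncarriers
    reducing mammography adherence after a negative result.

    One-time reading (default): participation x (1 - prevalence) x affected
    fraction x disutility.  The lifetime-annual reading multiplies the same
    product by the screening arm's discounted life expectancy and requires
    ``screen_disc_ly``.
    """
    base = ((1.0 - params["avoid_screening"])
            * (1.0 - params["carrier_prevalence"])
            * params["harm_affected_fraction"]
            * params["disutility.noncarrier_harm"])
    mode = params.settings.get("harm_mode", "one_time")
    if mode == "one_time":
        return base
    if mode == "lifetime_annual":
        if screen_disc_ly is None:
            raise ValueError("lifetime_annual harm needs the screening arm's "
                             "discounted life-years")
        return base * screen_disc_ly
    raise ValueError(f"unknown harm mode {mode!r}")


def apply_harm_scenario(result: CEResult, params: ParameterSet) -> CEResult:
    """Return a copy of ``result`` with the noncarrier-harm QALY decrement
    subtracted from the screening arm (ICER and incrementals re-derive)."""
    dec = harm_decrement_per_woman(params, screen_disc_ly=result.screen.ly)
    screen = replace(result.screen, qaly=result.screen.qaly - dec)
    return CEResult(screen=screen, comparator=result.comparator,
                    cohort_size=result.cohort_size, scenario="harm")
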