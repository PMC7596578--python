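"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis moves a single parameter to its low and then its high
bound, holding everything else fixed, and records the ICER at each.  The
probabilistic analysis draws every non-fixed parameter from its assigned
distribution, re-runs the whole pipeline per draw, and summarizes the
incremental outcomes as 95% credible ranges (2.5th-97.5th percentiles) and
cost-effectiveness acceptability curves (CEACs).

Reproducibility: each PSA draw uses its own substream seeded by
``(seed, draw_index)``, so a run of n draws reproduces the first half of a
run of 2n draws exactly, independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PopulationScreeningModel
from .parameters import ParameterSet, draw_psa_sample, perturb_one_way

__all__ = ["DEFAULT_WTP_GRID", "model_runner", "run_one_way", "PSAResult",
           "run_psa", "compute_ceac"]

# willingness-to-pay thresholds of primary interest, plus a fine grid for
# plotting the acceptability curve
DEFAULT_WTP_GRID = (50_000.0, 100_000.0, 150_000.0)


def model_runner(curves: dict | None = None, age: int = 30,
                 cohort_size: float = 100_000.0, include_cascade: bool = True,
                 scenario: str = "base"):
    """A model-runner closure for sensitivity analyses: maps a
    ``ParameterSet`` to the incremental outcome record of one full
    evaluation (screening vs family history)."""
    def run(params: ParameterSet) -> dict[str, float]:
        res = PopulationScreeningModel(
            params=params, curves=curves, age=age, cohort_size=cohort_size,
            include_cascade=include_cascade).run(scenario)
        c = res.cea
        return {
            "d_cost": c.d_cost,
            "d_qaly": c.d_qaly,
            "d_ly": c.d_ly,
            "d_cases_early": c.per_100k("cases_early"),
            "d_cases_late": c.per_100k("cases_late"),
            "d_cases_total": (c.per_100k("cases_early")
                              + c.per_100k("cases_late")),
        }
    return run


def _icer_value(rec: dict[str, float]) -> float:
    """Numeric ICER for tornado ordering; infinite when QALYs are tied."""
    if rec["d_qaly"] == 0.0:
        return np.inf if rec["d_cost"] > 0 else -np.inf
    return rec["d_cost"] / rec["d_qaly"]


def run_one_way(params: ParameterSet, param_ids, runner) -> pd.DataFrame:
    """Tornado table: ICER with each parameter at its low and high bound.

    Rows are sorted by bar width |icer_high - icer_low|, widest first.
    Parameters with degenerate bounds produce zero-width bars.
    """
    rows = []
    for name in param_ids:
        if name not in params.values:
            raise KeyError(f"unknown parameter id {name!r}")
        lo = runner(perturb_one_way(params, name, "low"))
        hi = runner(perturb_one_way(params, name, "high"))
        icer_lo, icer_hi = _icer_value(lo), _icer_value(hi)
        rows.append({
            "parameter": name,
            "icer_low": icer_lo,
            "icer_high": icer_hi,
            "width": abs(icer_hi - icer_lo),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    return table.sort_values("width", ascending=False)


@dataclass
class PSAResult:
    """Per-draw incremental outcomes of a probabilistic sensitivity run."""

    draws: pd.DataFrame
    seed: int
    n_requested: int
    failed_draws: list[int] = field(default_factory=list)
    wtp_grid: tuple = DEFAULT_WTP_GRID

    @property
    def n_effective(self) -> int:
        return len(self.draws)

    def credible_range(self, column: str) -> tuple[float, float]:
        """95% credible range (2.5th-97.5th percentile) of one output."""
        v = self.draws[column].to_numpy()
        lo, hi = np.percentile(v, [2.5, 97.5])
        return float(lo), float(hi)

    def credible_ranges(self) -> pd.DataFrame:
        rows = {c: self.credible_range(c) for c in self.draws.columns}
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def ceac(self, wtp_grid=None) -> pd.Series:
        grid = self.wtp_grid if wtp_grid is None else wtp_grid
        return compute_ceac(self.draws, grid)


def run_psa(params: ParameterSet, n: int, seed: int, runner,
            wtp_grid=DEFAULT_WTP_GRID) -> PSAResult:
    """``n`` joint parameter draws, each evaluated through ``runner``.

    A draw on which the model raises is recorded in ``failed_draws`` and
    excluded from the summaries (never silently dropped).  Deterministic
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    records = []
    failed: list[int] = []
    for i in range(n):
        rng = np.random.default_rng([int(seed), i])
        try:
            sample = draw_psa_sample(params, rng)
            records.append(runner(sample))
        except Exception:
            failed.append(i)
    draws = pd.DataFrame.from_records(records)
    return PSAResult(draws=draws, seed=int(seed), n_requested=n,
                     failed_draws=failed, wtp_grid=tuple(wtp_grid))


def compute_ceac(draws: pd.DataFrame, wtp_grid) -> pd.Series:
    """Cost-effectiveness acceptability curve: at each willingness-to-pay
    lambda, the fraction of draws with nonnegative incremental net monetary
    benefit, lambda * dQALY - dCost."""
    if len(draws) == 0:
        raise ValueError("no draws to summarize")
    dq = draws["d_qaly"].to_numpy()
    dc = draws["d_cost"].to_numpy()
    grid = np.asarray(list(wtp_grid), dtype=float)
    if np.any(grid < 0):
        raise ValueError("willingness-to-pay must be nonnegative")
    probs = [(lam * dq - dc >= 0.0).mean() for lam in grid]
    return pd.Series(probs, index=grid, name="p_cost_effective")
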