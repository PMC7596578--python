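"""Synthetic stand-ins for externally sourced inputs.

The analysis consumes several age-indexed curves that come from cited
external cohorts and registries: gene-specific cumulative cancer incidence,
cumulative risk-reducing-surgery uptake among identified carriers, a
background life table, and general-population cancer incidence.  None of
these are tabulated in machine-readable form, so this module generates
structurally faithful synthetic versions: monotone nondecreasing cumulative
curves on ages 20-100 bounded in [0, 1], with most surgical uptake before
age 50 and most cancer incidence after age 50, plus a parametric
(Gompertz-Makeham) adult life table.

The default levels below are plausibility-scaled placeholders, NOT
published values; reproducing any published cost-effectiveness estimate
requires supplying curves digitized from the original sources via
``CurveTable.read_csv``.  Generation is deterministic (no RNG) so written
fixtures are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epi import CurveTable, LifeTable

__all__ = [
    "CurveSpec",
    "make_life_table",
    "make_cumulative_curve",
    "default_curves",
    "write_curves",
    "load_curves",
    "make_toy_model",
    "ToyModel",
]

AGE_MIN, AGE_MAX = 20, 100


@dataclass(frozen=True)
class CurveSpec:
    """Shape specification for a synthetic cumulative curve.

    ``lifetime_level`` is the target cumulative value at age 80;
    ``midpoint`` is the age at which half that level is reached and
    ``steepness`` the logistic slope per year.
    """

    kind: str  # "incidence" | "uptake"
    lifetime_level: float
    midpoint: float
    steepness: float
    age_min: int = AGE_MIN
    age_max: int = AGE_MAX

    def __post_init__(self) -> None:
        if self.kind not in {"incidence", "uptake"}:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if not 0.0 <= self.lifetime_level <= 1.0:
            raise ValueError("lifetime_level must lie in [0, 1]")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


def make_life_table(makeham: float = 4e-4, gompertz_b: float = 2.5e-5,
                    gompertz_g: float = 0.095, age_min: int = AGE_MIN,
                    age_max: int = AGE_MAX) -> LifeTable:
    """Parametric adult life table, qx(a) = 1 - exp(-(c + b * e^(g*a))).

    Default hazard constants give a remaining life expectancy in the low
    fifties at age 30, in line with a contemporary high-income female
    population.  The terminal age carries qx = 1 so traces always close.
    """
    if makeham < 0 or gompertz_b < 0:
        raise ValueError("hazard parameters must be nonnegative")
    ages = np.arange(age_min, age_max + 1)
    hazard = makeham + gompertz_b * np.exp(gompertz_g * ages)
    qx = 1.0 - np.exp(-hazard)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def make_cumulative_curve(spec: CurveSpec) -> CurveTable:
    """Logistic-shaped cumulative curve: zero at the start age, reaching
    ``lifetime_level`` at age 80, half of it at the midpoint age."""
    ages = np.arange(spec.age_min, spec.age_max + 1)
    s = 1.0 / (1.0 + np.exp(-spec.steepness * (ages - spec.midpoint)))
    s0 = 1.0 / (1.0 + np.exp(-spec.steepness * (spec.age_min - spec.midpoint)))
    s80 = 1.0 / (1.0 + np.exp(-spec.steepness * (80 - spec.midpoint)))
    if s80 - s0 <= 0:
        values = np.zeros_like(ages, dtype=float)
    else:
        values = spec.lifetime_level * (s - s0) / (s80 - s0)
    values = np.clip(values, 0.0, 1.0 - 1e-9)
    values = np.maximum.accumulate(values)
    return CurveTable(ages, values)


# Placeholder curve shapes (NOT published values): carrier cancer incidence
# concentrated after age 50, surgical uptake concentrated before age 50,
# lifetime levels of the magnitude reported for high-penetrance carriers
# and for the general female population.
DEFAULT_CURVE_SPECS: dict[str, CurveSpec] = {
    "bc_BRCA1": CurveSpec("incidence", 0.72, 50.0, 0.10),
    "bc_BRCA2": CurveSpec("incidence", 0.69, 52.0, 0.10),
    "oc_BRCA1": CurveSpec("incidence", 0.44, 55.0, 0.11),
    "oc_BRCA2": CurveSpec("incidence", 0.17, 60.0, 0.11),
    "bc_pop": CurveSpec("incidence", 0.12, 62.0, 0.09),
    "oc_pop": CurveSpec("incidence", 0.013, 63.0, 0.09),
    "uptake_rrm": CurveSpec("uptake", 0.45, 38.0, 0.15),
    "uptake_rrso": CurveSpec("uptake", 0.75, 44.0, 0.15),
}


def default_curves() -> dict:
    """The full packaged input bundle: synthetic curves plus life table.

    Keys: per-gene/per-population cumulative incidence (``bc_*``/``oc_*``),
    cumulative BRCA surgical uptake (``uptake_rrm``/``uptake_rrso``) and the
    background ``life_table``.
    """
    curves = {name: make_cumulative_curve(spec)
              for name, spec in DEFAULT_CURVE_SPECS.items()}
    curves["life_table"] = make_life_table()
    return curves


CURVE_NAMES = tuple(DEFAULT_CURVE_SPECS)


def write_curves(directory, curves: dict | None = None) -> None:
    """Write a curve bundle as one ``age,value`` CSV per curve plus an
    ``age,qx`` life table, the formats the loaders read back."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    curves = curves if curves is not None else default_curves()
    for name in CURVE_NAMES:
        curves[name].write_csv(directory / f"{name}.csv")
    curves["life_table"].write_csv(directory / "life_table.csv")


def load_curves(directory) -> dict:
    """Load a curve bundle written by :func:`write_curves` (or digitized
    from published sources in the same layout)."""
    from pathlib import Path
    directory = Path(directory)
    curves = {name: CurveTable.read_csv(directory / f"{name}.csv")
              for name in CURVE_NAMES}
    curves["life_table"] = LifeTable.read_csv(directory / "life_table.csv")
    return curves


# ---------------------------------------------------------------------------
# frozen toy model (well -> cancer -> dead) for engine-oracle tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModel:
    """Frozen three-state chain with hand-set annual probabilities.

    Used as a small, fully known configuration: the cohort engine's
    discounted outcomes on it can be checked against closed forms and
    against an independent individual-level microsimulation.
    """

    states: tuple = ("well", "cancer", "dead")
    p_well_cancer: float = 0.02
    p_well_dead: float = 0.01
    p_cancer_dead: float = 0.15
    utility_well: float = 1.0
    utility_cancer: float = 0.65
    cost_well: float = 100.0
    cost_cancer: float = 20_000.0
    cost_onset: float = 50_000.0       # one-time, on the well -> cancer flow
    cost_palliative: float = 60_000.0  # one-time, on the cancer -> dead flow
    discount_rate: float = 0.03
    horizon: int = 60

    def transition_matrix(self) -> np.ndarray:
        m = np.array([
            [1.0 - self.p_well_cancer - self.p_well_dead,
             self.p_well_cancer, self.p_well_dead],
            [0.0, 1.0 - self.p_cancer_dead, self.p_cancer_dead],
            [0.0, 0.0, 1.0],
        ])
        return m

    def matrices(self) -> np.ndarray:
        return np.broadcast_to(self.transition_matrix(),
                               (self.horizon, 3, 3)).copy()

    def state_utilities(self) -> np.ndarray:
        return np.array([self.utility_well, self.utility_cancer, 0.0])

    def state_costs(self) -> np.ndarray:
        return np.array([self.cost_well, self.cost_cancer, 0.0])

    def flow_costs(self) -> np.ndarray:
        fc = np.zeros((3, 3))
        fc[0, 1] = self.cost_onset
        fc[1, 2] = self.cost_palliative
        return fc


def make_toy_model() -> ToyModel:
    """The frozen small configuration used by oracle and tornado tests."""
    return ToyModel()
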