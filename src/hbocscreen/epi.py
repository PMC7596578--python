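"""Epidemiological transforms between cumulative curves, rates and per-cycle probabilities.

The cohort engine advances in one-year cycles, so every input expressed as a
lifetime cumulative quantity (cancer incidence, surgical uptake) or as a
multi-year summary (5-year relative mortality) has to be converted to an
annual transition probability first.  Hazard ratios act on the rate scale,
odds ratios on the odds scale; both are exact, not rare-disease
approximations, so results stay in [0, 1) even for large effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurveTable",
    "LifeTable",
    "annual_prob_from_cumulative",
    "prob_to_rate",
    "rate_to_prob",
    "apply_hazard_ratio",
    "apply_odds_ratio",
    "annual_excess_mortality",
    "discount_factor",
    "annual_uptake_prob",
]


@dataclass(frozen=True)
class CurveTable:
    """Age-indexed cumulative curve F(a) on a contiguous integer-age grid.

    ``values[i]`` is the cumulative probability (incidence) or cumulative
    uptake at ``ages[i]``.  Values must be nondecreasing and lie in [0, 1].
    """

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.ndim != 1 or ages.size < 2:
            raise ValueError("curve needs at least two ages")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous integers with step 1")
        if values.shape != ages.shape:
            raise ValueError("ages and values must have equal length")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValueError("curve values must lie in [0, 1]")
        if np.any(np.diff(values) < -1e-12):
            raise ValueError("curve values must be nondecreasing in age")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def at(self, age) -> np.ndarray:
        """F(age); ``age`` may be scalar or array, must be on the grid."""
        idx = np.asarray(age, dtype=int) - self.min_age
        if np.any(idx < 0) or np.any(idx >= self.ages.size):
            raise ValueError(f"age {age} outside curve range "
                             f"[{self.min_age}, {self.max_age}]")
        return self.values[idx]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CurveTable":
        """Build from a two-column frame (``age``, ``value``), linearly
        interpolating onto the integer-age grid if the input is coarser."""
        df = df.sort_values("age")
        lo, hi = int(np.floor(df["age"].iloc[0])), int(np.ceil(df["age"].iloc[-1]))
        grid = np.arange(lo, hi + 1)
        vals = np.interp(grid, df["age"].to_numpy(float), df["value"].to_numpy(float))
        return cls(grid, vals)

    @classmethod
    def read_csv(cls, path) -> "CurveTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "value": self.values})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities qx on an integer-age grid.

    The terminal age must carry qx = 1 so cohort traces always close.
    """

    ages: np.ndarray
    qx: np.ndarray
    _surv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous integers with step 1")
        if np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("qx must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("terminal age must have qx = 1")
        # survival from the table's first age to each age (S(min_age) = 1)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
        object.__setattr__(self, "_surv", surv)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def qx_at(self, age) -> np.ndarray:
        idx = np.asarray(age, dtype=int) - self.min_age
        if np.any(idx < 0) or np.any(idx >= self.ages.size):
            raise ValueError(f"age {age} outside life table range")
        return self.qx[idx]

    def survival_to(self, age) -> float:
        """Probability of surviving from the table's first age to ``age``.

        Ages below the table start are treated as certain survival (the
        table covers adult ages only); ages past the end return 0.
        """
        age = int(age)
        if age <= self.min_age:
            return 1.0
        if age > self.max_age:
            return 0.0
        return float(self._surv[age - self.min_age])

    def life_expectancy(self, from_age: int) -> float:
        """Remaining life expectancy in whole-year cycles, under the cohort
        engine's accounting: a person contributes one year for every cycle
        entered alive (deaths happen at cycle end), so the expectation is
        sum over t >= 0 of survival to the start of cycle t."""
        i = int(from_age) - self.min_age
        surv = np.cumprod(1.0 - self.qx[i:])
        return float(1.0 + surv[:-1].sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(int), df["qx"].to_numpy(float))

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def annual_prob_from_cumulative(curve: CurveTable, age) -> np.ndarray:
    """Conditional one-year event probability at ``age`` among those still
    event-free: (F(a+1) - F(a)) / (1 - F(a)).

    Raises if the curve has already saturated (F(a) = 1), since the
    conditional probability is undefined for an exhausted risk pool.
    """
    f0 = curve.at(age)
    f1 = curve.at(np.asarray(age) + 1)
    if np.any(f0 >= 1.0):
        raise ValueError("cumulative curve reaches 1 at requested age; "
                         "conditional probability undefined")
    p = (f1 - f0) / (1.0 - f0)
    return np.clip(p, 0.0, 1.0)


def prob_to_rate(p):
    """Constant hazard over one year equivalent to probability ``p``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("probability must lie in [0, 1) for rate conversion")
    return -np.log1p(-p)


def rate_to_prob(rate):
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be nonnegative")
    return -np.expm1(-rate)


def apply_hazard_ratio(p, hr):
    """Scale an annual probability by a hazard ratio on the rate scale:
    1 - (1-p)^hr.  hr=0 removes all risk; hr=1 is the identity."""
    p = np.asarray(p, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(hr < 0):
        raise ValueError("hazard ratio must be nonnegative")
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("probability must lie in [0, 1)")
    return 1.0 - np.power(1.0 - p, hr)


def apply_odds_ratio(p0, or_val):
    """Adjust a baseline annual probability by an odds ratio, exactly:
    odds' = OR * p0/(1-p0); p' = odds'/(1+odds').  Stays in [0, 1) for any
    finite OR, which matters for the large ovarian-cancer odds ratios."""
    p0 = np.asarray(p0, dtype=float)
    or_val = np.asarray(or_val, dtype=float)
    if np.any(or_val <= 0):
        raise ValueError("odds ratio must be positive")
    if np.any(p0 < 0) or np.any(p0 >= 1):
        raise ValueError("baseline probability must lie in [0, 1)")
    odds = or_val * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def annual_excess_mortality(five_yr_rel_mortality):
    """Constant annual cancer-specific excess death probability whose
    five-year compound equals the given 5-year relative mortality:
    1 - (1 - m5)^(1/5)."""
    m5 = np.asarray(five_yr_rel_mortality, dtype=float)
    if np.any(m5 < 0) or np.any(m5 >= 1):
        raise ValueError("5-year relative mortality must lie in [0, 1)")
    return 1.0 - np.power(1.0 - m5, 0.2)


def discount_factor(year, rate: float):
    """(1 + rate)^(-year); year 0 is undiscounted."""
    year = np.asarray(year, dtype=float)
    if np.any(year < 0) or rate < 0:
        raise ValueError("year and rate must be nonnegative")
    return np.power(1.0 + rate, -year)


def annual_uptake_prob(curve: CurveTable, age, rate_ratio: float = 1.0):
    """Conditional annual surgical-uptake probability from a cumulative
    uptake curve, rate-scaled by ``rate_ratio`` (used to derive non-BRCA
    uptake from the BRCA curves)."""
    if rate_ratio < 0:
        raise ValueError("rate ratio must be nonnegative")
    p = annual_prob_from_cumulative(curve, age)
    return apply_hazard_ratio(p, rate_ratio)
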