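"""Model parameters: loading, validation, one-way perturbation and PSA sampling.

Every parameter carries its base value, its low/high range and a
distribution family (beta, dirichlet, log_normal, normal, or fixed).  The
packaged ``table1_base.yaml`` stores values on their printed scale (the
overall carrier prevalence is printed as a percent, 0.495, everything else
as proportions, dollars or ratios); conversion to model scale happens at
load so the config stays diff-able against its sources.

Sampling conventions
--------------------
* beta: moment-matched to mean = base, sd = (high - low) / (2 * 1.96); the
  variance is capped so both shape parameters stay >= 1, which only binds
  for near-boundary parameters such as test specificity.
* normal: mean = base, sd = (high - low) / (2 * 1.96); draws for
  proportions are clipped to [0, 1] and costs to >= 0.
* log_normal: parameterized so the 2.5th/97.5th percentiles reproduce the
  printed 95% interval exactly (mu = midpoint of the log interval,
  sigma = log-width / (2 * 1.96)); proportion-like draws are clipped below 1.
* dirichlet: the eight gene proportions are drawn jointly with
  concentration = base proportions x ``dirichlet_concentration`` (default 100).
* fixed: never sampled (hazard ratios printed as exactly 0 stay 0).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GENES",
    "NONBRCA_GENES",
    "DistributionSpec",
    "ParameterSet",
    "load_parameter_set",
    "base_parameter_set",
    "perturb_one_way",
    "draw_psa_sample",
]

GENES = ("BRCA1", "BRCA2", "ATM", "CHEK2", "MSH6", "PALB2", "RAD51C", "TP53")
NONBRCA_GENES = ("ATM", "CHEK2", "MSH6", "PALB2", "RAD51C", "TP53")

_FAMILIES = {"beta", "dirichlet", "log_normal", "normal", "fixed"}
_KINDS = {"proportion", "ratio", "cost", "rate"}

_Z95 = 2.0 * 1.959963984540054  # full width of a 95% normal interval, in sd


class ParameterError(ValueError):
    """Raised on schema or invariant violations in a parameter set."""


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty specification for one parameter."""

    family: str
    base: float
    low: float
    high: float
    kind: str = "ratio"
    block: str | None = None  # joint-sampling block (dirichlet)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown parameter kind {self.kind!r}")
        if not (self.low <= self.base <= self.high):
            raise ParameterError(
                f"bounds must satisfy low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})")
        if self.family == "fixed" and not (self.low == self.base == self.high):
            raise ParameterError("fixed family requires low = base = high")
        if self.family in {"beta", "dirichlet"} and not (
                0.0 <= self.low and self.high <= 1.0):
            raise ParameterError(
                f"{self.family} family values must lie in [0, 1]")
        if self.family == "log_normal" and self.low <= 0:
            raise ParameterError("log_normal requires positive bounds")


@dataclass
class ParameterSet:
    """A complete, validated set of model inputs.

    ``values`` maps flat dotted parameter ids (e.g. ``cost.assay``,
    ``gene_proportion.BRCA1``) to model-scale numbers; ``specs`` carries the
    matching :class:`DistributionSpec`; ``settings`` holds structural
    assumptions that are never sampled (stage policy, cascade family
    structure, engine switches).
    """

    values: dict[str, float]
    specs: dict[str, DistributionSpec]
    settings: dict = field(default_factory=dict)

    # -- dict-like access -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"unknown parameter id {name!r}") from None

    def group(self, prefix: str) -> dict[str, float]:
        """All parameters under ``prefix.`` keyed by their suffix."""
        pre = prefix + "."
        out = {k[len(pre):]: v for k, v in self.values.items()
               if k.startswith(pre)}
        if not out:
            raise ParameterError(f"no parameters under prefix {prefix!r}")
        return out

    # -- structured views used by the engine ------------------------------
    @property
    def carrier_prevalence(self) -> float:
        return self["carrier_prevalence"]

    @property
    def gene_proportions(self) -> dict[str, float]:
        return {g: self[f"gene_proportion.{g}"] for g in GENES}

    @property
    def discount_rate(self) -> float:
        return self["discount_rate"]

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.specs),
                            copy.deepcopy(self.settings))

    # -- validation --------------------------------------------------------
    def validate(self) -> "ParameterSet":
        for name, spec in self.specs.items():
            v = self.values[name]
            if spec.kind == "proportion" and not (0.0 <= v <= 1.0):
                raise ParameterError(
                    f"{name} = {v} outside [0, 1] for a proportion")
            if spec.kind == "cost" and v < 0:
                raise ParameterError(f"{name} = {v}: costs must be >= 0")
            if spec.kind in {"ratio", "rate"} and v < 0:
                raise ParameterError(f"{name} = {v}: must be >= 0")
        props = {k: v for k, v in self.values.items()
                 if k.startswith("gene_proportion.")}
        if props:
            s = sum(props.values())
            if abs(s - 1.0) > 1e-9:
                raise ParameterError(
                    f"gene proportions sum to {s}, expected 1 within 1e-9")
        return self

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (self.values == other.values and self.specs == other.specs
                and self.settings == other.settings)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_REQUIRED_SETTINGS = {
    "dirichlet_concentration": 100.0,
    "stage_policy": {"p_early_mammo_mri": 0.8, "p_early_mammo": 0.5,
                     "p_early_undetected_carrier": 0.5},
    "cascade": {"n_sisters": 1.0, "n_daughters": 1.0, "maternal_gap": 27},
    "excess_mortality_persists": True,
    "early_stage_reduction_as_multiplier": False,
    "harm_mode": "one_time",
}


def load_parameter_set(source) -> ParameterSet:
    """Load and validate a parameter set from a YAML config.

    ``source`` may be a path, an open file, or a YAML string.  Percent-scaled
    entries (``unit: percent``) are divided by 100; everything else is taken
    at face value.  Raises :class:`ParameterError` naming the offending field
    on any schema or invariant violation.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" in text or text.lstrip().startswith(("schema_version", "{")):
            doc = yaml.safe_load(text)
        else:
            with open(text) as fh:
                doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ParameterError("config must be a mapping with a 'parameters' block")

    values: dict[str, float] = {}
    specs: dict[str, DistributionSpec] = {}
    for name, row in doc["parameters"].items():
        if not isinstance(row, dict):
            raise ParameterError(f"parameter {name!r} must be a mapping")
        for key in ("value", "dist", "kind"):
            if key not in row:
                raise ParameterError(f"parameter {name!r} missing field {key!r}")
        scale = 0.01 if row.get("unit") == "percent" else 1.0
        base = float(row["value"]) * scale
        low = float(row.get("low", row["value"])) * scale
        high = float(row.get("high", row["value"])) * scale
        try:
            spec = DistributionSpec(family=row["dist"], base=base, low=low,
                                    high=high, kind=row["kind"],
                                    block=row.get("block"))
        except ParameterError as err:
            raise ParameterError(f"parameter {name!r}: {err}") from None
        values[name] = base
        specs[name] = spec

    settings = copy.deepcopy(_REQUIRED_SETTINGS)
    for key, val in (doc.get("settings") or {}).items():
        if isinstance(val, dict) and isinstance(settings.get(key), dict):
            settings[key].update(val)
        else:
            settings[key] = val

    return ParameterSet(values, specs, settings).validate()


def base_parameter_set() -> ParameterSet:
    """The packaged base-case parameter set."""
    ref = importlib.resources.files("hbocscreen.data") / "table1_base.yaml"
    return load_parameter_set(ref.read_text())


# ---------------------------------------------------------------------------
# one-way perturbation
# ---------------------------------------------------------------------------

def perturb_one_way(params: ParameterSet, name: str, bound: str) -> ParameterSet:
    """Return a copy of ``params`` with one parameter set to its low or high
    bound, all others untouched.  For a member of a jointly-constrained
    dirichlet block the remaining members are rescaled so the block still
    sums to 1."""
    if bound not in {"low", "high"}:
        raise ParameterError(f"bound must be 'low' or 'high', got {bound!r}")
    if name not in params.values:
        raise ParameterError(f"unknown parameter id {name!r}")
    spec = params.specs[name]
    new = params.copy()
    target = spec.low if bound == "low" else spec.high
    new.values[name] = target
    if spec.block is not None:
        others = [k for k, s in params.specs.items()
                  if s.block == spec.block and k != name]
        rest = sum(params.values[k] for k in others)
        if rest > 0:
            scale = (1.0 - target) / rest
            for k in others:
                new.values[k] = params.values[k] * scale
    return new.validate()


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters for a beta with the given mean and (possibly capped)
    sd.  The variance is capped so min(a, b) >= 1, keeping the density
    unimodal for near-boundary means."""
    m = mean
    var = sd * sd
    cap = m * (1.0 - m) / (1.0 + 1.0 / min(m, 1.0 - m))
    var = min(var, cap)
    nu = m * (1.0 - m) / var - 1.0
    return m * nu, (1.0 - m) * nu


def draw_psa_sample(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One joint probabilistic-sensitivity draw of every non-fixed parameter.

    Deterministic given the generator state; dirichlet blocks are drawn
    jointly so they sum to 1 exactly."""
    new = params.copy()
    conc = float(params.settings.get("dirichlet_concentration", 100.0))

    blocks: dict[str, list[str]] = {}
    for name, spec in params.specs.items():
        if spec.family == "dirichlet":
            blocks.setdefault(spec.block or "_dirichlet", []).append(name)

    # iterate in stored (insertion) order for a stable stream layout
    for name, spec in params.specs.items():
        if spec.family in {"fixed", "dirichlet"}:
            continue
        if spec.high == spec.low:
            continue
        if spec.family == "beta":
            m = spec.base
            if m <= 0.0 or m >= 1.0:
                continue
            a, b = _beta_moments(m, (spec.high - spec.low) / _Z95)
            new.values[name] = float(rng.beta(a, b))
        elif spec.family == "normal":
            sd = (spec.high - spec.low) / _Z95
            v = float(rng.normal(spec.base, sd))
            if spec.kind == "cost" or spec.kind == "rate":
                v = max(v, 0.0)
            elif spec.kind == "proportion":
                v = float(np.clip(v, 0.0, 1.0))
            new.values[name] = v
        elif spec.family == "log_normal":
            mu = 0.5 * (np.log(spec.low) + np.log(spec.high))
            sigma = (np.log(spec.high) - np.log(spec.low)) / _Z95
            v = float(np.exp(rng.normal(mu, sigma)))
            if spec.kind == "proportion":
                v = min(v, 1.0 - 1e-9)
            new.values[name] = v
        else:  # pragma: no cover - families are exhaustive
            raise ParameterError(
                f"no sampler for family {spec.family!r} ({name})")

    for _, members in sorted(blocks.items()):
        members = sorted(members)
        alpha = np.array([params.specs[m].base for m in members]) * conc
        draw = rng.dirichlet(alpha)
        for m, v in zip(members, draw):
            new.values[m] = float(v)

    return new.validate()
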