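"""Model parameters: definition, loading, validation, and uncertainty sampling.

Every quantitative input of the screening model lives in a :class:`ParameterSet`:
annual transition probabilities on the adenoma–carcinoma chain, stage-specific
CRC mortality, age-specific background mortality, screening-test performance,
unit costs (2021 USD), health-state utilities, initial prevalence, and the
strategy calendar. Each scalar input is an :class:`UncertainParameter` carrying
a point value, a provenance tag, and a :class:`DistributionSpec` describing its
uncertainty (Beta for probabilities and utilities, Gamma for costs), so the
same object feeds the deterministic run, the one-way sensitivity analysis, and
the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from typing import Any, Callable, Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "UncertainParameter",
    "MortalityTable",
    "ScreeningTechProfile",
    "CostTable",
    "UtilityTable",
    "TransitionTable",
    "VisitRateTable",
    "StrategyConfig",
    "ParameterSet",
    "ValidationError",
    "ConfigError",
    "load_parameter_set",
    "load_parameter_file",
    "serialize_parameter_set",
    "base_case_parameter_set",
    "mortality_for_age",
    "make_sampler",
]

SCHEMA_VERSION = 1

#: Provenance tags. ``reference_placeholder`` marks values the source article
#: cites from the literature without printing; they ship as documented defaults.
PROVENANCE_TAGS = ("paper_table", "supplementary_sm1", "reference_placeholder", "assumption")

CANCER_STAGES = ("I", "II", "III", "IV")
LESION_KEYS = ("lr_adenoma", "hr_adenoma", "crc_I", "crc_II", "crc_III", "crc_IV")

COST_KEYS = (
    "lr_adenoma_treat",
    "hr_adenoma_treat",
    "crc_I_treat",
    "crc_II_treat",
    "crc_III_treat",
    "crc_IV_treat",
    "crc_followup_annual",
    "project_total",
    "fit_unit",
    "colonoscopy_unit",
    "excision_unit",
    "pathology_unit",
    "surveillance_followup_unit",
)

UTILITY_KEYS = (
    "normal",
    "lr_adenoma",
    "hr_adenoma",
    "crc_I",
    "crc_II",
    "crc_III",
    "crc_IV",
    "false_positive",
    "death",
)

NATURAL_HISTORY_KEYS = (
    "normal_to_lr",
    "lr_to_hr",
    "hr_to_ud_I",
    "ud_I_to_ud_II",
    "ud_II_to_ud_III",
    "ud_III_to_ud_IV",
)

#: Post-diagnosis progression channels (incomplete-cure variant). ``from_X``
#: marks the stage at which the patient was originally diagnosed; each prior
#: round of treatment raises the onward progression probability.
POST_DIAGNOSIS_KEYS = (
    "d_I_to_d_II",
    "d_II_to_d_III",
    "d_II_to_d_III_from_I",
    "d_III_to_d_IV",
    "d_III_to_d_IV_from_II",
    "d_III_to_d_IV_from_I",
)

VISIT_KEYS = ("lr_adenoma", "hr_adenoma", "ud_I", "ud_II", "ud_III", "ud_IV")

PREVALENCE_KEYS = ("lr_adenoma", "hr_adenoma", "ud_I", "ud_II", "ud_III", "ud_IV")

STRATEGY_IDS = ("none", "FIT1", "FIT2", "eCSPY10", "eCSPY5")


class ConfigError(ValueError):
    """Structural problem in a parameter file (bad schema, missing key)."""


class ValidationError(ValueError):
    """A parameter set violates a model invariant.

    ``keys`` lists the offending parameter paths.
    """

    def __init__(self, violations: list[str]):
        self.keys = list(violations)
        super().__init__("parameter validation failed: " + "; ".join(violations))


# ---------------------------------------------------------------------------
# Distribution specifications and sampling


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty description for one scalar parameter.

    ``low``/``high`` are the deterministic sensitivity bounds (the printed
    tables use mean ± 25%); for sampling they are read as a 95% interval, so
    the implied standard deviation is ``(high − low) / (2 × 1.96)``.
    """

    family: str  # "beta" | "gamma" | "point"
    mean: float
    low: float
    high: float

    def validate(self, path: str = "spec") -> list[str]:
        errs = []
        if self.family not in ("beta", "gamma", "point"):
            errs.append(f"{path}: unknown family {self.family!r}")
            return errs
        if not (self.low <= self.mean <= self.high):
            errs.append(f"{path}: require low <= mean <= high, got ({self.low}, {self.mean}, {self.high})")
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            errs.append(f"{path}: beta bounds must lie in [0, 1]")
        if self.family == "point" and not (self.low == self.mean == self.high):
            errs.append(f"{path}: point spec requires low = mean = high")
        return errs

    @property
    def sd(self) -> float:
        """Standard deviation implied by reading (low, high) as a 95% interval."""
        return (self.high - self.low) / (2.0 * 1.96)


def make_sampler(spec: DistributionSpec, seed: int) -> Callable[..., np.ndarray | float]:
    """Build a reproducible sampler for a :class:`DistributionSpec`.

    Beta and Gamma distributions are parameterized by method of moments from
    ``spec.mean`` and the implied standard deviation. Returns a callable
    ``sample(size=None)``: with ``size=None`` a scalar draw, otherwise an
    ndarray. The same ``seed`` always reproduces the same stream.
    """
    errs = spec.validate()
    if errs:
        raise ValidationError(errs)
    rng = np.random.default_rng(seed)
    mean, sd = spec.mean, spec.sd

    if spec.family == "point" or sd == 0.0:
        def sample(size=None):
            return mean if size is None else np.full(size, mean)
        return sample

    if spec.family == "gamma":
        if mean <= 0:
            raise ValidationError([f"gamma spec requires mean > 0, got {mean}"])
        shape = (mean / sd) ** 2
        scale = sd**2 / mean

        def sample(size=None):
            return rng.gamma(shape, scale, size=size)
        return sample

    # beta via method of moments
    if not (0.0 < mean < 1.0):
        raise ValidationError([f"beta spec requires mean in (0, 1), got {mean}"])
    var = sd**2
    max_var = mean * (1.0 - mean)
    if var >= max_var:
        raise ValidationError([f"beta spec variance {var} too large for mean {mean}"])
    nu = max_var / var - 1.0
    a, b = mean * nu, (1.0 - mean) * nu

    def sample(size=None):
        return rng.beta(a, b, size=size)
    return sample


@dataclass
class UncertainParameter:
    """A scalar model input with provenance and an uncertainty spec."""

    value: float
    spec: DistributionSpec
    source: str = "reference_placeholder"

    @classmethod
    def of(
        cls,
        value: float,
        family: str,
        source: str = "reference_placeholder",
        rel: float = 0.25,
        low: float | None = None,
        high: float | None = None,
    ) -> "UncertainParameter":
        """Construct with the conventional mean ± ``rel`` bounds unless given."""
        if low is None:
            low = value * (1.0 - rel)
        if high is None:
            high = value * (1.0 + rel)
        if family == "beta":
            high = min(high, 1.0)
        if family == "point":
            low = high = value
        return cls(value, DistributionSpec(family, value, low, high), source)

    @classmethod
    def point(cls, value: float, source: str = "assumption") -> "UncertainParameter":
        return cls(value, DistributionSpec("point", value, value, value), source)

    def validate(self, path: str) -> list[str]:
        # note: self.value may legitimately differ from spec.mean while a
        # sensitivity analysis perturbs the working value
        errs = self.spec.validate(path)
        if self.source not in PROVENANCE_TAGS:
            errs.append(f"{path}: unknown provenance tag {self.source!r}")
        return errs


# ---------------------------------------------------------------------------
# Tables


@dataclass
class MortalityTable:
    """Age-specific annual probability of death from causes other than CRC.

    ``bands`` is an ordered list of ``(age_low, age_high, probability)`` with
    inclusive integer bounds (e.g. ``(50, 54, 0.0042)``). Ages beyond the last
    band carry the last band's rate forward; ages below the first are an error.
    """

    bands: list[tuple[int, int, float]]

    def validate(self, path: str = "mortality") -> list[str]:
        errs = []
        if not self.bands:
            return [f"{path}: empty table"]
        prev_high = None
        for lo, hi, p in self.bands:
            if lo > hi:
                errs.append(f"{path}: band ({lo},{hi}) reversed")
            if not (0.0 <= p <= 1.0):
                errs.append(f"{path}: probability {p} outside [0,1] in band ({lo},{hi})")
            if prev_high is not None and lo != prev_high + 1:
                errs.append(f"{path}: bands not contiguous at age {lo}")
            prev_high = hi
        if self.bands[0][0] > 40 or self.bands[-1][1] < 74:
            errs.append(f"{path}: bands must cover ages 40-74")
        return errs


def mortality_for_age(table: MortalityTable, age: float) -> float:
    """Annual other-cause mortality at ``age`` (last band carried forward)."""
    if age < table.bands[0][0]:
        raise ValueError(f"age {age} below mortality-table coverage (starts {table.bands[0][0]})")
    for lo, hi, p in table.bands:
        if lo <= age <= hi:
            return p
    return table.bands[-1][2]


@dataclass
class ScreeningTechProfile:
    """Test performance of one screening modality.

    ``sensitivity`` maps lesion class -> detection probability per application.
    ``miss_rate`` is the colonoscopy polyp-miss fraction; by default it
    discounts adenoma detection only (``miss_applies_to_cancer`` switches it on
    for cancers as well). Colonoscopy specificity is fixed at 1 in the base
    case, so a negative colonoscopy never creates a false positive.
    """

    name: str  # "FIT" | "colonoscopy"
    sensitivity: dict[str, UncertainParameter]
    specificity: UncertainParameter
    miss_rate: UncertainParameter
    miss_applies_to_cancer: bool = False

    def adenoma_detection(self, lesion: str) -> float:
        return self.sensitivity[lesion].value * (1.0 - self.miss_rate.value)

    def cancer_detection(self, stage: str) -> float:
        p = self.sensitivity[f"crc_{stage}"].value
        if self.miss_applies_to_cancer:
            p *= 1.0 - self.miss_rate.value
        return p

    def validate(self, path: str) -> list[str]:
        errs = []
        for k in LESION_KEYS:
            if k not in self.sensitivity:
                errs.append(f"{path}.sensitivity.{k}: missing")
                continue
            errs += self.sensitivity[k].validate(f"{path}.sensitivity.{k}")
            if not (0.0 <= self.sensitivity[k].value <= 1.0):
                errs.append(f"{path}.sensitivity.{k}: outside [0,1]")
        for nm, p in (("specificity", self.specificity), ("miss_rate", self.miss_rate)):
            errs += p.validate(f"{path}.{nm}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"{path}.{nm}: outside [0,1]")
        return errs


@dataclass
class CostTable:
    """Unit and episode costs in 2021 USD."""

    entries: dict[str, UncertainParameter]

    def __getitem__(self, key: str) -> float:
        return self.entries[key].value

    def validate(self, path: str = "costs") -> list[str]:
        errs = []
        for k in COST_KEYS:
            if k not in self.entries:
                errs.append(f"{path}.{k}: missing")
                continue
            p = self.entries[k]
            errs += p.validate(f"{path}.{k}")
            if p.value < 0:
                errs.append(f"{path}.{k}: negative cost")
        return errs


@dataclass
class UtilityTable:
    """Health-state utility weights in [0, 1]; normal is exactly 1, death 0."""

    by_state: dict[str, UncertainParameter]

    def __getitem__(self, key: str) -> float:
        return self.by_state[key].value

    def validate(self, path: str = "utilities") -> list[str]:
        errs = []
        for k in UTILITY_KEYS:
            if k not in self.by_state:
                errs.append(f"{path}.{k}: missing")
                continue
            p = self.by_state[k]
            errs += p.validate(f"{path}.{k}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"{path}.{k}: outside [0,1]")
        if "normal" in self.by_state and self.by_state["normal"].value != 1.0:
            errs.append(f"{path}.normal: must be exactly 1")
        if "death" in self.by_state and self.by_state["death"].value != 0.0:
            errs.append(f"{path}.death: must be exactly 0")
        return errs


@dataclass
class TransitionTable:
    """Annual transition probabilities.

    ``natural_history`` drives the stepwise adenoma–carcinoma chain;
    ``crc_mortality`` is stage-specific CRC death risk applied to preclinical
    and diagnosed cancer alike; ``post_diagnosis`` holds the incomplete-cure
    variant's progression channels (all zero in the base case, where diagnosis
    halts progression).
    """

    natural_history: dict[str, UncertainParameter]
    crc_mortality: dict[str, UncertainParameter]
    post_diagnosis: dict[str, UncertainParameter] = field(default_factory=dict)

    def validate(self, path: str = "transitions") -> list[str]:
        errs = []
        for k in NATURAL_HISTORY_KEYS:
            if k not in self.natural_history:
                errs.append(f"{path}.natural_history.{k}: missing")
                continue
            p = self.natural_history[k]
            errs += p.validate(f"{path}.natural_history.{k}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"{path}.natural_history.{k}: outside [0,1]")
        for s in CANCER_STAGES:
            k = f"crc_{s}"
            if k not in self.crc_mortality:
                errs.append(f"{path}.crc_mortality.{k}: missing")
                continue
            p = self.crc_mortality[k]
            errs += p.validate(f"{path}.crc_mortality.{k}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"{path}.crc_mortality.{k}: outside [0,1]")
        for k, p in self.post_diagnosis.items():
            if k not in POST_DIAGNOSIS_KEYS:
                errs.append(f"{path}.post_diagnosis.{k}: unknown channel")
                continue
            errs += p.validate(f"{path}.post_diagnosis.{k}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"{path}.post_diagnosis.{k}: outside [0,1]")
        return errs


@dataclass
class VisitRateTable:
    """Annual probability of a symptomatic clinic visit leading to diagnosis.

    Adenomas are asymptomatic (rate 0); stage-IV disease always presents
    (rate 1).
    """

    by_stage: dict[str, UncertainParameter]

    def __getitem__(self, key: str) -> float:
        return self.by_stage[key].value

    def validate(self, path: str = "visits") -> list[str]:
        errs = []
        for k in VISIT_KEYS:
            if k not in self.by_stage:
                errs.append(f"{path}.{k}: missing")
                continue
            p = self.by_stage[k]
            errs += p.validate(f"{path}.{k}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"{path}.{k}: outside [0,1]")
        if "lr_adenoma" in self.by_stage and self.by_stage["lr_adenoma"].value != 0.0:
            errs.append(f"{path}.lr_adenoma: adenoma visit rate must be 0")
        if "hr_adenoma" in self.by_stage and self.by_stage["hr_adenoma"].value != 0.0:
            errs.append(f"{path}.hr_adenoma: adenoma visit rate must be 0")
        if "ud_IV" in self.by_stage and self.by_stage["ud_IV"].value != 1.0:
            errs.append(f"{path}.ud_IV: stage-IV visit rate must be 1")
        return errs


@dataclass
class StrategyConfig:
    """One screening strategy: modality, calendar, and uptake."""

    id: str
    modality: str  # "fit_then_colonoscopy" | "colonoscopy" | "none"
    interval_years: int
    participation: UncertainParameter
    colonoscopy_compliance: UncertainParameter

    def validate(self, path: str) -> list[str]:
        errs = []
        if self.modality not in ("fit_then_colonoscopy", "colonoscopy", "none"):
            errs.append(f"{path}.modality: unknown {self.modality!r}")
        if self.modality != "none" and self.interval_years not in (1, 2, 5, 10):
            errs.append(f"{path}.interval_years: must be one of 1,2,5,10")
        for nm, p in (("participation", self.participation), ("colonoscopy_compliance", self.colonoscopy_compliance)):
            errs += p.validate(f"{path}.{nm}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"{path}.{nm}: outside [0,1]")
        return errs


@dataclass
class ParameterSet:
    """Complete model input set. See module docstring."""

    cohort_size: float
    start_age: int
    end_age: int
    discount_rate: UncertainParameter
    followup_horizon_years: int
    prevalence: dict[str, UncertainParameter]
    mortality: MortalityTable
    costs: CostTable
    utilities: UtilityTable
    transitions: TransitionTable
    visits: VisitRateTable
    tech: dict[str, ScreeningTechProfile]
    strategies: dict[str, StrategyConfig]
    cycle_length: int = 1
    #: scenario presets (regional cost blocks, alternative start age, the
    #: incomplete-cure transition table) parked here by the loader
    scenario_data: dict[str, Any] = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every violated invariant."""
        errs: list[str] = []
        if self.cohort_size <= 0:
            errs.append("cohort_size: must be positive")
        if not self.start_age < self.end_age:
            errs.append("start_age: must be < end_age")
        if self.cycle_length != 1:
            errs.append("cycle_length: fixed at 1 year")
        if self.followup_horizon_years < 1:
            errs.append("followup_horizon_years: must be >= 1")
        errs += self.discount_rate.validate("discount_rate")
        if self.discount_rate.value < 0:
            errs.append("discount_rate: must be >= 0")
        prev_sum = 0.0
        for k in PREVALENCE_KEYS:
            if k not in self.prevalence:
                errs.append(f"prevalence.{k}: missing")
                continue
            p = self.prevalence[k]
            errs += p.validate(f"prevalence.{k}")
            if not (0.0 <= p.value <= 1.0):
                errs.append(f"prevalence.{k}: outside [0,1]")
            prev_sum += p.value
        if prev_sum >= 1.0:
            errs.append("prevalence: proportions must sum to < 1")
        errs += self.mortality.validate()
        if self.mortality.bands and self.start_age < self.mortality.bands[0][0]:
            errs.append("mortality: table does not cover start_age")
        errs += self.costs.validate()
        errs += self.utilities.validate()
        errs += self.transitions.validate()
        errs += self.visits.validate()
        for name, t in self.tech.items():
            errs += t.validate(f"tech.{name}")
        if "colonoscopy" in self.tech and self.tech["colonoscopy"].specificity.value != 1.0:
            errs.append("tech.colonoscopy.specificity: fixed at 1.0")
        for sid, s in self.strategies.items():
            if s.id != sid:
                errs.append(f"strategies.{sid}: id mismatch ({s.id})")
            errs += s.validate(f"strategies.{sid}")
        # total annual exit probability per compartment (sequential application
        # conserves mass regardless, but a nominal sum > 1 signals bad inputs)
        q_max = max(p for _, _, p in self.mortality.bands)
        nh = {k: v.value for k, v in self.transitions.natural_history.items()}
        mu = {s: self.transitions.crc_mortality[f"crc_{s}"].value for s in CANCER_STAGES}
        exits = {
            "normal": nh.get("normal_to_lr", 0) + q_max,
            "lr_adenoma": nh.get("lr_to_hr", 0) + q_max,
            "hr_adenoma": nh.get("hr_to_ud_I", 0) + q_max,
            "ud_I": mu["I"] + q_max + nh.get("ud_I_to_ud_II", 0),
            "ud_II": mu["II"] + q_max + nh.get("ud_II_to_ud_III", 0),
            "ud_III": mu["III"] + q_max + nh.get("ud_III_to_ud_IV", 0),
            "ud_IV": mu["IV"] + q_max,
        }
        for c, tot in exits.items():
            if tot > 1.0 + 1e-9:
                errs.append(f"exit probability at {c}: {tot:.4f} > 1")
        if errs:
            raise ValidationError(errs)

    # -- horizon helpers ----------------------------------------------------

    @property
    def n_cycles(self) -> int:
        return self.end_age - self.start_age

    # -- uncertain-parameter traversal --------------------------------------

    def iter_uncertain(self) -> Iterator[tuple[str, UncertainParameter]]:
        """Yield (dotted path, parameter) for every scalar input."""
        yield "discount_rate", self.discount_rate
        for k in PREVALENCE_KEYS:
            yield f"prevalence.{k}", self.prevalence[k]
        for k in COST_KEYS:
            yield f"costs.{k}", self.costs.entries[k]
        for k in UTILITY_KEYS:
            yield f"utilities.{k}", self.utilities.by_state[k]
        for k in NATURAL_HISTORY_KEYS:
            yield f"transitions.natural_history.{k}", self.transitions.natural_history[k]
        for s in CANCER_STAGES:
            yield f"transitions.crc_mortality.crc_{s}", self.transitions.crc_mortality[f"crc_{s}"]
        for k, p in self.transitions.post_diagnosis.items():
            yield f"transitions.post_diagnosis.{k}", p
        for k in VISIT_KEYS:
            yield f"visits.{k}", self.visits.by_stage[k]
        for name, t in self.tech.items():
            for lk in LESION_KEYS:
                yield f"tech.{name}.sensitivity.{lk}", t.sensitivity[lk]
            yield f"tech.{name}.specificity", t.specificity
            yield f"tech.{name}.miss_rate", t.miss_rate
        for sid, s in self.strategies.items():
            if s.modality == "none":
                continue
            yield f"strategies.{sid}.participation", s.participation
            yield f"strategies.{sid}.colonoscopy_compliance", s.colonoscopy_compliance

    def get_parameter(self, path: str) -> UncertainParameter:
        obj: Any = self
        parts = path.split(".")
        for i, part in enumerate(parts):
            if isinstance(obj, Mapping):
                if part not in obj:
                    raise KeyError(f"no parameter at path {path!r} (missing {part!r})")
                obj = obj[part]
            elif isinstance(obj, CostTable):
                obj = obj.entries[part]
            elif isinstance(obj, (UtilityTable, ScreeningTechProfile)) and part in ("by_state",):
                obj = obj.by_state[part]
            elif hasattr(obj, part):
                obj = getattr(obj, part)
            else:
                # tables expose their dict under a conventional attribute
                for attr in ("entries", "by_state", "by_stage"):
                    d = getattr(obj, attr, None)
                    if isinstance(d, dict) and part in d:
                        obj = d[part]
                        break
                else:
                    raise KeyError(f"no parameter at path {path!r} (at {part!r})")
        if not isinstance(obj, UncertainParameter):
            raise KeyError(f"path {path!r} does not address a scalar parameter")
        return obj

    def set_value(self, path: str, value: float) -> None:
        """Overwrite the point value at ``path`` (spec/provenance untouched)."""
        self.get_parameter(path).value = value

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Loading / serialization


def _parse_uncertain(node: Any, path: str, default_family: str, source_default: str) -> UncertainParameter:
    if isinstance(node, (int, float)):
        v = float(node)
        return UncertainParameter(v, DistributionSpec("point", v, v, v), source_default)
    if not isinstance(node, Mapping):
        raise ConfigError(f"{path}: expected number or mapping, got {type(node).__name__}")
    try:
        v = float(node["value"])
    except KeyError:
        raise ConfigError(f"{path}: missing 'value'") from None
    fam = node.get("dist", default_family)
    low = float(node.get("low", v * 0.75 if fam != "point" else v))
    high = float(node.get("high", v * 1.25 if fam != "point" else v))
    if fam == "beta":
        high = min(high, 1.0)
    if fam == "point":
        low = high = v
    src = node.get("source", source_default)
    return UncertainParameter(v, DistributionSpec(fam, v, low, high), src)


def _parse_map(node: Any, path: str, keys: tuple[str, ...], default_family: str, source_default: str) -> dict[str, UncertainParameter]:
    if not isinstance(node, Mapping):
        raise ConfigError(f"{path}: expected mapping")
    out = {}
    for k in keys:
        if k not in node:
            raise ConfigError(f"{path}.{k}: missing required key")
        out[k] = _parse_uncertain(node[k], f"{path}.{k}", default_family, source_default)
    return out


def load_parameter_set(config_text: str) -> ParameterSet:
    """Parse and validate a YAML/JSON parameter document.

    Structural problems raise :class:`ConfigError` naming the offending path;
    invariant violations raise :class:`ValidationError` listing the keys.
    """
    try:
        doc = yaml.safe_load(io.StringIO(config_text))
    except yaml.YAMLError as e:
        raise ConfigError(f"could not parse config: {e}") from e
    if not isinstance(doc, Mapping):
        raise ConfigError("config root must be a mapping")
    if doc.get("schema") != SCHEMA_VERSION:
        raise ConfigError(f"schema: expected {SCHEMA_VERSION}, got {doc.get('schema')!r}")

    def req(key: str) -> Any:
        if key not in doc:
            raise ConfigError(f"{key}: missing required section")
        return doc[key]

    cohort = req("cohort")
    mort_node = req("mortality")
    if not isinstance(mort_node, list):
        raise ConfigError("mortality: expected a list of bands")
    bands = []
    for i, b in enumerate(mort_node):
        try:
            bands.append((int(b["age_low"]), int(b["age_high"]), float(b["probability"])))
        except (KeyError, TypeError) as e:
            raise ConfigError(f"mortality[{i}]: {e}") from e

    costs = CostTable(_parse_map(req("costs"), "costs", COST_KEYS, "gamma", "paper_table"))
    utilities = UtilityTable(_parse_map(req("utilities"), "utilities", UTILITY_KEYS, "beta", "reference_placeholder"))
    trans_node = req("transitions")
    post = {}
    if "post_diagnosis" in trans_node:
        post = _parse_map(trans_node["post_diagnosis"], "transitions.post_diagnosis", POST_DIAGNOSIS_KEYS, "beta", "paper_table")
    transitions = TransitionTable(
        natural_history=_parse_map(trans_node.get("natural_history"), "transitions.natural_history", NATURAL_HISTORY_KEYS, "beta", "reference_placeholder"),
        crc_mortality=_parse_map(trans_node.get("crc_mortality"), "transitions.crc_mortality", tuple(f"crc_{s}" for s in CANCER_STAGES), "beta", "reference_placeholder"),
        post_diagnosis=post,
    )
    visits = VisitRateTable(_parse_map(req("visits"), "visits", VISIT_KEYS, "beta", "reference_placeholder"))
    prevalence = _parse_map(req("prevalence"), "prevalence", PREVALENCE_KEYS, "beta", "reference_placeholder")

    tech_node = req("tech")
    tech = {}
    for name in ("FIT", "colonoscopy"):
        if name not in tech_node:
            raise ConfigError(f"tech.{name}: missing")
        tn = tech_node[name]
        tech[name] = ScreeningTechProfile(
            name=name,
            sensitivity=_parse_map(tn.get("sensitivity"), f"tech.{name}.sensitivity", LESION_KEYS, "beta", "supplementary_sm1"),
            specificity=_parse_uncertain(tn.get("specificity"), f"tech.{name}.specificity", "beta", "supplementary_sm1"),
            miss_rate=_parse_uncertain(tn.get("miss_rate", 0.0), f"tech.{name}.miss_rate", "beta", "paper_table"),
            miss_applies_to_cancer=bool(tn.get("miss_applies_to_cancer", False)),
        )

    strat_node = req("strategies")
    strategies = {}
    for sid in STRATEGY_IDS:
        if sid not in strat_node:
            raise ConfigError(f"strategies.{sid}: missing")
        sn = strat_node[sid]
        strategies[sid] = StrategyConfig(
            id=sid,
            modality=sn.get("modality", "none"),
            interval_years=int(sn.get("interval_years", 0)),
            participation=_parse_uncertain(sn.get("participation", 0.0), f"strategies.{sid}.participation", "beta", "supplementary_sm1"),
            colonoscopy_compliance=_parse_uncertain(sn.get("colonoscopy_compliance", 1.0), f"strategies.{sid}.colonoscopy_compliance", "beta", "supplementary_sm1"),
        )

    ps = ParameterSet(
        cohort_size=float(cohort.get("size", 100_000)),
        start_age=int(cohort.get("start_age", 50)),
        end_age=int(cohort.get("end_age", 75)),
        discount_rate=_parse_uncertain(doc.get("discount_rate", 0.05), "discount_rate", "beta", "paper_table"),
        followup_horizon_years=int(doc.get("followup_horizon_years", 5)),
        prevalence=prevalence,
        mortality=MortalityTable(bands),
        costs=costs,
        utilities=utilities,
        transitions=transitions,
        visits=visits,
        tech=tech,
        strategies=strategies,
        scenario_data=dict(doc.get("scenarios", {})),
    )
    ps.validate()
    return ps


def load_parameter_file(path: str) -> ParameterSet:
    with open(path, "r", encoding="utf-8") as fh:
        return load_parameter_set(fh.read())


def _dump_uncertain(p: UncertainParameter) -> Any:
    return {
        "value": p.value,
        "low": p.spec.low,
        "high": p.spec.high,
        "dist": p.spec.family,
        "source": p.source,
    }


def serialize_parameter_set(ps: ParameterSet) -> str:
    """Emit a YAML document that :func:`load_parameter_set` reads back."""
    doc: dict[str, Any] = {
        "schema": SCHEMA_VERSION,
        "cohort": {"size": ps.cohort_size, "start_age": ps.start_age, "end_age": ps.end_age},
        "discount_rate": _dump_uncertain(ps.discount_rate),
        "followup_horizon_years": ps.followup_horizon_years,
        "prevalence": {k: _dump_uncertain(v) for k, v in ps.prevalence.items()},
        "mortality": [
            {"age_low": lo, "age_high": hi, "probability": p} for lo, hi, p in ps.mortality.bands
        ],
        "costs": {k: _dump_uncertain(v) for k, v in ps.costs.entries.items()},
        "utilities": {k: _dump_uncertain(v) for k, v in ps.utilities.by_state.items()},
        "transitions": {
            "natural_history": {k: _dump_uncertain(v) for k, v in ps.transitions.natural_history.items()},
            "crc_mortality": {k: _dump_uncertain(v) for k, v in ps.transitions.crc_mortality.items()},
            **(
                {"post_diagnosis": {k: _dump_uncertain(v) for k, v in ps.transitions.post_diagnosis.items()}}
                if ps.transitions.post_diagnosis
                else {}
            ),
        },
        "visits": {k: _dump_uncertain(v) for k, v in ps.visits.by_stage.items()},
        "tech": {
            name: {
                "sensitivity": {k: _dump_uncertain(v) for k, v in t.sensitivity.items()},
                "specificity": _dump_uncertain(t.specificity),
                "miss_rate": _dump_uncertain(t.miss_rate),
                "miss_applies_to_cancer": t.miss_applies_to_cancer,
            }
            for name, t in ps.tech.items()
        },
        "strategies": {
            sid: {
                "modality": s.modality,
                "interval_years": s.interval_years,
                "participation": _dump_uncertain(s.participation),
                "colonoscopy_compliance": _dump_uncertain(s.colonoscopy_compliance),
            }
            for sid, s in ps.strategies.items()
        },
        "scenarios": ps.scenario_data,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def base_case_parameter_set() -> ParameterSet:
    """Load the packaged base-case parameter file."""
    from importlib.resources import files

    text = files("crcscreen.data").joinpath("base_case.yaml").read_text(encoding="utf-8")
    return load_parameter_set(text)
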