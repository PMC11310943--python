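"""Typed model parameters, configuration I/O, the base-case fixture and scenarios.

Every model input lives on a :class:`ParameterSet`, addressable through dotted
paths (e.g. ``costs.stage.IV.first_3_months``) so that scenario overrides,
one-way sensitivity analysis and probabilistic draws share one addressing
scheme.  Domain invariants are checked by :func:`validate`, which returns the
full list of violations instead of raising on the first one.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Dict, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

STAGES = ("I", "II", "III", "IV")

#: Stage whose survival curves stand in for never-diagnosed cancers.
MISSED = "missed"


class ConfigurationError(ValueError):
    """A config file could not be parsed into a :class:`ParameterSet`."""


class ParameterValidationError(ValueError):
    """A :class:`ParameterSet` violates one or more domain invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ScenarioError(KeyError):
    """A scenario override addresses a path that does not exist."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class DistributionSpec(_Model):
    """Probabilistic-sensitivity distribution attached to one parameter."""

    kind: Literal["fixed", "beta", "gamma", "dirichlet_group"]
    mean: float
    se: Optional[float] = None
    group_id: Optional[str] = None


class Demography(_Model):
    total_population: float
    frac_aged_50_74: float
    smoking_rate: float
    mean_entry_age: float = 58.0


class Epidemiology(_Model):
    annual_incidence_eligible: float
    clinical_stage_distribution: Dict[str, float]


class ScreeningSettings(_Model):
    uptake: float
    adherence: float = 1.0
    n_rounds: int = 17
    cycle_length: float = 0.25
    horizon: float = 42.0
    wtp: float = 50_000.0
    discount_rate_costs: float = 0.05
    discount_rate_health: float = 0.05


class StageCosts(_Model):
    first_3_months: float
    rest_of_year1: float
    year2: float
    second_line: float


class CostSchedule(_Model):
    stage: Dict[str, StageCosts]
    invitation_letter: float
    gp_consult: float
    ct_scan: float
    diag_screen_detected: float
    diag_clinical: float
    followup_ct: float
    followup_consult: float
    end_of_life: float


class UtilitySet(_Model):
    pre_progression: Dict[str, float]
    post_progression: Dict[str, float]
    population_utility_by_age: Dict[int, float] = {}


class SurvivalSummary(_Model):
    os_5yr: Dict[str, float]
    dpfs_1yr: Dict[str, float]
    missed_behaves_as: str = "II"


class SpecialFlags(_Model):
    """Scenario switches that are not plain parameter overrides."""

    fp_disutility: float = 0.0
    smoking_cessation_cost: float = 0.0
    immunotherapy_uplift: float = 0.0
    #: share of late-stage first-line cost attributable to immunotherapy;
    #: the uplift scales that share in both arms.
    immunotherapy_cost_share: float = 0.35
    #: hook for survival improvement of late-stage patients (<1 lowers the
    #: stage III/IV disease hazard).
    late_stage_hazard_multiplier: float = 1.0


class ParameterSet(_Model):
    demography: Demography
    epidemiology: Epidemiology
    settings: ScreeningSettings
    costs: CostSchedule
    utilities: UtilitySet
    survival: SurvivalSummary
    distributions: Dict[str, DistributionSpec] = {}
    background_mortality_multiplier: float = 1.0
    special_flags: SpecialFlags = SpecialFlags()
    #: optional screen-performance override (fields of ScreeningOutcomeModel);
    #: when absent the shipped calibrated default is used
    screening_outcomes: Optional[Dict[str, object]] = None


class Scenario(_Model):
    name: str
    overrides: Dict[str, float] = {}
    special_flags: SpecialFlags = SpecialFlags()


# ---------------------------------------------------------------------------
# dotted-path addressing


def get_path(p: ParameterSet, path: str):
    """Return the value at a dotted parameter path."""
    obj = p
    for part in path.split("."):
        if isinstance(obj, BaseModel):
            if part not in obj.__class__.model_fields:
                raise ScenarioError(f"unknown parameter path: {path!r} (at {part!r})")
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            key = int(part) if part.lstrip("-").isdigit() else part
            if key not in obj:
                raise ScenarioError(f"unknown parameter path: {path!r} (at {part!r})")
            obj = obj[key]
        else:
            raise ScenarioError(f"unknown parameter path: {path!r} (at {part!r})")
    return obj


def set_path(p: ParameterSet, path: str, value) -> None:
    """Set the value at a dotted parameter path in place."""
    parts = path.split(".")
    obj = get_path(p, ".".join(parts[:-1])) if len(parts) > 1 else p
    last = parts[-1]
    if isinstance(obj, BaseModel):
        if last not in obj.__class__.model_fields:
            raise ScenarioError(f"unknown parameter path: {path!r} (at {last!r})")
        current = getattr(obj, last)
        if isinstance(current, int) and not isinstance(current, bool):
            if isinstance(value, float) and value.is_integer():
                value = int(value)
        setattr(obj, last, value)
    elif isinstance(obj, dict):
        key = int(last) if last.lstrip("-").isdigit() else last
        if key not in obj:
            raise ScenarioError(f"unknown parameter path: {path!r} (at {last!r})")
        obj[key] = value
    else:
        raise ScenarioError(f"unknown parameter path: {path!r}")


# ---------------------------------------------------------------------------
# validation


def _frac(violations, path, v, lo=0.0, hi=1.0):
    if not (lo <= v <= hi):
        violations.append(f"{path}: value {v} outside [{lo}, {hi}]")


def validate(p: ParameterSet) -> list:
    """Check all domain invariants; return a (possibly empty) list of violations."""
    v: list = []
    d = p.demography
    if d.total_population <= 0:
        v.append("demography.total_population: must be > 0")
    _frac(v, "demography.frac_aged_50_74", d.frac_aged_50_74)
    _frac(v, "demography.smoking_rate", d.smoking_rate)
    if not (50.0 <= d.mean_entry_age <= 74.0):
        v.append("demography.mean_entry_age: must lie in [50, 74]")

    e = p.epidemiology
    if not (0.0 < e.annual_incidence_eligible < 0.05):
        v.append("epidemiology.annual_incidence_eligible: must lie in (0, 0.05)")
    missing = [s for s in STAGES if s not in e.clinical_stage_distribution]
    if missing:
        v.append(f"epidemiology.clinical_stage_distribution: missing stages {missing}")
    else:
        total = sum(e.clinical_stage_distribution[s] for s in STAGES)
        if abs(total - 1.0) > 1e-9:
            v.append(
                f"epidemiology.clinical_stage_distribution: stage fractions sum to {total}, not 1"
            )

    s = p.settings
    _frac(v, "settings.uptake", s.uptake)
    _frac(v, "settings.adherence", s.adherence)
    if s.n_rounds < 1:
        v.append("settings.n_rounds: must be >= 1")
    if s.cycle_length <= 0:
        v.append("settings.cycle_length: must be > 0")
    if s.horizon <= 0:
        v.append("settings.horizon: must be > 0")
    for name in ("discount_rate_costs", "discount_rate_health"):
        rate = getattr(s, name)
        if not (0.0 <= rate <= 0.2):
            v.append(f"settings.{name}: value {rate} outside [0, 0.2]")

    for path, val in _iter_cost_values(p.costs):
        if val < 0:
            v.append(f"{path}: cost must be >= 0")

    u = p.utilities
    for kind in ("pre_progression", "post_progression"):
        table = getattr(u, kind)
        for st in STAGES:
            if st not in table:
                v.append(f"utilities.{kind}: missing stage {st}")
            else:
                _frac(v, f"utilities.{kind}.{st}", table[st])
    for st in STAGES:
        pre = u.pre_progression.get(st)
        post = u.post_progression.get(st)
        if pre is not None and post is not None and post > pre + 1e-12:
            v.append(f"utilities.post_progression.{st}: exceeds pre-progression utility")
    for age, util in u.population_utility_by_age.items():
        _frac(v, f"utilities.population_utility_by_age.{age}", util)

    for kind, table in (("os_5yr", p.survival.os_5yr), ("dpfs_1yr", p.survival.dpfs_1yr)):
        for st in STAGES:
            if st not in table:
                v.append(f"survival.{kind}: missing stage {st}")
            elif not (0.0 < table[st] < 1.0):
                v.append(f"survival.{kind}.{st}: value {table[st]} outside (0, 1)")
    if p.survival.missed_behaves_as not in STAGES:
        v.append("survival.missed_behaves_as: must name a stage I-IV")

    if p.background_mortality_multiplier <= 0:
        v.append("background_mortality_multiplier: must be > 0")

    # distribution invariants
    groups: Dict[str, list] = {}
    for path, spec in p.distributions.items():
        if spec.kind == "beta" and not (0.0 <= spec.mean <= 1.0):
            v.append(f"distributions.{path}: beta mean {spec.mean} outside [0, 1]")
        if spec.kind == "gamma" and spec.mean <= 0:
            v.append(f"distributions.{path}: gamma mean must be > 0")
        if spec.kind == "dirichlet_group":
            groups.setdefault(spec.group_id or path, []).append(spec.mean)
    for gid, means in groups.items():
        if abs(sum(means) - 1.0) > 1e-9:
            v.append(f"distributions group {gid!r}: means sum to {sum(means)}, not 1")
    return v


def _iter_cost_values(cs: CostSchedule):
    for st, sc in cs.stage.items():
        for f in ("first_3_months", "rest_of_year1", "year2", "second_line"):
            yield f"costs.stage.{st}.{f}", getattr(sc, f)
    for f in (
        "invitation_letter",
        "gp_consult",
        "ct_scan",
        "diag_screen_detected",
        "diag_clinical",
        "followup_ct",
        "followup_consult",
        "end_of_life",
    ):
        yield f"costs.{f}", getattr(cs, f)


# ---------------------------------------------------------------------------
# default PSA distribution map

#: one-way sensitivity span; also the default relative spread for PSA draws
DEFAULT_RELATIVE_SE = 0.2


def default_distributions(p: ParameterSet) -> Dict[str, DistributionSpec]:
    """Attach the documented default distribution to every varied parameter.

    Beta/gamma parameters get ``se = 0.2 * mean``; the clinical stage
    distribution is one joint dirichlet group.  Discount rates, horizon and
    survival anchors stay fixed.
    """
    out: Dict[str, DistributionSpec] = {}

    def beta(path):
        m = get_path(p, path)
        out[path] = DistributionSpec(kind="beta", mean=m, se=DEFAULT_RELATIVE_SE * m)

    def gamma(path):
        m = get_path(p, path)
        out[path] = DistributionSpec(kind="gamma", mean=m, se=DEFAULT_RELATIVE_SE * m)

    beta("settings.uptake")
    gamma("demography.total_population")
    beta("demography.frac_aged_50_74")
    beta("demography.smoking_rate")
    gamma("epidemiology.annual_incidence_eligible")
    for st in STAGES:
        path = f"epidemiology.clinical_stage_distribution.{st}"
        out[path] = DistributionSpec(
            kind="dirichlet_group", mean=get_path(p, path), group_id="clinical_stage"
        )
    for path, _ in _iter_cost_values(p.costs):
        gamma(path)
    for st in STAGES:
        beta(f"utilities.pre_progression.{st}")
        beta(f"utilities.post_progression.{st}")
    # Table-level background mortality uncertainty is exposed through a single
    # multiplier; gamma keeps it positive around 1.
    gamma("background_mortality_multiplier")
    return out


# ---------------------------------------------------------------------------
# I/O


def serialize(p: ParameterSet) -> str:
    """Serialize a ParameterSet to the YAML config schema."""
    return yaml.safe_dump(p.model_dump(), sort_keys=False)


def _build(data: dict) -> ParameterSet:
    try:
        p = ParameterSet(**data)
    except ValidationError as err:
        keys = ", ".join(
            ".".join(str(x) for x in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ConfigurationError(f"invalid configuration at key(s): {keys}") from err
    if not p.utilities.population_utility_by_age:
        from lcscea.synthetic_data import make_population_utilities

        p.utilities.population_utility_by_age = make_population_utilities()
    if not p.distributions:
        p.distributions = default_distributions(p)
    violations = validate(p)
    if violations:
        raise ParameterValidationError(violations)
    return p


def load_parameters(source) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML file path or YAML text."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigurationError(f"could not parse configuration: {err}") from err
    if not isinstance(data, dict):
        raise ConfigurationError("configuration must be a mapping")
    return _build(data)


def table1_fixture() -> ParameterSet:
    """The shipped base case (Austria, 2022 EUR)."""
    text = resources.files("lcscea").joinpath("data/table1_austria_2022.yaml").read_text()
    return load_parameters(text)


def apply_scenario(p: ParameterSet, s: Scenario) -> ParameterSet:
    """Return a new ParameterSet with scenario overrides applied; ``p`` is untouched."""
    out = copy.deepcopy(p)
    for path, value in s.overrides.items():
        get_path(out, path)  # raises ScenarioError on unknown paths
        set_path(out, path, value)
        if path in out.distributions:
            spec = out.distributions[path]
            scale = value / spec.mean if spec.mean else 0.0
            spec.mean = value
            if spec.se is not None:
                spec.se *= abs(scale)
    out.special_flags = s.special_flags.model_copy(deep=True)
    return out
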