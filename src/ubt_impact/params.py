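"""Parameter containers, validation, and configuration I/O.

The model is driven by four blocks of parameters:

* :class:`RegionInputs` — published demographic and epidemiologic inputs for
  sub-Saharan Africa (live births, delivery-setting shares, PPH rates, the
  atonic fraction).
* :class:`InterventionSpec` — a treatment step's availability (penetration),
  appropriate use given availability (utilization), and severity-stratified
  efficacy.  The uterine balloon tamponade (UBT) is the intervention of
  interest; uterotonic drugs are modelled through a collapsed per-setting
  coverage map plus a single efficacy.
* :class:`HiddenParams` — cascade internals that are not published (severity
  dynamics, surgical access, case-fatality rates); these are estimated by the
  :mod:`ubt_impact.calibration` module.
* :class:`Constants` — fixed clinical conventions (the 1000 mL severe-PPH
  threshold and the 12 % severe-anemia fraction among severe hemorrhage).

Scenario configuration files are plain YAML with top-level keys
``region``, ``uterotonic_coverage``, ``ubt``, ``hidden``, ``constants`` and
``scenario``; see the packaged files under ``ubt_impact/configs``.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

SETTINGS = ("home", "clinic", "hospital")
FACILITY_SETTINGS = ("clinic", "hospital")

POPULATION_FILTERS = ("all", "nonsevere_only")


class ValidationError(ValueError):
    """A parameter value or parameter map violates a model invariant."""


def _check_prob(name: str, value: float) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} must be a number, got {value!r}") from None
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    return v


def _check_setting_map(name: str, mapping: Mapping[str, float]) -> dict[str, float]:
    if set(mapping) != set(SETTINGS):
        raise ValidationError(
            f"{name} must have exactly the keys {SETTINGS}, got {sorted(mapping)}"
        )
    return {s: _check_prob(f"{name}[{s}]", mapping[s]) for s in SETTINGS}


@dataclass(frozen=True)
class RegionInputs:
    """Published cohort inputs for one region-year."""

    live_births: float
    setting_shares: dict[str, float]
    pph_rate: dict[str, float]
    atonic_fraction: float
    year_label: str = "2018"

    def __post_init__(self) -> None:
        if self.live_births < 0:
            raise ValidationError(f"live_births must be >= 0, got {self.live_births}")
        shares = _check_setting_map("setting_shares", self.setting_shares)
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"setting_shares must sum to 1 (got {total!r}): {shares}"
            )
        object.__setattr__(self, "setting_shares", shares)
        object.__setattr__(self, "pph_rate", _check_setting_map("pph_rate", self.pph_rate))
        _check_prob("atonic_fraction", self.atonic_fraction)

    def to_dict(self) -> dict[str, Any]:
        return {
            "live_births": self.live_births,
            "setting_shares": dict(self.setting_shares),
            "pph_rate": dict(self.pph_rate),
            "atonic_fraction": self.atonic_fraction,
            "year_label": self.year_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RegionInputs":
        return cls(**d)


@dataclass(frozen=True)
class InterventionSpec:
    """Penetration / utilization / severity-stratified efficacy of a treatment."""

    name: str
    penetration: dict[str, float]
    utilization: dict[str, float]
    efficacy_nonsevere: float
    efficacy_severe: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "penetration", _check_setting_map("penetration", self.penetration)
        )
        object.__setattr__(
            self, "utilization", _check_setting_map("utilization", self.utilization)
        )
        _check_prob("efficacy_nonsevere", self.efficacy_nonsevere)
        _check_prob("efficacy_severe", self.efficacy_severe)

    def coverage(self, setting: str) -> float:
        """Probability a case in `setting` actually receives the intervention."""
        return self.penetration[setting] * self.utilization[setting]

    def replace(self, **kwargs: Any) -> "InterventionSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "penetration": dict(self.penetration),
            "utilization": dict(self.utilization),
            "efficacy_nonsevere": self.efficacy_nonsevere,
            "efficacy_severe": self.efficacy_severe,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "InterventionSpec":
        return cls(**d)


@dataclass(frozen=True)
class HiddenParams:
    """Unpublished cascade internals, subject to calibration.

    ``presevere_fraction`` is the share of atonic PPH already past the
    1000 mL threshold when second-line treatment begins.  ``progression_prob``
    applies to nonsevere cases whose bleeding is *not* controlled;
    ``rebleed_prob`` applies to cases whose bleeding *was* controlled by the
    balloon but who nonetheless cross the threshold later (the in-place device
    is then used at severe-stratum efficacy where severe-stratum use is
    permitted).  Last-resort surgery is offered to every unresolved case —
    severe or persistently bleeding nonsevere — with per-setting access.
    """

    uterotonic_efficacy: float
    presevere_fraction: float
    progression_prob: float
    rebleed_prob: float
    surgery_access: dict[str, float]
    cfr_severe_no_surgery: float
    cfr_severe_surgery: float
    cfr_nonsevere_resolved: float
    nonatonic_death_load: float

    def __post_init__(self) -> None:
        for name in (
            "uterotonic_efficacy",
            "presevere_fraction",
            "progression_prob",
            "rebleed_prob",
            "cfr_severe_no_surgery",
            "cfr_severe_surgery",
            "cfr_nonsevere_resolved",
        ):
            _check_prob(name, getattr(self, name))
        object.__setattr__(
            self, "surgery_access", _check_setting_map("surgery_access", self.surgery_access)
        )
        if self.cfr_severe_surgery > self.cfr_severe_no_surgery + 1e-12:
            raise ValidationError(
                "cfr_severe_surgery must not exceed cfr_severe_no_surgery "
                f"({self.cfr_severe_surgery} > {self.cfr_severe_no_surgery})"
            )
        if self.rebleed_prob > self.progression_prob + 1e-12:
            raise ValidationError(
                "rebleed_prob must not exceed progression_prob "
                f"({self.rebleed_prob} > {self.progression_prob})"
            )
        if self.nonatonic_death_load < 0:
            raise ValidationError(
                f"nonatonic_death_load must be >= 0, got {self.nonatonic_death_load}"
            )

    def replace(self, **kwargs: Any) -> "HiddenParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {
            "uterotonic_efficacy": self.uterotonic_efficacy,
            "presevere_fraction": self.presevere_fraction,
            "progression_prob": self.progression_prob,
            "rebleed_prob": self.rebleed_prob,
            "surgery_access": dict(self.surgery_access),
            "cfr_severe_no_surgery": self.cfr_severe_no_surgery,
            "cfr_severe_surgery": self.cfr_severe_surgery,
            "cfr_nonsevere_resolved": self.cfr_nonsevere_resolved,
            "nonatonic_death_load": self.nonatonic_death_load,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "HiddenParams":
        return cls(**d)


#: Dotted paths of all scalar hidden-parameter fields (calibration free list).
HIDDEN_PARAM_PATHS = (
    "uterotonic_efficacy",
    "presevere_fraction",
    "progression_prob",
    "rebleed_prob",
    "surgery_access.home",
    "surgery_access.clinic",
    "surgery_access.hospital",
    "cfr_severe_no_surgery",
    "cfr_severe_surgery",
    "cfr_nonsevere_resolved",
    "nonatonic_death_load",
)


@dataclass(frozen=True)
class Constants:
    """Fixed clinical conventions."""

    severe_threshold_ml: float = 1000.0
    anemia_fraction: float = 0.12

    def __post_init__(self) -> None:
        if self.severe_threshold_ml <= 0:
            raise ValidationError(
                f"severe_threshold_ml must be > 0, got {self.severe_threshold_ml}"
            )
        _check_prob("anemia_fraction", self.anemia_fraction)

    def to_dict(self) -> dict[str, Any]:
        return {
            "severe_threshold_ml": self.severe_threshold_ml,
            "anemia_fraction": self.anemia_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Constants":
        return cls(**d)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named scenario: which population may receive the UBT, plus efficacy overrides."""

    name: str = "base"
    population_filter: str = "all"
    efficacy_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population_filter not in POPULATION_FILTERS:
            raise ValidationError(
                f"population_filter must be one of {POPULATION_FILTERS}, "
                f"got {self.population_filter!r}"
            )
        allowed = {"efficacy_nonsevere", "efficacy_severe"}
        bad = set(self.efficacy_overrides) - allowed
        if bad:
            raise ValidationError(f"unknown efficacy_overrides keys: {sorted(bad)}")
        for k, v in self.efficacy_overrides.items():
            _check_prob(f"efficacy_overrides.{k}", v)

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "population_filter": self.population_filter,
            "efficacy_overrides": dict(self.efficacy_overrides),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioSpec":
        return cls(**d)


@dataclass(frozen=True)
class ModelConfig:
    """A complete, runnable model configuration (one scenario)."""

    region: RegionInputs
    uterotonic_coverage: dict[str, float]
    ubt: InterventionSpec
    hidden: HiddenParams
    constants: Constants = field(default_factory=Constants)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "uterotonic_coverage",
            _check_setting_map("uterotonic_coverage", self.uterotonic_coverage),
        )

    def effective_ubt(self) -> InterventionSpec:
        """UBT spec with the scenario's efficacy overrides applied."""
        return self.ubt.replace(**self.scenario.efficacy_overrides)

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {
            "region": self.region.to_dict(),
            "uterotonic_coverage": dict(self.uterotonic_coverage),
            "ubt": self.ubt.to_dict(),
            "hidden": self.hidden.to_dict(),
            "constants": self.constants.to_dict(),
            "scenario": self.scenario.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelConfig":
        return cls(
            region=RegionInputs.from_dict(d["region"]),
            uterotonic_coverage=dict(d["uterotonic_coverage"]),
            ubt=InterventionSpec.from_dict(d["ubt"]),
            hidden=HiddenParams.from_dict(d["hidden"]),
            constants=Constants.from_dict(d.get("constants", {})),
            scenario=ScenarioSpec.from_dict(d.get("scenario", {"name": "base"})),
        )


# ---------------------------------------------------------------------------
# Reference values (published model inputs for SSA, 2018)
# ---------------------------------------------------------------------------

REGION_SSA_2018 = RegionInputs(
    live_births=34_806_654,
    setting_shares={"home": 0.50, "clinic": 0.35, "hospital": 0.15},
    pph_rate={"home": 0.12, "clinic": 0.10, "hospital": 0.08},
    atonic_fraction=0.90,
    year_label="2018",
)

UBT_REFERENCE = InterventionSpec(
    name="low-cost UBT",
    penetration={"home": 0.0, "clinic": 0.60, "hospital": 0.80},
    utilization={"home": 0.0, "clinic": 0.85, "hospital": 0.85},
    efficacy_nonsevere=0.85,
    efficacy_severe=0.70,
)

#: Uterotonic coverage is pinned to the UBT penetration assumption
#: (availability matched to existing uterotonic drug use); home defaults to 0.
UTEROTONIC_COVERAGE = {"home": 0.0, "clinic": 0.60, "hospital": 0.80}

#: Pre-calibration placeholder values; every analysis uses the fitted file.
DEFAULT_HIDDEN = HiddenParams(
    uterotonic_efficacy=0.85,
    presevere_fraction=0.15,
    progression_prob=0.30,
    rebleed_prob=0.10,
    surgery_access={"home": 0.05, "clinic": 0.30, "hospital": 0.80},
    cfr_severe_no_surgery=0.20,
    cfr_severe_surgery=0.05,
    cfr_nonsevere_resolved=0.001,
    nonatonic_death_load=6000.0,
)


# ---------------------------------------------------------------------------
# Dotted-path access (stable addressing for sensitivity and calibration)
# ---------------------------------------------------------------------------

def get_path(tree: Mapping[str, Any], path: str) -> Any:
    """Resolve a dotted path such as ``hidden.surgery_access.clinic``."""
    node: Any = tree
    for key in path.split("."):
        if not isinstance(node, Mapping) or key not in node:
            raise KeyError(f"cannot resolve parameter path {path!r} (missing {key!r})")
        node = node[key]
    return node


def set_path(tree: dict[str, Any], path: str, value: Any) -> dict[str, Any]:
    """Return a deep copy of `tree` with `path` set to `value`.

    The full path must already exist: sensitivity analysis addresses existing
    numeric fields, it does not create new ones.
    """
    get_path(tree, path)  # raises KeyError naming the path
    new = copy.deepcopy(tree)
    node = new
    keys = path.split(".")
    for key in keys[:-1]:
        node = node[key]
    node[keys[-1]] = value
    return new


# ---------------------------------------------------------------------------
# YAML I/O and packaged configuration files
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> ModelConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} did not parse to a mapping")
    return ModelConfig.from_dict(data)


def dump_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def packaged_config_path(name: str) -> Path:
    """Filesystem path of a YAML file shipped under ``ubt_impact/configs``."""
    p = resources.files("ubt_impact").joinpath("configs", name)
    return Path(str(p))


def load_packaged_config(name: str) -> ModelConfig:
    return load_config(packaged_config_path(name))


def load_fitted_hidden(path: str | Path | None = None) -> HiddenParams:
    """Load the reference calibrated hidden parameters (or another fitted file)."""
    if path is None:
        path = packaged_config_path("fitted_params.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return HiddenParams.from_dict(data["hidden"] if "hidden" in data else data)


def iter_packaged_scenarios() -> Iterator[str]:
    """Names of the shipped scenario configuration files, in reporting order."""
    yield from (
        "base.yaml",
        "optimistic.yaml",
        "pessimistic.yaml",
        "nonsevere_only.yaml",
        "nonsevere_eff95.yaml",
    )
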