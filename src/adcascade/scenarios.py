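"""Scenario presets, config file round-tripping, and validation.

Four published scenario parameterizations are shipped as presets:

``early_onset``
    early-onset autosomal dominant AD — larger initial amyloid seed
    (0.05), no comorbidity.
``late_amyloid_first``
    late-onset amyloid-first AD — small amyloid seed (0.01), faster amyloid
    growth, moderate aging/SNAP burden (AS=1) seeding SNAP-tau at 0.05.
``late_tau_first``
    late-onset tau-first (SNAP-first) AD — heavier comorbidity (AS=2), so
    non-amyloid tauopathy reaches detection before amyloid.
``late_amyloid_first_rx``
    the amyloid-first scenario with anti-amyloid therapy switched on at age
    65 (clearance rate 0.04/yr), natural-history carrying capacities.

Config files are YAML with a required ``schema_version`` key; unknown keys
are rejected by name and omitted optional sections fall back to the
defaults documented on each type.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from adcascade.model_core import (
    DEGRADATION_FORMS,
    BiomarkerState,
    CarryingCapacities,
    HostFactors,
    RateParameters,
    TherapySchedule,
)
from adcascade.simulation import AgeGrid

__all__ = [
    "ScenarioConfig",
    "Violation",
    "PRESET_NAMES",
    "preset",
    "validate",
    "read_config",
    "write_config",
    "config_to_dict",
    "config_from_dict",
]

SCHEMA_VERSION = 1

PRESET_NAMES = (
    "early_onset",
    "late_amyloid_first",
    "late_tau_first",
    "late_amyloid_first_rx",
)

_ALIASES = {
    "late_onset_amyloid_first": "late_amyloid_first",
    "late_onset_tau_first": "late_tau_first",
    "late_snap_first": "late_tau_first",
    "antiamyloid_rx": "late_amyloid_first_rx",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one simulation scenario."""

    name: str = "custom"
    initial: BiomarkerState = field(default_factory=BiomarkerState)
    rates: RateParameters = field(default_factory=RateParameters)
    caps: CarryingCapacities = field(default_factory=CarryingCapacities)
    host: HostFactors = field(default_factory=HostFactors)
    therapy: TherapySchedule = field(default_factory=TherapySchedule)
    grid: AgeGrid = field(default_factory=AgeGrid)
    degradation_form: str = "literal"


# Rates shared by all four published scenario columns (per-year units).
_SHARED_RATES = dict(
    lam_ab_ao=0.0,
    lam_tp_ab=0.025,
    lam_tp=0.05,
    lam_to_as=0.002,
    lam_n=0.05,
    lam_n_tp=0.025,
    lam_n_to=0.0075,
    lam_n_as=0.0,
    lam_c=0.05,
    lam_cn=0.001,
    lam_c_as=0.0,
    lam_c_eps=0.001,
)


def _make_preset(name, a_beta0, tau_o0, lam_ab, as_level, delta_ab=0.0, therapy=None):
    return ScenarioConfig(
        name=name,
        initial=BiomarkerState(a_beta=a_beta0, tau_o=tau_o0),
        rates=RateParameters(lam_ab=lam_ab, delta_ab=delta_ab, **_SHARED_RATES),
        caps=CarryingCapacities(1.0, 1.0, 1.0, 1.0),
        host=HostFactors(a_o=0.0, as_level=as_level, eps=0.0, reserve_low=1.0, reserve_high=25.0),
        therapy=therapy if therapy is not None else TherapySchedule(),
    )


_PRESETS = {
    "early_onset": _make_preset("early_onset", 0.05, 0.0, 0.08, 0.0),
    "late_amyloid_first": _make_preset("late_amyloid_first", 0.01, 0.05, 0.12, 1.0),
    "late_tau_first": _make_preset("late_tau_first", 0.01, 0.05, 0.1, 2.0),
    "late_amyloid_first_rx": _make_preset(
        "late_amyloid_first_rx",
        0.01,
        0.05,
        0.12,
        1.0,
        delta_ab=0.04,
        therapy=TherapySchedule(active=True, onset_age=65.0),
    ),
}


def preset(name: str) -> ScenarioConfig:
    """Return a shipped scenario preset by (case-insensitive) name."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return _PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None


@dataclass(frozen=True)
class Violation:
    """One validation failure: the offending field, its value, and the rule."""

    field: str
    value: object
    rule: str

    def __str__(self) -> str:
        return f"{self.field}={self.value!r} violates: {self.rule}"


def validate(config: ScenarioConfig) -> list[Violation]:
    """Check every type invariant; an empty list means the config is valid."""
    v: list[Violation] = []
    for f in dataclasses.fields(config.initial):
        val = getattr(config.initial, f.name)
        if not val >= 0:
            v.append(Violation(f"initial.{f.name}", val, "initial levels must be >= 0"))
    for f in dataclasses.fields(config.rates):
        val = getattr(config.rates, f.name)
        if not val >= 0:
            v.append(Violation(f"rates.{f.name}", val, "rate constants must be >= 0"))
    for f in dataclasses.fields(config.caps):
        val = getattr(config.caps, f.name)
        if not val > 0:
            v.append(Violation(f"caps.{f.name}", val, "carrying capacities must be > 0"))
    for f in dataclasses.fields(config.host):
        val = getattr(config.host, f.name)
        if not val >= 0:
            v.append(Violation(f"host.{f.name}", val, "host factors must be >= 0"))
    if not config.therapy.onset_age >= 0:
        v.append(
            Violation("therapy.onset_age", config.therapy.onset_age, "onset age must be >= 0")
        )
    if config.degradation_form not in DEGRADATION_FORMS:
        v.append(
            Violation(
                "degradation_form",
                config.degradation_form,
                f"must be one of {DEGRADATION_FORMS}",
            )
        )
    return v


_SECTIONS = {
    "initial": BiomarkerState,
    "rates": RateParameters,
    "caps": CarryingCapacities,
    "host": HostFactors,
    "therapy": TherapySchedule,
    "grid": AgeGrid,
}
_TOP_KEYS = {"schema_version", "name", "degradation_form", *_SECTIONS}


def config_to_dict(config: ScenarioConfig) -> dict:
    d: dict = {"schema_version": SCHEMA_VERSION, "name": config.name}
    for section, _ in _SECTIONS.items():
        d[section] = dataclasses.asdict(getattr(config, section))
    d["degradation_form"] = config.degradation_form
    return d


def config_from_dict(data: dict) -> ScenarioConfig:
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    if "schema_version" not in data:
        raise ValueError("config missing required key 'schema_version'")
    if data["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {data['schema_version']!r}")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {
        "name": data.get("name", "custom"),
        "degradation_form": data.get("degradation_form", "literal"),
    }
    for section, cls in _SECTIONS.items():
        raw = data.get(section, {})
        if not isinstance(raw, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
        kwargs[section] = cls(**raw)
    config = ScenarioConfig(**kwargs)
    violations = validate(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(str(v) for v in violations))
    return config


def write_config(config: ScenarioConfig, path) -> None:
    """Serialize a scenario to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def read_config(path) -> ScenarioConfig:
    """Read and validate a YAML scenario file (round-trip inverse of write)."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data)
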