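"""Model configuration: loading, validation, and access to bundled data files.

All quantities the underlying literature does not print — compartment
volume/flow fractions, tissue partition coefficients, the adult reference
plasma clearance, bone-uptake behaviour, daily urine volumes — live in a
versioned YAML file rather than in code, so they can be replaced wholesale
when better reference values are transcribed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

#: Compartments every configuration must define.
REQUIRED_COMPARTMENTS = ("liver", "kidney", "bone", "rest_of_body")

_COMPARTMENT_KEYS = ("volume_fraction_bw", "flow_fraction_co", "partition_coefficient")


def data_path(name: str) -> Path:
    """Return the filesystem path of a bundled data file."""
    return Path(str(resources.files("fluokin").joinpath("data", name)))


@dataclass(frozen=True)
class ModelConfig:
    """Validated model configuration.

    Thin frozen wrapper around the raw mapping; accessors return plain
    floats/dicts so downstream code never touches YAML structure directly.
    """

    raw: Mapping[str, Any] = field(repr=False)

    # -- accessors ---------------------------------------------------------
    @property
    def reference_plasma_clearance(self) -> float:
        return float(self.raw["reference_clearance"]["plasma_l_min"])

    @property
    def reference_body_weight(self) -> float:
        return float(self.raw["reference_clearance"]["body_weight_kg"])

    @property
    def cardiac_output_coefficient(self) -> float:
        return float(self.raw["cardiac_output"]["coefficient_l_min"])

    @property
    def cardiac_output_exponent(self) -> float:
        return float(self.raw["cardiac_output"]["exponent"])

    @property
    def blood_volume_fraction(self) -> float:
        return float(self.raw["blood"]["volume_fraction_bw"])

    @property
    def compartments(self) -> dict[str, dict[str, float]]:
        return {
            name: {k: float(v) for k, v in spec.items()}
            for name, spec in self.raw["compartments"].items()
        }

    @property
    def bone_mode(self) -> str:
        return str(self.raw["bone_uptake"]["mode"])

    @property
    def mineral_partition(self) -> float:
        return float(self.raw["bone_uptake"]["mineral_partition"])

    @property
    def clearance_driving(self) -> str:
        return str(self.raw.get("clearance_driving", {}).get("concentration", "arterial"))

    def daily_urine_volume(self, age_years: float) -> float:
        """Daily urine volume (L/day), linearly interpolated between config ages."""
        table = {float(a): float(v) for a, v in self.raw["daily_urine_volume_l"].items()}
        ages = sorted(table)
        if age_years <= ages[0]:
            return table[ages[0]]
        if age_years >= ages[-1]:
            return table[ages[-1]]
        for lo, hi in zip(ages, ages[1:]):
            if lo <= age_years <= hi:
                w = (age_years - lo) / (hi - lo)
                return (1 - w) * table[lo] + w * table[hi]
        raise ConfigurationError(f"no urine volume rule covers age {age_years}")

    # -- manipulation ------------------------------------------------------
    def with_updates(self, **sections: Any) -> "ModelConfig":
        """Return a copy with top-level sections replaced/merged (one level deep)."""
        raw = copy.deepcopy(dict(self.raw))
        for key, value in sections.items():
            if isinstance(value, Mapping) and isinstance(raw.get(key), dict):
                raw[key].update(value)
            else:
                raw[key] = value
        return validate_config(raw)

    def content_hash(self) -> str:
        """Stable sha256 of the canonical JSON form, for provenance records."""
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def validate_config(raw: Mapping[str, Any]) -> ModelConfig:
    """Validate a raw mapping and return a :class:`ModelConfig`.

    Raises
    ------
    ConfigurationError
        Listing every missing compartment or malformed entry.
    """
    missing_sections = [
        s
        for s in ("reference_clearance", "cardiac_output", "blood", "compartments",
                  "bone_uptake", "daily_urine_volume_l")
        if s not in raw
    ]
    if missing_sections:
        raise ConfigurationError(f"config missing sections: {missing_sections}")

    comps = raw["compartments"]
    missing = [c for c in REQUIRED_COMPARTMENTS if c not in comps]
    if missing:
        raise ConfigurationError(f"config missing compartments: {missing}")
    bad_keys = {
        name: [k for k in _COMPARTMENT_KEYS if k not in spec]
        for name, spec in comps.items()
    }
    bad_keys = {k: v for k, v in bad_keys.items() if v}
    if bad_keys:
        raise ConfigurationError(f"compartment entries missing keys: {bad_keys}")

    for name, spec in comps.items():
        for k in _COMPARTMENT_KEYS:
            if float(spec[k]) <= 0:
                raise ConfigurationError(f"compartment {name}: {k} must be > 0")

    flow_sum = sum(float(spec["flow_fraction_co"]) for spec in comps.values())
    if abs(flow_sum - 1.0) > 1e-9:
        raise ConfigurationError(
            f"compartment flow fractions sum to {flow_sum:.6f}, must equal 1 "
            "(flows must balance cardiac output)"
        )

    vol_sum = float(raw["blood"]["volume_fraction_bw"]) + sum(
        float(spec["volume_fraction_bw"]) for spec in comps.values()
    )
    if vol_sum > 1.0:
        raise ConfigurationError(
            f"volume fractions sum to {vol_sum:.3f} of body weight (> 1)"
        )

    mode = raw["bone_uptake"].get("mode")
    if mode not in ("store", "sink"):
        raise ConfigurationError(f"bone_uptake.mode must be 'store' or 'sink', got {mode!r}")

    driving = raw.get("clearance_driving", {}).get("concentration", "arterial")
    if driving not in ("arterial", "venous"):
        raise ConfigurationError(
            f"clearance_driving.concentration must be 'arterial' or 'venous', got {driving!r}"
        )

    return ModelConfig(raw=dict(raw))


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML model configuration.

    With no argument, loads the bundled default configuration.
    """
    p = Path(path) if path is not None else data_path("default_config.yaml")
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{p}: top level must be a mapping")
    return validate_config(raw)


def default_config() -> ModelConfig:
    """The bundled default configuration (fresh copy each call)."""
    return load_config(None)
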