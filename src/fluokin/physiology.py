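"""Age-specific physiology for the reference 4- and 8-year-old children.

Body size comes from growth-chart 50th-percentile values; compartment
volumes and perfusion are fractions of body weight and cardiac output taken
from the model configuration; fluoride plasma clearance scales
allometrically with body weight to the 0.75 power and is split between bone
uptake and renal excretion along two straight lines in age — 90%/10%
(bone/renal) at birth converging to 50%/50% at age 18, the pattern observed
longitudinally in growing dogs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ModelConfig, default_config
from .errors import AgeRangeError, ConfigurationError, DomainError

#: Growth-chart 50th-percentile anthropometry for the built-in reference ages.
REFERENCE_ANTHROPOMETRY: dict[float, tuple[float, float]] = {
    4.0: (16.0, 103.0),   # (body weight kg, height cm)
    8.0: (25.0, 127.0),
}

_CLEARANCE_SLOPE = 40.0 / 18.0  # percentage points of plasma clearance per year


@dataclass(frozen=True)
class ChildPhysiology:
    """Anatomy and perfusion of one reference child.

    Attributes
    ----------
    age_years, body_weight, height
        Age (years), body weight (kg), height (cm).
    compartment_volumes
        Tissue volumes in L by compartment name (excludes blood).
    compartment_flows
        Tissue blood flows in L/min by compartment name.
    blood_volume, cardiac_output
        Whole-blood volume (L) and cardiac output (L/min).
    daily_urine_volume
        Urine output (L/day) used to convert excreted amounts to
        concentrations; calibration-sensitive.
    """

    age_years: float
    body_weight: float
    height: float
    compartment_volumes: dict[str, float]
    compartment_flows: dict[str, float]
    blood_volume: float
    cardiac_output: float
    daily_urine_volume: float

    def __post_init__(self) -> None:
        for name, v in self.compartment_volumes.items():
            if v <= 0:
                raise ConfigurationError(f"compartment {name}: volume must be > 0")
        for name, q in self.compartment_flows.items():
            if q <= 0:
                raise ConfigurationError(f"compartment {name}: flow must be > 0")
        if self.blood_volume <= 0 or self.cardiac_output <= 0:
            raise ConfigurationError("blood volume and cardiac output must be > 0")
        flow_sum = sum(self.compartment_flows.values())
        if abs(flow_sum - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ConfigurationError(
                f"compartment flows sum to {flow_sum:.6g} L/min but cardiac "
                f"output is {self.cardiac_output:.6g} L/min"
            )
        total_volume = sum(self.compartment_volumes.values()) + self.blood_volume
        if total_volume > self.body_weight:  # ~1 kg/L density
            raise ConfigurationError(
                f"total volume {total_volume:.3g} L exceeds body weight "
                f"{self.body_weight:.3g} kg"
            )


@dataclass(frozen=True)
class ClearanceSet:
    """Plasma clearance and its age-dependent bone/renal partition (L/min)."""

    plasma_clearance: float
    bone_fraction: float
    renal_fraction: float
    bone_clearance: float
    renal_clearance: float

    def __post_init__(self) -> None:
        if self.plasma_clearance <= 0:
            raise DomainError("plasma clearance must be > 0")
        if self.bone_fraction + self.renal_fraction != 1.0:
            raise ConfigurationError("bone and renal fractions must sum to 1 exactly")
        resid = abs(self.bone_clearance + self.renal_clearance - self.plasma_clearance)
        if resid > 1e-12 * self.plasma_clearance:
            raise ConfigurationError("bone + renal clearance must equal plasma clearance")

    @classmethod
    def from_fractions(cls, plasma_clearance: float, bone_fraction: float) -> "ClearanceSet":
        renal_fraction = 1.0 - bone_fraction
        return cls(
            plasma_clearance=plasma_clearance,
            bone_fraction=bone_fraction,
            renal_fraction=renal_fraction,
            bone_clearance=plasma_clearance * bone_fraction,
            renal_clearance=plasma_clearance * renal_fraction,
        )


def reference_anthropometry(
    age_years: float,
    overrides: dict[float, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Body weight (kg) and height (cm) of the reference child of a given age.

    Built-in values exist for ages 4 and 8 only; any other age must be
    supplied through ``overrides`` (mapping age -> (weight, height)).
    """
    table = dict(REFERENCE_ANTHROPOMETRY)
    if overrides:
        table.update({float(a): (float(w), float(h)) for a, (w, h) in overrides.items()})
    key = float(age_years)
    if key not in table:
        raise AgeRangeError(
            f"no reference anthropometry for age {age_years}; "
            f"supported ages: {sorted(table)} (pass overrides for others)"
        )
    return table[key]


def interpolated_anthropometry(age_years: float) -> tuple[float, float]:
    """Linear interpolation of (weight, height) between the reference ages.

    Used for validation cohorts at ages 5 and 7.  Beyond age 8 the 4-8
    chord is extrapolated (callers outside the validated range are expected
    to warn); defined on [4, 12].
    """
    if not 4.0 <= age_years <= 12.0:
        raise AgeRangeError(f"interpolated anthropometry defined on [4, 12], got {age_years}")
    (w4, h4), (w8, h8) = REFERENCE_ANTHROPOMETRY[4.0], REFERENCE_ANTHROPOMETRY[8.0]
    w = (age_years - 4.0) / 4.0
    return (1 - w) * w4 + w * w8, (1 - w) * h4 + w * h8


def clearance_fractions(age_years: float) -> tuple[float, float]:
    """(bone_fraction, renal_fraction) of plasma clearance at a given age.

    Bone falls linearly from 0.90 at birth to 0.50 at 18 years; renal rises
    from 0.10 to 0.50.  Only defined on [0, 18].
    """
    if not 0.0 <= age_years <= 18.0:
        raise AgeRangeError(f"clearance split defined on ages [0, 18], got {age_years}")
    bone = (90.0 - _CLEARANCE_SLOPE * age_years) / 100.0
    renal = 1.0 - bone
    return bone, renal


def scale_plasma_clearance(
    body_weight: float, reference_clearance: float, reference_bw: float
) -> float:
    """Allometric BW^0.75 scaling of plasma clearance from a reference body."""
    if body_weight <= 0 or reference_clearance <= 0 or reference_bw <= 0:
        raise DomainError("scale_plasma_clearance requires strictly positive inputs")
    return reference_clearance * (body_weight / reference_bw) ** 0.75


def build_clearances(age_years: float, body_weight: float, config: ModelConfig | None = None) -> ClearanceSet:
    """Age- and weight-scaled :class:`ClearanceSet` from a configuration."""
    cfg = config or default_config()
    plasma = scale_plasma_clearance(
        body_weight, cfg.reference_plasma_clearance, cfg.reference_body_weight
    )
    bone_fraction, _ = clearance_fractions(age_years)
    return ClearanceSet.from_fractions(plasma, bone_fraction)


def build_physiology(
    age_years: float,
    body_weight: float | None = None,
    height: float | None = None,
    config: ModelConfig | None = None,
) -> ChildPhysiology:
    """Assemble a :class:`ChildPhysiology` from configuration rules.

    Volumes are ``volume_fraction_bw * body_weight`` and flows are
    ``flow_fraction_co * cardiac_output`` with CO following the configured
    allometric rule.  Deterministic: identical inputs give identical output.
    """
    cfg = config or default_config()
    if body_weight is None or height is None:
        bw_ref, h_ref = reference_anthropometry(age_years)
        body_weight = body_weight if body_weight is not None else bw_ref
        height = height if height is not None else h_ref
    if body_weight <= 0:
        raise DomainError("body weight must be > 0")

    cardiac_output = cfg.cardiac_output_coefficient * body_weight ** cfg.cardiac_output_exponent
    volumes = {
        name: spec["volume_fraction_bw"] * body_weight
        for name, spec in cfg.compartments.items()
    }
    flows = {
        name: spec["flow_fraction_co"] * cardiac_output
        for name, spec in cfg.compartments.items()
    }
    # Remove float residue so the flow-balance invariant holds bitwise.
    flow_sum = sum(flows.values())
    if abs(flow_sum - cardiac_output) > 1e-9 * cardiac_output:
        raise ConfigurationError(
            "flow fractions do not balance cardiac output (checked at config load)"
        )
    return ChildPhysiology(
        age_years=age_years,
        body_weight=body_weight,
        height=height,
        compartment_volumes=volumes,
        compartment_flows=flows,
        blood_volume=cfg.blood_volume_fraction * body_weight,
        cardiac_output=flow_sum,
        daily_urine_volume=cfg.daily_urine_volume(age_years),
    )
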