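"""Model bundle: one child, one exposure, one parameterized PBPK model.

A :class:`ModelBundle` freezes everything needed to run the forward model —
age, anthropometry, configuration, exposure scenario, optional empirical
calibration factor — and exposes the derived physiology, clearances and
compartments.  Bundles are immutable; ``perturb`` returns a copy with a
named parameter scaled, which is the primitive the sensitivity analysis is
built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from types import MappingProxyType
from typing import Mapping

from .config import ModelConfig, default_config
from .errors import CalibrationError, ConfigurationError, DomainError
from .exposure import ExposureScenario, to_infusion_rate, total_absorbed_tdfi
from .pbpk import (
    CompartmentSpec,
    DoseSchedule,
    SimulationResult,
    auc_24h,
    build_compartments,
    simulate,
    steady_state_daily_excretion,
    urinary_concentration,
)
from .physiology import (
    ChildPhysiology,
    ClearanceSet,
    build_physiology,
    clearance_fractions,
    reference_anthropometry,
    scale_plasma_clearance,
)

#: Parameters the sensitivity analysis can perturb (each a multiplicative knob).
PERTURBABLE_PARAMETERS = (
    "body_weight",
    "oral_absorption_fraction",
    "renal_clearance",
    "bone_clearance",
    "cardiac_output",
    "blood_volume",
    "liver_volume",
    "kidney_volume",
    "bone_volume",
    "rest_of_body_volume",
    "mineral_partition",
    "water_intake",
    "diet_intake",
    "toothpaste_intake",
    "soil_intake",
    "air_intake",
)

_INTAKE_PARAMS = {
    "water_intake": "water",
    "diet_intake": "diet",
    "toothpaste_intake": "toothpaste",
    "soil_intake": "soil",
    "air_intake": "air",
}

_VOLUME_PARAMS = {
    "liver_volume": "liver",
    "kidney_volume": "kidney",
    "bone_volume": "bone",
    "rest_of_body_volume": "rest_of_body",
}


@dataclass(frozen=True)
class ModelBundle:
    """Immutable forward-model configuration for one child and exposure."""

    age_years: float
    scenario: ExposureScenario | None = None
    config: ModelConfig = field(default_factory=default_config)
    calibration_factor: float | None = None
    body_weight: float | None = None
    height: float | None = None
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.multipliers) - set(PERTURBABLE_PARAMETERS)
        if unknown:
            raise ConfigurationError(f"unknown perturbable parameters: {sorted(unknown)}")
        object.__setattr__(self, "multipliers", MappingProxyType(dict(self.multipliers)))
        if self.calibration_factor is not None and self.calibration_factor <= 0:
            raise CalibrationError("calibration factor must be > 0")

    # -- construction ------------------------------------------------------
    @classmethod
    def build(
        cls,
        age_years: float,
        scenario: ExposureScenario | None = None,
        config: ModelConfig | None = None,
        calibration_factor: float | None = None,
        body_weight: float | None = None,
        height: float | None = None,
    ) -> "ModelBundle":
        cfg = config or default_config()
        if body_weight is None:
            if scenario is not None:
                body_weight = scenario.body_weight
            else:
                body_weight, height = reference_anthropometry(age_years)
        return cls(
            age_years=age_years,
            scenario=scenario,
            config=cfg,
            calibration_factor=calibration_factor,
            body_weight=body_weight,
            height=height,
        )

    def _mult(self, name: str) -> float:
        return float(self.multipliers.get(name, 1.0))

    def perturb(self, parameter_name: str, factor: float) -> "ModelBundle":
        """Copy of the bundle with one named parameter multiplied by ``factor``."""
        if parameter_name not in PERTURBABLE_PARAMETERS:
            raise ConfigurationError(
                f"unknown parameter {parameter_name!r}; "
                f"perturbable: {PERTURBABLE_PARAMETERS}"
            )
        if factor <= 0:
            raise DomainError("perturbation factor must be > 0")
        mult = dict(self.multipliers)
        mult[parameter_name] = mult.get(parameter_name, 1.0) * factor
        return replace(self, multipliers=mult)

    def calibrated(self, factor: float) -> "ModelBundle":
        """Copy carrying the empirical adjustment factor for urinary outputs."""
        if self.calibration_factor is not None:
            raise CalibrationError("bundle already carries a calibration factor")
        return replace(self, calibration_factor=factor)

    # -- derived model pieces ---------------------------------------------
    @cached_property
    def effective_body_weight(self) -> float:
        bw = self.body_weight
        if bw is None:
            bw, _ = reference_anthropometry(self.age_years)
        return bw * self._mult("body_weight")

    @cached_property
    def physiology(self) -> ChildPhysiology:
        base = build_physiology(
            self.age_years,
            body_weight=self.effective_body_weight,
            height=self.height if self.height is not None else float("nan"),
            config=self.config,
        )
        co = base.cardiac_output * self._mult("cardiac_output")
        flows = {
            name: q * self._mult("cardiac_output")
            for name, q in base.compartment_flows.items()
        }
        volumes = dict(base.compartment_volumes)
        for pname, comp in _VOLUME_PARAMS.items():
            volumes[comp] = volumes[comp] * self._mult(pname)
        return replace(
            base,
            cardiac_output=co,
            compartment_flows=flows,
            compartment_volumes=volumes,
            blood_volume=base.blood_volume * self._mult("blood_volume"),
            daily_urine_volume=base.daily_urine_volume,
        )

    @cached_property
    def clearances(self) -> ClearanceSet:
        plasma = scale_plasma_clearance(
            self.effective_body_weight,
            self.config.reference_plasma_clearance,
            self.config.reference_body_weight,
        )
        bone_frac, renal_frac = clearance_fractions(self.age_years)
        cl_bone = plasma * bone_frac * self._mult("bone_clearance")
        cl_renal = plasma * renal_frac * self._mult("renal_clearance")
        total = cl_bone + cl_renal
        bone_fraction = cl_bone / total
        return ClearanceSet(
            plasma_clearance=total,
            bone_fraction=bone_fraction,
            renal_fraction=1.0 - bone_fraction,
            bone_clearance=cl_bone,
            renal_clearance=total - cl_bone,
        )

    @cached_property
    def compartments(self) -> tuple[CompartmentSpec, ...]:
        return build_compartments(self.physiology, self.config)

    @property
    def bone_mode(self) -> str:
        return self.config.bone_mode

    @property
    def mineral_partition(self) -> float:
        return self.config.mineral_partition * self._mult("mineral_partition")

    @property
    def daily_urine_volume(self) -> float:
        return self.config.daily_urine_volume(self.age_years)

    # -- dosing ------------------------------------------------------------
    @cached_property
    def effective_scenario(self) -> ExposureScenario | None:
        if self.scenario is None:
            return None
        scaled = self.scenario.scaled(
            {medium: self._mult(p) for p, medium in _INTAKE_PARAMS.items()}
        )
        return replace(scaled, body_weight=self.effective_body_weight)

    @cached_property
    def absorbed_daily_dose_mg(self) -> float:
        """Scenario absorbed dose (mg/day) including the oral-absorption knob."""
        if self.effective_scenario is None:
            raise ConfigurationError("bundle has no exposure scenario")
        tdfi = total_absorbed_tdfi(self.effective_scenario)  # ug/kg/day
        rate = to_infusion_rate(tdfi, self.effective_body_weight)
        return rate * 1440.0 * self._mult("oral_absorption_fraction")

    # -- forward runs ------------------------------------------------------
    def run(
        self,
        absorbed_dose_mg_day: float | None = None,
        duration_days: int = 150,
        checkpoint_min: float = 60.0,
        method: str = "exact",
    ) -> SimulationResult:
        """Simulate continuous exposure; dose defaults to the scenario's."""
        if absorbed_dose_mg_day is None:
            absorbed_dose_mg_day = self.absorbed_daily_dose_mg
        else:
            absorbed_dose_mg_day *= self._mult("oral_absorption_fraction")
        dose = DoseSchedule.from_daily_dose(absorbed_dose_mg_day)
        return simulate(
            self.physiology,
            self.clearances,
            self.compartments,
            dose,
            duration_days=duration_days,
            checkpoint_min=checkpoint_min,
            method=method,
            bone_mode=self.bone_mode,
            mineral_partition=self.mineral_partition,
            driving=self.config.clearance_driving,
        )

    @cached_property
    def _scenario_result_150(self) -> SimulationResult:
        return self.run(duration_days=150)

    def steady_state_excretion(
        self, calibrated: bool | None = None, result: SimulationResult | None = None
    ) -> float:
        """24-h urinary excretion at the day-150 steady state (mg/day).

        Applies the empirical adjustment factor when the bundle carries one
        (or when ``calibrated=True`` is requested explicitly).
        """
        if result is None:
            result = self._scenario_result_150
        value = steady_state_daily_excretion(result)
        if calibrated is None:
            calibrated = self.calibration_factor is not None
        if calibrated:
            if self.calibration_factor is None:
                raise CalibrationError("bundle carries no calibration factor")
            value *= self.calibration_factor
        return value

    def urinary_concentration(self, calibrated: bool | None = None) -> float:
        """Steady-state urinary concentration (mg/L) for the scenario."""
        return urinary_concentration(
            self.steady_state_excretion(calibrated=calibrated),
            self.daily_urine_volume,
        )

    def auc_vc_24h(self, day: int = 150) -> float:
        """AUC of venous concentration over the stated day (mg*min/L)."""
        return auc_24h(self._scenario_result_150, day)

    def excretion_for_dose(self, absorbed_dose_mg_kg_day: float) -> float:
        """Calibrated steady-state excretion (mg/day) at a given absorbed dose.

        The forward map inverted by reverse dosimetry.
        """
        if absorbed_dose_mg_kg_day < 0:
            raise DomainError("absorbed dose cannot be negative")
        dose_mg_day = absorbed_dose_mg_kg_day * self.effective_body_weight
        result = self.run(absorbed_dose_mg_day=dose_mg_day, duration_days=150)
        value = steady_state_daily_excretion(result)
        if self.calibration_factor is not None:
            value *= self.calibration_factor
        return value

    # -- introspection -----------------------------------------------------
    def parameter_value(self, name: str) -> float:
        """Baseline numeric value of a perturbable parameter (model units)."""
        if name == "body_weight":
            return self.effective_body_weight
        if name == "oral_absorption_fraction":
            return self._mult("oral_absorption_fraction")
        if name == "renal_clearance":
            return self.clearances.renal_clearance
        if name == "bone_clearance":
            return self.clearances.bone_clearance
        if name == "cardiac_output":
            return self.physiology.cardiac_output
        if name == "blood_volume":
            return self.physiology.blood_volume
        if name == "mineral_partition":
            return self.mineral_partition
        if name in _VOLUME_PARAMS:
            return self.physiology.compartment_volumes[_VOLUME_PARAMS[name]]
        if name in _INTAKE_PARAMS and self.effective_scenario is not None:
            medium = _INTAKE_PARAMS[name]
            for s in self.effective_scenario.sources:
                if s.medium == medium:
                    return s.water_l_day if medium == "water" else s.intake_ug_kg_day
            return 0.0
        raise ConfigurationError(f"unknown parameter {name!r}")
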