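"""Validation against published child urinary-excretion cohorts.

Six cohorts (ages 4-7, four countries) report estimated daily fluoride
intake by source together with measured 24-h urinary fluoride (AuF-24).
The forward model predicts AuF-24 for each cohort's absorbed intake; the
mean of the per-study measured/modeled ratios is the empirical adjustment
factor applied once to every subsequently reported urinary quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import fmean, geometric_mean

import pandas as pd

from .config import ModelConfig, data_path, default_config
from .errors import CalibrationError, DomainError, DoubleCalibrationError
from .exposure import DEFAULT_BIOAVAILABILITY
from .model import ModelBundle
from .physiology import interpolated_anthropometry

#: Fraction of each study-reported intake that reaches circulation.
#: Supplements are fluoride tablets taken as fully absorbed.
STUDY_BIOAVAILABILITY = {
    "diet": DEFAULT_BIOAVAILABILITY["diet"],
    "toothpaste": DEFAULT_BIOAVAILABILITY["toothpaste"],
    "water": DEFAULT_BIOAVAILABILITY["water"],
    "supplement": 1.0,
}


@dataclass(frozen=True)
class ValidationStudy:
    """One published cohort: per-source intake (mg/day) and measured AuF-24."""

    age_years: float
    n_children: int
    intake_diet: float
    intake_toothpaste: float
    intake_water: float
    intake_supplement: float
    measured_auf24: float
    country: str = ""

    def __post_init__(self) -> None:
        intakes = (
            self.intake_diet,
            self.intake_toothpaste,
            self.intake_water,
            self.intake_supplement,
        )
        if any(v < 0 for v in intakes):
            raise DomainError("intakes cannot be negative")
        if self.measured_auf24 <= 0:
            raise DomainError("measured AuF-24 must be > 0")
        if self.measured_auf24 >= sum(intakes):
            raise DomainError(
                "measured urinary excretion cannot exceed total intake "
                f"({self.measured_auf24} vs {sum(intakes)})"
            )

    @property
    def absorbed_intake_mg_day(self) -> float:
        """Bioavailability-weighted absorbed intake (mg/day)."""
        return (
            self.intake_diet * STUDY_BIOAVAILABILITY["diet"]
            + self.intake_toothpaste * STUDY_BIOAVAILABILITY["toothpaste"]
            + self.intake_water * STUDY_BIOAVAILABILITY["water"]
            + self.intake_supplement * STUDY_BIOAVAILABILITY["supplement"]
        )


@dataclass(frozen=True)
class CalibrationResult:
    """Per-study measured/modeled ratios and their mean, the adjustment factor."""

    per_study_ratio: tuple[float, ...]
    adjustment_factor: float
    mean_kind: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.adjustment_factor <= 0:
            raise CalibrationError("adjustment factor must be > 0")
        mean_fn = fmean if self.mean_kind == "arithmetic" else geometric_mean
        expected = mean_fn(self.per_study_ratio)
        if abs(expected - self.adjustment_factor) > 1e-12 * expected:
            raise CalibrationError("factor must equal the mean of the ratios")


@dataclass(frozen=True)
class CalibratedValue:
    """A urinary quantity with the adjustment factor already applied.

    Guards against applying the factor twice.
    """

    value: float
    factor: float


def load_validation_studies(path: str | Path | None = None) -> list[ValidationStudy]:
    """Read a validation-cohort table (bundled reference cohorts by default)."""
    p = Path(path) if path is not None else data_path("table1_validation_cohorts.tsv")
    frame = pd.read_csv(p, sep="\t")
    return [
        ValidationStudy(
            age_years=float(r.age_years),
            n_children=int(r.n_children),
            intake_diet=float(r.intake_diet_mg_day),
            intake_toothpaste=float(r.intake_toothpaste_mg_day),
            intake_water=float(r.intake_water_mg_day),
            intake_supplement=float(r.intake_supplement_mg_day),
            measured_auf24=float(r.measured_auf24_mg_day),
            country=str(r.country),
        )
        for r in frame.itertuples(index=False)
    ]


def study_bundle(study: ValidationStudy, config: ModelConfig | None = None) -> ModelBundle:
    """Uncalibrated model for a study's age (anthropometry interpolated)."""
    cfg = config or default_config()
    if study.age_years in (4.0, 8.0):
        from .physiology import reference_anthropometry

        bw, h = reference_anthropometry(study.age_years)
    else:
        bw, h = interpolated_anthropometry(study.age_years)
    return ModelBundle.build(
        study.age_years, scenario=None, config=cfg, body_weight=bw, height=h
    )


def predict_auf24(study: ValidationStudy, config: ModelConfig | None = None) -> float:
    """Uncalibrated model prediction of 24-h urinary fluoride (mg/day)."""
    import warnings

    if study.age_years > 8.0:
        warnings.warn(
            f"study age {study.age_years} exceeds the validated range (<= 8 years)",
            stacklevel=2,
        )
    absorbed = study.absorbed_intake_mg_day
    if absorbed == 0.0:
        return 0.0
    bundle = study_bundle(study, config)
    result = bundle.run(absorbed_dose_mg_day=absorbed, duration_days=150)
    from .pbpk import steady_state_daily_excretion

    return steady_state_daily_excretion(result)


def compute_adjustment_factor(
    studies: list[ValidationStudy],
    config: ModelConfig | None = None,
    mean_kind: str = "arithmetic",
) -> CalibrationResult:
    """Mean of per-study measured/modeled ratios over the validation cohorts.

    ``mean_kind`` may be ``"arithmetic"`` (default) or ``"geometric"``.
    """
    if not studies:
        raise CalibrationError("at least one validation study is required")
    if mean_kind not in ("arithmetic", "geometric"):
        raise DomainError(f"unknown mean kind {mean_kind!r}")
    ratios = []
    for study in studies:
        modeled = predict_auf24(study, config)
        if modeled <= 0:
            raise CalibrationError(
                f"modeled AuF-24 is non-positive for the {study.country} "
                f"{study.age_years}-year-old cohort"
            )
        ratios.append(study.measured_auf24 / modeled)
    mean_fn = fmean if mean_kind == "arithmetic" else geometric_mean
    return CalibrationResult(
        per_study_ratio=tuple(ratios),
        adjustment_factor=mean_fn(ratios),
        mean_kind=mean_kind,
    )


def apply_adjustment(prediction: float | CalibratedValue, factor: float) -> CalibratedValue:
    """Apply the empirical adjustment factor exactly once.

    Accepts a raw model prediction (mg/day or mg/L); re-applying to an
    already-calibrated value raises :class:`DoubleCalibrationError`.
    """
    if factor <= 0:
        raise CalibrationError("adjustment factor must be > 0")
    if isinstance(prediction, CalibratedValue):
        raise DoubleCalibrationError(
            "value already carries the adjustment factor; refusing to apply twice"
        )
    return CalibratedValue(value=prediction * factor, factor=factor)
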