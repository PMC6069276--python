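"""Synthetic inputs for testing the pipeline without any downloads.

Two generators and the bundled reference tables:

- lognormal spot-urine concentration samples with prescribed geometric mean
  and geometric standard deviation (the reporting convention of national
  biomonitoring surveys);
- validation cohorts with a known true multiplicative bias between
  measured and model-predicted excretion, for parameter-recovery tests of
  the calibration stage;
- checksummed machine-readable copies of the study's intake, validation and
  biomonitoring tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ValidationStudy, predict_auf24
from .config import ModelConfig, data_path
from .errors import DomainError, FixtureIntegrityError
from .reverse_dosimetry import BiomonitoringRecord

#: z-score of the 95th percentile; p95 = GM * GSD**P95_Z for a lognormal.
P95_Z = 1.6448536269514722


@dataclass(frozen=True)
class LognormalSpec:
    """Specification of a lognormal spot-urine concentration sample."""

    geometric_mean: float  # mg/L
    geometric_sd: float  # dimensionless, > 1
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.geometric_mean <= 0:
            raise DomainError("geometric mean must be > 0")
        if self.geometric_sd <= 1.0:
            raise DomainError("geometric SD must exceed 1")
        if self.n < 1:
            raise DomainError("sample size must be >= 1")

    @property
    def p95(self) -> float:
        """Closed-form 95th percentile of the specified distribution."""
        return self.geometric_mean * self.geometric_sd ** P95_Z


@dataclass(frozen=True)
class SyntheticCohort:
    """Validation cohorts generated with a known true bias."""

    true_bias: float
    studies: tuple[ValidationStudy, ...]
    noise_gsd: float
    seed: int


def sample_urinary_concentrations(
    spec: LognormalSpec, region: str = "synthetic", age_group_median: float = 4.0
) -> list[BiomonitoringRecord]:
    """Draw ``spec.n`` spot-urine concentrations as biomonitoring records.

    Reproducible for a given seed; all values strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    draws = rng.lognormal(
        mean=np.log(spec.geometric_mean), sigma=np.log(spec.geometric_sd), size=spec.n
    )
    return [
        BiomonitoringRecord(
            region=region,
            age_group_median=age_group_median,
            statistic="geometric_mean",
            urinary_concentration=float(c),
        )
        for c in draws
    ]


# Pool of plausible cohort designs the generator resamples from: per-source
# intake ranges (mg/day) roughly spanning the published validation cohorts.
_INTAKE_RANGES = {
    "diet": (0.05, 0.6),
    "toothpaste": (0.2, 1.2),
    "water": (0.02, 0.45),
}


def make_validation_cohort(
    true_bias: float,
    noise_gsd: float = 1.3,
    n_studies: int = 200,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> SyntheticCohort:
    """Generate cohorts whose measurements are ``bias x noise x prediction``.

    The multiplicative noise is lognormal with unit *arithmetic* mean
    (median exp(-sigma^2/2)), so the arithmetic mean of measured/modeled
    ratios is an unbiased estimator of ``true_bias`` and the calibration
    stage should recover it as ``n_studies`` grows.  ``noise_gsd = 1``
    means no noise.
    """
    if true_bias <= 0:
        raise DomainError("true bias must be > 0")
    if noise_gsd < 1.0:
        raise DomainError("noise GSD must be >= 1")
    rng = np.random.default_rng(seed)
    ages = np.round(rng.uniform(4.0, 8.0, size=n_studies), 1)

    # Predictions scale linearly with absorbed dose, so one simulation per
    # distinct age at unit dose prices every study of that age.
    slope_cache: dict[float, float] = {}

    def prediction(age: float, absorbed: float) -> float:
        if age not in slope_cache:
            probe = ValidationStudy(
                age_years=age, n_children=1, intake_diet=0.0, intake_toothpaste=1.0,
                intake_water=0.0, intake_supplement=0.0, measured_auf24=0.5,
                country="probe",
            )
            slope_cache[age] = predict_auf24(probe, config)  # per 1 mg/day toothpaste
        return slope_cache[age] * absorbed

    sigma = np.log(noise_gsd)
    studies = []
    for age in ages:
        intakes = {
            src: float(rng.uniform(*rng_range))
            for src, rng_range in _INTAKE_RANGES.items()
        }
        absorbed = (
            intakes["diet"] * 0.40 + intakes["toothpaste"] * 1.0 + intakes["water"] * 0.83
        )
        noise = 1.0 if sigma == 0.0 else float(
            rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        )
        measured = true_bias * noise * prediction(float(age), absorbed)
        # Keep the physical invariant measured < ingested intake.
        total_intake = sum(intakes.values())
        measured = min(measured, 0.999 * total_intake)
        studies.append(
            ValidationStudy(
                age_years=float(age),
                n_children=int(rng.integers(10, 60)),
                intake_diet=intakes["diet"],
                intake_toothpaste=intakes["toothpaste"],
                intake_water=intakes["water"],
                intake_supplement=0.0,
                measured_auf24=measured,
                country="synthetic",
            )
        )
    return SyntheticCohort(
        true_bias=true_bias,
        studies=tuple(studies),
        noise_gsd=noise_gsd,
        seed=seed,
    )


#: sha256 checksums of the bundled reference tables.
FIXTURE_CHECKSUMS = {
    "table1_validation_cohorts.tsv": "cf034db6d16b5f6205e53586c936e7353a9be8642c36021e3e59f63cb26927b1",
    "table2_child_exposure.tsv": "26e983c349c122d8369b7c08d39048710bb31b59a0dee238c8db9501128621f8",
    "table3_chms_urinary.tsv": "2516c5f1dcf16d05af07cbcfa8e2ba06153fb17f890faac224fff84e84a02c85",
}


def bundled_fixtures(verify: bool = True) -> dict[str, pd.DataFrame]:
    """Load the bundled reference tables, verifying checksums.

    Returns a mapping of fixture name (without extension) to DataFrame.
    """
    out = {}
    for fname, expected in FIXTURE_CHECKSUMS.items():
        p = data_path(fname)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if verify and digest != expected:
            raise FixtureIntegrityError(
                f"{fname}: checksum {digest} does not match packaged value"
            )
        out[fname.rsplit(".", 1)[0]] = pd.read_csv(p, sep="\t")
    return out


def export_fixtures(directory: str | Path) -> list[Path]:
    """Write the bundled tables as TSV files into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for fname in FIXTURE_CHECKSUMS:
        target = directory / fname
        target.write_bytes(data_path(fname).read_bytes())
        written.append(target)
    return written
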