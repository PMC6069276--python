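"""Multi-source fluoride exposure: intakes, bioavailability, scenarios.

Children ingest fluoride from toothpaste, diet, soil, air and drinking
water.  Each source carries its own oral bioavailability (water 0.83,
toothpaste 1.0, air 1.0, diet 0.40, soil 0.40); the absorbed total daily
fluoride intake (TDFI, ug/kg/day) is the bioavailability-weighted sum and
is what the PBPK model receives as a continuous liver infusion.

Three named population scenarios mirror the study design: Ontario-style
fluoridated water (scenario 1), Quebec's population-equivalent water at
0.06 mg/L (scenario 2), and the same with the dietary source removed
(scenario 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .config import data_path
from .errors import ConfigurationError, DomainError
from .pbpk import MINUTES_PER_DAY

#: Default oral bioavailability by exposure medium.
DEFAULT_BIOAVAILABILITY = {
    "water": 0.83,
    "air": 1.0,
    "toothpaste": 1.0,
    "diet": 0.40,
    "soil": 0.40,
}

MEDIA = tuple(DEFAULT_BIOAVAILABILITY)

#: Aggregate bioavailability for the intake -> absorbed-dose conversion of
#: population intake/TDI values (the water/diet mix implied by 0.04/0.05).
AGGREGATE_BIOAVAILABILITY = 0.8

#: Reference thresholds on the absorbed scale (mg/kg/day).
OPTIMAL_ABSORBED_DOSE = 0.04
ABSORBED_TDI_CANADA = 0.08
ABSORBED_TDI_AUNZ = 0.16


@dataclass(frozen=True)
class ExposureSource:
    """One fluoride source for one child.

    Mass-rate sources specify ``intake_ug_kg_day``; the water source instead
    specifies daily consumption (``water_l_day``) and a concentration
    (``concentration_mg_l``).
    """

    medium: str
    intake_ug_kg_day: float | None = None
    water_l_day: float | None = None
    concentration_mg_l: float | None = None
    bioavailability: float | None = None

    def __post_init__(self) -> None:
        if self.medium not in MEDIA:
            raise ConfigurationError(
                f"unknown medium {self.medium!r}; expected one of {MEDIA}"
            )
        if self.bioavailability is not None and not 0.0 <= self.bioavailability <= 1.0:
            raise DomainError("bioavailability must lie in [0, 1]")
        for label, value in (
            ("intake_ug_kg_day", self.intake_ug_kg_day),
            ("water_l_day", self.water_l_day),
            ("concentration_mg_l", self.concentration_mg_l),
        ):
            if value is not None and value < 0:
                raise DomainError(f"{label} cannot be negative")
        if self.medium == "water":
            if self.water_l_day is None:
                raise ConfigurationError("water source requires water_l_day")
        elif self.intake_ug_kg_day is None:
            raise ConfigurationError(f"{self.medium} source requires intake_ug_kg_day")

    @property
    def effective_bioavailability(self) -> float:
        if self.bioavailability is not None:
            return self.bioavailability
        return DEFAULT_BIOAVAILABILITY[self.medium]


@dataclass(frozen=True)
class ExposureScenario:
    """A complete exposure description for one child."""

    label: str
    age_years: float
    body_weight: float
    sources: tuple[ExposureSource, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        media = [s.medium for s in self.sources]
        if len(set(media)) != len(media):
            dupes = sorted({m for m in media if media.count(m) > 1})
            raise ConfigurationError(f"media listed more than once: {dupes}")
        if media.count("water") != 1:
            raise ConfigurationError("scenario must contain exactly one water source")
        if self.body_weight <= 0:
            raise DomainError("body weight must be > 0")

    @property
    def water_concentration(self) -> float:
        (water,) = [s for s in self.sources if s.medium == "water"]
        if water.concentration_mg_l is None:
            raise ConfigurationError("water source missing concentration")
        return water.concentration_mg_l

    def without(self, medium: str) -> "ExposureScenario":
        """Copy of the scenario with one non-water source removed."""
        if medium == "water":
            raise ConfigurationError("cannot remove the water source")
        return replace(
            self,
            label=f"{self.label}-no-{medium}",
            sources=tuple(s for s in self.sources if s.medium != medium),
        )

    def scaled(self, factors: dict[str, float]) -> "ExposureScenario":
        """Copy with per-medium intakes multiplied by the given factors."""
        sources = []
        for s in self.sources:
            f = factors.get(s.medium, 1.0)
            if s.medium == "water":
                sources.append(replace(s, water_l_day=s.water_l_day * f))
            else:
                sources.append(replace(s, intake_ug_kg_day=s.intake_ug_kg_day * f))
        return replace(self, sources=tuple(sources))


def equivalent_water_concentration(
    coverage: float, fluoridated_conc: float, background_conc: float
) -> float:
    """Population-average water fluoride when only a fraction is fluoridated.

    ``coverage`` of the population drinks water at ``fluoridated_conc`` and
    the remainder at ``background_conc`` (mg/L).
    """
    if not 0.0 <= coverage <= 1.0:
        raise DomainError("coverage must lie in [0, 1]")
    if fluoridated_conc < 0 or background_conc < 0:
        raise DomainError("concentrations cannot be negative")
    return coverage * fluoridated_conc + (1.0 - coverage) * background_conc


def absorbed_intake(source: ExposureSource, body_weight: float) -> float:
    """Absorbed intake from one source, in ug/kg/day."""
    if body_weight <= 0:
        raise DomainError("body weight must be > 0")
    f = source.effective_bioavailability
    if source.medium == "water":
        if source.concentration_mg_l is None:
            raise ConfigurationError("water source missing concentration")
        # L/day x mg/L -> mg/day -> ug/kg/day
        return source.water_l_day * source.concentration_mg_l * 1000.0 / body_weight * f
    return source.intake_ug_kg_day * f


def total_absorbed_tdfi(scenario: ExposureScenario) -> float:
    """Absorbed total daily fluoride intake of the scenario (ug/kg/day)."""
    return sum(absorbed_intake(s, scenario.body_weight) for s in scenario.sources)


def source_contributions(scenario: ExposureScenario) -> dict[str, float]:
    """Fraction of absorbed TDFI contributed by each source.

    The PBPK model is linear in dose, so these intake shares equal the
    shares of steady-state urinary excretion attributable to each source.
    """
    total = total_absorbed_tdfi(scenario)
    if total <= 0:
        raise DomainError("source contributions undefined for zero total intake")
    return {
        s.medium: absorbed_intake(s, scenario.body_weight) / total
        for s in scenario.sources
    }


def intake_to_absorbed(
    intake_mg_kg_day: float, aggregate_bioavailability: float = AGGREGATE_BIOAVAILABILITY
) -> float:
    """Convert a population intake value to the absorbed scale (mg/kg/day)."""
    if intake_mg_kg_day < 0:
        raise DomainError("intake cannot be negative")
    if not 0.0 < aggregate_bioavailability <= 1.0:
        raise DomainError("aggregate bioavailability must lie in (0, 1]")
    return intake_mg_kg_day * aggregate_bioavailability


def to_infusion_rate(total_absorbed_ug_kg_day: float, body_weight: float) -> float:
    """Absorbed TDFI (ug/kg/day) -> constant liver infusion rate (mg/min)."""
    if total_absorbed_ug_kg_day < 0 or body_weight < 0:
        raise DomainError("inputs cannot be negative")
    return total_absorbed_ug_kg_day * body_weight / 1000.0 / MINUTES_PER_DAY


def load_reference_intakes(path=None) -> pd.DataFrame:
    """Age-specific intake table (bundled reference values by default)."""
    p = path if path is not None else data_path("table2_child_exposure.tsv")
    return pd.read_csv(p, sep="\t")


#: Named water presets: (concentration mg/L, description).
WATER_PRESETS = {
    "fluoridated-tap": (0.7, "community-fluoridated tap water at 0.7 mg/L"),
    "ontario-population": (
        equivalent_water_concentration(0.70, 0.7, 0.05),
        "Ontario population equivalent (70% coverage at 0.7, background 0.05)",
    ),
    "quebec-population": (
        0.06,
        "Quebec population equivalent as reported (2.5% coverage; exact "
        "weighted mean is 0.06625 but the reported 0.06 is kept)",
    ),
}

SCENARIO_PRESETS = ("ontario-s1", "ontario-population", "quebec-s2", "quebec-s3")


def scenario_preset(name: str, age_years: float, intakes: pd.DataFrame | None = None) -> ExposureScenario:
    """Build one of the named population scenarios for a reference child.

    - ``ontario-s1``: all sources, water at the fluoridated-tap 0.7 mg/L
      (the concentration the scenario is labelled with and the one used for
      the water-contribution analysis).
    - ``ontario-population``: same, water at the 0.505 mg/L population
      equivalent.
    - ``quebec-s2``: all sources, water at 0.06 mg/L.
    - ``quebec-s3``: scenario 2 with the dietary source removed (water
      fluoride reaches food via preparation, so diet double-counts it in a
      low-fluoridation province).
    """
    if name not in SCENARIO_PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {SCENARIO_PRESETS}"
        )
    table = intakes if intakes is not None else load_reference_intakes()
    rows = table[table["age_years"] == age_years]
    if rows.empty:
        raise ConfigurationError(
            f"no reference intakes for age {age_years}; ages: "
            f"{sorted(table['age_years'].unique())}"
        )
    row = rows.iloc[0]

    water_conc = {
        "ontario-s1": WATER_PRESETS["fluoridated-tap"][0],
        "ontario-population": WATER_PRESETS["ontario-population"][0],
        "quebec-s2": WATER_PRESETS["quebec-population"][0],
        "quebec-s3": WATER_PRESETS["quebec-population"][0],
    }[name]

    sources = [
        ExposureSource("toothpaste", intake_ug_kg_day=float(row["toothpaste_ug_kg_day"])),
        ExposureSource("diet", intake_ug_kg_day=float(row["diet_ug_kg_day"])),
        ExposureSource("soil", intake_ug_kg_day=float(row["soil_ug_kg_day"])),
        ExposureSource("air", intake_ug_kg_day=float(row["air_ug_kg_day"])),
        ExposureSource(
            "water",
            water_l_day=float(row["water_l_day"]),
            concentration_mg_l=water_conc,
        ),
    ]
    scenario = ExposureScenario(
        label=name,
        age_years=age_years,
        body_weight=float(row["body_weight_kg"]),
        sources=tuple(sources),
    )
    if name == "quebec-s3":
        scenario = replace(scenario.without("diet"), label=name)
    return scenario
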