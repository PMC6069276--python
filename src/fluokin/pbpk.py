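"""Flow-limited compartmental kinetics of fluoride with liver infusion dosing.

The model is the simplified single-bone-compartment topology: well-mixed
blood; flow-limited liver, kidney, bone tissue and rest-of-body pools;
zero-order infusion of the absorbed daily dose into the liver spread over
24 h; renal clearance draining blood to urine; and a bone-mineral pool that
either equilibrates slowly with blood (``bone_mode="store"``, the default —
net bone flux vanishes at steady state and urinary recovery of the dose is
complete) or removes fluoride irreversibly (``bone_mode="sink"``, in which
case the steady-state urinary fraction is CL_renal/(CL_renal+CL_bone)).

The system is linear and time-invariant, so the default propagator advances
the augmented state with one matrix exponential per checkpoint step — exact
for any step size.  A stiff ODE-solver path (``method="ivp"``) is kept for
cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .config import ModelConfig, default_config
from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDurationError,
    IntegrationError,
)
from .physiology import ChildPhysiology, ClearanceSet

MINUTES_PER_DAY = 1440.0

#: Order of the perfused tissue compartments in the state vector.
TISSUES = ("liver", "kidney", "bone", "rest_of_body")

#: Full state layout: tissue amounts, blood, bone-mineral pool, cumulative urine.
STATE_NAMES = TISSUES + ("blood", "bone_mineral", "urine")


@dataclass(frozen=True)
class CompartmentSpec:
    """One perfused tissue: volume (L), blood flow (L/min), partition coefficient."""

    name: str
    volume: float
    blood_flow: float
    partition_coefficient: float

    def __post_init__(self) -> None:
        if min(self.volume, self.blood_flow, self.partition_coefficient) <= 0:
            raise ConfigurationError(
                f"compartment {self.name}: volume, flow and partition "
                "coefficient must all be > 0"
            )


@dataclass(frozen=True)
class DoseSchedule:
    """Constant liver infusion equivalent to an absorbed daily dose.

    ``infusion_rate`` is in mg/min; ``absorbed_daily_dose`` in mg/day.  The
    two are locked together (rate x 1440 = daily dose).
    """

    infusion_rate: float
    absorbed_daily_dose: float

    def __post_init__(self) -> None:
        if self.infusion_rate < 0:
            raise DomainError("infusion rate must be >= 0")
        expected = self.infusion_rate * MINUTES_PER_DAY
        scale = max(abs(self.absorbed_daily_dose), 1.0)
        if abs(expected - self.absorbed_daily_dose) > 1e-12 * scale:
            raise ConfigurationError(
                "infusion_rate x 1440 must equal absorbed_daily_dose"
            )

    @classmethod
    def from_daily_dose(cls, absorbed_daily_dose_mg: float) -> "DoseSchedule":
        if absorbed_daily_dose_mg < 0:
            raise DomainError("absorbed daily dose must be >= 0")
        return cls(
            infusion_rate=absorbed_daily_dose_mg / MINUTES_PER_DAY,
            absorbed_daily_dose=absorbed_daily_dose_mg,
        )


def build_compartments(
    physiology: ChildPhysiology, config: ModelConfig | None = None
) -> tuple[CompartmentSpec, ...]:
    """Tissue specs from a physiology and the configured partition coefficients."""
    cfg = config or default_config()
    specs = []
    for name in TISSUES:
        if name not in physiology.compartment_volumes:
            raise ConfigurationError(f"physiology lacks compartment {name!r}")
        specs.append(
            CompartmentSpec(
                name=name,
                volume=physiology.compartment_volumes[name],
                blood_flow=physiology.compartment_flows[name],
                partition_coefficient=cfg.compartments[name]["partition_coefficient"],
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class SimulationResult:
    """Time series output of one continuous-exposure simulation.

    All amounts in mg, concentrations in mg/L, time in minutes from the
    start of exposure.  ``per_day_excretion[d-1]`` is the urinary amount
    excreted during day ``d`` (1-based).
    """

    time_grid: np.ndarray
    arterial_concentration: np.ndarray
    venous_concentration: np.ndarray
    compartment_amounts: dict[str, np.ndarray]
    cumulative_urinary: np.ndarray
    cumulative_bone_uptake: np.ndarray
    per_day_excretion: np.ndarray
    infusion_rate: float
    duration_days: int
    checkpoint_min: float
    bone_mode: str = "store"
    calibrated: bool = field(default=False, compare=False)

    def validate(self, mass_rel_tol: float = 1e-3) -> None:
        """Check monotone cumulants and mass balance against total infused."""
        if np.any(np.diff(self.cumulative_urinary) < -1e-12):
            raise IntegrationError("cumulative urinary excretion decreased")
        if np.any(np.diff(self.cumulative_bone_uptake) < -1e-12):
            raise IntegrationError("cumulative bone uptake decreased")
        infused = self.infusion_rate * self.time_grid
        total = (
            sum(self.compartment_amounts.values())
            + self.cumulative_urinary
        )
        mask = infused > 0
        if self.infusion_rate == 0:
            if np.max(np.abs(total)) > 1e-12:
                raise IntegrationError("mass appeared without any dose")
            return
        err = np.max(np.abs(total[mask] - infused[mask]) / infused[mask])
        if err > mass_rel_tol:
            raise IntegrationError(
                f"mass balance violated: max relative error {err:.2e}"
            )

    def to_frame(self):
        """Tidy table of the simulation (pandas DataFrame, one row per checkpoint)."""
        import pandas as pd

        data = {
            "time_min": self.time_grid,
            "arterial_mg_per_l": self.arterial_concentration,
            "venous_mg_per_l": self.venous_concentration,
            "cumulative_urinary_mg": self.cumulative_urinary,
            "cumulative_bone_uptake_mg": self.cumulative_bone_uptake,
        }
        for name, series in self.compartment_amounts.items():
            data[f"amount_{name}_mg"] = series
        return pd.DataFrame(data)

    def summary(self) -> dict:
        """Compact JSON-ready summary of steady-state behaviour."""
        return {
            "duration_days": self.duration_days,
            "infusion_rate_mg_min": self.infusion_rate,
            "steady_state_daily_excretion_mg": float(self.per_day_excretion[-1]),
            "final_arterial_mg_per_l": float(self.arterial_concentration[-1]),
            "bone_mode": self.bone_mode,
        }


class _System:
    """Assembled coefficients of the linear fluoride disposition system."""

    def __init__(
        self,
        physiology: ChildPhysiology,
        clearances: ClearanceSet,
        compartments: tuple[CompartmentSpec, ...],
        dose: DoseSchedule,
        bone_mode: str = "store",
        mineral_partition: float = 150.0,
        driving: str = "arterial",
    ):
        if bone_mode not in ("store", "sink"):
            raise ConfigurationError(f"unknown bone_mode {bone_mode!r}")
        if driving not in ("arterial", "venous"):
            raise ConfigurationError(f"unknown driving concentration {driving!r}")
        by_name = {c.name: c for c in compartments}
        missing = [t for t in TISSUES if t not in by_name]
        if missing:
            raise ConfigurationError(f"missing compartment specs: {missing}")
        self.tissues = tuple(by_name[t] for t in TISSUES)
        self.blood_volume = physiology.blood_volume
        self.cardiac_output = sum(c.blood_flow for c in self.tissues)
        self.clearances = clearances
        self.dose = dose
        self.bone_mode = bone_mode
        self.driving = driving
        bone = by_name["bone"]
        self.mineral_capacity = bone.volume * mineral_partition  # L of blood-equivalent
        self.k_return = (
            clearances.bone_clearance / self.mineral_capacity
            if bone_mode == "store"
            else 0.0
        )

    # state layout: [liver, kidney, bone, rest_of_body, blood, bone_mineral, urine]
    def derivatives(self, state: np.ndarray) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (len(STATE_NAMES),):
            raise DomainError(
                f"state must have {len(STATE_NAMES)} components {STATE_NAMES}"
            )
        for name, value in zip(STATE_NAMES, state):
            if np.isnan(value):
                raise IntegrationError(f"state component {name!r} is NaN")
            if value < 0:
                raise IntegrationError(f"state component {name!r} is negative")

        amounts = state[: len(TISSUES)]
        a_blood, a_mineral = state[4], state[5]
        c_art = a_blood / self.blood_volume
        c_exit = np.array(
            [
                a / (c.volume * c.partition_coefficient)
                for a, c in zip(amounts, self.tissues)
            ]
        )
        flows = np.array([c.blood_flow for c in self.tissues])
        c_ven = float(flows @ c_exit) / self.cardiac_output
        c_drv = c_art if self.driving == "arterial" else c_ven

        rates = np.empty_like(state)
        rates[: len(TISSUES)] = flows * (c_art - c_exit)
        rates[0] += self.dose.infusion_rate  # absorbed dose enters the liver
        urine_rate = self.clearances.renal_clearance * c_drv
        uptake_rate = self.clearances.bone_clearance * c_drv
        return_rate = self.k_return * a_mineral
        rates[4] = (
            float(flows @ c_exit)
            - self.cardiac_output * c_art
            - urine_rate
            - uptake_rate
            + return_rate
        )
        rates[5] = uptake_rate - return_rate
        rates[6] = urine_rate
        return rates

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact (M, b) of dx/dt = M x + b, built from the derivative map."""
        n = len(STATE_NAMES)
        b = self.derivatives(np.zeros(n))
        m = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            m[:, j] = self.derivatives(e) - b
        return m, b

    def venous_series(self, states: np.ndarray) -> np.ndarray:
        flows = np.array([c.blood_flow for c in self.tissues])
        caps = np.array([c.volume * c.partition_coefficient for c in self.tissues])
        return (states[:, : len(TISSUES)] / caps) @ flows / self.cardiac_output


def derivatives(
    state,
    physiology: ChildPhysiology,
    clearances: ClearanceSet,
    compartments: tuple[CompartmentSpec, ...],
    dose: DoseSchedule,
    *,
    bone_mode: str = "store",
    mineral_partition: float = 150.0,
    driving: str = "arterial",
) -> np.ndarray:
    """Rate of change of the state vector (mg/min per component).

    State layout: ``(liver, kidney, bone, rest_of_body, blood, bone_mineral,
    urine)`` amounts in mg.  Raises :class:`IntegrationError` on NaN or
    negative components, naming the offender.
    """
    return _System(
        physiology, clearances, compartments, dose,
        bone_mode=bone_mode, mineral_partition=mineral_partition, driving=driving,
    ).derivatives(state)


def simulate(
    physiology: ChildPhysiology,
    clearances: ClearanceSet,
    compartments: tuple[CompartmentSpec, ...],
    dose: DoseSchedule,
    duration_days: int = 150,
    checkpoint_min: float = 60.0,
    *,
    method: str = "exact",
    bone_mode: str = "store",
    mineral_partition: float = 150.0,
    driving: str = "arterial",
) -> SimulationResult:
    """Simulate continuous exposure and return the full time series.

    Parameters
    ----------
    duration_days
        Length of the continuous-exposure simulation (>= 1).
    checkpoint_min
        Output grid step in minutes; must divide 1440 so day boundaries are
        exact grid points.
    method
        ``"exact"`` — matrix-exponential propagation (default, exact for
        this linear system); ``"ivp"`` — scipy BDF at rtol 1e-8 / atol
        1e-12 mg, used for cross-validation.
    """
    if duration_days < 1:
        raise DomainError("duration must be at least 1 day")
    steps_per_day = MINUTES_PER_DAY / checkpoint_min
    if abs(steps_per_day - round(steps_per_day)) > 1e-9 or checkpoint_min <= 0:
        raise DomainError("checkpoint_min must be a positive divisor of 1440")
    steps_per_day = int(round(steps_per_day))

    system = _System(
        physiology, clearances, compartments, dose,
        bone_mode=bone_mode, mineral_partition=mineral_partition, driving=driving,
    )
    n = len(STATE_NAMES)
    n_steps = duration_days * steps_per_day
    time_grid = np.arange(n_steps + 1) * checkpoint_min
    m, b = system.matrix()

    if method == "exact":
        # Augment with a constant channel so one expm handles the forcing.
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = m * checkpoint_min
        aug[:n, n] = b * checkpoint_min
        step = expm(aug)
        x = np.zeros(n + 1)
        x[n] = 1.0
        states = np.empty((n_steps + 1, n))
        states[0] = 0.0
        for k in range(1, n_steps + 1):
            x = step @ x
            states[k] = x[:n]
    elif method == "ivp":
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda _t, y: m @ y + b,
            (0.0, time_grid[-1]),
            np.zeros(n),
            method="BDF",
            jac=lambda _t, _y: m,
            rtol=1e-8,
            atol=1e-12,
            t_eval=time_grid,
        )
        if not sol.success:
            raise IntegrationError(
                f"stiff solver failed: {sol.message}",
                last_valid_time_min=float(sol.t[-1]) if sol.t.size else 0.0,
            )
        states = sol.y.T
    else:
        raise DomainError(f"unknown method {method!r}")

    # Exact propagation can leave ~1e-18 negative zeros; clamp before reporting.
    states = np.where(np.abs(states) < 1e-15, np.maximum(states, 0.0), states)

    amounts = {
        name: states[:, i].copy() for i, name in enumerate(STATE_NAMES[:-1])
    }
    cumulative_urinary = states[:, 6].copy()
    day_idx = np.arange(0, n_steps + 1, steps_per_day)
    per_day = np.diff(cumulative_urinary[day_idx])
    result = SimulationResult(
        time_grid=time_grid,
        arterial_concentration=states[:, 4] / system.blood_volume,
        venous_concentration=system.venous_series(states),
        compartment_amounts=amounts,
        cumulative_urinary=cumulative_urinary,
        cumulative_bone_uptake=states[:, 5].copy(),
        per_day_excretion=per_day,
        infusion_rate=dose.infusion_rate,
        duration_days=duration_days,
        checkpoint_min=checkpoint_min,
        bone_mode=bone_mode,
    )
    result.validate()
    return result


def steady_state_daily_excretion(result: SimulationResult, day: int = 150) -> float:
    """Urinary amount excreted during ``day`` (default: day 150 minus day 149).

    The 24-h steady-state excretion metric: cumulative urine at the end of
    the stated day minus cumulative urine one day earlier.
    """
    if result.duration_days < day:
        raise InsufficientDurationError(
            f"need at least {day} simulated days, have {result.duration_days}"
        )
    return float(result.per_day_excretion[day - 1])


def time_to_steady_state(result: SimulationResult, rel_tol: float = 0.01) -> int | None:
    """First day whose 24-h excretion is within ``rel_tol`` of the final day's.

    The tolerance band must hold from that day through the end of the
    simulated span.  Returns ``None`` when the band is only entered on the
    final day itself (steady state cannot be certified at the edge) or never
    at all.  ``rel_tol`` must lie in (0, 0.1].
    """
    if not 0.0 < rel_tol <= 0.1:
        raise DomainError("rel_tol must be in (0, 0.1]")
    series = result.per_day_excretion
    final = series[-1]
    if final == 0.0:
        if np.allclose(series, 0.0):
            return 1
        return None
    within = np.abs(series - final) <= rel_tol * abs(final)
    suffix_ok = np.flip(np.logical_and.accumulate(np.flip(within)))
    days = np.nonzero(suffix_ok)[0]
    if not days.size or days[0] == len(series) - 1:
        return None
    return int(days[0]) + 1


def auc_24h(result: SimulationResult, day_index: int) -> float:
    """Trapezoidal AUC of venous concentration over one day (mg*min/L)."""
    if not 1 <= day_index <= result.duration_days:
        raise DomainError(
            f"day_index {day_index} outside simulated span 1..{result.duration_days}"
        )
    t0, t1 = (day_index - 1) * MINUTES_PER_DAY, day_index * MINUTES_PER_DAY
    mask = (result.time_grid >= t0 - 1e-9) & (result.time_grid <= t1 + 1e-9)
    return float(
        np.trapezoid(result.venous_concentration[mask], result.time_grid[mask])
    )


def urinary_concentration(daily_excretion: float, daily_urine_volume: float) -> float:
    """Spot-equivalent urinary concentration (mg/L) at steady state."""
    if daily_urine_volume <= 0:
        raise DomainError("daily urine volume must be > 0")
    if daily_excretion < 0:
        raise DomainError("daily excretion cannot be negative")
    return daily_excretion / daily_urine_volume
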