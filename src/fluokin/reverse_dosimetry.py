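"""Reverse dosimetry: from spot-urine fluoride back to absorbed daily dose.

Under the steady-state assumption, a biomonitored urinary concentration is
converted to a 24-h excreted amount using the configured daily urine
volume, and the absorbed total daily fluoride intake is recovered as the
positive root of

    f(d) = calibrated steady-state excretion at dose d  -  target amount.

The solver is a bracketed scalar root find, mirroring the single-unknown
constrained-solver procedure the forward model was designed for; because
the model is linear in dose the closed-form solution ``target / slope`` is
also computed and serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import DomainError, NotConvergedError
from .exposure import (
    ABSORBED_TDI_AUNZ,
    ABSORBED_TDI_CANADA,
    OPTIMAL_ABSORBED_DOSE,
)
from .model import ModelBundle

#: Absorbed-dose reference values (mg/kg/day).
DEFAULT_THRESHOLDS = {
    "optimal": OPTIMAL_ABSORBED_DOSE,
    "tdi_canada_absorbed": ABSORBED_TDI_CANADA,
    "tdi_aunz_absorbed": ABSORBED_TDI_AUNZ,
}


@dataclass(frozen=True)
class BiomonitoringRecord:
    """A spot-urine fluoride concentration with its population labels."""

    region: str
    age_group_median: float
    statistic: str  # "geometric_mean" | "p95"
    urinary_concentration: float

    def __post_init__(self) -> None:
        if self.urinary_concentration <= 0:
            raise DomainError("urinary concentration must be > 0")
        if self.statistic not in ("geometric_mean", "p95"):
            raise DomainError(
                f"statistic must be 'geometric_mean' or 'p95', got {self.statistic!r}"
            )


@dataclass(frozen=True)
class InversionResult:
    """Recovered absorbed dose with convergence diagnostics."""

    absorbed_tdfi: float  # mg/kg/day
    converged: bool
    residual: float  # mg/day
    iterations: int

    def __post_init__(self) -> None:
        if self.converged and self.absorbed_tdfi <= 0:
            raise DomainError("a converged absorbed dose must be positive")


def conc_to_daily_amount(concentration: float, daily_urine_volume: float) -> float:
    """Urinary concentration (mg/L) x urine output (L/day) -> amount (mg/day)."""
    if concentration <= 0 or daily_urine_volume <= 0:
        raise DomainError("concentration and urine volume must be > 0")
    return concentration * daily_urine_volume


def invert_absorbed_dose(
    target_daily_amount: float,
    bundle: ModelBundle,
    bracket: tuple[float, float] = (1e-6, 1.0),
    tol: float = 1e-10,
    max_expansions: int = 4,
) -> InversionResult:
    """Solve for the absorbed dose (mg/kg/day) matching a 24-h urinary amount.

    Parameters
    ----------
    target_daily_amount
        Excreted urinary fluoride to reproduce (mg/day, > 0).
    bundle
        Forward model; its calibration factor (if any) is part of the map
        being inverted.
    bracket
        Initial dose bracket in mg/kg/day; expanded upward (x10, at most
        ``max_expansions`` times) if the target is not enclosed.
    tol
        Absolute tolerance on the residual (mg/day).
    """
    lo, hi = bracket
    if lo <= 0 or hi <= lo:
        raise DomainError("bracket must satisfy 0 < lo < hi")
    if target_daily_amount <= 0:
        raise DomainError("target daily amount must be > 0")

    evals = 0

    def f(dose: float) -> float:
        nonlocal evals
        evals += 1
        return bundle.excretion_for_dose(dose) - target_daily_amount

    f_lo, f_hi = f(lo), f(hi)
    expansions = 0
    while f_lo * f_hi > 0 and expansions < max_expansions:
        hi *= 10.0
        f_hi = f(hi)
        expansions += 1
    if f_lo * f_hi > 0:
        raise NotConvergedError(
            f"target {target_daily_amount} mg/day not bracketed by doses "
            f"[{lo}, {hi}] mg/kg/day",
            residual=min(abs(f_lo), abs(f_hi)),
        )

    root, info = brentq(f, lo, hi, xtol=1e-14, maxiter=200, full_output=True)
    residual = f(root)
    converged = bool(info.converged) and abs(residual) <= max(
        tol, 1e-9 * target_daily_amount
    )
    if not converged:
        raise NotConvergedError(
            f"root find did not converge (residual {residual:.3e} mg/day)",
            residual=abs(residual),
        )
    return InversionResult(
        absorbed_tdfi=float(root),
        converged=True,
        residual=float(residual),
        iterations=evals,
    )


def linear_dose_estimate(target_daily_amount: float, bundle: ModelBundle) -> float:
    """Closed-form inverse using dose linearity: target / slope at unit dose.

    Cross-check for :func:`invert_absorbed_dose`, not the primary path.
    """
    if target_daily_amount <= 0:
        raise DomainError("target daily amount must be > 0")
    slope = bundle.excretion_for_dose(1.0)  # mg/day per (mg/kg/day)
    return target_daily_amount / slope


def compare_to_thresholds(
    absorbed_tdfi: float, thresholds: dict[str, float] | None = None
) -> dict[str, str]:
    """Classify an absorbed dose against reference thresholds.

    Each threshold maps to ``"not reached"``, ``"reached"`` or
    ``"exceeded"``; no rounding is applied before comparison.
    """
    thr = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    if any(v <= 0 for v in thr.values()):
        raise DomainError("thresholds must be positive")
    out = {}
    for name, value in thr.items():
        if absorbed_tdfi > value:
            out[name] = "exceeded"
        elif absorbed_tdfi == value:
            out[name] = "reached"
        else:
            out[name] = "not reached"
    return out


def load_biomonitoring_records(path=None) -> list[BiomonitoringRecord]:
    """Read a biomonitoring table (bundled survey geometric means by default)."""
    import pandas as pd

    from .config import data_path

    p = path if path is not None else data_path("table3_chms_urinary.tsv")
    frame = pd.read_csv(p, sep="\t")
    return [
        BiomonitoringRecord(
            region=str(r.region),
            age_group_median=float(r.age_group_median),
            statistic=str(r.statistic),
            urinary_concentration=float(r.urinary_concentration_mg_l),
        )
        for r in frame.itertuples(index=False)
    ]


def invert_record(
    record: BiomonitoringRecord, bundle: ModelBundle
) -> tuple[InversionResult, dict[str, str]]:
    """Invert one biomonitoring record and classify the recovered dose."""
    amount = conc_to_daily_amount(
        record.urinary_concentration, bundle.daily_urine_volume
    )
    inv = invert_absorbed_dose(amount, bundle)
    return inv, compare_to_thresholds(inv.absorbed_tdfi)
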