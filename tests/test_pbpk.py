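import numpy as np
import pytest

from fluokin.errors import (
    DomainError,
    InsufficientDurationError,
    IntegrationError,
)
from fluokin.pbpk import (
    STATE_NAMES,
    DoseSchedule,
    SimulationResult,
    auc_24h,
    build_compartments,
    derivatives,
    simulate,
    steady_state_daily_excretion,
    time_to_steady_state,
    urinary_concentration,
)
from fluokin.physiology import build_clearances, build_physiology


@pytest.fixture(scope="module")
def model4(config):
    phys = build_physiology(4, config=config)
    clear = build_clearances(4, phys.body_weight, config)
    comps = build_compartments(phys, config)
    return phys, clear, comps


def _run(model4, dose_mg_day, days=150, step=60.0, **kw):
    phys, clear, comps = model4
    return simulate(
        phys, clear, comps, DoseSchedule.from_daily_dose(dose_mg_day),
        duration_days=days, checkpoint_min=step, **kw,
    )


def _synthetic_result(per_day, venous=None, step=60.0):
    """Minimal hand-built result for metric-function tests."""
    days = len(per_day)
    n = int(days * 1440 / step)
    t = np.arange(n + 1) * step
    venous = venous if venous is not None else np.zeros(n + 1)
    cum = np.concatenate([[0.0], np.cumsum(per_day)])
    zeros = np.zeros(n + 1)
    return SimulationResult(
        time_grid=t,
        arterial_concentration=venous,
        venous_concentration=venous,
        compartment_amounts={name: zeros for name in STATE_NAMES[:-1]},
        cumulative_urinary=np.interp(t, np.arange(days + 1) * 1440.0, cum),
        cumulative_bone_uptake=zeros,
        per_day_excretion=np.asarray(per_day, dtype=float),
        infusion_rate=0.0,
        duration_days=days,
        checkpoint_min=step,
    )


class TestDoseSchedule:
    def test_rate_and_daily_dose_locked(self):
        d = DoseSchedule.from_daily_dose(1.44)
        assert d.infusion_rate == pytest.approx(1e-3)
        assert d.infusion_rate * 1440 == pytest.approx(d.absorbed_daily_dose, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(DomainError):
            DoseSchedule.from_daily_dose(-0.1)


class TestDerivatives:
    def test_zero_state_zero_dose_is_equilibrium(self, model4):
        phys, clear, comps = model4
        rates = derivatives(
            np.zeros(len(STATE_NAMES)), phys, clear, comps,
            DoseSchedule.from_daily_dose(0.0),
        )
        assert np.allclose(rates, 0.0)

    def test_dose_enters_liver_only(self, model4):
        phys, clear, comps = model4
        dose = DoseSchedule.from_daily_dose(1.0)
        rates = derivatives(np.zeros(len(STATE_NAMES)), phys, clear, comps, dose)
        assert rates[0] == pytest.approx(dose.infusion_rate)
        assert np.allclose(rates[1:], 0.0)

    def test_total_mass_rate_is_zero_counting_urine(self, model4):
        # conservation: with zero dose, d(total incl. urine)/dt = 0
        phys, clear, comps = model4
        state = np.array([0.1, 0.02, 0.3, 0.5, 0.05, 2.0, 1.0])
        rates = derivatives(state, phys, clear, comps, DoseSchedule.from_daily_dose(0.0))
        assert np.sum(rates) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("bad, name", [(np.nan, "NaN"), (-0.1, "negative")])
    def test_invalid_state_names_offender(self, model4, bad, name):
        phys, clear, comps = model4
        state = np.zeros(len(STATE_NAMES))
        state[4] = bad  # blood
        with pytest.raises(IntegrationError, match=f"blood.*{name}"):
            derivatives(state, phys, clear, comps, DoseSchedule.from_daily_dose(0.0))


class TestSimulate:
    def test_zero_dose_everything_zero(self, model4):
        res = _run(model4, 0.0, days=5)
        assert np.all(res.arterial_concentration == 0.0)
        assert np.all(res.cumulative_urinary == 0.0)

    def test_dose_linearity_superposition(self, model4):
        r1 = _run(model4, 0.5, days=30)
        r2 = _run(model4, 1.0, days=30)
        np.testing.assert_allclose(
            r2.cumulative_urinary[1:], 2 * r1.cumulative_urinary[1:], rtol=1e-9
        )
        np.testing.assert_allclose(
            r2.arterial_concentration[1:], 2 * r1.arterial_concentration[1:], rtol=1e-9
        )

    def test_mass_balance_within_tolerance(self, model4):
        res = _run(model4, 1.0, days=150)
        infused = res.infusion_rate * res.time_grid[1:]
        total = sum(a[1:] for a in res.compartment_amounts.values())
        total = total + res.cumulative_urinary[1:]
        err = np.max(np.abs(total - infused) / infused)
        assert err < 1e-3  # criterion; the exact propagator is ~machine precision
        assert err < 1e-9

    def test_cumulative_series_monotone(self, model4):
        res = _run(model4, 1.0, days=60)
        assert np.all(np.diff(res.cumulative_urinary) >= 0)
        assert np.all(np.diff(res.cumulative_bone_uptake) >= -1e-12)

    def test_grid_robustness_of_steady_state_metric(self, model4):
        coarse = _run(model4, 1.0, days=150, step=120.0)
        fine = _run(model4, 1.0, days=150, step=60.0)
        a, b = (steady_state_daily_excretion(r) for r in (coarse, fine))
        assert abs(a - b) / b < 1e-3

    def test_exact_and_stiff_solver_agree(self, model4):
        exact = _run(model4, 1.0, days=20)
        ivp = _run(model4, 1.0, days=20, method="ivp")
        np.testing.assert_allclose(
            ivp.cumulative_urinary[1:], exact.cumulative_urinary[1:], rtol=1e-6
        )

    def test_sink_mode_steady_state_split_matches_closed_form(self, model4):
        # with irreversible bone uptake and both clearances driven by the
        # arterial concentration, the steady-state urinary fraction is
        # CL_renal / (CL_renal + CL_bone)
        phys, clear, comps = model4
        res = _run(model4, 1.0, days=150, bone_mode="sink")
        fraction = steady_state_daily_excretion(res) / 1.0
        expected = clear.renal_clearance / clear.plasma_clearance
        assert fraction == pytest.approx(expected, rel=0.01)

    def test_store_mode_recovers_dose_in_urine_at_steady_state(self, model4):
        res = _run(model4, 1.0, days=150, bone_mode="store")
        assert steady_state_daily_excretion(res) == pytest.approx(1.0, rel=0.01)

    def test_bad_checkpoint_rejected(self, model4):
        with pytest.raises(DomainError):
            _run(model4, 1.0, days=2, step=77.0)


class TestSteadyStateDailyExcretion:
    def test_requires_150_days(self, model4):
        res = _run(model4, 1.0, days=10)
        with pytest.raises(InsufficientDurationError):
            steady_state_daily_excretion(res)

    def test_constant_rate_series_returns_rate(self):
        res = _synthetic_result(np.full(150, 0.37))
        assert steady_state_daily_excretion(res) == pytest.approx(0.37)

    def test_doubling_dose_doubles_metric(self, model4):
        a = steady_state_daily_excretion(_run(model4, 0.5))
        b = steady_state_daily_excretion(_run(model4, 1.0))
        assert b == pytest.approx(2 * a, rel=1e-9)


class TestTimeToSteadyState:
    def test_exponential_approach_closed_form(self):
        # a(d) = A (1 - exp(-d/30)): tolerance 1% is reached on day 139
        days = np.arange(1, 301)
        res = _synthetic_result(1.0 - np.exp(-days / 30.0))
        assert time_to_steady_state(res, rel_tol=0.01) == 139

    def test_flat_series_is_day_one(self):
        res = _synthetic_result(np.full(200, 0.5))
        assert time_to_steady_state(res, rel_tol=0.01) == 1

    @pytest.mark.parametrize("tol", [0.0, -0.01, 0.2])
    def test_tolerance_domain(self, tol):
        res = _synthetic_result(np.full(10, 0.5))
        with pytest.raises(DomainError):
            time_to_steady_state(res, rel_tol=tol)

    def test_non_converged_returns_sentinel(self):
        # strictly growing series never stays within 1% of the final value
        res = _synthetic_result(np.linspace(0.1, 10.0, 50) ** 2)
        days = np.arange(1, 51)
        res = _synthetic_result(days**3.0)
        assert time_to_steady_state(res, rel_tol=0.01) is None


class TestAuc24h:
    def test_zero_dose_zero_auc(self, model4):
        res = _run(model4, 0.0, days=3)
        assert auc_24h(res, 2) == 0.0

    def test_constant_concentration_rectangle(self):
        res = _synthetic_result(np.zeros(3), venous=np.full(3 * 24 + 1, 0.2))
        assert auc_24h(res, 2) == pytest.approx(1440 * 0.2)

    def test_grid_refinement_agreement(self, model4):
        coarse = _run(model4, 1.0, days=150, step=120.0)
        fine = _run(model4, 1.0, days=150, step=15.0)
        assert auc_24h(coarse, 150) == pytest.approx(auc_24h(fine, 150), rel=1e-3)

    def test_day_outside_span_rejected(self, model4):
        res = _run(model4, 1.0, days=3)
        with pytest.raises(DomainError):
            auc_24h(res, 4)


class TestUrinaryConcentration:
    @pytest.mark.parametrize(
        "excretion, volume, expected",
        [(0.5, 0.5, 1.0), (0.423, 0.5, 0.846), (0.0, 0.5, 0.0)],
    )
    def test_ratio(self, excretion, volume, expected):
        assert urinary_concentration(excretion, volume) == pytest.approx(expected)

    def test_zero_volume_rejected(self):
        with pytest.raises(DomainError):
            urinary_concentration(0.5, 0.0)


class TestResultExport:
    def test_tidy_frame_and_summary(self, model4):
        res = _run(model4, 1.0, days=2)
        frame = res.to_frame()
        assert len(frame) == len(res.time_grid)
        assert {"time_min", "arterial_mg_per_l", "cumulative_urinary_mg"} <= set(
            frame.columns
        )
        summary = res.summary()
        assert summary["duration_days"] == 2
        assert summary["steady_state_daily_excretion_mg"] >= 0
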