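import numpy as np
import pytest

from respirisk.clearance import (ClearanceParameters, ExposureSchedule,
                                 RangeError, ScheduleError, _build_system,
                                 _propagator, local_concentration,
                                 regional_daily_max, simulate_retention)
from respirisk.deposition import deposition_profile, dose_rate_per_generation
from respirisk.geometry import ParticleProperties
from respirisk.scenarios import scenario_fixtures


@pytest.fixture(scope="module")
def phmg_rates(geometry):
    from respirisk.geometry import BreathingParameters
    b = BreathingParameters()
    sc = [s for s in scenario_fixtures() if s.name == "PHMG humidifier"][0]
    profile = deposition_profile(geometry, sc.particle, b)
    return dose_rate_per_generation(sc, profile, b)


class TestPropagator:
    def test_single_compartment_closed_form(self):
        """Matrix-exponential step reproduces m0*exp(-kt) to 1e-12."""
        k = 0.37
        for dt in (0.1, 10.0, 1440.0):
            e_hom, e_aff = _propagator(np.array([[-k]]), np.array([0.0]), dt)
            assert e_hom[0, 0] == pytest.approx(np.exp(-k * dt), rel=1e-12)
            assert e_aff[0] == 0.0

    def test_single_compartment_steady_state(self):
        """Constant source b with rate k relaxes to b/k."""
        k, b = 0.01, 5.0
        e_hom, e_aff = _propagator(np.array([[-k]]), np.array([b]), 1e6)
        x = e_hom[0, 0] * 0.0 + e_aff[0]
        assert x == pytest.approx(b / k, rel=1e-9)

    def test_zero_rate_accumulates_source(self):
        e_hom, e_aff = _propagator(np.array([[0.0]]), np.array([2.0]), 30.0)
        assert e_aff[0] == pytest.approx(60.0, rel=1e-12)


class TestSimulateRetention:
    def test_no_clearance_retains_all_deposit(self, phmg_rates):
        """With all rates zero, retained mass equals cumulative deposition."""
        params = ClearanceParameters.default().scaled(0.0)
        sched = ExposureSchedule(minutes_per_event=660.0, n_days=3)
        series = simulate_retention(phmg_rates, sched, params)
        retained = series.gen_mass.sum(axis=1) + series.et_mass
        np.testing.assert_allclose(retained, series.deposited_mass,
                                   rtol=1e-12, atol=1e-12)
        assert np.all(series.cleared_mass == 0.0)

    def test_mass_balance(self, phmg_rates):
        series = simulate_retention(
            phmg_rates, ExposureSchedule(minutes_per_event=660.0, n_days=12))
        assert series.mass_balance_error() < 1e-3

    def test_retained_mass_nonnegative_and_decays_between_events(
            self, phmg_rates):
        series = simulate_retention(
            phmg_rates, ExposureSchedule(minutes_per_event=660.0, n_days=4))
        assert np.all(series.gen_mass >= -1e-12)
        # total retained mass never grows while the source is off
        switch = series.schedule.day_switch_times()
        retained = series.gen_mass.sum(axis=1) + series.et_mass
        for i in range(1, len(series.times_min)):
            minute_of_day = series.times_min[i] % 1440.0 or 1440.0
            on = any(end == minute_of_day and o for end, o in switch)
            if not on:
                assert retained[i] <= retained[i - 1] + 1e-9

    def test_explicit_euler_oracle(self, phmg_rates):
        """Exact propagation matches a fine-step Euler integration."""
        params = ClearanceParameters.default()
        sched = ExposureSchedule(minutes_per_event=660.0, n_days=2)
        series = simulate_retention(phmg_rates, sched, params)

        A, b_on = _build_system(phmg_rates, params)
        dt = 0.01
        x = np.zeros(len(b_on))
        t = 0.0
        results = {}
        targets = set(np.round(series.times_min, 6))
        n_steps = int(round(2 * 1440.0 / dt))
        on_windows = [(d * 1440.0 + s, d * 1440.0 + s + 660.0)
                      for d in range(2) for s in sched.event_start_times]
        for _ in range(n_steps):
            on = any(lo <= t < hi for lo, hi in on_windows)
            x = x + dt * (A @ x + (b_on if on else 0.0))
            t += dt
            key = round(t, 6)
            if key in targets:
                results[key] = x.copy()

        scale = series.deposited_mass[-1]
        for i, tm in enumerate(series.times_min):
            key = round(float(tm), 6)
            if key in results and key > 0:
                exact = np.concatenate([
                    series.compartment_mass[i].ravel(),
                    [series.et_mass[i], series.cleared_mass[i]]])
                err = np.max(np.abs(exact - results[key])) / scale
                assert err < 1e-4

    def test_negative_dose_rate_rejected(self):
        bad = np.full(24, -1.0)
        with pytest.raises(ValueError):
            simulate_retention(bad, ExposureSchedule(minutes_per_event=60.0))


class TestSchedule:
    def test_overlapping_events_rejected(self):
        with pytest.raises(ScheduleError):
            ExposureSchedule(minutes_per_event=600.0, events_per_day=2,
                             event_start_times=[480.0, 600.0])

    def test_exposure_exceeding_day_rejected(self):
        with pytest.raises(ScheduleError):
            ExposureSchedule(minutes_per_event=800.0, events_per_day=2)


class TestLocalConcentration:
    def test_mass_over_area(self, geometry, phmg_rates):
        series = simulate_retention(
            phmg_rates, ExposureSchedule(minutes_per_event=660.0, n_days=2))
        conc = local_concentration(series, geometry)
        areas = geometry.surface_area_cm2
        np.testing.assert_allclose(conc.conc[:, 1:],
                                   series.gen_mass / areas[None, :],
                                   rtol=1e-12)

    def test_linearity_in_airborne_concentration(self, geometry, phmg_rates):
        sched = ExposureSchedule(minutes_per_event=660.0, n_days=2)
        c1 = local_concentration(simulate_retention(phmg_rates, sched),
                                 geometry)
        c2 = local_concentration(simulate_retention(2 * phmg_rates, sched),
                                 geometry)
        np.testing.assert_allclose(c2.conc, 2 * c1.conc, rtol=1e-9)

    def test_deep_lung_accumulates_while_upper_equilibrates(
            self, geometry, phmg_rates):
        """Upper-airway growth slows over days; AI generations keep rising."""
        series = simulate_retention(
            phmg_rates, ExposureSchedule(minutes_per_event=660.0, n_days=12))
        conc = local_concentration(series, geometry)
        summary = regional_daily_max(conc)
        lower = [summary.lower[d].value_ug_cm2 for d in (1, 4, 8, 12)]
        assert lower == sorted(lower)  # monotone accumulation
        upper = {d: summary.upper[d].value_ug_cm2 for d in (1, 4, 8, 12)}
        early_growth = upper[4] / upper[1]
        late_growth = upper[12] / upper[8]
        assert late_growth < 0.5 * early_growth  # approach to equilibrium


class TestRegionalDailyMax:
    def test_matches_brute_force_scan(self, geometry, phmg_rates):
        params = ClearanceParameters.default()
        series = simulate_retention(
            phmg_rates, ExposureSchedule(minutes_per_event=660.0, n_days=12),
            params)
        conc = local_concentration(series, geometry)
        summary = regional_daily_max(conc, params)
        last_end = 480.0 + 660.0
        for day in (1, 4, 8, 12):
            t_obs = (day - 1) * 1440.0 + last_end
            i = int(np.argmin(np.abs(conc.times_min - t_obs)))
            lower_cols = params.lower_generations()
            expected = max(conc.conc[i, g] for g in lower_cols)
            assert summary.lower[day].value_ug_cm2 == pytest.approx(expected)

    def test_uniform_concentration_tie_breaks_to_first(self, geometry):
        from respirisk.clearance import ConcentrationSeries
        sched = ExposureSchedule(minutes_per_event=60.0, n_days=1,
                                 observation_days=(1,))
        times = np.array([0.0, 480.0, 540.0, 1440.0])
        conc = ConcentrationSeries(times_min=times,
                                   conc=np.ones((4, 24)), schedule=sched)
        summary = regional_daily_max(conc, days=(1,))
        assert summary.upper[1].value_ug_cm2 == 1.0
        assert summary.upper[1].argmax_generation == 0      # ET first
        assert summary.lower[1].argmax_generation == 9      # first bb gen

    def test_no_clearance_max_nondecreasing_in_days(self, geometry,
                                                    phmg_rates):
        params = ClearanceParameters.default().scaled(0.0)
        series = simulate_retention(
            phmg_rates, ExposureSchedule(minutes_per_event=660.0, n_days=12),
            params)
        conc = local_concentration(series, geometry)
        summary = regional_daily_max(conc, params)
        for region in (summary.upper, summary.lower):
            vals = [region[d].value_ug_cm2 for d in (1, 4, 8, 12)]
            assert vals == sorted(vals)

    def test_day_beyond_horizon_rejected(self, geometry, phmg_rates):
        series = simulate_retention(
            phmg_rates, ExposureSchedule(minutes_per_event=660.0, n_days=2))
        conc = local_concentration(series, geometry)
        with pytest.raises(RangeError):
            regional_daily_max(conc, days=(5,))
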