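import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respirisk.deposition import (ConfigurationError, ExposureScenario,
                                  WrongRouteError, _monodisperse_profile,
                                  _physics_for_flow, deposition_profile,
                                  dose_rate_per_generation,
                                  lower_rt_deposition_peak,
                                  nasal_surface_dose)
from respirisk.geometry import (BreathingParameters, ParticleProperties,
                                toy_geometry)


def montecarlo_oracle(geometry, d_um, breathing, n_particles, seed):
    """Independent particle-tracking simulation of the transport model.

    Tracks individual particles stochastically through the same
    inhale/exhale path (Bernoulli capture per generation) instead of the
    analytic survival-probability quadrature.
    """
    rng = np.random.default_rng(seed)
    tab = geometry.table
    vol = tab["volume_ml"].to_numpy()
    cum_above = np.concatenate([[0.0], np.cumsum(vol)[:-1]])
    urt, v_t = breathing.urt_volume_ml, breathing.tidal_volume_ml
    phys_in = _physics_for_flow(geometry, d_um,
                                breathing.inspiratory_flow_ml_s, 1.0)
    phys_out = _physics_for_flow(geometry, d_um,
                                 breathing.expiratory_flow_ml_s, 1.0)

    v = rng.uniform(0.0, v_t, size=n_particles)
    depth = v_t - v
    frac = np.clip((depth[:, None] - urt - cum_above[None, :])
                   / vol[None, :], 0.0, 1.0)

    alive = np.ones(n_particles, dtype=bool)
    head_hits = 0
    gen_hits = np.zeros(len(tab))

    def head_pass(phys):
        nonlocal head_hits, alive
        hit = alive & (rng.uniform(size=n_particles) < phys.eta_head)
        head_hits += hit.sum()
        alive &= ~hit

    def gen_pass(g, phys):
        nonlocal alive
        p = np.where(
            frac[:, g] > 0,
            1.0 - (1.0 - phys.eta_imp[g]) * np.exp(-phys.k_sd[g] * frac[:, g]),
            0.0,
        )
        hit = alive & (rng.uniform(size=n_particles) < p)
        gen_hits[g] += hit.sum()
        alive &= ~hit

    head_pass(phys_in)
    for g in range(len(tab)):
        gen_pass(g, phys_in)
    for g in range(len(tab) - 1, -1, -1):
        gen_pass(g, phys_out)
    head_pass(phys_out)

    return (head_hits / n_particles, gen_hits / n_particles,
            alive.sum() / n_particles)


class TestDepositionProfile:
    def test_monte_carlo_oracle_on_toy_geometry(self, breathing):
        """Analytic serial-filter profile matches particle tracking to 2%."""
        geom = toy_geometry([10.0, 5.0, 2.0], [1.5, 1.0, 0.6])
        profile = _monodisperse_profile(geom, 3.0, breathing, 1.0, n_quad=2000)
        head_mc, gen_mc, exh_mc = montecarlo_oracle(
            geom, 3.0, breathing, n_particles=10**5, seed=42)
        np.testing.assert_allclose(profile.head_fraction, head_mc,
                                   rtol=0.02, atol=2e-3)
        np.testing.assert_allclose(profile.generation_fractions, gen_mc,
                                   rtol=0.02, atol=2e-3)
        np.testing.assert_allclose(profile.exhaled_fraction, exh_mc,
                                   rtol=0.02, atol=2e-3)

    @pytest.mark.parametrize("mmad", [0.05, 0.5, 1.0, 3.0, 5.5, 10.0, 30.0])
    @pytest.mark.parametrize("tidal", [500.0, 625.0, 1000.0])
    def test_mass_conservation(self, geometry, mmad, tidal):
        """Head + generations + exhaled = 1 to 1e-9 across the input grid."""
        b = BreathingParameters(tidal_volume_ml=tidal)
        profile = deposition_profile(geometry, ParticleProperties(mmad),
                                     b)
        assert profile.conservation_error() < 1e-9
        assert 0.0 <= profile.head_fraction <= 1.0
        assert np.all(profile.generation_fractions >= 0.0)
        assert 0.0 <= profile.exhaled_fraction <= 1.0

    def test_mechanism_monotonicity(self, geometry, breathing):
        """eta_sed/eta_imp grow and eta_diff falls with diameter >= 1 um."""
        diams = [1.0, 2.0, 4.0, 8.0, 16.0]
        profiles = [_monodisperse_profile(geometry, d, breathing, 1.0)
                    for d in diams]
        for a, b in zip(profiles, profiles[1:]):
            assert np.all(b.eta_sed >= a.eta_sed - 1e-12)
            assert np.all(b.eta_imp >= a.eta_imp - 1e-12)
            assert np.all(b.eta_diff <= a.eta_diff + 1e-12)

    def test_diffusion_dominates_for_ultrafine(self, geometry, breathing):
        profile = _monodisperse_profile(geometry, 0.011, breathing, 1.0)
        assert np.all(profile.eta_diff > 10 * profile.eta_sed)
        assert np.all(profile.eta_diff > 10 * profile.eta_imp)

    def test_coarse_particles_trapped_in_head(self, geometry, breathing):
        profile = _monodisperse_profile(geometry, 50.0, breathing, 1.0)
        assert profile.head_fraction > 0.9

    def test_polydisperse_converges_to_monodisperse(self, geometry, breathing):
        mono = deposition_profile(geometry, ParticleProperties(3.0, gsd=1.0),
                                  breathing)
        near = deposition_profile(geometry,
                                  ParticleProperties(3.0, gsd=1.001),
                                  breathing)
        assert np.max(np.abs(mono.generation_fractions
                             - near.generation_fractions)) < 1e-3
        assert abs(mono.head_fraction - near.head_fraction) < 1e-3


class TestLowerRTPeak:
    def test_peak_at_three_micron(self, geometry, breathing):
        """Sweeping 1-10 um, sub-head deposition is maximal at 3 um."""
        assert lower_rt_deposition_peak(
            geometry, breathing, list(range(1, 11))) == 3.0

    def test_single_element_grid(self, geometry, breathing):
        assert lower_rt_deposition_peak(geometry, breathing, [7.0]) == 7.0

    def test_argmax_invariant_to_worse_diameters(self, geometry, breathing):
        base = lower_rt_deposition_peak(geometry, breathing, [2.0, 3.0, 4.0])
        extended = lower_rt_deposition_peak(geometry, breathing,
                                            [2.0, 3.0, 4.0, 30.0, 60.0])
        assert base == extended

    def test_empty_grid_rejected(self, geometry, breathing):
        with pytest.raises(Exception):
            lower_rt_deposition_peak(geometry, breathing, [])


class TestDoseRate:
    def _scenario(self, conc):
        return ExposureScenario(
            name="x", route="aerosol", risk_label="low",
            airborne_concentration_mg_m3=conc,
            particle=ParticleProperties(5.5),
            minutes_per_event=660.0)

    def test_zero_concentration(self, geometry, breathing):
        profile = deposition_profile(geometry, ParticleProperties(5.5),
                                     breathing)
        rates = dose_rate_per_generation(self._scenario(0.0), profile,
                                         breathing)
        np.testing.assert_array_equal(rates, 0.0)

    def test_total_inhaled_rate(self, geometry, breathing):
        """0.95 mg/m3 at 7.5 L/min ventilation -> 7.125 ug/min inhaled."""
        profile = deposition_profile(geometry, ParticleProperties(5.5),
                                     breathing)
        rates = dose_rate_per_generation(self._scenario(0.95), profile,
                                         breathing)
        total = 0.95 * breathing.minute_ventilation_l_min
        assert total == pytest.approx(7.125)
        deposited = rates.sum()
        exhaled = total * profile.exhaled_fraction
        assert deposited + exhaled == pytest.approx(total, rel=1e-9)

    def test_wrong_route_rejected(self, geometry, breathing):
        profile = deposition_profile(geometry, ParticleProperties(5.5),
                                     breathing)
        nasal = ExposureScenario(name="n", route="nasal_spray",
                                 risk_label="low",
                                 delivered_mass_ug_per_event=80.0)
        with pytest.raises(WrongRouteError):
            dose_rate_per_generation(nasal, profile, breathing)


class TestNasalDose:
    def _scenario(self, mass, events=1):
        return ExposureScenario(name="n", route="nasal_spray",
                                risk_label="low",
                                delivered_mass_ug_per_event=mass,
                                events_per_day=events)

    def test_mass_over_area(self):
        assert nasal_surface_dose(self._scenario(80.0), 160.0) == \
            pytest.approx(0.5)

    def test_zero_mass(self):
        assert nasal_surface_dose(self._scenario(0.0), 160.0) == 0.0

    def test_daily_dose_linear_in_events(self):
        one = nasal_surface_dose(self._scenario(80.0, events=1), 160.0)
        two = nasal_surface_dose(self._scenario(80.0, events=2), 160.0)
        assert two == pytest.approx(2 * one)

    def test_missing_area_rejected(self):
        with pytest.raises(ConfigurationError):
            nasal_surface_dose(self._scenario(80.0), 0.0)

    def test_aerosol_route_rejected(self):
        aero = ExposureScenario(
            name="a", route="aerosol", risk_label="low",
            airborne_concentration_mg_m3=1.0,
            particle=ParticleProperties(3.0), minutes_per_event=10.0)
        with pytest.raises(WrongRouteError):
            nasal_surface_dose(aero, 160.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(mmad=st.floats(0.05, 40.0), tidal=st.floats(300.0, 1200.0),
       bpm=st.floats(8.0, 25.0))
def test_conservation_property(mmad, tidal, bpm):
    """Deposition fractions always partition unity, whatever the inputs."""
    b = BreathingParameters(breaths_per_min=bpm, tidal_volume_ml=tidal)
    from respirisk.geometry import build_airway_geometry
    geom = build_airway_geometry(b)
    profile = deposition_profile(geom, ParticleProperties(mmad), b, n_quad=50)
    assert profile.conservation_error() < 1e-9
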