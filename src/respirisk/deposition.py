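"""Per-generation aerosol deposition in the symmetric airway tree.

The transport model is a one-dimensional serial filter with volumetric
penetration.  Air is treated as an incompressible column moving at constant
inspiratory/expiratory flow; a particle entering the mouth at inhaled-volume
offset ``v`` (uniform on ``[0, V_T]``) penetrates to the airway depth where
the cumulative dead-space volume (URT, then generations in order, alveolar
volume included) equals ``V_T - v``, then retraces its path on exhalation.

Within each generation a particle is captured by three competing mechanisms:

* inertial impaction at the branching point, from the Stokes number and the
  branching angle (applied once per entry into the generation, both passes);
* gravitational sedimentation in an inclined tube, exponential in the
  settling velocity, residence time and gravity angle;
* Brownian diffusion, with the Gormley-Kennedy laminar-tube efficiency.

The combined single-pass capture probability is
``1 - (1 - eta_imp) * (1 - eta_sed) * (1 - eta_diff)``; partial traversal of
the deepest generation reached scales the sedimentation/diffusion exponents
by the traversed volume fraction.  Extrathoracic (head) capture uses a
semi-empirical sigmoid in ``d_a**2 * Q``, applied on both passes.  All
probabilities are partitioned exactly, so head + generations + exhaled
mass fractions sum to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import (
    AirwayGeometry,
    BreathingParameters,
    InvalidParameterError,
    ParticleProperties,
)

# Air and particle-physics constants (CGS, body temperature).
AIR_VISCOSITY_POISE = 1.81e-4
MEAN_FREE_PATH_UM = 0.0664
GRAVITY_CM_S2 = 981.0
KB_T_ERG = 1.38e-16 * 310.0

# Semi-empirical head (extrathoracic) capture: eta = 1 - 1/(1 + A*(d^2 Q)^P)
# with d in um and Q in L/min.  Constants are an ICRP-66-style fit to
# classic nasal-inhalation data (nose breathing is the reference-worker
# default of generation-resolved dosimetry models).
HEAD_COEF_A = 1.6e-3
HEAD_COEF_P = 1.1


class WrongRouteError(ValueError):
    """Raised when an operation is applied to a scenario of the wrong route."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureScenario:
    """One benchmark chemical-use pairing (airborne level, particle, schedule)."""

    name: str
    route: Literal["aerosol", "nasal_spray", "systemic"]
    risk_label: Literal["low", "high"]
    airborne_concentration_mg_m3: float | None = None
    particle: ParticleProperties | None = None
    minutes_per_event: float = 0.0
    events_per_day: int = 1
    n_days: int = 12
    cmax_uM: float | None = None
    delivered_mass_ug_per_event: float | None = None

    def __post_init__(self) -> None:
        if self.route == "aerosol":
            if self.airborne_concentration_mg_m3 is None or self.particle is None:
                raise ConfigurationError(
                    f"aerosol scenario {self.name!r} needs airborne concentration "
                    "and particle properties"
                )
            if self.airborne_concentration_mg_m3 < 0:
                raise ConfigurationError("airborne concentration must be >= 0")
        elif self.route == "systemic":
            if self.cmax_uM is None:
                raise ConfigurationError(
                    f"systemic scenario {self.name!r} needs a literature cmax_uM"
                )
        elif self.route == "nasal_spray":
            if self.delivered_mass_ug_per_event is None:
                raise ConfigurationError(
                    f"nasal scenario {self.name!r} needs delivered_mass_ug_per_event"
                )


@dataclass
class DepositionProfile:
    """Fractions of inhaled mass deposited per region, plus efficiencies.

    ``eta_imp``/``eta_sed``/``eta_diff`` are full-pass single-generation
    capture efficiencies at the inspiratory flow, for diagnostics and tests.
    """

    head_fraction: float
    generation_fractions: np.ndarray
    exhaled_fraction: float
    eta_imp: np.ndarray
    eta_sed: np.ndarray
    eta_diff: np.ndarray

    @property
    def lower_rt_fraction(self) -> float:
        """Total deposition below the head (all 23 generations)."""
        return float(self.generation_fractions.sum())

    def conservation_error(self) -> float:
        return abs(
            self.head_fraction + self.generation_fractions.sum() + self.exhaled_fraction
            - 1.0
        )


def cunningham_slip(d_um: np.ndarray | float) -> np.ndarray | float:
    kn = 2.0 * MEAN_FREE_PATH_UM / np.asarray(d_um, dtype=float)
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def settling_velocity_cm_s(d_um: float, density: float = 1.0) -> float:
    """Stokes terminal settling velocity with slip correction."""
    d_cm = d_um * 1e-4
    return (
        density
        * GRAVITY_CM_S2
        * d_cm**2
        * float(cunningham_slip(d_um))
        / (18.0 * AIR_VISCOSITY_POISE)
    )


def diffusion_coefficient_cm2_s(d_um: float) -> float:
    d_cm = d_um * 1e-4
    return KB_T_ERG * float(cunningham_slip(d_um)) / (
        3.0 * np.pi * AIR_VISCOSITY_POISE * d_cm
    )


def eta_impaction(stk: np.ndarray, branching_angle_rad: np.ndarray) -> np.ndarray:
    """Yeh-Schum bend impaction efficiency from Stokes number and angle."""
    x = np.clip(branching_angle_rad * stk, 0.0, 1.0)
    acx = np.arccos(x)
    return np.where(
        branching_angle_rad * stk >= 1.0,
        1.0,
        1.0 - (2.0 / np.pi) * acx + (1.0 / np.pi) * np.sin(2.0 * acx),
    )


def eta_sedimentation(
    v_settle: float, residence_s: np.ndarray, diameter_cm: np.ndarray,
    gravity_angle_rad: np.ndarray,
) -> np.ndarray:
    """Inclined-tube sedimentation, exponential Yeh-Schum form."""
    expo = (
        (8.0 / np.pi)
        * v_settle
        * residence_s
        * np.cos(gravity_angle_rad)
        / diameter_cm
    )
    return 1.0 - np.exp(-expo)


def eta_diffusion_gk(
    d_coef: float, residence_s: np.ndarray, radius_cm: np.ndarray
) -> np.ndarray:
    """Gormley-Kennedy diffusional capture for laminar tube flow.

    Parametrised by the dimensionless group ``x = D * t / (4 a**2)`` with
    ``t`` the mean residence time and ``a`` the tube radius.
    """
    x = d_coef * residence_s / (4.0 * radius_cm**2)
    small = x < 0.0156
    with np.errstate(invalid="ignore"):
        eta_small = 6.45 * x ** (2.0 / 3.0) - 4.8 * x - 1.123 * x ** (4.0 / 3.0)
    penetration = (
        0.8191 * np.exp(-14.63 * x)
        + 0.0975 * np.exp(-89.22 * x)
        + 0.0325 * np.exp(-228.0 * x)
    )
    return np.clip(np.where(small, eta_small, 1.0 - penetration), 0.0, 1.0)


def eta_head(d_um: float, flow_l_min: float) -> float:
    """Semi-empirical extrathoracic capture as a sigmoid in d_a**2 * Q."""
    g = d_um**2 * flow_l_min
    return 1.0 - 1.0 / (1.0 + HEAD_COEF_A * g**HEAD_COEF_P)


@dataclass
class _GenerationPhysics:
    """Per-generation capture rates for one diameter and one flow direction."""

    eta_imp: np.ndarray       # impaction probability per entry
    k_sd: np.ndarray          # sed+diff exponent for a full pass
    eta_head: float


def _physics_for_flow(
    geometry: AirwayGeometry, d_um: float, flow_ml_s: float, density: float
) -> _GenerationPhysics:
    tab = geometry.table
    diam = tab["diameter_cm"].to_numpy()
    count = tab["count"].to_numpy(dtype=float)
    vol = tab["volume_ml"].to_numpy()
    branch = np.deg2rad(tab["branching_angle_deg"].to_numpy())
    grav = np.deg2rad(tab["gravity_angle_deg"].to_numpy())

    # Tube velocity from the conducting cross-section; residence time from the
    # full generation volume (alveolar air moves with the column).
    u = flow_ml_s / (count * np.pi / 4.0 * diam**2)
    residence = vol / flow_ml_s

    v_s = settling_velocity_cm_s(d_um, density)
    d_b = diffusion_coefficient_cm2_s(d_um)

    stk = v_s * u / (GRAVITY_CM_S2 * diam)
    e_imp = eta_impaction(stk, branch)
    e_sed = eta_sedimentation(v_s, residence, diam, grav)
    e_dif = eta_diffusion_gk(d_b, residence, diam / 2.0)

    # Convert sed+diff to a common exponential rate so partial traversal of
    # the turnaround generation scales correctly.
    surv = np.clip((1.0 - e_sed) * (1.0 - e_dif), 1e-300, 1.0)
    k_sd = -np.log(surv)
    flow_l_min = flow_ml_s * 60.0 / 1000.0
    return _GenerationPhysics(
        eta_imp=e_imp, k_sd=k_sd, eta_head=eta_head(d_um, flow_l_min)
    )


def _monodisperse_profile(
    geometry: AirwayGeometry,
    d_um: float,
    breathing: BreathingParameters,
    density: float,
    n_quad: int = 200,
) -> DepositionProfile:
    tab = geometry.table
    n_gen = len(tab)
    vol = tab["volume_ml"].to_numpy()
    cum_above = np.concatenate([[0.0], np.cumsum(vol)[:-1]])  # volume above gen g
    urt = breathing.urt_volume_ml
    v_t = breathing.tidal_volume_ml

    phys_in = _physics_for_flow(
        geometry, d_um, breathing.inspiratory_flow_ml_s, density
    )
    phys_out = _physics_for_flow(
        geometry, d_um, breathing.expiratory_flow_ml_s, density
    )

    # Midpoint quadrature over the entry offset v in [0, V_T].
    v = (np.arange(n_quad) + 0.5) / n_quad * v_t          # (q,)
    depth = v_t - v                                        # penetration depth
    # Fraction of each generation's volume traversed by each parcel.
    frac = np.clip((depth[:, None] - urt - cum_above[None, :]) / vol[None, :], 0.0, 1.0)

    head = np.zeros(n_quad)
    gen = np.zeros((n_quad, n_gen))

    surv = np.ones(n_quad)
    # --- head, inspiratory
    head += surv * phys_in.eta_head
    surv *= 1.0 - phys_in.eta_head
    # --- inward pass
    for g in range(n_gen):
        enters = frac[:, g] > 0.0
        p_gen = np.where(
            enters,
            1.0
            - (1.0 - phys_in.eta_imp[g])
            * np.exp(-phys_in.k_sd[g] * frac[:, g]),
            0.0,
        )
        gen[:, g] += surv * p_gen
        surv *= 1.0 - p_gen
    # --- outward pass (reverse order, expiratory physics)
    for g in range(n_gen - 1, -1, -1):
        enters = frac[:, g] > 0.0
        p_gen = np.where(
            enters,
            1.0
            - (1.0 - phys_out.eta_imp[g])
            * np.exp(-phys_out.k_sd[g] * frac[:, g]),
            0.0,
        )
        gen[:, g] += surv * p_gen
        surv *= 1.0 - p_gen
    # --- head, expiratory
    head += surv * phys_out.eta_head
    surv *= 1.0 - phys_out.eta_head

    head_fraction = float(head.mean())
    gen_fractions = gen.mean(axis=0)
    exhaled = float(surv.mean())

    # Full-pass diagnostic efficiencies at the inspiratory flow.
    e_imp = phys_in.eta_imp
    residence = vol / breathing.inspiratory_flow_ml_s
    v_s = settling_velocity_cm_s(d_um, density)
    d_b = diffusion_coefficient_cm2_s(d_um)
    diam = tab["diameter_cm"].to_numpy()
    grav = np.deg2rad(tab["gravity_angle_deg"].to_numpy())
    e_sed = eta_sedimentation(v_s, residence, diam, grav)
    e_dif = eta_diffusion_gk(d_b, residence, diam / 2.0)

    return DepositionProfile(
        head_fraction=head_fraction,
        generation_fractions=gen_fractions,
        exhaled_fraction=exhaled,
        eta_imp=e_imp,
        eta_sed=e_sed,
        eta_diff=e_dif,
    )


def lognormal_mass_quadrature(
    mmad_um: float, gsd: float, n_nodes: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights over the mass-weighted size distribution."""
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    d = mmad_um * np.exp(x * np.log(gsd))
    w = w / w.sum()
    return d, w


def deposition_profile(
    geometry: AirwayGeometry,
    particle: ParticleProperties,
    breathing: BreathingParameters | None = None,
    n_quad: int = 200,
    n_size_nodes: int = 16,
) -> DepositionProfile:
    """Deposition fractions for a (possibly polydisperse) aerosol.

    Polydisperse aerosols (``gsd > 1``) are handled by Gauss-Hermite
    quadrature over the lognormal mass distribution; the profile is the
    mass-weighted average of monodisperse profiles.
    """
    breathing = breathing or BreathingParameters()
    if particle.gsd <= 1.0 + 1e-12:
        return _monodisperse_profile(
            geometry, particle.mmad_um, breathing, particle.density_g_cm3, n_quad
        )
    diams, weights = lognormal_mass_quadrature(
        particle.mmad_um, particle.gsd, n_size_nodes
    )
    diams = np.clip(diams, 0.011, 99.9)
    profiles = [
        _monodisperse_profile(geometry, float(d), breathing,
                              particle.density_g_cm3, n_quad)
        for d in diams
    ]
    head = float(sum(w * p.head_fraction for w, p in zip(weights, profiles)))
    gen = np.sum([w * p.generation_fractions for w, p in zip(weights, profiles)],
                 axis=0)
    exhaled = float(sum(w * p.exhaled_fraction for w, p in zip(weights, profiles)))
    mid = profiles[len(profiles) // 2]
    return DepositionProfile(
        head_fraction=head,
        generation_fractions=gen,
        exhaled_fraction=exhaled,
        eta_imp=mid.eta_imp,
        eta_sed=mid.eta_sed,
        eta_diff=mid.eta_diff,
    )


def lower_rt_deposition_peak(
    geometry: AirwayGeometry,
    breathing: BreathingParameters,
    diameters_um: Sequence[float],
) -> float:
    """Diameter (from the supplied grid) maximising total sub-head deposition."""
    diameters = list(diameters_um)
    if len(diameters) == 0:
        raise InvalidParameterError("diameter grid must be non-empty")
    fractions = []
    for d in diameters:
        prof = _monodisperse_profile(geometry, float(d), breathing, 1.0)
        fractions.append(prof.lower_rt_fraction)
    return float(diameters[int(np.argmax(fractions))])


def dose_rate_per_generation(
    scenario: ExposureScenario,
    profile: DepositionProfile,
    breathing: BreathingParameters | None = None,
) -> np.ndarray:
    """Deposited dose rate during exposure, ug/min: [head, gen 1..23].

    ``mg/m**3 * L/min`` is ``ug/min`` directly, so the total inhaled mass
    rate is the airborne concentration times the minute ventilation and is
    partitioned by the deposition fractions.
    """
    if scenario.route != "aerosol":
        raise WrongRouteError(
            f"dose_rate_per_generation requires an aerosol scenario, "
            f"got route={scenario.route!r}"
        )
    breathing = breathing or BreathingParameters()
    total_rate = (
        scenario.airborne_concentration_mg_m3 * breathing.minute_ventilation_l_min
    )
    fractions = np.concatenate([[profile.head_fraction],
                                profile.generation_fractions])
    return total_rate * fractions


def nasal_surface_dose(
    scenario: ExposureScenario, nasal_area_cm2: float = 160.0
) -> float:
    """Daily nasal-cavity surface dose (ug/cm**2) for a nasal-spray scenario.

    All delivered mass is assumed confined to the nasal cavity; the daily
    dose is the per-event mass divided by the nasal surface area, accumulated
    over the day's events.
    """
    if scenario.route != "nasal_spray":
        raise WrongRouteError(
            f"nasal_surface_dose requires a nasal_spray scenario, "
            f"got route={scenario.route!r}"
        )
    if nasal_area_cm2 is None or nasal_area_cm2 <= 0:
        raise ConfigurationError("nasal_area_cm2 must be positive")
    return (
        scenario.delivered_mass_ug_per_event / nasal_area_cm2 * scenario.events_per_day
    )
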