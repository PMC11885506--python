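"""Benchmark exposure scenarios and YAML round-trip helpers.

The bundled fixtures reproduce the published benchmark chemical-use
scenarios used to evaluate the toolbox: consumer sprays, occupational
silica exposures, the humidifier-disinfectant (PHMG) and tile-coating
(Akemi) poisoning incidents, two nasal sprays, and two systemically
administered drugs with literature plasma C_max values.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .deposition import ExposureScenario
from .geometry import ParticleProperties


def _aerosol(name, risk, conc, mmad, minutes, events=1, days=12):
    return ExposureScenario(
        name=name,
        route="aerosol",
        risk_label=risk,
        airborne_concentration_mg_m3=conc,
        particle=ParticleProperties(mmad_um=mmad),
        minutes_per_event=minutes,
        events_per_day=events,
        n_days=days,
    )


def scenario_fixtures(include_systemic: bool = False) -> list[ExposureScenario]:
    """The 12 inhaled/nasal benchmark scenarios (plus 2 systemic on request).

    Nasal sprays carry a delivered mass per event chosen so that the
    published surface dose (mass per area over a default 160 cm**2 nasal
    cavity) is reproduced: 1.25 ug/cm**2 for the CMC spray and 0.5 ug/cm**2
    for the BAC spray.
    """
    scenarios = [
        _aerosol("BE PVM/MA hair spray", "low", 0.017383, 8.53, 10.0),
        _aerosol("Coumarin anti-perspirant", "low", 0.00183, 5.22, 10.0, events=2),
        _aerosol("Acrylate copolymer hair spray", "low", 0.022518, 3.632, 10.0),
        _aerosol("Amorphous silica anti-perspirant", "low", 0.001461, 6.317, 10.0,
                 events=2),
        _aerosol("Amorphous silica occupational", "low", 6.0, 3.0, 480.0),
        _aerosol("BAC cleaning spray", "low", 0.0081, 7.0, 10.0),
        _aerosol("Crystalline silica occupational low", "low", 0.05, 3.0, 480.0),
        _aerosol("Crystalline silica occupational high", "high", 5.0, 3.0, 480.0),
        _aerosol("PHMG humidifier", "high", 0.95, 5.5, 660.0),
        _aerosol("Akemi tile coating", "high", 563.0, 3.0, 150.0),
        ExposureScenario(
            name="CMC nasal spray",
            route="nasal_spray",
            risk_label="low",
            delivered_mass_ug_per_event=200.0,   # 1.25 ug/cm2 over 160 cm2
            events_per_day=1,
            n_days=1,
        ),
        ExposureScenario(
            name="BAC nasal spray",
            route="nasal_spray",
            risk_label="low",
            delivered_mass_ug_per_event=80.0,    # 0.50 ug/cm2 over 160 cm2
            events_per_day=1,
            n_days=12,
        ),
    ]
    if include_systemic:
        scenarios += [
            ExposureScenario(
                name="Doxorubicin therapeutic", route="systemic",
                risk_label="high", cmax_uM=1.3,
            ),
            ExposureScenario(
                name="Amiodarone therapeutic", route="systemic",
                risk_label="high", cmax_uM=2.0,
            ),
        ]
    return scenarios


def scenario_to_dict(scenario: ExposureScenario) -> dict:
    d = asdict(scenario)
    return {k: v for k, v in d.items() if v is not None}


def scenario_from_dict(d: dict) -> ExposureScenario:
    d = dict(d)
    particle = d.pop("particle", None)
    if particle is not None:
        particle = ParticleProperties(**particle)
    return ExposureScenario(particle=particle, **d)


def write_scenarios_yaml(scenarios: list[ExposureScenario], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([scenario_to_dict(s) for s in scenarios], fh,
                       sort_keys=False)


def read_scenarios_yaml(path) -> list[ExposureScenario]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [scenario_from_dict(d) for d in raw]
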