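"""Pipeline orchestration: dosimetry -> PoD inference -> BER report.

Thin, file-oriented wrappers over the library stages so the command line,
the analysis scripts and the tests all run exactly the same code paths.
Every numeric artifact is JSON or long-format CSV; seeds and configuration
are recorded in each output's metadata so a run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ber import ExposureEstimate, compute_ber, lowest_pod, risk_summary
from .clearance import (ClearanceParameters, ExposureSchedule,
                        local_concentration, regional_daily_max,
                        simulate_retention)
from .dataset import BioactivityDataset
from .deposition import (deposition_profile, dose_rate_per_generation,
                         nasal_surface_dose)
from .geometry import BreathingParameters, build_airway_geometry
from .pod import derive_pod, posterior_predictive
from .scenarios import read_scenarios_yaml, scenario_fixtures
from .statespace import StateSpaceConfig, fit_state_space, normalize_dataset

log = logging.getLogger("respirisk")


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    profile: str = "desk_scale"          # or "paper_faithful"
    scenario_yaml: Path | None = None
    dataset_csvs: tuple[Path, ...] = ()
    clearance_yaml: Path | None = None
    cds_threshold: float = 0.5
    ber_threshold: float = 1.0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for p in [self.scenario_yaml, self.clearance_yaml, *self.dataset_csvs]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def statespace_config(self, **overrides) -> StateSpaceConfig:
        if self.profile == "paper_faithful":
            return StateSpaceConfig.paper_faithful(seed=self.seed, **overrides)
        return StateSpaceConfig.desk_scale(seed=self.seed, **overrides)


def _write_json(path: Path, payload: dict, seed: int) -> None:
    payload = {"seed": seed, **payload}
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def run_dosimetry(config: PipelineConfig) -> dict[str, dict]:
    """Exposure summaries (ug/cm2 per region per day) for every scenario.

    Returns the summary dict and writes one JSON per scenario plus a
    concentration CSV; logs the mass-balance check for each aerosol run.
    """
    scenarios = (read_scenarios_yaml(config.scenario_yaml)
                 if config.scenario_yaml else scenario_fixtures())
    if not scenarios:
        log.info("no scenarios configured; nothing to do")
        return {}
    breathing = BreathingParameters()
    geometry = build_airway_geometry(breathing)
    clearance = (ClearanceParameters.from_yaml(config.clearance_yaml)
                 if config.clearance_yaml else ClearanceParameters.default())
    outdir = config.outdir / "dosimetry"
    outdir.mkdir(parents=True, exist_ok=True)
    summaries: dict[str, dict] = {}
    for sc in scenarios:
        if sc.route == "systemic":
            summaries[sc.name] = {
                "route": sc.route, "risk_label": sc.risk_label,
                "cmax_uM": sc.cmax_uM,
            }
        elif sc.route == "nasal_spray":
            dose = nasal_surface_dose(sc, geometry.head_region.surface_area_cm2)
            summaries[sc.name] = {
                "route": sc.route, "risk_label": sc.risk_label,
                "upper_ug_cm2": {str(d): dose for d in (1, 4, 8, 12)
                                 if d <= sc.n_days or sc.n_days == 1},
            }
        else:
            profile = deposition_profile(geometry, sc.particle, breathing)
            cons_err = profile.conservation_error()
            log.info("mass-balance (deposition) %s: %s (err=%.2e)",
                     sc.name, "PASS" if cons_err < 1e-9 else "FAIL", cons_err)
            rates = dose_rate_per_generation(sc, profile, breathing)
            schedule = ExposureSchedule(
                minutes_per_event=sc.minutes_per_event,
                events_per_day=sc.events_per_day, n_days=sc.n_days,
            )
            series = simulate_retention(rates, schedule, clearance)
            bal = series.mass_balance_error()
            log.info("mass-balance (clearance) %s: %s (err=%.2e)",
                     sc.name, "PASS" if bal < 1e-3 else "FAIL", bal)
            conc = local_concentration(series, geometry)
            days = tuple(d for d in schedule.observation_days
                         if d <= sc.n_days)
            summary = regional_daily_max(conc, clearance, days)
            summaries[sc.name] = {
                "route": sc.route, "risk_label": sc.risk_label,
                "mass_balance_error": bal,
                "upper_ug_cm2": {str(d): v.value_ug_cm2
                                 for d, v in summary.upper.items()},
                "lower_ug_cm2": {str(d): v.value_ug_cm2
                                 for d, v in summary.lower.items()},
                "upper_argmax_generation": {str(d): v.argmax_generation
                                            for d, v in summary.upper.items()},
                "lower_argmax_generation": {str(d): v.argmax_generation
                                            for d, v in summary.lower.items()},
                "upper_intraday_ug_cm2": {str(d): v.intraday_max_ug_cm2
                                          for d, v in summary.upper.items()},
                "lower_intraday_ug_cm2": {str(d): v.intraday_max_ug_cm2
                                          for d, v in summary.lower.items()},
            }
        _write_json(outdir / f"{_slug(sc.name)}.json",
                    summaries[sc.name], config.seed)
    _write_json(outdir / "summary.json", {"scenarios": summaries}, config.seed)
    return summaries


def run_pod(config: PipelineConfig) -> dict[str, list]:
    """Fit the state-space model per dataset CSV and write PoD results."""
    if not config.dataset_csvs:
        log.info("no dataset CSVs configured; nothing to do")
        return {}
    outdir = config.outdir / "pod"
    outdir.mkdir(parents=True, exist_ok=True)
    ss_config = config.statespace_config()
    results: dict[str, list] = {}
    for path in config.dataset_csvs:
        dataset = BioactivityDataset.from_csv(path)
        norm, _ = normalize_dataset(dataset)
        samples = fit_state_space(norm, ss_config)
        per_readout = []
        materials = sorted({m for m, c in norm.series if c > 0})
        for material in materials:
            predictive = posterior_predictive(samples, material)
            per_readout.extend(derive_pod(predictive))
        results[dataset.readout] = per_readout
        payload = {
            "readout": dataset.readout,
            "max_rhat": samples.max_rhat,
            "rhat_table": samples.rhat_table,
            "results": [
                {
                    "material": r.material, "timepoint": r.timepoint,
                    "cds": r.cds, "es_increase": r.es_increase,
                    "es_decrease": r.es_decrease, "median_pod": r.median_pod,
                    "ci_low": r.ci_low, "ci_high": r.ci_high,
                }
                for r in per_readout
            ],
        }
        _write_json(outdir / f"{_slug(dataset.readout)}.json", payload,
                    config.seed)
    return results


def run_ber(config: PipelineConfig) -> "pd.DataFrame":
    """Combine dosimetry summaries and PoD results into the BER report."""
    import pandas as pd

    dos_path = config.outdir / "dosimetry" / "summary.json"
    pod_dir = config.outdir / "pod"
    if not dos_path.exists() or not pod_dir.exists():
        raise DependencyError(
            "run_ber needs dosimetry and pod outputs; run those stages first")
    with open(dos_path) as fh:
        dosimetry = json.load(fh)["scenarios"]
    pod_payloads = [json.loads(p.read_text()) for p in sorted(
        pod_dir.glob("*.json"))]

    records = []
    no_bioactivity = []
    for name, summary in dosimetry.items():
        pods = []
        for payload in pod_payloads:
            for r in payload["results"]:
                if r["median_pod"] is not None and r["cds"] > config.cds_threshold:
                    pods.append((payload["readout"], r["median_pod"], r["cds"]))
        if not pods:
            no_bioactivity.append(name)
            continue
        readout, pod_value, _ = min(pods, key=lambda x: x[1])
        if summary["route"] == "systemic":
            exposure = summary["cmax_uM"]
        else:
            region = "upper_ug_cm2"
            if summary["route"] == "aerosol" and "lower_ug_cm2" in summary:
                region = "lower_ug_cm2"
            exposure = max(summary[region].values())
        if exposure <= 0:
            no_bioactivity.append(name)
            continue
        est = ExposureEstimate(
            scenario=name,
            metric="plasma_uM" if summary["route"] == "systemic"
            else "lung_surface_ug_cm2",
            value=float(exposure),
        )
        records.append(compute_ber(pod_value, est, readout=readout))

    if records:
        report = risk_summary(records, threshold=config.ber_threshold)
        table = report.table
    else:
        table = pd.DataFrame(columns=["scenario", "min_ber", "flagged"])
    for name in no_bioactivity:
        table = pd.concat([table, pd.DataFrame([{
            "scenario": name, "min_ber": np.nan, "flagged": False,
            "tissue_model": "", "readout": "no observed bioactivity",
            "day": None,
        }])], ignore_index=True)
    outdir = config.outdir / "ber"
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "ber_table.csv", index=False)
    _write_json(outdir / "ber_report.json",
                {"threshold": config.ber_threshold,
                 "rows": table.where(table.notna(), None).to_dict("records")},
                config.seed)
    return table


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name.lower()).strip("_")
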