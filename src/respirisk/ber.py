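"""Bioactivity-exposure-ratio (BER) integration and risk ranking.

The BER for a chemical-use scenario is the lowest in vitro PoD (among
readouts whose Concentration Dependency Score passes the decision
threshold) divided by the predicted human exposure for the matching
compartment: upper-airway tissue PoDs against the upper-respiratory-tract
surface concentration, alveolar tissue PoDs against the lower-tract
concentration, and systemic drugs against the literature plasma C_max.
A small BER means bioactivity at (or below) real exposure levels; scenarios
whose minimum BER falls under the classification threshold are flagged as
potential risks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

from .pod import PoDResult

matplotlib.use("Agg")


class UnitError(ValueError):
    pass


class UndefinedBERError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureEstimate:
    """One exposure value to ratio a PoD against."""

    scenario: str
    metric: str                      # "lung_surface_ug_cm2" | "plasma_uM"
    value: float
    region: str = ""                 # "upper" | "lower" | "" for plasma
    day: int | None = None
    provenance: str = "modelled"     # or "literature"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("exposure value must be >= 0")


@dataclass
class BERRecord:
    scenario: str
    tissue_model: str
    readout: str
    lowest_pod: float
    exposure: float
    ber: float
    day: int | None
    includes_transcriptomics: bool
    cds_filtered: bool = True


def lowest_pod(
    pods: list[PoDResult],
    cds_threshold: float = 0.5,
    include_transcriptomics: bool = True,
    units: list[str] | None = None,
) -> tuple[str, float] | None:
    """Minimum median PoD among results passing the CDS decision rule.

    Transcriptomic readouts (named ``LV*``) can be excluded to mirror the
    readout-panel variants of the ratio rules.  Returns ``None`` when no
    readout shows a concentration-dependent effect.
    """
    if units is not None and len(set(units)) > 1:
        raise UnitError(f"mixed PoD units: {sorted(set(units))}")
    candidates = [
        p for p in pods
        if p.cds > cds_threshold and p.median_pod is not None
        and (include_transcriptomics or not p.readout.startswith("LV"))
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda p: p.median_pod)
    return best.readout, float(best.median_pod)


def compute_ber(
    lowest_pod_value: float,
    exposure: ExposureEstimate,
    day: int | None = None,
    tissue_model: str = "",
    readout: str = "",
    includes_transcriptomics: bool = True,
) -> BERRecord:
    """BER = lowest PoD / exposure for one matched (model, region) pair."""
    if exposure.value == 0:
        raise UndefinedBERError(
            f"exposure for {exposure.scenario!r} is zero; BER undefined")
    return BERRecord(
        scenario=exposure.scenario,
        tissue_model=tissue_model,
        readout=readout,
        lowest_pod=lowest_pod_value,
        exposure=exposure.value,
        ber=lowest_pod_value / exposure.value,
        day=day if day is not None else exposure.day,
        includes_transcriptomics=includes_transcriptomics,
    )


@dataclass
class RiskReport:
    table: pd.DataFrame              # one row per scenario
    threshold: float

    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "scenario"])


def risk_summary(
    records: list[BERRecord], threshold: float = 1.0
) -> RiskReport:
    """Minimum BER per scenario and the potential-risk classification.

    A scenario is flagged when its minimum BER across tissue models and
    observation days falls below the threshold (default 1; 3 is the
    precedent-based conservative option).  Permutation-invariant in the
    record order.
    """
    if not records:
        raise ValueError("need at least one BER record")
    rows = []
    for scenario in sorted({r.scenario for r in records}):
        recs = [r for r in records if r.scenario == scenario]
        best = min(recs, key=lambda r: r.ber)
        rows.append({
            "scenario": scenario,
            "min_ber": best.ber,
            "tissue_model": best.tissue_model,
            "readout": best.readout,
            "day": best.day,
            "flagged": best.ber < threshold,
        })
    table = pd.DataFrame(rows).sort_values("min_ber").reset_index(drop=True)
    return RiskReport(table=table, threshold=threshold)


def plot_pod_exposure(
    pods_by_scenario: dict[str, list[PoDResult]],
    exposures: dict[str, float],
    path,
    cds_threshold: float = 0.5,
) -> None:
    """Dot plot of median PoDs per scenario with exposure reference lines."""
    import matplotlib.pyplot as plt

    scenarios = sorted(pods_by_scenario)
    fig, ax = plt.subplots(figsize=(8, 0.6 * len(scenarios) + 2))
    for i, sc in enumerate(scenarios):
        pods = [p for p in pods_by_scenario[sc]
                if p.cds > cds_threshold and p.median_pod is not None]
        ax.scatter([p.median_pod for p in pods], [i] * len(pods),
                   s=25, color="tab:blue", zorder=3)
        if sc in exposures and exposures[sc] > 0:
            ax.plot([exposures[sc]] * 2, [i - 0.3, i + 0.3],
                    color="tab:red", lw=2, zorder=2)
    ax.set_yticks(range(len(scenarios)))
    ax.set_yticklabels(scenarios)
    ax.set_xscale("log")
    ax.set_xlabel("concentration (PoD blue, exposure red)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
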