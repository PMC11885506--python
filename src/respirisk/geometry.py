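"""Symmetric 23-generation airway geometry and breathing parameters.

The lung is modelled as a symmetric bifurcating tree of cylindrical tubes:
generation 1 is the trachea and every generation doubles the tube count, so
generation g holds ``2**(g-1)`` identical tubes.  A classic whole-lung
typical-path morphometry table (tube length, diameter, branching and gravity
angles, and an alveolar volume attached to the respiratory generations) ships
with the package and is rescaled isotropically so that the total airway plus
alveolar volume equals the configured functional residual capacity (FRC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

N_GENERATIONS = 23


class InvalidParameterError(ValueError):
    """Raised when a physical parameter is outside its valid domain."""


@dataclass(frozen=True)
class BreathingParameters:
    """Fixed tidal-breathing pattern of the exposed person.

    Defaults correspond to light-activity adult breathing: 12 breaths per
    minute, 625 mL tidal volume (minute ventilation 7.5 L/min), FRC of
    3300 mL, a 50 mL upper-respiratory-tract (URT) dead volume, and an
    inspiratory fraction of 0.5 with no end-inspiratory pause.
    """

    breaths_per_min: float = 12.0
    tidal_volume_ml: float = 625.0
    inspiratory_fraction: float = 0.5
    pause_fraction: float = 0.0
    frc_ml: float = 3300.0
    urt_volume_ml: float = 50.0

    def __post_init__(self) -> None:
        if self.breaths_per_min <= 0 or self.tidal_volume_ml <= 0:
            raise InvalidParameterError("minute ventilation must be positive")
        if not 0 < self.inspiratory_fraction <= 1:
            raise InvalidParameterError("inspiratory_fraction must be in (0, 1]")
        if self.pause_fraction < 0:
            raise InvalidParameterError("pause_fraction must be >= 0")
        if self.inspiratory_fraction + self.pause_fraction > 1:
            raise InvalidParameterError(
                "inspiratory_fraction + pause_fraction must be <= 1"
            )
        if self.frc_ml <= 0:
            raise InvalidParameterError("frc_ml must be positive")

    @property
    def minute_ventilation_l_min(self) -> float:
        """Minute ventilation in L/min."""
        return self.breaths_per_min * self.tidal_volume_ml / 1000.0

    @property
    def breath_period_s(self) -> float:
        return 60.0 / self.breaths_per_min

    @property
    def inspiratory_flow_ml_s(self) -> float:
        """Volumetric flow during inspiration (mL/s), constant-flow assumption."""
        t_insp = self.breath_period_s * self.inspiratory_fraction
        return self.tidal_volume_ml / t_insp

    @property
    def expiratory_flow_ml_s(self) -> float:
        t_exp = self.breath_period_s * (
            1.0 - self.inspiratory_fraction - self.pause_fraction
        )
        return self.tidal_volume_ml / t_exp


@dataclass(frozen=True)
class ParticleProperties:
    """Aerodynamic description of the inhaled aerosol.

    ``mmad_um`` is the mass median aerodynamic diameter; with the aerodynamic
    convention the effective particle density is 1 g/cm**3.  ``gsd`` is the
    geometric standard deviation of the (mass-weighted) lognormal size
    distribution; 1 means monodisperse.
    """

    mmad_um: float
    gsd: float = 1.0
    density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if not 0.01 < self.mmad_um < 100.0:
            raise InvalidParameterError(
                f"mmad_um={self.mmad_um} outside validity range (0.01, 100) um"
            )
        if self.gsd < 1.0:
            raise InvalidParameterError("gsd must be >= 1")
        if self.density_g_cm3 <= 0:
            raise InvalidParameterError("density must be positive")


@dataclass
class HeadRegion:
    volume_ml: float
    surface_area_cm2: float


@dataclass
class AirwayGeometry:
    """Scaled per-generation morphometry plus the extrathoracic head region.

    ``table`` columns: generation (1..23), length_cm, diameter_cm, count,
    branching_angle_deg, gravity_angle_deg, alveolar_volume_ml,
    surface_area_cm2, volume_ml (tube + alveolar), cumulative_volume_ml.
    """

    table: pd.DataFrame
    head_region: HeadRegion
    scale_factor: float = 1.0

    @property
    def n_generations(self) -> int:
        return len(self.table)

    @property
    def surface_area_cm2(self) -> np.ndarray:
        return self.table["surface_area_cm2"].to_numpy()

    @property
    def total_volume_ml(self) -> float:
        return float(self.table["volume_ml"].sum())


def _load_raw_morphometry() -> pd.DataFrame:
    with resources.files("respirisk.data").joinpath("morphometry.csv").open() as fh:
        return pd.read_csv(fh)


def build_airway_geometry(
    breathing: BreathingParameters | None = None,
    nasal_area_cm2: float = 160.0,
) -> AirwayGeometry:
    """Build the symmetric 23-generation geometry scaled to the FRC.

    All linear dimensions of the reference morphometry are multiplied by a
    single factor ``s`` chosen so the total (tube + alveolar) volume equals
    ``breathing.frc_ml`` exactly; tube volumes scale as ``s**3`` and surface
    areas as ``s**2``.  The head region is not part of the scaled tree: its
    volume is the configured URT dead volume.
    """
    breathing = breathing or BreathingParameters()
    raw = _load_raw_morphometry()
    if len(raw) != N_GENERATIONS:
        raise InvalidParameterError(
            f"morphometry table must have {N_GENERATIONS} generations"
        )

    tube_vol = (
        np.pi / 4.0 * raw["diameter_cm"] ** 2 * raw["length_cm"] * raw["count"]
    )
    raw_total = float(tube_vol.sum() + raw["alveolar_volume_ml"].sum())
    s = (breathing.frc_ml / raw_total) ** (1.0 / 3.0)

    table = raw.copy()
    table["length_cm"] = raw["length_cm"] * s
    table["diameter_cm"] = raw["diameter_cm"] * s
    table["alveolar_volume_ml"] = raw["alveolar_volume_ml"] * s**3
    table["surface_area_cm2"] = (
        np.pi * table["diameter_cm"] * table["length_cm"] * table["count"]
    )
    table["volume_ml"] = (
        np.pi / 4.0 * table["diameter_cm"] ** 2 * table["length_cm"] * table["count"]
        + table["alveolar_volume_ml"]
    )
    table["cumulative_volume_ml"] = table["volume_ml"].cumsum()

    head = HeadRegion(
        volume_ml=breathing.urt_volume_ml, surface_area_cm2=nasal_area_cm2
    )
    return AirwayGeometry(table=table, head_region=head, scale_factor=s)


def toy_geometry(
    lengths_cm: list[float],
    diameters_cm: list[float],
    head_volume_ml: float = 50.0,
) -> AirwayGeometry:
    """Small hand-specified tree for oracle tests (counts still double)."""
    n = len(lengths_cm)
    counts = 2 ** np.arange(n)
    table = pd.DataFrame(
        {
            "generation": np.arange(1, n + 1),
            "length_cm": lengths_cm,
            "diameter_cm": diameters_cm,
            "count": counts,
            "branching_angle_deg": 45.0,
            "gravity_angle_deg": 45.0,
            "alveolar_volume_ml": 0.0,
        }
    )
    table["surface_area_cm2"] = (
        np.pi * table["diameter_cm"] * table["length_cm"] * table["count"]
    )
    table["volume_ml"] = (
        np.pi / 4.0 * table["diameter_cm"] ** 2 * table["length_cm"] * table["count"]
    )
    table["cumulative_volume_ml"] = table["volume_ml"].cumsum()
    return AirwayGeometry(
        table=table,
        head_region=HeadRegion(volume_ml=head_volume_ml, surface_area_cm2=160.0),
    )
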