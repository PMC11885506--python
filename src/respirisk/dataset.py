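"""Long-format bioactivity dataset container and CSV round-trip.

One dataset holds one readout measured within one laboratory/tissue model:
values indexed by test material, concentration (0 = vehicle control),
timepoint (day) and replicate.  The on-disk form is a plain CSV with columns
``material, concentration, unit, timepoint_day, replicate, readout, value``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["material", "concentration", "unit", "timepoint_day",
           "replicate", "readout", "value"]

VEHICLE = "vehicle"


class DatasetError(ValueError):
    pass


@dataclass
class BioactivityDataset:
    """One readout's measurements across materials/concentrations/timepoints."""

    df: pd.DataFrame
    readout: str
    unit: str = ""
    lab: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise DatasetError(f"dataset missing columns: {missing}")
        tps = self.timepoints
        veh = self.df[self.df["concentration"] == 0.0]
        for t in tps:
            if not (veh["timepoint_day"] == t).any():
                raise DatasetError(f"no vehicle controls at timepoint {t}")

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.df["timepoint_day"].unique())

    @property
    def materials(self) -> list[str]:
        mats = self.df.loc[self.df["concentration"] > 0, "material"].unique()
        return sorted(mats)

    def concentrations(self, material: str) -> list[float]:
        sel = self.df["material"] == material
        return sorted(self.df.loc[sel & (self.df["concentration"] > 0),
                                  "concentration"].unique())

    def control_values(self, timepoint: float) -> np.ndarray:
        sel = (self.df["concentration"] == 0.0) & (
            self.df["timepoint_day"] == timepoint)
        return self.df.loc[sel, "value"].to_numpy()

    def series(self) -> list[tuple[str, float]]:
        """(material, concentration) series; the shared vehicle comes first."""
        out: list[tuple[str, float]] = [(VEHICLE, 0.0)]
        for m in self.materials:
            out.extend((m, c) for c in self.concentrations(m))
        return out

    def to_arrays(self) -> tuple[np.ndarray, list[tuple[str, float]], list[float]]:
        """Return (Y[t, s, r], series, timepoints) with NaN padding."""
        tps = self.timepoints
        series = self.series()
        max_rep = int(self.df.groupby(
            ["material", "concentration", "timepoint_day"]).size().max())
        y = np.full((len(tps), len(series), max_rep), np.nan)
        for si, (mat, conc) in enumerate(series):
            if conc == 0.0:
                sel = self.df["concentration"] == 0.0
            else:
                sel = (self.df["material"] == mat) & (
                    self.df["concentration"] == conc)
            for ti, t in enumerate(tps):
                vals = self.df.loc[sel & (self.df["timepoint_day"] == t),
                                   "value"].to_numpy()
                y[ti, si, : len(vals)] = vals
        return y, series, tps

    def to_csv(self, path) -> None:
        self.df[COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BioactivityDataset":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise DatasetError(f"malformed dataset CSV {path}: {exc}") from exc
        readouts = df["readout"].unique()
        if len(readouts) != 1:
            raise DatasetError(
                f"one dataset must hold exactly one readout, got {list(readouts)}"
            )
        unit = df["unit"].iloc[0] if len(df) else ""
        return cls(df=df, readout=str(readouts[0]), unit=str(unit))
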