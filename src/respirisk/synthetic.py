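"""Synthetic bioactivity data with known ground-truth points of departure.

The generator emulates the statistical structure of repeated-exposure
air-liquid-interface studies: a handful of concentrations plus vehicle,
observations on days 1/4/8/12 with 3-5 replicate tissues, multiplicative
log-normal measurement noise, and monotone-in-concentration effects that
switch on after a latency (e.g., mucin secretion rising from day 8 onward).

The mean response is ``baseline * 10**effect(t, c)`` with

    effect(t, c) = amplitude * c**hill / (ec50**hill + c**hill) * ramp(t)

where ``ramp`` rises linearly from 0 at ``onset_day`` to 1 over 4 days
(and decays again afterwards if the effect is reversible).  Because the
mean function is known in closed form, a brute-force oracle can report the
exact concentration at which the effect becomes detectable, which the
Bayesian pipeline is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import COLUMNS, VEHICLE, BioactivityDataset
from .scenarios import scenario_fixtures  # noqa: F401  (fixture re-export)


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseSurfaceSpec:
    """Ground-truth concentration-time response for one material."""

    direction: str = "increase"           # or "decrease"
    baseline: float = 100.0
    amplitude: float = 0.0                # max |log10 fold-change|
    ec50: float = 1.0
    hill: float = 2.0
    onset_day: float = 0.0
    noise_sd: float = 0.1                 # additive on log10 scale
    reversible: bool = False
    ramp_days: float = 4.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise InvalidSpecError("baseline must be positive")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be positive")
        if self.ec50 <= 0 or self.hill <= 0:
            raise InvalidSpecError("ec50 and hill must be positive")
        if self.onset_day < 0:
            raise InvalidSpecError("onset_day must be >= 0")
        if self.direction not in ("increase", "decrease"):
            raise InvalidSpecError("direction must be increase|decrease")

    def ramp(self, day: np.ndarray | float) -> np.ndarray | float:
        x = np.clip((np.asarray(day, dtype=float) - self.onset_day)
                    / self.ramp_days, 0.0, 1.0)
        if self.reversible:
            decay_start = self.onset_day + self.ramp_days
            x = x * np.exp(-np.maximum(0.0, np.asarray(day) - decay_start)
                           / self.ramp_days)
        return x

    def effect(self, day, concentration):
        """Noiseless log10 fold-change over baseline (signed)."""
        c = np.asarray(concentration, dtype=float)
        with np.errstate(divide="ignore"):
            hill_term = np.where(
                c > 0, c**self.hill / (self.ec50**self.hill + c**self.hill), 0.0
            )
        sign = 1.0 if self.direction == "increase" else -1.0
        return sign * self.amplitude * hill_term * self.ramp(day)

    def mean_value(self, day, concentration):
        return self.baseline * 10.0 ** self.effect(day, concentration)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of one synthetic study: materials, concentrations, schedule."""

    materials: tuple[tuple[str, ResponseSurfaceSpec], ...]
    concentrations: tuple[float, ...]
    timepoints: tuple[float, ...] = (1.0, 4.0, 8.0, 12.0)
    n_replicates: int = 3
    seed: int = 0
    readout: str = "readout"
    unit: str = "ug/cm2"

    def __post_init__(self) -> None:
        concs = [c for c in self.concentrations if c > 0]
        if len(concs) < 3:
            raise InvalidSpecError("need at least 3 non-zero concentrations")
        if any(c <= 0 for c in concs):
            raise InvalidSpecError("concentrations must be positive")
        if len(set(concs)) != len(concs) or sorted(concs) != concs:
            raise InvalidSpecError("concentrations must be strictly increasing")
        if sorted(self.timepoints) != list(self.timepoints) or len(
                set(self.timepoints)) != len(self.timepoints):
            raise InvalidSpecError("timepoints must be strictly increasing")
        if self.n_replicates < 2:
            raise InvalidSpecError("n_replicates must be >= 2")
        for name, surf in self.materials:
            if surf.amplitude != 0 and not (
                    min(concs) <= surf.ec50 <= max(concs)):
                raise InvalidSpecError(
                    f"ec50 of {name!r} outside the simulated range")

    def surface(self, material: str) -> ResponseSurfaceSpec:
        for name, surf in self.materials:
            if name == material:
                return surf
        raise KeyError(material)


def generate_bioactivity(spec: SyntheticStudySpec) -> BioactivityDataset:
    """Draw one dataset: Y = mean(t, c) * 10**eps, eps ~ N(0, noise_sd).

    Vehicle rows (concentration 0) are generated for every timepoint using
    the first material's baseline and noise level.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    first_surf = spec.materials[0][1]
    concs = [c for c in spec.concentrations if c > 0]
    for t in spec.timepoints:
        for r in range(spec.n_replicates):
            eps = rng.normal(0.0, first_surf.noise_sd)
            rows.append((VEHICLE, 0.0, spec.unit, t, r,
                         spec.readout, first_surf.baseline * 10.0**eps))
    for name, surf in spec.materials:
        for c in concs:
            for t in spec.timepoints:
                mean = surf.mean_value(t, c)
                for r in range(spec.n_replicates):
                    eps = rng.normal(0.0, surf.noise_sd)
                    rows.append((name, c, spec.unit, t, r,
                                 spec.readout, mean * 10.0**eps))
    df = pd.DataFrame(rows, columns=COLUMNS)
    return BioactivityDataset(df=df, readout=spec.readout, unit=spec.unit)


def ground_truth_pod(
    spec: SyntheticStudySpec, material: str, grid_size: int = 2000
) -> float | None:
    """Analytic detectability oracle for the generated mean function.

    Returns the lowest concentration, on a dense log grid spanning
    [lowest tested / 10, highest tested], at which the noiseless mean
    effect at any timepoint exceeds the standard-error analogue of a 95%
    control band, ``1.96 * noise_sd / sqrt(n_replicates)``.  ``None`` if
    the effect never becomes detectable.  Pure grid evaluation; no
    sampling, no model fit.
    """
    surf = spec.surface(material)
    concs = [c for c in spec.concentrations if c > 0]
    grid = np.logspace(np.log10(min(concs) / 10.0), np.log10(max(concs)),
                       grid_size)
    threshold = 1.96 * surf.noise_sd / np.sqrt(spec.n_replicates)
    for c in grid:
        effects = np.abs([surf.effect(t, c) for t in spec.timepoints])
        if np.max(effects) > threshold:
            return float(c)
    return None
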