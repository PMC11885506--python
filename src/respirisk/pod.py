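"""Point-of-departure derivation from the fitted state-space posterior.

For every posterior draw the deterministic mean-response trajectory is
propagated over a log-spaced concentration grid (starting from that draw's
control initial state, so the vehicle column reproduces the control
trajectory exactly).  The 95% credible range of control is the pointwise
band, per timepoint, of the control trajectory plus the draw's predictive
replicate-mean observation noise.  A draw's PoD at a timepoint is the
lowest grid concentration whose mean response lies outside that band; the
Concentration Dependency Score (CDS) is the fraction of draws with a PoD,
split into ES_increase / ES_decrease by the direction of the first exit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .statespace import PosteriorSamples


@dataclass
class PosteriorPredictive:
    """Per-draw mean-response trajectories on a concentration grid."""

    grid: np.ndarray                  # (G,) concentrations
    timepoints: list[float]
    response: np.ndarray              # (D, T, G) mean response per draw
    control: np.ndarray               # (D, T) control trajectory per draw
    band_low: np.ndarray              # (T,) control band, 2.5%
    band_high: np.ndarray             # (T,) control band, 97.5%
    material: str
    readout: str

    def median_response(self) -> np.ndarray:
        return np.median(self.response, axis=0)

    def heatmap_frame(self) -> pd.DataFrame:
        """Median response minus control median per (timepoint, conc)."""
        med = self.median_response()
        ctrl_med = np.median(self.control, axis=0)
        rows = []
        for ti, t in enumerate(self.timepoints):
            for gi, c in enumerate(self.grid):
                rows.append((t, c, med[ti, gi] - ctrl_med[ti]))
        return pd.DataFrame(rows, columns=["timepoint_day", "concentration",
                                           "delta_response"])


def posterior_predictive(
    samples: PosteriorSamples,
    material: str | None = None,
    concentration_grid: np.ndarray | None = None,
) -> PosteriorPredictive:
    """Mean-response trajectories for a material over a concentration grid.

    The default grid is ``pod_grid_size`` log-spaced points from one decade
    below the lowest tested non-zero concentration to the highest tested;
    grids outside that support raise an extrapolation warning.
    """
    norm = samples.norm
    cfg = samples.config
    model = samples.model
    materials = sorted({m for m, c in norm.series if c > 0})
    if material is None:
        material = materials[0]
    concs = np.array([c for m, c in norm.series if m == material and c > 0])
    if len(concs) == 0:
        raise KeyError(f"material {material!r} not in dataset")

    if concentration_grid is None:
        grid = np.logspace(np.log10(concs.min() / 10.0),
                           np.log10(concs.max()), cfg.pod_grid_size)
    else:
        grid = np.asarray(concentration_grid, dtype=float)
        if grid.min() < concs.min() / 10.0 - 1e-12 or grid.max() > concs.max() * (
                1 + 1e-12):
            warnings.warn("concentration grid extends outside tested support; "
                          "extrapolating the response surface", UserWarning)
    u_grid = norm.u_of_concentration(grid)                    # (G,)
    u_ctrl = float(norm.u[0])

    w_eff = samples.effective_weights_flat()                  # (D, m, m)
    states = samples.states_flat()                            # (D, T, S)
    n_draws = w_eff.shape[0]
    t_n = len(norm.timepoints)

    def propagate(u_values: np.ndarray) -> np.ndarray:
        """Deterministic trajectories: (D, T, len(u_values))."""
        from .statespace import hsgp_basis
        phi_u = hsgp_basis(u_values, model.m, model.l_u)      # (G, m)
        x = np.repeat(states[:, 0, 0][:, None], len(u_values), axis=1)  # (D,G)
        out = np.empty((n_draws, t_n, len(u_values)))
        out[:, 0, :] = x
        for t in range(1, t_n):
            x = x + model.f_increment(w_eff, x, phi_u)
            out[:, t, :] = x
        return out

    response = propagate(u_grid)
    control = propagate(np.array([u_ctrl]))[:, :, 0]          # (D, T)

    # Control band: control trajectory plus predictive replicate-mean noise.
    rng = np.random.default_rng([cfg.seed, 7791])
    sig_e = samples.sigma_e_flat()
    n_rep = max(norm.n_vehicle_replicates, 1)
    noise = rng.normal(size=control.shape) * (sig_e[:, None] / np.sqrt(n_rep))
    ctrl_pred = control + noise
    band_low = np.quantile(ctrl_pred, 0.025, axis=0)
    band_high = np.quantile(ctrl_pred, 0.975, axis=0)

    return PosteriorPredictive(
        grid=grid, timepoints=list(norm.timepoints), response=response,
        control=control, band_low=band_low, band_high=band_high,
        material=material, readout=norm.readout,
    )


def plot_posterior_predictive(predictive: PosteriorPredictive, path) -> None:
    """Panel per timepoint: median response, credible band, control band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_t = len(predictive.timepoints)
    fig, axes = plt.subplots(1, n_t, figsize=(3.2 * n_t, 3), sharey=True)
    med = predictive.median_response()
    lo = np.quantile(predictive.response, 0.025, axis=0)
    hi = np.quantile(predictive.response, 0.975, axis=0)
    for ti, (ax, t) in enumerate(zip(np.atleast_1d(axes),
                                     predictive.timepoints)):
        ax.fill_between(predictive.grid, lo[ti], hi[ti], alpha=0.3,
                        color="tab:red", label="mean response 95%")
        ax.plot(predictive.grid, med[ti], color="tab:red")
        ax.axhline(predictive.band_low[ti], ls="--", color="tab:pink")
        ax.axhline(predictive.band_high[ti], ls="--", color="tab:pink")
        ax.set_xscale("log")
        ax.set_title(f"day {t:g}")
        ax.set_xlabel(f"concentration")
    np.atleast_1d(axes)[0].set_ylabel(
        f"{predictive.readout} (normalized)")
    fig.suptitle(predictive.material)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class PoDResult:
    """PoD distribution and effect scores for one (material, readout, day)."""

    material: str
    readout: str
    timepoint: float
    pod_samples: np.ndarray           # crossing concentrations, one per draw
                                      # with a PoD (possibly empty)
    cds: float
    es_increase: float
    es_decrease: float
    median_pod: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def concentration_dependent(self) -> bool:
        return self.cds > 0.5


def derive_pod(predictive: PosteriorPredictive) -> list[PoDResult]:
    """Per-timepoint PoD samples, CDS and effect scores.

    For each posterior draw and timepoint, the PoD is the lowest grid
    concentration at which the draw's mean response exits the control band
    (lowest-crossing tie-break for non-monotone draws); draws that never
    exit contribute no PoD.  CDS is the fraction of draws with a PoD and
    ES_increase / ES_decrease split that fraction by exit direction, so
    ES_increase + ES_decrease = CDS <= 1 for every output.
    """
    n_draws = predictive.response.shape[0]
    if n_draws == 0:
        raise ValueError("empty posterior")
    results = []
    for ti, t in enumerate(predictive.timepoints):
        resp = predictive.response[:, ti, :]                  # (D, G)
        above = resp > predictive.band_high[ti]
        below = resp < predictive.band_low[ti]
        outside = above | below
        has_pod = outside.any(axis=1)
        first = np.where(has_pod, outside.argmax(axis=1), -1)
        pods = predictive.grid[first[has_pod]]
        d_idx = np.nonzero(has_pod)[0]
        went_up = above[d_idx, first[has_pod]]
        cds = float(has_pod.mean())
        es_inc = float(went_up.sum() / n_draws)
        es_dec = float((~went_up).sum() / n_draws)
        if len(pods):
            median = float(np.median(pods))
            lo, hi = np.quantile(pods, [0.025, 0.975])
        else:
            median = lo = hi = None
        results.append(PoDResult(
            material=predictive.material, readout=predictive.readout,
            timepoint=t, pod_samples=pods, cds=cds,
            es_increase=es_inc, es_decrease=es_dec,
            median_pod=median,
            ci_low=None if lo is None else float(lo),
            ci_high=None if hi is None else float(hi),
        ))
    return results
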