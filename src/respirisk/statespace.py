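"""Nonlinear state-space concentration-time response model with SMC inference.

Normalized readout values ``y_t`` for each exposure series (one material at
one concentration, vehicle included) are modelled as noisy observations of a
latent mean response ``x_t``:

    y_t^(s,r) ~ Normal(x_t^s, sigma_e)
    x_t^s     = x_{t-1}^s + f(x_{t-1}^s, u_s) + v_t,   v_t ~ Normal(0, sigma_v)

where ``u_s`` is the (standardised log10) concentration of series ``s`` and
``f`` is an unknown smooth interaction/perturbation function given a
Gaussian-process prior, represented by a reduced-rank (Hilbert-space) basis
function expansion: ``f(x, u) = sum_jk w_jk phi_j(x) phi_k(u)`` with
squared-exponential spectral shrinkage on the weights.  Modelling the
increment (rather than the next state directly) makes "no effect" the
natural null: with ``f ~ 0`` every series stays at its initial level.

Posterior draws are obtained with an adaptive-tempering sequential Monte
Carlo sampler (systematic resampling, random-walk Metropolis move kernels
with a covariance adapted from the particle population).  Several
independent chains are run and the Rhat diagnostic across chains must fall
below the configured threshold, otherwise the fit fails loudly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np

from .dataset import BioactivityDataset


class PreprocessingError(ValueError):
    pass


class DegenerateNormalizationError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, rhat_table: dict[str, float]):
        super().__init__(message)
        self.rhat_table = rhat_table


# --------------------------------------------------------------------------
# TEER conversion (data-ingestion helper for barrier-integrity readouts)

def teer_from_resistance(
    resistance_ohm: float, variant: str, blank_ohm: float | None = None
) -> float:
    """Convert a raw resistance reading (Ohm) to TEER (Ohm * cm**2).

    The upper-airway tissue format subtracts a 100 Ohm membrane resistance
    and multiplies by its 0.33 cm**2 epithelium area; the alveolar format
    subtracts the measured tissue-free membrane (blank) resistance and
    multiplies by its 1.12 cm**2 insert area.  Readings below the membrane
    value are clamped to zero with a warning.
    """
    if variant == "mucilair":
        value = (resistance_ohm - 100.0) * 0.33
    elif variant == "epialveolar":
        if blank_ohm is None:
            raise ValueError("epialveolar conversion needs blank_ohm")
        value = (resistance_ohm - blank_ohm) * 1.12
    else:
        raise ValueError(f"unknown TEER variant {variant!r}")
    if value < 0:
        warnings.warn(
            f"resistance {resistance_ohm} below membrane blank; TEER clamped to 0",
            UserWarning,
        )
        return 0.0
    return value


# --------------------------------------------------------------------------
# Normalization

@dataclass(frozen=True)
class NormalizationParams:
    """log10 z-scoring constants plus the max-median scale factor.

    ``shift`` is the constant added to every raw value before taking logs
    when the readout contains non-positive values (e.g., Delta-TEER); zero
    when no shift was needed.
    """

    mu: float
    sigma: float
    scale: float
    shift: float = 0.0


@dataclass
class NormalizedDataset:
    """Normalized observations on a (timepoint, series, replicate) grid."""

    y: np.ndarray                       # (T, S, R), NaN-padded
    series: list[tuple[str, float]]     # (material, concentration), vehicle first
    timepoints: list[float]
    u: np.ndarray                       # (S,) standardised log-concentration
    params: NormalizationParams
    readout: str
    log_center: float
    log_halfrange: float
    floor_concentration: float

    def u_of_concentration(self, c: np.ndarray | float) -> np.ndarray:
        c = np.maximum(np.asarray(c, dtype=float), self.floor_concentration)
        return (np.log10(c) - self.log_center) / self.log_halfrange

    @property
    def n_vehicle_replicates(self) -> int:
        return int(np.sum(~np.isnan(self.y[:, 0, :])) // len(self.timepoints))


def normalize_dataset(
    dataset: BioactivityDataset,
    shift_nonpositive: bool = False,
) -> tuple[NormalizedDataset, NormalizationParams]:
    """log10 z-score against first-timepoint controls, then max-median scale.

    ``mu`` and ``sigma`` are the sample mean and standard deviation of the
    log10 control values at the first timepoint; after z-scoring, one scale
    factor per dataset makes the maximum absolute replicate-median equal
    one (the absolute value keeps strong decreases on the same working
    scale as increases).

    Readouts that can legitimately go non-positive (difference readouts
    such as Delta-TEER) are handled with ``shift_nonpositive=True``: a
    constant (the smallest positive observed value minus the minimum) is
    added to every value before the log transform and recorded in the
    returned parameters.  Without the flag, non-positive values raise.
    """
    shift = 0.0
    values = dataset.df["value"]
    if (values <= 0).any():
        if not shift_nonpositive:
            bad = dataset.df[values <= 0]
            row = bad.iloc[0]
            raise PreprocessingError(
                f"non-positive readout value {row['value']} at material="
                f"{row['material']!r} c={row['concentration']} day="
                f"{row['timepoint_day']} rep={row['replicate']}"
            )
        positive = values[values > 0]
        if positive.empty:
            raise PreprocessingError("no positive readout values to anchor "
                                     "the non-positivity shift")
        shift = float(positive.min() - values.min())
        dataset = BioactivityDataset(
            df=dataset.df.assign(value=values + shift),
            readout=dataset.readout, unit=dataset.unit, lab=dataset.lab)
    y_raw, series, tps = dataset.to_arrays()
    controls = dataset.control_values(tps[0])
    if len(controls) < 2:
        raise InsufficientDataError(
            "need >= 2 control replicates at the first timepoint")
    if len(tps) < 2:
        raise InsufficientDataError("need >= 2 timepoints")
    logc = np.log10(controls)
    mu = float(np.mean(logc))
    sigma = float(np.std(logc, ddof=1))
    if sigma <= 0:
        raise DegenerateNormalizationError("zero control variance at timepoint 1")

    z = (np.log10(y_raw) - mu) / sigma
    medians = np.nanmedian(z, axis=2)
    # One scale per dataset so the largest absolute replicate median is 1.
    # Using the absolute value keeps decrease-dominated readouts on the same
    # O(1) working scale as increases; for near-null (control-only) data the
    # scale falls back to 1 instead of dividing by ~0.
    max_abs = float(np.nanmax(np.abs(medians)))
    scale = max_abs if max_abs > 0.1 else 1.0
    z = z / scale
    params = NormalizationParams(mu=mu, sigma=sigma, scale=scale, shift=shift)

    concs = np.array([c for _, c in series])
    pos = concs[concs > 0]
    floor = float(pos.min() / 10.0)
    logs = np.log10(pos)
    center = float((logs.min() + logs.max()) / 2.0)
    halfrange = float(max((logs.max() - logs.min()) / 2.0, 0.5))
    u = (np.log10(np.maximum(concs, floor)) - center) / halfrange

    norm = NormalizedDataset(
        y=z, series=series, timepoints=tps, u=u, params=params,
        readout=dataset.readout, log_center=center, log_halfrange=halfrange,
        floor_concentration=floor,
    )
    return norm, params


def denormalize(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    raw = 10.0 ** (np.asarray(values) * params.scale * params.sigma + params.mu)
    return raw - params.shift


# --------------------------------------------------------------------------
# Model configuration

@dataclass(frozen=True)
class StateSpaceConfig:
    """Sampler and prior settings.

    ``n_iterations`` is the per-chain sample budget and ``n_burnin`` the
    discarded share, so each chain retains ``n_iterations - n_burnin``
    posterior draws (the SMC particle population size).  Priors are
    weakly-informative on the normalized scale.
    """

    n_basis: int = 10
    domain_halfwidth_x: float = 5.0
    lengthscale_prior: tuple[float, float] = (np.log(1.5), 0.5)
    amplitude_prior: tuple[float, float] = (np.log(0.3), 0.7)
    obs_noise_prior: tuple[float, float] = (np.log(0.5), 0.5)
    process_noise_prior: tuple[float, float] = (np.log(0.1), 0.7)
    init_state_sd: float = 2.0
    n_chains: int = 3
    n_iterations: int = 5000
    n_burnin: int = 1000
    rhat_threshold: float = 1.1
    pod_grid_size: int = 100
    seed: int = 0
    n_mcmc_moves: int = 40
    ess_target: float = 0.5
    max_restarts: int = 2

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.rhat_threshold <= 1:
            raise ValueError("rhat_threshold must be > 1")

    @property
    def n_particles(self) -> int:
        return self.n_iterations - self.n_burnin

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "StateSpaceConfig":
        """Small fast profile for development-scale runs."""
        defaults = dict(n_basis=4, n_iterations=500, n_burnin=100, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def paper_faithful(cls, seed: int = 0, **overrides) -> "StateSpaceConfig":
        defaults = dict(n_basis=10, n_iterations=5000, n_burnin=1000, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


# --------------------------------------------------------------------------
# Reduced-rank GP basis (Hilbert-space approximation on a box)

def hsgp_basis(z: np.ndarray, m: int, L: float) -> np.ndarray:
    """Eigenfunctions of the Laplacian on [-L, L]: shape z.shape + (m,)."""
    zc = np.clip(np.asarray(z, dtype=float), -L, L)
    j = np.arange(1, m + 1)
    return np.sqrt(1.0 / L) * np.sin(
        np.pi * j * (zc[..., None] + L) / (2.0 * L))


def hsgp_sqrt_eigenvalues(m: int, L: float) -> np.ndarray:
    return np.pi * np.arange(1, m + 1) / (2.0 * L)


def spectral_sd(
    log_ell_x: np.ndarray, log_ell_u: np.ndarray, log_tau: np.ndarray,
    m: int, l_x: float, l_u: float,
) -> np.ndarray:
    """Weight prior sd sqrt(S(omega_j, omega_k)); shape (..., m, m)."""
    wx = hsgp_sqrt_eigenvalues(m, l_x)
    wu = hsgp_sqrt_eigenvalues(m, l_u)
    ell_x = np.exp(log_ell_x)[..., None, None]
    ell_u = np.exp(log_ell_u)[..., None, None]
    tau = np.exp(log_tau)[..., None, None]
    s2 = (
        tau**2 * ell_x * ell_u * 2.0 * np.pi
        * np.exp(-0.5 * (wx[:, None]**2 * ell_x**2 + wu[None, :]**2 * ell_u**2))
    )
    return np.sqrt(s2)


# --------------------------------------------------------------------------
# Posterior evaluation (vectorised across particles)

class _Model:
    """Caches data-dependent quantities for fast log-posterior evaluation."""

    def __init__(self, norm: NormalizedDataset, config: StateSpaceConfig):
        self.norm = norm
        self.cfg = config
        self.m = config.n_basis
        self.l_x = config.domain_halfwidth_x
        self.l_u = float(1.2 * np.max(np.abs(norm.u)) + 1.0)
        self.t_n, self.s_n, _ = norm.y.shape
        self.obs_mask = ~np.isnan(norm.y)
        self.y_filled = np.where(self.obs_mask, norm.y, 0.0)
        self.n_obs = int(self.obs_mask.sum())
        self.phi_u = hsgp_basis(norm.u, self.m, self.l_u)      # (S, m)
        # parameter layout
        self.i_hyper = 5
        self.i_w = self.i_hyper
        self.n_w = self.m * self.m
        self.i_x = self.i_w + self.n_w
        self.dim = self.i_x + self.t_n * self.s_n

    # -- unpacking helpers ------------------------------------------------
    def hypers(self, p: np.ndarray):
        return p[:, 0], p[:, 1], p[:, 2], p[:, 3], p[:, 4]

    def weights_tilde(self, p: np.ndarray) -> np.ndarray:
        n = p.shape[0]
        return p[:, self.i_w:self.i_w + self.n_w].reshape(n, self.m, self.m)

    def states(self, p: np.ndarray) -> np.ndarray:
        n = p.shape[0]
        return p[:, self.i_x:].reshape(n, self.t_n, self.s_n)

    def effective_weights(self, p: np.ndarray) -> np.ndarray:
        lex, leu, lta, _, _ = self.hypers(p)
        sd = spectral_sd(lex, leu, lta, self.m, self.l_x, self.l_u)
        return sd * self.weights_tilde(p)

    def f_increment(self, w_eff: np.ndarray, x_prev: np.ndarray,
                    phi_u: np.ndarray) -> np.ndarray:
        """f(x_prev, u): w_eff (N,m,m), x_prev (N,S), phi_u (S,m) -> (N,S)."""
        phi_x = hsgp_basis(x_prev, self.m, self.l_x)           # (N, S, m)
        tmp = np.einsum("njk,sk->njs", w_eff, phi_u)           # (N, m, S)
        return np.einsum("nsj,njs->ns", phi_x, tmp)

    # -- log densities ----------------------------------------------------
    def log_prior(self, p: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        lex, leu, lta, lse, lsv = self.hypers(p)
        out = _norm_logpdf(lex, *cfg.lengthscale_prior)
        out += _norm_logpdf(leu, *cfg.lengthscale_prior)
        out += _norm_logpdf(lta, *cfg.amplitude_prior)
        out += _norm_logpdf(lse, *cfg.obs_noise_prior)
        out += _norm_logpdf(lsv, *cfg.process_noise_prior)
        wt = p[:, self.i_w:self.i_w + self.n_w]
        out += np.sum(_norm_logpdf(wt, 0.0, 1.0), axis=1)
        x = self.states(p)
        out += np.sum(_norm_logpdf(x[:, 0, :], 0.0, cfg.init_state_sd), axis=1)
        return out

    def log_transition(self, p: np.ndarray) -> np.ndarray:
        _, _, _, _, lsv = self.hypers(p)
        sig_v = np.exp(lsv)
        x = self.states(p)
        w_eff = self.effective_weights(p)
        out = np.zeros(p.shape[0])
        for t in range(1, self.t_n):
            pred = x[:, t - 1, :] + self.f_increment(
                w_eff, x[:, t - 1, :], self.phi_u)
            out += np.sum(_norm_logpdf(x[:, t, :], pred, sig_v[:, None]), axis=1)
        return out

    def log_likelihood(self, p: np.ndarray) -> np.ndarray:
        _, _, _, lse, _ = self.hypers(p)
        sig_e = np.exp(lse)
        x = self.states(p)                                    # (N, T, S)
        resid = self.y_filled[None] - x[..., None]            # (N, T, S, R)
        se = sig_e[:, None, None, None]
        ll = -0.5 * (resid / se) ** 2 - np.log(se) - 0.5 * np.log(2 * np.pi)
        return np.sum(np.where(self.obs_mask[None], ll, 0.0), axis=(1, 2, 3))

    def log_target(self, p: np.ndarray, beta: float) -> np.ndarray:
        return (self.log_prior(p) + self.log_transition(p)
                + beta * self.log_likelihood(p))

    # -- initial particles ------------------------------------------------
    def sample_initial(self, n: int, rng: np.random.Generator) -> np.ndarray:
        cfg = self.cfg
        p = np.empty((n, self.dim))
        p[:, 0] = rng.normal(*cfg.lengthscale_prior, size=n)
        p[:, 1] = rng.normal(*cfg.lengthscale_prior, size=n)
        p[:, 2] = rng.normal(*cfg.amplitude_prior, size=n)
        p[:, 3] = rng.normal(*cfg.obs_noise_prior, size=n)
        p[:, 4] = rng.normal(*cfg.process_noise_prior, size=n)
        p[:, self.i_w:self.i_w + self.n_w] = rng.normal(size=(n, self.n_w))
        x = np.empty((n, self.t_n, self.s_n))
        x[:, 0, :] = rng.normal(0.0, cfg.init_state_sd, size=(n, self.s_n))
        w_eff = None
        sig_v = np.exp(p[:, 4])
        for t in range(1, self.t_n):
            if w_eff is None:
                w_eff = self.effective_weights(p)
            pred = x[:, t - 1, :] + self.f_increment(w_eff, x[:, t - 1, :],
                                                     self.phi_u)
            x[:, t, :] = pred + rng.normal(size=(n, self.s_n)) * sig_v[:, None]
        p[:, self.i_x:] = x.reshape(n, -1)
        return p


def _norm_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z**2 - np.log(scale) - 0.5 * np.log(2 * np.pi)


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator):
    n = len(weights)
    positions = (rng.uniform() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def _next_beta(ll: np.ndarray, beta: float, ess_frac: float) -> float:
    """Largest step in beta keeping the incremental ESS above the target."""
    n = len(ll)
    target = ess_frac * n

    def ess(delta):
        lw = delta * (ll - ll.max())
        w = np.exp(lw)
        w /= w.sum()
        return 1.0 / np.sum(w**2)

    if ess(1.0 - beta) >= target:
        return 1.0
    lo, hi = 0.0, 1.0 - beta
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if ess(mid) >= target:
            lo = mid
        else:
            hi = mid
    return beta + lo


def _run_smc_chain(
    model: _Model, n_particles: int, rng: np.random.Generator,
    n_moves: int, ess_target: float,
) -> np.ndarray:
    """One adaptive-tempering SMC run; returns the final particle matrix."""
    p = model.sample_initial(n_particles, rng)
    beta = 0.0
    step_scale = 2.38 / np.sqrt(model.dim)
    max_stages = 200
    for _ in range(max_stages):
        if beta >= 1.0:
            break
        ll = model.log_likelihood(p)
        new_beta = _next_beta(ll, beta, ess_target)
        lw = (new_beta - beta) * (ll - ll.max())
        w = np.exp(lw)
        w /= w.sum()
        idx = _systematic_resample(w, rng)
        p = p[idx]
        beta = new_beta

        cov = np.cov(p, rowvar=False) + 1e-10 * np.eye(model.dim)
        chol = np.linalg.cholesky(cov)
        logpi = model.log_target(p, beta)
        for _ in range(n_moves):
            z = rng.normal(size=p.shape)
            prop = p + step_scale * z @ chol.T
            logpi_prop = model.log_target(prop, beta)
            accept = np.log(rng.uniform(size=n_particles)) < logpi_prop - logpi
            p[accept] = prop[accept]
            logpi[accept] = logpi_prop[accept]
            rate = accept.mean()
            # gentle scale adaptation towards ~25% acceptance
            step_scale *= np.exp(0.5 * (rate - 0.25))
            step_scale = float(np.clip(step_scale, 1e-3, 10.0))
    return p


# --------------------------------------------------------------------------
# Posterior container

@dataclass
class PosteriorSamples:
    """Per-chain SMC particle populations plus convergence diagnostics."""

    particles: np.ndarray               # (C, N, dim)
    model: _Model
    config: StateSpaceConfig
    norm: NormalizedDataset
    rhat_table: dict[str, float]
    max_rhat: float

    @property
    def n_draws(self) -> int:
        return self.particles.shape[0] * self.particles.shape[1]

    def flat(self) -> np.ndarray:
        c, n, d = self.particles.shape
        return self.particles.reshape(c * n, d)

    def effective_weights_flat(self) -> np.ndarray:
        return self.model.effective_weights(self.flat())

    def sigma_e_flat(self) -> np.ndarray:
        return np.exp(self.flat()[:, 3])

    def states_flat(self) -> np.ndarray:
        return self.model.states(self.flat())


def _compute_rhat(particles: np.ndarray, model: _Model) -> dict[str, float]:
    """Split-Rhat across chains for every scalar parameter group."""
    c, n, _ = particles.shape
    data = {
        "log_ell_x": particles[:, :, 0],
        "log_ell_u": particles[:, :, 1],
        "log_tau": particles[:, :, 2],
        "log_sigma_e": particles[:, :, 3],
        "log_sigma_v": particles[:, :, 4],
        "w": particles[:, :, model.i_w:model.i_w + model.n_w],
        "x": particles[:, :, model.i_x:].reshape(c, n, model.t_n, model.s_n),
    }
    idata = az.from_dict(posterior=data)
    rhat = az.rhat(idata)
    table = {}
    for name in rhat.data_vars:
        table[str(name)] = float(np.nanmax(rhat[name].values))
    return table


def fit_state_space(
    norm: NormalizedDataset, config: StateSpaceConfig | None = None
) -> PosteriorSamples:
    """Fit the model by multi-chain adaptive-tempering SMC.

    Runs ``n_chains`` independent samplers (seeded from ``config.seed``),
    checks Rhat across chains for every parameter, restarts with fresh
    seeds up to ``max_restarts`` times and raises ``ConvergenceError`` if
    the diagnostic never falls below the threshold.  Deterministic for a
    given seed and config.
    """
    config = config or StateSpaceConfig()
    if len(norm.timepoints) < 2:
        raise InsufficientDataError("need >= 2 timepoints to fit dynamics")
    model = _Model(norm, config)
    last_table: dict[str, float] = {}
    for attempt in range(config.max_restarts + 1):
        chains = []
        for chain in range(config.n_chains):
            rng = np.random.default_rng([config.seed, attempt, chain])
            chains.append(_run_smc_chain(
                model, config.n_particles, rng,
                config.n_mcmc_moves, config.ess_target,
            ))
        particles = np.stack(chains)
        table = _compute_rhat(particles, model)
        max_rhat = max(table.values())
        last_table = table
        if max_rhat < config.rhat_threshold:
            return PosteriorSamples(
                particles=particles, model=model, config=config, norm=norm,
                rhat_table=table, max_rhat=max_rhat,
            )
    raise ConvergenceError(
        f"Rhat did not fall below {config.rhat_threshold} after "
        f"{config.max_restarts + 1} attempts (max Rhat "
        f"{max(last_table.values()):.3f})",
        rhat_table=last_table,
    )
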