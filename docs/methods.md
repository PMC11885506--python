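# Methods

`respirisk` implements the computational chain of an exposure-led,
non-animal inhalation risk assessment: (1) generation-resolved lung
dosimetry, (2) particle-transport clearance, (3) Bayesian state-space
modelling of in vitro concentration–time response data to derive points of
departure (PoDs), and (4) bioactivity-exposure-ratio (BER) integration.
A synthetic-data generator with analytically known ground truth stands in
for laboratory measurements, so every stage is testable end to end.

## Airway geometry

The lung is a symmetric bifurcating tree of cylindrical tubes, generations
1 (trachea) through 23, with `2**(g-1)` identical tubes in generation `g`.
The bundled morphometry (`data/morphometry.csv`) uses classic typical-path
whole-lung dimensions with branching and gravity angles per generation and
an alveolar volume attached to generations 16–23.  All linear dimensions
are rescaled isotropically so that total tube plus alveolar volume equals
the configured functional residual capacity (FRC; default 3300 mL), which
makes similarity checks exact: doubling FRC scales lengths by `2^(1/3)`
and areas by `2^(2/3)`.  Tube surface area is `pi * d * L * count`.  The
extrathoracic (head) region carries the upper-respiratory-tract dead
volume (default 50 mL) and a nasal surface area (default 160 cm², a
configuration value, since published nasal-cavity areas vary).

Reference breathing: 12 breaths/min, tidal volume 625 mL, inspiratory
fraction 0.5 with no pause, minute ventilation 7.5 L/min.

## Deposition model

Transport is a one-dimensional serial filter with volumetric penetration.
Air moves as an incompressible column at constant inspiratory/expiratory
flow; a particle entering at inhaled-volume offset `v` (uniform on
`[0, V_T]`) penetrates to the depth where cumulative dead-space volume
equals `V_T - v` and retraces its path on exhalation.  Per generation,
three mechanisms compete:

* **Impaction** — Stokes-number/branching-angle bend efficiency
  `1 - (2/pi) arccos(theta*Stk) + (1/pi) sin(2 arccos(theta*Stk))`,
  applied once per entry into a generation (both passes);
* **Sedimentation** — inclined-tube exponential form with exponent
  `(8/pi) * v_settle * t * cos(phi) / d_tube`, where the residence time
  `t` is generation volume over flow;
* **Diffusion** — Gormley–Kennedy laminar-tube efficiency in
  `x = D * t / (4 a^2)`, with the series expansion below `x = 0.0156`.

Slip correction, settling velocity and the Brownian diffusion coefficient
use standard aerosol physics at body temperature with the aerodynamic
convention (unit density).  Sedimentation and diffusion are folded into a
single exponential rate so that partial traversal of the deepest
generation reached scales the exponent by the traversed volume fraction;
probabilities are partitioned exactly, so head + generations + exhaled
sums to one at machine precision.

**Head capture** uses a semi-empirical sigmoid in the impaction parameter
`d_a^2 * Q`: `eta = 1 - 1/(1 + A (d^2 Q)^P)` with `A = 1.6e-3`,
`P = 1.1` (d in µm, Q in L/min), applied on both passes.  These constants
fit classic nasal-inhalation measurements; nose breathing is the
reference-worker default of generation-resolved dosimetry models, and
under it the total sub-head (lower-respiratory) deposition across a
1–10 µm sweep peaks at 3 µm with the reference breathing pattern — the
worst-case diameter convention used for scenarios lacking measured
particle sizes.  With an oral-fit parameterisation the peak moves to 4 µm;
the nasal choice is deliberate and is the package default.

**Polydispersity**: Table-style scenario inputs give only a mass median
aerodynamic diameter, so the default is monodisperse (GSD 1).  When a GSD
is supplied, the profile is the Gauss–Hermite quadrature average (16
nodes) over the lognormal mass distribution.

Numerical choices: 200 midpoint quadrature nodes over the entry offset
(2000 in oracle comparisons); the Monte-Carlo particle-tracking oracle in
the test suite replays the same capture rules per particle with Bernoulli
draws, checking the transport logic independently of the survival
quadrature.

## Clearance kinetics

Each generation carries a three-compartment (fast/slow/sequestered)
structure by region — bronchial BB (generations 1–8), bronchiolar bb
(9–15), alveolar-interstitial AI (16–23) — plus an extrathoracic
compartment.  Mucociliary transport routes mass up the escalator
(generation `g` to `g-1`, generation 1 to ET, ET out of the model);
sequestered bronchial material leaves to lymph.  Default first-order
rates (per day) ship as an editable YAML: BB 10 / 0.03 / 0.01, bb 2 /
0.03 / 0.01 (fractions 0.793 / 0.2 / 0.007), AI 0.02 / 0.001 / 0.0001
(fractions 0.3 / 0.6 / 0.1), ET 100.  These follow the particle-transport
values of the standard human respiratory tract clearance model.
Absorption to blood is zero (pure particle transport), configurable.
The region map is configuration, not a constant.

The resulting linear ODE system with piecewise-constant sources
(deposition dose rate on during exposure events) is propagated exactly by
the matrix exponential of the augmented system per constant-source
interval, so mass balance (deposited = retained + cleared) holds to
machine precision and no solver tolerance enters downstream results.
Local concentration is retained mass divided by generation surface area
(µg/cm²).  The per-day regional summary takes the maximum over the
upper region (ET + BB) and lower region (bb + AI) at the end of the day's
final exposure event (the worst case within the day is reported
alongside, since the choice between the two conventions is open); ties
resolve to the shallowest generation.

## Synthetic bioactivity generator

One readout is `Y = baseline * 10^(effect(t,c) + eps)`,
`eps ~ N(0, noise_sd)` on the log10 scale, with

    effect(t, c) = ±amplitude * c^hill / (ec50^hill + c^hill) * ramp(t)

and `ramp` rising linearly from 0 at `onset_day` to 1 over 4 days
(decaying again with a 4-day constant if the effect is reversible).  The
defaults emulate the repeated-exposure air–liquid-interface study design:
3 concentrations plus vehicle, observations on days 1/4/8/12, 3
replicates, log-scale multiplicative noise of ~0.1 decades, monotone
concentration effects with a time onset.  The generator does **not**
emulate inter-donor variability, plate/batch effects, missing wells or
assay-specific detection limits, so passing recovery tests demonstrates
correctness of the inference machinery under the model's own noise
structure, not robustness to those real-data features.

The ground-truth oracle reports the lowest concentration (dense log grid
from a tenth of the lowest tested concentration to the highest) at which
the noiseless mean effect at any timepoint exceeds
`1.96 * noise_sd / sqrt(n_replicates)` — the standard-error analogue of a
95% control band.  It is a closed-form grid evaluation, independent of the
Bayesian pipeline it benchmarks.

## Normalization

Values are log10-transformed and z-scored against the mean and standard
deviation of the first-timepoint vehicle controls, then divided by one
per-dataset scale factor equal to the largest **absolute** replicate
median, so the working scale is O(1).  Using the absolute median (rather
than the signed maximum median) matters for decrease-dominated readouts:
with the signed rule the maximum median is a control cell near zero and
strong decreases land ~50 units below the working scale, outside what the
bounded transition prior can represent.  For increase-dominated data the
two rules coincide.  Near-null data fall back to unit scale instead of
dividing by ~0.  Difference readouts that go non-positive (ΔTEER) are
handled by an optional shift-by-constant (smallest positive value minus
the minimum), recorded in the normalization parameters and undone on
denormalization.

## State-space model and inference

For each series `s` (one material at one concentration, vehicle included;
vehicle enters the concentration input at one decade below the lowest
tested level):

    y_t^(s,r) ~ Normal(x_t^s, sigma_e)
    x_t^s     = x_{t-1}^s + f(x_{t-1}^s, u_s) + v_t,  v_t ~ Normal(0, sigma_v)

with `u_s` the log10 concentration standardised to roughly [-1, 1] over
the tested range.  `f` is an unknown smooth perturbation function with a
Gaussian-process prior, represented by a reduced-rank (Hilbert-space)
basis expansion: products of Laplacian eigenfunctions on a box, weights
shrunk by the squared-exponential spectral density of the kernel
(lengthscales and amplitude are hyperparameters with lognormal priors).
Modelling the increment rather than the next state makes "no effect" the
natural null: with `f ~ 0` every series stays flat at its initial level.
One transition step per consecutive observation timepoint is used; the
uneven day spacing (1/4/8/12) is absorbed into `f` rather than modelled
explicitly.

Priors (normalized scale): lengthscales LogNormal(log 1.5, 0.5),
GP amplitude LogNormal(log 0.3, 0.7), observation noise
LogNormal(log 0.5, 0.5), process noise LogNormal(log 0.1, 0.7), initial
states Normal(0, 2).  These are weakly informative defaults chosen for
the O(1) working scale; they are not taken from any published fit.

**Sampler.** Posterior draws come from an adaptive-tempering sequential
Monte Carlo sampler: particles start from the prior, the tempering
exponent rises by the largest step that keeps the incremental effective
sample size at half the population, systematic resampling, then
random-walk Metropolis moves (default 40 per stage) with proposal
covariance estimated from the particle population and a step size adapted
towards 25% acceptance.  Several independent chains (default 3) run with
separate seeds; the split-Rhat diagnostic across chains is computed for
every parameter (hyperparameters, basis weights, latent states) and the
fit restarts with fresh seeds, then fails loudly, if max Rhat does not
fall below 1.1.  The per-chain sample budget is `n_iterations` with
`n_burnin` discarded, so each chain retains
`n_iterations - n_burnin` draws (the SMC population size).  Two profiles
ship: `desk_scale` (400 retained draws/chain, 4 basis functions per
input) and `paper_faithful` (4000 retained draws/chain, 10 basis
functions).  All results in the test-suite and the acceptance script use
the desk profile; with it a three-chain fit takes a few seconds on one
CPU.  Everything is deterministic given the seed.

## PoD, CDS and effect scores

For each posterior draw, the deterministic mean-response trajectory is
replayed over a log-spaced concentration grid (default 100 points from a
tenth of the lowest tested concentration to the highest; no extrapolation
below that floor), starting from the draw's vehicle initial state — so
the vehicle column reproduces the control trajectory exactly.  The 95%
credible range of control is the pointwise, per-timepoint band of the
control trajectory plus the draw's predictive replicate-mean observation
noise (`sigma_e / sqrt(n_reps)`); including the observation-noise layer
makes the band a predictive interval for a fresh control replicate mean,
which is what the empirical coverage check measures (~95-98% observed)
and makes the PoD decision conservative.

A draw's PoD at a timepoint is the lowest grid concentration whose mean
response exits the band; non-monotone draws use the lowest crossing.  The
concentration-dependency score (CDS) is the fraction of draws with a PoD;
ES_increase and ES_decrease split that fraction by the direction of the
first exit, so ES_increase + ES_decrease = CDS ≤ 1 identically.  Effects
are declared concentration-dependent at CDS > 0.5.  Median PoD and the
2.5/97.5 percentiles summarise the PoD sample.

**Known limitation.** The transition `f(x, u)` is time-homogeneous, so an
effect switching on late (between days 8 and 12) requires a steep
dependence on `x` that the smooth low-rank prior discourages; part of the
onset mismatch is absorbed into process noise, which widens the control
band at late timepoints and makes late-onset effects conservatively
detected (CDS near the 0.5 decision boundary where an immediate-onset
effect of the same size reaches CDS ~0.95).  Day-1 effects are likewise
expressed only from the second timepoint onward, because the predictive
replay starts at the control initial state.  PoD resolution is limited by
the spacing of tested concentrations: for step-like effects the recovery
tests use a PoD grid whose step matches the bracketing interval of the
tested concentrations, since the data cannot localise a crossing more
finely than that.

## BER integration

The BER for a scenario is the lowest median PoD among readouts passing
the CDS filter divided by the matched exposure: upper-airway tissue PoDs
against the maximum upper-respiratory-tract surface concentration,
alveolar PoDs against the lower-tract value, systemic drugs against the
literature plasma C_max, with nasal-spray scenarios confined to the nasal
cavity (delivered mass per area per day).  The headline per scenario is
the minimum BER across tissue models and observation days (worst case).
Classification threshold defaults to 1; 3 is offered as the
precedent-based conservative option.  A flag allows including PoDs that
fail the CDS filter for sensitivity analysis, and transcriptomic
(latent-variable) readouts can be excluded to mirror readout-panel
variants of the ratio rules.

## Problem sizes

The test-suite and the acceptance script run the desk profile throughout:
synthetic studies with 1 material × (vehicle + 3 concentrations) × 4
timepoints × 3 replicates; 3 SMC chains × 400 retained draws; 10 datasets
for the null-calibration and risk-separation properties; 10^5 particles
for the Monte-Carlo deposition oracle on a 3-generation toy tree; 0.01-min
explicit-Euler steps over 2 days for the clearance oracle; 500 fresh
control means per timepoint for the coverage check.  These sizes were
chosen so each property is measured well inside its Monte-Carlo error at
desk scale.
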