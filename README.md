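# respirisk

Exposure-led, non-animal inhalation risk assessment in Python: predict how
much of an inhaled aerosol ends up on each region of the human airway,
model in vitro concentration–time bioactivity to extract points of
departure (PoDs), and combine the two into bioactivity-exposure ratios
(BERs) that separate low- from high-risk chemical-use scenarios.

It is written for toxicologists and exposure scientists building
new-approach-methodology (NAM) risk assessments, and for methodologists
who want a fully testable, seed-reproducible reference implementation of
the chain:

1. **Lung dosimetry** — a symmetric 23-generation airway tree (trachea =
   generation 1); per-generation deposition from impaction, gravitational
   sedimentation and Brownian diffusion along a two-pass (inhale/exhale)
   serial filter, with semi-empirical extrathoracic capture.
2. **Clearance kinetics** — a compartmental particle-transport model
   (fast/slow/sequestered per generation, mucociliary escalator routing)
   driven by repeated daily exposure events and integrated exactly with
   matrix exponentials; local exposure is retained mass over generation
   surface area (µg/cm²).
3. **PoD inference** — a nonlinear state-space model
   `y_t ~ N(x_t, σ_e)`, `x_t = x_{t-1} + f(x_{t-1}, u) + v_t` with a
   reduced-rank Gaussian-process prior on `f`, fitted by adaptive-tempering
   sequential Monte Carlo over multiple chains (Rhat-checked).  PoDs are
   the lowest concentrations at which the posterior mean response exits
   the 95% credible range of control; the concentration-dependency score
   (CDS) is the fraction of posterior draws exhibiting a PoD, split into
   ES_increase / ES_decrease by exit direction.
4. **Risk integration** — BER = lowest concentration-dependent PoD /
   predicted exposure, per matched region (or plasma C_max for systemic
   drugs); scenarios with minimum BER below the threshold are flagged.

A synthetic-data generator with closed-form ground truth emulates the
12-day repeated-exposure study design (3 concentrations + vehicle, days
1/4/8/12, 3 replicates, log-normal noise, time-onset effects), so the
whole pipeline runs and is validated without any external data.
`docs/methods.md` documents the models, priors and numerical choices.

## Worked example

The `analysis/` scripts run the pipeline end to end on the bundled
benchmark scenarios and a simulated bioactivity study, writing tables to
`results/`:

```bash
python analysis/01_dosimetry_scenarios.py   # exposure per scenario
python analysis/02_simulate_bioactivity.py  # synthetic 2-readout study
python analysis/03_fit_pod.py               # SMC fits -> PoD/CDS tables
python analysis/04_ber_ranking.py           # BER ranking
```

The dosimetry stage prints worst-case regional surface exposures, e.g.
(µg/cm², 12 exposure days):

```
                 scenario risk   max_upper_ug_cm2  max_lower_ug_cm2
       Akemi tile coating high           1.53e+03               557
          PHMG humidifier high               15.9              4.43
 Coumarin anti-perspirant  low           0.000922           0.00026
```

The fitting stage recovers the simulated effect: the barrier-integrity
readout (true detectability threshold 0.245 µg/cm²) is declared
concentration-dependent from day 4 with a conservative median PoD, while
the null cytokine readout stays below the CDS decision threshold:

```
teer (ground truth 0.245 ug/cm2):
  day  4.0: CDS=0.97 ES+=0.03 ES-=0.94 median PoD=0.464
  day 12.0: CDS=0.99 ES+=0.04 ES-=0.95 median PoD=0.534
il8 (ground truth no effect):
  day 12.0: CDS=0.35 ES+=0.35 ES-=0.01 median PoD=0.201
```

The BER ranking then divides that lowest PoD by each scenario's exposure:
high-exposure scenarios (tile-coating worker, humidifier, occupational
silica) come out with BER « 1 and are flagged, while consumer sprays sit
two to three orders of magnitude above their exposure:

```
                 scenario  min_ber  flagged
       Akemi tile coating 0.000777     True
          PHMG humidifier   0.0976     True
 Coumarin anti-perspirant 1.66e+03    False
```

A CLI wraps the same stages: `respirisk dosimetry|pod|ber|simulate`.

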