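# musthtrack

Detecting **musth** — the periodic reproductive state of male African
savanna elephants, marked by temporal-gland secretion and sharply
elevated activity — directly from GPS tracking collars.

Adult bulls in musth travel roughly twice as fast over much larger daily
ranges than outside it, and the contrast grows with age. `musthtrack`
turns that movement signature into a tested analysis pipeline for
movement ecologists working with bio-logging data:

1. **Track preprocessing** — hourly downsampling of raw fixes, gap
   filling with a continuous-time correlated random walk (integrated
   Ornstein–Uhlenbeck velocity model, exact Kalman filter/smoother), and
   per-day quality control (≥ 20 hourly fixes, no gap over 4 h).
2. **Daily movement statistics** — mean speed from haversine step
   distances, daily range as a 95% minimum convex polygon on a local
   azimuthal-equidistant plane, Benhamou's corrected sinuosity.
3. **Musth × age mixed-effects models** — for log daily speed or log
   daily range: musth interacting with age, age², and five environmental
   covariates (NDVI, slope, terrain ruggedness, distance to water,
   protected area), a per-individual random intercept and NDVI slope,
   lag-1 autoregressive residuals with state-specific variances,
   backward selection by likelihood-ratio tests, and musth/non-musth
   effect ratios with bootstrap confidence intervals.
4. **An ordered three-state Bayesian HMM** that finds a musth bout in a
   window of daily series without using the observations at all: states
   may only advance (before → musth → after), emissions are Gaussian per
   state, latent states are marginalised by the forward algorithm, and
   the posterior is sampled by seeded adaptive MCMC with split-R̂
   convergence checks, posterior decoding and posterior predictive checks.
5. **Evaluation** — field sightings (2–3 musth signals = musth, one
   signal excluded) expanded to ±1 day, confusion matrices, and
   sensitivity/specificity pooled and per individual.
6. **A synthetic-data generator** that reproduces the statistical
   structure of the study system (age-scheduled bouts, 2.14× speed and
   2.11× SD musth multipliers, AR1 day noise, individual heterogeneity,
   covariate fields), so the whole pipeline is testable end to end with
   known ground truth.

## The models in brief

Daily log speed $y_{it}$ for bull $i$ on day $t$:

$$y_{it} = x_{it}^\top\beta + z_{it}^\top b_i + \varepsilon_{it},\qquad
b_i \sim N(0, G),\qquad
\mathrm{corr}(\varepsilon_{it}, \varepsilon_{it'}) = \varphi^{|t-t'|},$$

with residual SD $\sigma$ on non-musth days and $\delta\sigma$ in musth.
$\beta$ is profiled by GLS and $\sigma^2$ analytically; ML fits feed the
LRT-based selection, REML the reported estimates.

The detector models a window of daily log speed $\bar S_t$ as

$$\bar S_t \mid k \sim N(\beta_k, \sigma_k),\qquad k \in \{1,2,3\},$$

with transitions restricted to $\{1\to1, 1\to2, 2\to2, 2\to3, 3\to3\}$
and daily transition probabilities $q_1, q_2$. The run of days in state
2 is the musth bout; its posterior gives the bout interval and a
duration SD.

## Worked example

`examples/05_detect_musth.py` draws a 240-day window with a musth bout
on days 100–160 (state means 4 residual SDs apart) and runs the
detector at the scaled sampler configuration:

```
retained samples: 4000 (4 chains x 1000)
max R-hat: 1.002 (converged: True)
  beta1  posterior mean -1.173 [-1.211, -1.133]
  beta2  posterior mean -0.400 [-0.451, -0.348]
  beta3  posterior mean -1.209 [-1.248, -1.169]
  q1     posterior mean +0.015 [+0.002, +0.041]

decoded musth days 100-160 (truth 100-160), duration 61.0 +/- 0.4 days
PPC quantiles: mean 0.51, max 0.41, lag-1 acf 0.77
```

The state means recover the generating values (−1.2, −0.4, −1.2 log
km/h), every day of the bout is decoded correctly, and the posterior
predictive quantiles sit in the interior, i.e. no misfit flag. The other
examples cover roster bookkeeping, preprocessing, daily metrics, the
mixed model (ratios 1.01 / 1.48 / 2.16 at ages 20 / 35 / 50 against
generating values 1.0 / 1.49 / 1.99) and the full pipeline, where three
simulated over-35 bulls are detected with sensitivity and specificity
1.00.

A thin command line mirrors the stages:

```bash
musthtrack simulate --out sim --seed 2
musthtrack metrics --fixes sim/fixes.csv --env sim/env --ages sim/ages.csv --out daily.csv
musthtrack detect-musth --daily daily.csv --obs sim/observations.csv --seed 1 --out det
musthtrack report --detection det/detection.json --out report
```

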