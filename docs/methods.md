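# Methods

This note records the models, conventions and numerical choices behind
`musthtrack`, in the order data flows through the pipeline.

## Data model and calendar conventions

Fixes are WGS84 positions with UTC timestamps, strictly increasing per
individual; duplicate timestamps collapse to the first with a warning.
All calendar "days" downstream are defined in East Africa Time (UTC+3),
the study-site timezone, so a day spans one local day–night cycle. Ages
are integer years anchored to a fixed 31 August birthday (the dry-season
midpoint, chosen so bulls do not change age class during peak musth
months); `age_at` increments on that date.

Field sightings score three musth signals (temporal gland swelling,
secretion, urine dribbling). 2–3 signals → `musth`, 0 → `non_musth`,
exactly 1 → `excluded` (retained but skipped by every downstream stage).
Pre-labelled exports are accepted via a `prelabelled` flag. For
evaluation and for building the mixed-model analysis set, each usable
sighting labels the day before, the day of, and the day after the
observation; when a musth and a non-musth observation both claim a day,
a same-day observation wins, otherwise the day is dropped as conflicted.

The packaged roster (`data/roster.csv`) is a transcription of the study
sample table, one row per bull, no totals row; totals are always
computed. Its tallies — 25 bulls aged 20–52, 538/199 observation days
and 1,375/496 analysed tracking days (non-musth/musth) — serve as exact
bookkeeping fixtures.

## Track regularisation

Collars deliver 15/30/60-min fixes; `downsample_hourly` keeps the fix
nearest each top-of-hour within a ±5-min snap tolerance (the tolerance
is our choice; timestamps are snapped to the hour so the regular grid is
exact). Hours with no fix inside the tolerance become gaps — nothing is
fabricated at this stage.

Gaps of at most 4 h are filled by the continuous-time correlated random
walk: per axis of a local azimuthal-equidistant projection (spherical
formulas, centred on the track centroid), velocity follows a stationary
Ornstein–Uhlenbeck process with mean-reversion rate θ (1/h) and
stationary SD ζ (km/h), and position integrates velocity. The exact
discretisation gives a 2×2 linear-Gaussian state space; measurement
error is fixed at zero (collar GPS error is metres against hourly
displacements of hundreds of metres), so the likelihood conditions on
the first fix with velocity at its stationary distribution. Parameters
are shared across axes and fitted per individual by L-BFGS on
(log θ, log ζ); a ζ estimate pinned at the lower bound flags a
degenerate (e.g. stationary) track and interpolation falls back to
linear-in-time. The Kalman filter was validated against a dense
Gaussian-process oracle built from the analytic integrated-OU
covariance (agreement ~1e-13), the smoother reproduces observed fixes
exactly, and predictions converge to straight-line interpolation as
θ → ∞ — the three contracts the test suite asserts.

Day QC: a day is analysable iff it has ≥ 20 hourly fixes (interpolated
fixes count) and no gap > 4 h. A gap is charged to every day
overlapping the open interval between its bracketing fixes, so an
overnight hole counts against both adjacent days.

## Daily movement statistics

*Mean speed* is the mean over consecutive-fix steps of great-circle
(haversine, R = 6371.0088 km) distance divided by elapsed time, so days
with a few merged 2-h steps remain comparable. The step crossing local
midnight belongs to the day it ends in.

*Daily range* is the 95% minimum convex polygon: fixes are projected to
a local azimuthal-equidistant plane, the ⌈0.05 n⌉ points farthest from
the arithmetic centroid are peeled (ties: earlier timestamp first), and
the convex hull area of the rest is reported in km². Collinear days give
area 0 rather than an error. Whether to hull geographic or projected
coordinates is a genuine choice; we project, which makes areas metric
and rotation-invariant (asserted to 1e-9 relative).

*Sinuosity* is Benhamou's corrected index
S = 2[p((1+c)/(1−c) + b²)]^(−1/2) with p the mean step length, c the
mean cosine of turning angles, b the CV of step lengths (population
convention); a perfectly straight path returns 0. It is computed and
carried as an optional column only — in data of this kind it is nearly
collinear with speed and range, so the models use the other two.

## Environmental covariates

Rasters are ESRI ASCII grids in geographic coordinates (a plain-text
format that carries its own georeferencing); cell sizes are converted to
metres at the grid's central latitude. Slope (0–90°) and aspect use
Horn's eight-neighbour differences with edge padding; the vector
ruggedness measure decomposes per-cell unit normals from slope/aspect
and takes 1 − |mean resultant| over a 3×3 window, so flat and uniformly
inclined terrain both score 0. NDVI comes as 16-day composites named by
window start date; a fix samples the slice whose window contains its
(EAT) date. Raster sampling is nearest-cell (appropriate to 250-m NDVI
against sub-km daily movements; bilinear would be a one-line change).
Distance to water is the planar distance (km) to the nearest water
geometry on the shared study projection — indistinguishable from
great-circle at study-area scale; protected-area membership is
point-in-polygon. Daily covariates are arithmetic means over the day's
fixes, with protected rounded to the nearest binary (0.5 rounds up).

Model inputs are standardized (x − x̄)/s with the sample SD (n − 1),
computed once over the pooled analysis set, never per individual; age is
centred at 35 years (the age from which clear annual musth periods are
expected) but kept in years.

## Mixed-effects models

Response: log daily mean speed or log daily 95% MCP over the labelled
analysis days. Fixed effects: musth (0/1) interacting with age, age²,
and the five standardized covariates with their squares (24 columns
including intercept; quadratics only with their linear term,
interactions only with both mains). Random effects: per-individual
intercept and NDVI slope with unstructured 2×2 covariance G. Residuals:
AR1 within individual with correlation φ^Δdays across calendar gaps
(the continuous-AR1 convention — bulls have non-consecutive included
days) and state-specific variances σ² / (δσ)².

The marginal likelihood is evaluated per individual through Cholesky
factorisations of V_i = Z_i A Z_iᵀ + C_i (A = G/σ², C_i the
δ-weighted AR1 correlation), with β profiled by GLS and σ² analytically;
the optimizer (Nelder–Mead polished by L-BFGS) works on the Cholesky of
A, atanh φ and log δ. The degenerate case (G = 0, φ = 0, δ = 1)
reproduces the closed-form OLS log-likelihood to 1e-13, and with φ = 0,
δ = 1 the fit matches statsmodels' MixedLM random-intercept+slope
estimates — the two independent anchors in the test suite.

Backward selection drops one term per step — the least significant
droppable term under marginality — using single-term-deletion LRTs on
ML fits (χ², df = difference in parameter counts), stopping when all
remaining terms have p < 0.05; the final model is refit by REML. The
random structure is fixed, not selected; fits with φ or δ disabled
exist to reproduce the within-group correlation LRT diagnostics.

Effect ratios: ratio(a) = exp(musth contrast at centred age a − 35 and
mean covariates) — only the musth main effect and musth × age terms
survive because standardized covariates sit at 0 (protected is taken at
0, i.e. outside). Confidence intervals resample individuals with
replacement (1,000 resamples by default); each resample re-estimates β
by GLS with the variance parameters held at the full-data estimates,
which keeps 1,000 resamples affordable — a full re-maximisation per
resample is available via `refit="full"`. Percentile intervals are
reported.

## The musth detector

Windows: an individual is eligible with ≥ 6 usable sightings including
≥ 1 in musth, and the window takes up to 120 days either side of the
midpoint between the first and last musth sightings, truncated to data
availability, requiring ≥ 120 days total and < 10% missing daily
values. The series is daily log mean speed (or log MCP via the response
switch, which runs the identical machinery).

Model: three ordered states — slower before (state 1), elevated during
(state 2), slower after (state 3) — with Gaussian emissions N(β_k, σ_k)
and daily transition probabilities q₁ = P(1→2), q₂ = P(2→3); the chain
starts in state 1 and no other moves are possible, so a window encodes
exactly one bout (multi-bout windows are out of contract, and this is
precisely why short-bout young bulls degrade). Missing days contribute
transition-only steps. The forward algorithm in log space exploits the
sparse transition structure; it is tested against brute-force
enumeration of all monotone paths (T ≤ 8, 1e-10) and an
importance-sampling estimate over prior path draws. Environmental
covariates are deliberately absent: the point is detection from
movement alone.

Priors: β₁, β₃ ~ N(m₀, 0.5) and β₂ ~ N(m₀ + 0.7, 0.5) with m₀ the
window median of the observed series, the ordering β₂ > max(β₁, β₃)
enforced by an offset parameterization (β₂ = max(β₁, β₃) + e^u);
σ_k ~ half-normal(0.5); q₁, q₂ ~ Beta(1, 30), encoding that a bout is
entered rarely on any given day and lasts weeks. These are this
package's own weakly-informative choices, anchored to the window like
the mixed-model-informed priors they stand in for.

Sampling: component-wise adaptive random-walk Metropolis in the
unconstrained parameterization (8 coordinates per sweep), compiled with
numba. Per-coordinate proposal scales adapt toward 0.44 acceptance
during warmup only and are frozen afterwards, so retained draws target
the exact posterior. Chains are independent with seeds derived from the
run seed; two runs with the same seed are bit-identical. The reference
configuration is 8 chains × 5,000 warmup + 5,000 sampling = 40,000
retained samples; the scaled default for simulation studies is 4 chains
× 1,000 + 1,000 with within-chain thinning of 4 (thinning buys the
mixing that the full run gets from length; retained draws remain
chains × iters). Convergence is rank-normalised split R̂ (arviz) with
the R̂ ≤ 1.1 criterion; failures flag the posterior rather than stop it.

Decoding: per-day P(state 2) averages forward–backward smoothed
marginals over (thinned) posterior draws; a day is called musth when
P > 0.5 (the natural symmetric threshold). Bout-duration uncertainty
comes from forward-filter backward-sampling path draws: the SD over
draws of the number of state-2 days. On 4σ-separated synthetic windows
the decoded interval matches truth to within ±2 days in ≥ 90% of seeded
replicates with all R̂ ≤ 1.1.

Posterior predictive checks simulate a replicated series per draw (path
from FFBS, then Gaussian emissions) and report the mid-quantile of the
observed mean, max and lag-1 autocorrelation among replicates. Note a
structural caveat: PPC p-values of statistics the fit has adapted to
are conservative (they concentrate near ½ rather than being uniform),
so the calibration property we assert is the operational one — model-
drawn data are essentially never flagged, while a constant series or
strongly autocorrelated residuals are flagged at the extremes. The
lag-1 check flags AR1-generated windows, the expected misfit of an
independent-error emission model.

## Evaluation

Decoded days are scored against the expanded ±1-day labels on their
overlap. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), reported
both pooled and as the mean of per-individual values; the per-individual
mean is primary because bulls contribute very different numbers of
observation days. Counts partition the evaluable labelled days, and
swapping classes swaps the two rates — both asserted as properties.

## Synthetic data generator

The generator is first-class, tested code and defines the conditions
every simulation study runs under. Each individual-day draws a latent
log mean-speed level: non-musth baseline 0.3 km/h at age 35 (a
plausible daily mean for savanna bulls at this fix rate) with a
−0.005/yr age trend, a per-individual N(0, 0.15²) intercept, AR1(0.4)
day-to-day noise with stationary log-SD 0.15, and a musth shift.
Musth multiplies expected speed by 2.14 and its day-to-day SD by 2.11
via exact lognormal moment matching. Bulls ≥ 35 get one ~60-day bout
per simulated year; younger bulls get ~three ~14-day bouts. Hourly
tracks realise each day's level as a correlated walk (gamma step
lengths renormalised so the day's mean hourly step equals the level,
wrapped-normal headings, soft containment within the study extent) on
the projected plane, inverse-projected to WGS84 — so haversine-based
metrics recover the generated levels to within 2%. Sightings are
Bernoulli per day (default 0.05) with 2–3 signals in musth, 0 outside,
and a configurable single-signal fraction to exercise the exclusion
rule. Covariate stacks are smooth random elevation (non-trivial
slope/VRM), seasonal sinusoidal NDVI at the 16-day cadence, one river
polyline and one protected rectangle; everything is deterministic per
seed.

What the generator does *not* emulate: habitat selection and covariate-
dependent movement (covariates influence nothing in the simulator, so
pipeline tests of the covariate terms are purely structural),
social/rank dynamics, collar failure patterns beyond iid dropout, and
multi-year age progression. Passing tests therefore demonstrate the
statistical machinery under the assumed generative structure, not
ecological realism.

## Problem sizes and numerical choices

Simulation studies use deliberately modest sizes chosen for single-CPU
runs: 240-day windows with 25–50 replicates for recovery, 4–5
individuals per age class over 300 days for detection quality, 30 × 90
to 30 × 120 individual-days for mixed-model recovery, 200-resample
bootstrap CIs in scripts. Tolerances: forward-vs-enumeration 1e-10,
Kalman-vs-GP 1e-6, OLS degenerate case 1e-8, MCP-vs-oracle 1e-9
relative; parameter-recovery checks use 3 SEs from the observed
information. Ties: the MCP peel removes the earlier timestamp first; a
protected-area day mean of exactly 0.5 rounds up; the PPC quantile is
the mid-quantile (average of < and ≤ fractions) so ties are unbiased.
Degenerate inputs: constant-position tracks flag the CTCRW boundary;
constant windows drive σ to the half-normal boundary and flag
non-convergence rather than crash; zero-variance covariates error by
name at standardization.

## Known limitations

- Exactly one bout per window by construction; multi-bout behaviour
  must be windowed externally.
- The random-walk sampler, while well within the R̂ contract on this
  8-parameter posterior, is not gradient-based; very flat windows (no
  bout) can flag non-convergence because q₁ is then prior-dominated.
- The AR1 found in real daily speed series is deliberately absent from
  the HMM emission model (the autoregressive-error variant was
  evaluated and rejected in the source analysis); the lag-1 PPC
  reports, but does not correct, this misfit.
- Distance-to-water and the projection are spherical-Earth
  approximations; at continental scales an ellipsoidal implementation
  would be needed.
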