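# Methods

`coraltol` estimates how fast the thermal tolerance of a coral assemblage has
risen over recent decades, by asking which simulated tolerance trajectory makes
historic heat stress best explain historic bleaching, and then carries the
selected trajectory into future bleaching projections. This note documents the
model, the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Heat stress (DHW) with a moving tolerance baseline

Heat stress follows the standard degree-heating-week convention. For a cell
with daily SST, the climatology is the set of 12 monthly mean temperatures
over a configurable period (default 1985–2012) and MMM is their maximum. The
daily HotSpot is the positive part of SST − (MMM + Δ_y), and DHW on day *i*
is the sum of HotSpot/7 over days *i*−83 … *i*, counting only days whose
HotSpot is at least 1 °C. Numerical details:

- **Accumulation cutoff.** The boundary case HotSpot = 1.0 °C accumulates
  (the condition is ≥ 1, not > 1).
- **Tolerance enhancement.** A scenario with rate ρ (°C/decade) raises the
  baseline by ρ/10 at each Jan-1 boundary after a start year (default 1988,
  when temperatures are at their seasonal low), so Δ_y = ρ·max(0, y−y₀)/10,
  constant within a calendar year. Δ is added to MMM, so the HotSpot
  reference and the effective MMM + Δ + 1 accumulation threshold shift
  together. This makes daily DHW, annual event counts and high-frequency
  proportions non-increasing in ρ — a property the test suite checks across
  the whole rate grid.
- **Exact accumulation.** The 84-day window is accumulated oldest-day-first
  so the rolling result is bit-identical to a sequential per-window sum;
  the suite verifies equality with an independent double-loop oracle.
- **Warm-up.** The first 83 days carry a truncated-window DHW and a warm-up
  flag; analyses exclude flagged days.
- **Missing data** are never imputed here: a missing SST day blanks its
  HotSpot, and any missing HotSpot inside a window blanks that day's DHW.
- **Leap days** join February's monthly mean; no day-of-year climatology is
  needed at this stage.

## Bleaching observations

Surveys are ordinal severity scores: 0 (0 % bleached), 1 (1–10 %), 2
(11–50 %), 3 (> 50 %). For the beta likelihood, scores are divided by 3 and
squeezed off the boundary with (y·(n−1)+0.5)/n, where n is the record count
of the modelled dataset (recomputed for any subset analysed). Observations
dated only to a month use the DHW of the 15th; each record takes DHW from
the 0.05° cell whose half-open interval [west, east) × [south, north)
contains it.

## Spatial beta regression

The response CB_i ∈ (0,1) is modelled as Beta(mean π_i, precision θ) with
logit(π_i) = β₀ + β₁·DHW_i + u_i, Var(CB_i) = π_i(1−π_i)/(1+θ), and u a
zero-mean Gaussian field with Matérn covariance (smoothness ν = 1, the
stochastic-PDE default; range r parameterised as κ = √(8ν)/r so correlation
≈ 0.1 — exactly 0.1397 for ν = 1 — at distance r). Distances are great-circle
kilometres. Rather than a triangulated-mesh approximation, the field is
represented exactly at the observation sites, which is practical for the
hundreds of observations this problem involves.

Inference is empirical-Bayes MAP + Laplace:

1. For fixed hyperparameters (θ, σ, r), the latent block (β₀, β₁, u) is
   maximised by damped Fisher scoring (expected information; always
   positive definite).
2. Hyperparameters maximise the Laplace-approximated marginal posterior by
   Nelder–Mead on the log scale, warm-starting the inner mode.
3. Uncertainty, credible bands and DIC come from Gaussian draws around the
   mode (seeded; results store the seed and are deterministic given it).
   Conditioning the latent covariance on the hyperparameter mode alone
   measurably undercovers (β coverage ≈ 0.94 instead of 0.95 in
   model-matched simulation), so hyperparameter uncertainty is restored by
   the delta method: the numeric Hessian of the marginal objective gives
   Var(λ), finite-difference sensitivities give dz/dλ, and the coefficient
   covariance becomes H⁻¹ + J Var(λ) Jᵀ.

Priors: vague N(0, 10²) on β₀ and β₁; Gamma(2, rate 0.1) on θ; log-normal
priors with unit log-scale spread centred at r₀ = 20 km and σ₀ = 1. An
observation-level Gaussian nugget is available but off by default: with a
beta likelihood already carrying a dispersion parameter, the nugget is
weakly identified at these sample sizes. Correlation matrices receive a
relative 1e-8 diagonal jitter so near-coincident sites (observations in the
same cell) stay numerically positive definite.

DIC is D̄ + p_D with p_D = D̄ − D(mode), where D̄ averages the deviance over
the Laplace draws (default 400; ~300 in the scan). The Monte-Carlo noise on
DIC is well below 1 unit at these sizes, versus the >10-unit gaps that drive
rate selection. A non-spatial fit (u ≡ 0) is available and flagged in the
results; with the field disabled the estimates agree with a quasi-likelihood
logit fit, which the suite checks against statsmodels, and an ensemble-MCMC
cross-check (emcee) of the non-spatial posterior is provided and tested.

Interval calibration: at n = 200 with the model-matched generator, the 95 %
Laplace intervals for β₀ and β₁ cover the generating values in ≥ 90 % of
replicates (the suite measures this over 50 fits).

## Rate selection

The scan refits the regression under each candidate rate (default grid
0–0.3 °C/decade, step 0.025), rebuilding offsets and DHW but sharing one
climatology (the baseline moves; the climatology period does not). The
selected rate minimises DIC; ties break to the lower rate (the more
conservative claim of enhancement); a max ΔDIC < 2 raises a flat-profile
warning. Per-rate seeds derive from the master seed plus round(rate·1000),
so duplicate rates are bit-identical while distinct rates are independent.

Prediction skill snaps each fitted π to the nearest of {0, 1/3, 2/3, 1};
exact midpoints (1/6, 1/2, 5/6) snap to the lower severity, a fixed
deterministic convention. Correct / over- / under-prediction rates always
partition to one.

## Future projections

GCM-like series are seasonally adjusted by the delta method: subtract the
model's day-of-year climatology and add the observational one, both taken
over a shared 1985–2010 baseline and smoothed with a centred circular
31-day running mean (Feb 29 folds into day 59). An identical model series
comes back unchanged and a constant bias is removed exactly. With the
31-day smoother, the post-correction climatology reproduces the
observational one exactly wherever the climatological bias is locally
constant across the smoothing window (the interior of a biased season);
with smoothing disabled (window = 1) the identity is exact everywhere. The
suite checks all three identities.

Future DHW uses the historical observational MMM with scenario offsets
continued forward from the start year — a fixed-baseline design, so the
tolerance scenarios rather than re-estimated climatologies drive the
differences. A bleaching event is a year whose annual-max DHW reaches
8 °C-weeks (Alert Level 2, boundary included). High-frequency bleaching in
year y means ≥ 2 events within the centred decade y−4 … y+5 (a fixed
convention for the even window; edge years use the truncated window and are
flagged). Per year, the proportion of cells flagged is summarised across
GCMs as mean ± SE (sd/√G); the machinery is GCM-count-agnostic. Regridding
(bilinear to a shared coarse grid, nearest-neighbour to the fine grid) is
provided as in-memory interpolation operators. Gregorian and 365-day model
calendars are supported — the noleap mapping places day-of-year onto the
matching Gregorian date and, as part of the calendar conversion, leaves
Feb 29 missing; 360-day calendars are rejected with an explicit error.

## Synthetic data

The generator emulates the data the analysis consumes, with stored ground
truth. Daily SST per cell = mean (28.5 °C, Palau-like) + 1.0 °C seasonal
sinusoid (peak in early September) + 0.15 °C/decade trend + AR(1) anomalies
(coefficient 0.7; innovations split into a shared regional component and a
smaller per-cell component, since SST anomalies are coherent at the ~100 km
domain scale) + scheduled heatwaves. Defaults place three half-sine pulses
of equal size (1.4 °C amplitude, 75 days) on the seasonal peak of 1998,
2010 and 2017 — three widely separated events of similar magnitude, giving
annual-max DHW of roughly 6–9 °C-weeks under a fixed baseline, the observed
magnitude of major bleaching events. Because the events are equal by
construction, any divergence in simulated bleaching between early and late
events is caused purely by the true enhancement rate, which is exactly the
signal the rate scan must detect.

Surveys: sites are uniform within randomly chosen cells; a Matérn field
(default σ = 0.5, r = 20 km) is drawn at the sites; percent-bleached comes
from Beta(mean = logistic(β₀ + β₁·DHW_true + u), precision θ) with defaults
β₀ = −3.5, β₁ = 0.6, θ = 10 (near-zero bleaching probability in calm years,
severe bleaching at DHW ≈ 7). Percent is recorded to the nearest whole
percent before binning, emulating how surveyors report: a continuous draw
is never exactly 0 %, but sub-0.5 % bleaching is recorded as "no
bleaching", and without this step the score-0 class — which anchors the
regression at low DHW — would never occur. Survey dates
cover the three events plus calm years (2014–2016), mirroring a realistic
monitoring history. Everything is bit-reproducible under the stored seed,
and the generator writes the same CSV formats the pipeline reads.

What the generator does **not** emulate: satellite retrieval error, cloud
gaps, real bathymetry/geography, non-linear or piecewise tolerance change,
and observer differences between survey methods. Passing recovery tests
therefore show the inference machinery is correct and well calibrated under
the model's own assumptions — not that real-world selection noise is this
benign.

A note on the recovery report's coefficient coverage: in the full pipeline
the fitted response is the transformed ordinal score while the generator's
β applies to the continuous percent scale, so binning attenuates the
coefficients and their intervals are not expected to cover the generative β
(the report still records this). Calibration is instead assessed with the
model-matched generator (`simulate_beta_response`), where coverage is the
meaningful check.

## Problem sizes and determinism

Default study sizes used by the test suite and the acceptance script — 20
cells (3 for pure monotonicity checks), 36 years of daily SST, 300
observations per replicate, 20 replicates per truth level, 50 calibration
fits at n = 200, 200–400 Laplace draws — were chosen as the smallest sizes
at which the signals of interest (ΔDIC ≫ 2, coverage estimable to a few
percent) are comfortably resolved. Every stochastic routine takes an
explicit seed; scans derive per-rate seeds as above; replicated experiments
spawn child seeds from a master seed.

## Known limitations

- The enhancement rate is constant and linear from 1988; time-varying or
  piecewise rates are out of scope.
- The non-spatial fit is the default in the replicated scan for speed; the
  spatial field is exercised in dedicated recovery tests. With strongly
  clustered observations, the non-spatial DIC profile can understate
  uncertainty in the selected rate.
- DIC conditions on plug-in hyperparameters (empirical Bayes); hyperprior
  uncertainty is not propagated into the deviance draws.
- The 360-day model calendar is rejected rather than mapped.
- Identification of ρ degrades gracefully with weak data (few observations,
  or events far from the accumulation threshold); the flat-profile warning
  flags this.
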