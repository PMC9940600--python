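# Methods

`relkin` analyses cumulative drug-release profiles from oral nanoparticle
formulations measured sequentially in simulated gastric fluid (SGF, pH 1.2,
0–2 h), simulated intestinal fluid (SIF, pH 4.5, 2–5 h) and simulated
colonic fluid (SCoF, pH 7.4, 5–48 h), and provides the companion cell-assay
computations (viability %, doubling time, IC50). This note records the
models, conventions, numerical choices and limitations.

## Kinetic models

Cumulative release F(t) is in percent of loaded drug; time t is in hours.
The registry holds the eight classical empirical models:

| model | equation | parameters |
|---|---|---|
| zero order | F = k0·t | k0 |
| first order | F = 100·(1 − e^(−k1·t)) | k1 |
| Higuchi | F = kH·t^0.5 | kH |
| Korsmeyer–Peppas | F = kKP·t^n | kKP, n |
| Peppas–Sahlin | F = k1·t^m + k2·t^(2m) | k1, k2, m |
| Hopfenberg | F = 100·(1 − (1 − kHB·t)^n) | kHB, n |
| Hixson–Crowell | F = 100·(1 − (1 − kHC·t)^3) | kHC |
| Weibull | F = 100·(1 − e^(−(t − Ti)^β / α)) | α, β, Ti |

Default bounds: rate-like constants (1e−6, 1e3); power-law exponents n, m
∈ (0.01, 3); the Hopfenberg exponent is treated as continuous in [0.5, 5]
(fitted values need not sit on the slab/cylinder/sphere integers); Weibull
α ∈ (1e−6, 1e6) so that α = 1/k1 is representable across the full
first-order rate range, β ∈ (0.01, 5). The Peppas–Sahlin relaxation
coefficient k2 may be negative. The Weibull lag time Ti is fixed at 0 by
default (lag behaviour is not part of the intended use); it can be freed
via `FitOptions(fix_params={"Ti": None})`. The Peppas–Sahlin diffusional
exponent m is free by default; the constrained software variant (m pinned,
typically at 0.45) is available via `FitOptions(fix_params={"m": 0.45})`.

Algebraic identities used as self-checks: Weibull with β = 1, Ti = 0,
α = 1/k1 is pointwise identical to first order with rate k1, and
Hixson–Crowell equals Hopfenberg with n = 3.

## Segmentation and fitting

A transit profile is split per medium window. A sample exactly on a
boundary belongs to the earlier window and re-enters the next one as its
anchor (time origin). By default each sub-profile is re-zeroed — times and
releases are expressed relative to the anchor, so every segment starts at
(0, 0) and that anchor point participates in the fit. This is required for
the power-law models, which force F(0) = 0. Absolute-coordinate fitting is
available (`rezero=False`) since either convention is defensible for the
saturating models; the package does not assert one as canonical. If no
sample falls exactly on a boundary the anchor value is linearly
interpolated. The 48 h endpoint is part of the default schedule
(0.5, 1, 2, 3, 5, 7, 10, 24, 48 h) and hence of the colonic fit.

Fits minimise the unweighted residual sum of squares between the replicate
mean and the model curve (1/SD² weighting is optional; goodness statistics
are always computed unweighted). Optimisation is `scipy.optimize.least_squares`
(trust-region reflective, bounds, xtol = ftol = 1e−14) with deterministic
multi-start: model-specific linearisation heuristics (log–log regression
for the power laws, ln(−ln(1 − F/100)) regression for Weibull, endpoint
inversion for the saturating models) plus a fixed coarse grid. No
randomness enters the optimiser, so identical inputs give bit-identical
results. For Hopfenberg and Hixson–Crowell the rate's upper bound is
tightened to (1 − 1e−12)/t_max so the (1 − k·t) base stays non-negative
over the fitted window; a free Weibull lag clamps F to 0 for t < Ti
(the physical no-release-yet reading) inside the optimiser.

## Goodness of fit and model selection

With unit weights,

    R² = 1 − SS_res/SS_tot
    AIC = n·ln(SS_res) + 2p
    MSC = ln(SS_tot/SS_res) − 2p/n

the convention of the dissolution-modelling add-ins this package mirrors.
For one dataset the two rankings coincide exactly (MSC = ln SS_tot − AIC/n),
which the suite asserts on every fitted dataset. Fits with SS_res at or
below double-precision resolution of the data (SS_res ≤ 1e−12·SS_tot) are
flagged perfect and carry AIC = −∞ / MSC = +∞ sentinels, so that ties
between perfect fits are broken by parameter count (then registry order)
rather than by rounding noise. Constant observations (SS_tot = 0) are
rejected as degenerate.

Model ranking is by ascending AIC; all models within ΔAIC ≤ 2 of the
minimum (default, configurable) are reported as co-best. This reproduces
the practice of reporting two compatible models for one segment without
inventing a sharper rule; ΔAIC ≈ 2 is the conventional "substantial
support" boundary.

## Mechanism classification

For the power-law models the diffusional exponent (n for Korsmeyer–Peppas,
m for Peppas–Sahlin; slab geometry) maps to:

* exponent ≤ 0.45 → Fickian diffusion
* 0.45 < exponent < 0.85 → anomalous (non-Fickian) transport
* exponent = 0.85 → case II transport
* exponent > 0.85 → super case II transport

For the Weibull shape parameter: β ≤ 0.75 → Fickian; 0.75 < β < 1 →
combined Fickian diffusion + controlled release; β = 1 → first-order
release; β > 1 → complex mechanism. Equality at the measure-zero
thresholds (0.85, 1.0) is taken within ε = 0.005, matching the
three-decimal reporting precision of fitted exponents; the 0.45 boundary
itself is classified Fickian (the ≤ reading, consistent with m = 0.450
being reported as Fickian). The classifiers are total step functions:
labels partition their domains with no gaps and never move backwards as
the exponent grows, which the suite property-tests on dense grids.

## Profile similarity

The difference and similarity factors follow the Moore–Flanner/FDA form:

    f1 = 100·Σ|R_t − T_t| / ΣR_t
    f2 = 50·log10(100·[1 + (1/n)·Σ(R_t − T_t)²]^(−1/2))

with verdict "similar" iff f1 ≤ 15 and f2 ≥ 50. f1 is deliberately
asymmetric (reference in the denominator); f2 is symmetric. Profiles are
compared on exactly matching time points by default; linear interpolation
of the test profile onto the reference grid is opt-in. Fewer than three
common points, and more than one reference point above 85 % release, are
surfaced as warnings rather than errors — the regulatory truncation rule
is advisory here, not enforced.

## Cell assays

Viability % = 100·OD_treated/OD_control, optionally re-normalised to a
vehicle (DMSO) group. Doubling time = duration·log 2 / (log N_final −
log N_initial); the result is base- and scale-invariant, and a negative
value signals a shrinking population. IC50 comes from a four-parameter
logistic on log-concentration, v(c) = bottom + (top − bottom)/(1 +
(c/ic50)^hill), fitted by the same deterministic multi-start least-squares
machinery with default constraints top ≤ 110 %, bottom ≥ −5 %, hill ∈
(0.1, 10) and a log10-IC50 window two decades beyond the tested range.
An IC50 outside the tested concentrations is flagged extrapolated; a flat
table returns a non-converged result with a diagnostic.

## Synthetic data

The release generator emulates the structure of the transit experiment:
the 9-point 0.5–48 h schedule, three replicates, additive Gaussian noise
on the percent scale (default SD 2 %, truncated at 0 because cumulative
release cannot be negative), reported as mean ± SD. The generating curve
is continuous across medium switches — each segment's model is evaluated
in segment-local time and offset by the cumulative release already
reached — because physical cumulative release cannot jump; this convention
is independent of the fit-side re-zeroing option. Curves that would exceed
100 % are clipped with a warning. Dose-response tables are 4PL means with
per-replicate Gaussian noise (default 6 replicates, matching the assay
design); growth counts use median-unbiased multiplicative lognormal noise.
Every stochastic call takes an explicit seed and is bit-reproducible.

What the simulations do not emulate: sampling-volume/sink-condition
corrections, inter-batch variability, autocorrelated or heteroscedastic
replicate error, instrument drift. Passing recovery tests therefore shows
the estimators are correct and well-calibrated under the stated noise
model, not that real dialysis-bag data meet that model.

### Recovery study conditions

The model-selection recovery study simulates 200 seeded profiles at 1 %
replicate noise on the 9-point schedule and asks how often the generating
model is AIC-best against all eight candidates. The generator is
Peppas–Sahlin with k1 = 5 %·h^−0.5, k2 = 1.2 %·h^−1, m = 0.5 — a release
curve with a pronounced relaxational second term reaching ≈ 92 % at 48 h.
The generator must not be nested inside another candidate: for a nested
pair the richer model absorbs noise and the ΔAIC = 2 penalty race caps the
simpler truth's win rate near 84 % regardless of noise level, which is a
property of AIC, not a defect of the fit. Peppas–Sahlin is the one
registry model no other candidate contains, and its two-term shape is the
hardest for the two-parameter models to imitate, making the ≥ 90 %
recovery target a meaningful end-to-end check of the fit-and-select
pipeline. Mechanism-label recovery uses Korsmeyer–Peppas generators with
n = 0.3 (kKP = 20) and n = 1.3 (kKP = 0.5), scaled so F(48 h) stays on the
percent scale.

Problem sizes used throughout the suite and the acceptance script — 200
selection runs, 100 label-recovery runs per exponent, 200 noisy IC50
tables, 50 brute-force-oracle instances with ≥ 10⁴ grid points each — were
chosen so the binomial/median estimates are stable at the asserted
thresholds.

## Known limitations

* Fitting uses replicate means; per-replicate curve fitting and bootstrap
  confidence intervals are out of scope.
* No geometry-aware (cylinder/sphere) exponent thresholds; slab rules only.
* The f1/f2 module performs no bootstrap confidence estimation.
* AIC here is the SSR-based small-sample convention of the dissolution
  literature, not the likelihood form with an estimated variance term;
  values are comparable within a dataset, not across datasets of
  different length.
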