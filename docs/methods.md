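# Methods

## The synthetic scene

The generator emulates two gridded records: a fine grid of 15-day NDVI
composites (24 per year, dated by a fixed 365-day calendar in which composite
`i` starts on day `1 + round((i−1)·365/24)`) and a monthly climate grid a
factor `agg_factor` coarser (default 5, so a 20×20 NDVI grid pairs with a
4×4 climate grid).

Each pixel-year NDVI curve is a double logistic

```
v(t) = base + amp · [σ(g₁(t − s₁)) − σ(g₂(t − s₂))] + ε,   ε ~ N(0, noise_sd²)
```

sampled at the 24 composite start days. `s₁`/`s₂` are the midpoints of the
green-up and senescence limbs; `g₁`/`g₂` their steepnesses (1/day). Each
December–March composite is independently replaced with probability
`snow_prob` by a snow-contaminated value drawn uniformly from
[−0.2, −0.01], which exercises the positive-February–March winter-baseline
substitution. Values are clipped to the physical NDVI range [−1, 1].

Climate is `climatology[m] + trend·(y − y₀)/10 + anomaly`, with independent
Gaussian anomalies per coarse pixel, month and year; precipitation is clipped
at zero. Configured couplings shift `s₁` (spring targets), `s₂` (autumn
targets) or `amp` (stage-NDVI targets) of every fine pixel linearly in the
deviation of the chosen month's climate value from its climatology
(trend + anomaly, after clipping) at the containing coarse pixel — so the
phenology shifts are exactly linear in what the regression stage later sees,
and both cubes draw from the same seeded streams. A static per-pixel jitter
(sd 5 days) spreads the midpoints spatially, which also decorrelates
composite-grid quantization across the pixels of a coarse cell.

**Defaults as study conditions.** 25 years, 20×20 fine pixels, baseline 0.1,
amplitude 0.5, `g₁ = 0.07`, `g₂ = 0.05`, `s₁ = 135`, `s₂ = 290`,
`noise_sd = 0.02`, `snow_prob = 0.1`, a +1 K/decade temperature trend with
1 K monthly anomalies, no precipitation trend, and three couplings: April
temperature → BGS (−3 d/K), August temperature → EGS (−4 d/K), June
temperature → mature-stage NDVI (+0.03 /K). The slopes were chosen so that
(a) the noise-free seasonal maximum sits near `base + amp` (the plateau is
>0.97 of the amplitude), (b) the ratio rises/falls by ~0.15–0.25 per
composite near the detection thresholds, as in real bimonthly grassland
series — a much steeper limb makes the literal three-consecutive-change rule
fragile, because the look-ahead window lands on the flat plateau or the
winter noise floor, which is a property of the detection rule, not of the
noise level. Coupling months were chosen to fall inside the 12-month
predictor window that the typical-date rule produces (a same-year May driver
of an early-May BGS would be excluded by the 15th-of-month rule).

**Ground truth.** True event dates are the analytic threshold crossings of
the noise-free limbs: `BGS = s₁ + logit(0.2)/g₁`, `maturity = s₁ +
logit(0.8)/g₁`, `EGS = s₂ + logit(0.4)/g₂`, `SOG = BGS − 365/24`,
`SOS = EGS − 2·365/24`, recorded both as continuous days and as the first
composite after each crossing. This keeps truth strictly linear in the
climate deviations (so regressions recover the injected coefficients to
machine precision) and fully independent of the detector code. The analytic
crossing ignores the sampled-curve normalization (the observed annual
maximum is slightly below `base + amp`, and the February–March mean slightly
above `base`), so a crossing landing very close to a composite boundary may
legitimately differ from noise-free detection by one composite; comparisons
against ground truth are therefore made at ±1 composite resolution.

## Phenology detection

Detection follows the ratio rules exactly, with these choices where the rule
is under-specified:

- "Increasing/decreasing" are strict inequalities on consecutive composites;
  a tie breaks the run and the scan continues at the next candidate.
- The three-step run *follows* the crossing composite (the crossing composite
  itself is not part of the run).
- February–March membership of a composite is decided by its start day.
- BGS is searched over composites 2–20 (room for SOG below and the
  look-ahead above); EGS over maturity+1 to 21 (look-ahead within the year).
- "Two weeks" in the stage windows is one composite. Green-up therefore
  always spans exactly 2 composites and senescence exactly 3; fast growth
  (`BGS+1 .. maturity−1`) and mature (`maturity .. SOS−1`) may be empty, in
  which case the stage mean is undefined (NaN).

Invalid pixel-years carry exactly one reason: `no_min_ref` (no positive
February–March composite), `flat_curve` (maximum does not exceed the
baseline), `event_missing`, `order_violation` (including a senescence onset
that would precede maturity), or `sparse_vegetation` (growing-season mean
NDVI < 0.1). Under the default conditions ~7% of pixel-years drop out,
almost entirely `event_missing` from noise breaking a strict run.

## Trend analysis

Mann–Kendall with tie-corrected variance
`var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18` and the ±1 continuity
correction on the normal score; two-sided p; significance defaults to
p < 0.1 (configurable — 0.05 is the common alternative). Slopes are plain
OLS per decade and are reported only where the test is significant;
non-significant pixels keep their statistics (the "gray" map state), and
pixels with fewer than 4 valid years are missing. Annual climate aggregates
are the mean of the 12 monthly temperatures and the sum of the 12 monthly
precipitation values. Monte-Carlo calibration (1000 white-noise series,
n = 25) puts the empirical type-I error at the nominal 0.10 within ±0.02.
No Sen's slope, prewhitening or field-significance correction is applied.

## Regridding

Block means ignore missing cells but a block with fewer than half its cells
valid is missing. Grids are cell-center registered in abstract units; the
bilinear step interpolates between source cell centers
(scipy `RegularGridInterpolator`) with edge clamping, and is exact on affine
fields. With the default target (the coarsened source grid) the aggregated
and target centers coincide and the bilinear step is the identity.
Event dates (composite indices/day-of-year) are regridded as continuous
values. A coarse pixel enters the PLS stage only with at least
`min_valid_years` (default 15 of 25) valid years.

## PLS driver screening

Per pixel, the design matrix holds 24 predictors (12 monthly temperatures,
12 precipitations) for the window anchored at the event's typical date —
the 75th percentile (linear interpolation) of all valid pixel-year dates
across the domain, computed once, not per pixel. Stage-NDVI responses anchor
at the end of the stage (BGS for green-up, one composite before maturity for
fast growth, one before SOS for mature, EGS for senescence). Months after
the last window month take the previous year's values; years with any
missing entry are dropped; predictors and response are centered and scaled
to unit variance (sd with one delta degree of freedom). Zero-variance
predictor columns are dropped and reported unimportant; a zero-variance
response marks the pixel insufficient.

The fit is single-response PLS (NIPALS, via scikit-learn, deterministic).
The component count is the smallest `A ≤ 10` whose leave-one-out
cross-validated explained variance `Q² = 1 − PRESS/SS` reaches 0.90; if the
criterion is never reached the cap is used. A fitted-R² selection mode is
provided as an alternative since either reading of "explained variance under
cross-validation" is defensible; CV is the default. Each fold is fitted once
at the maximum count and smaller counts are evaluated through the cumulative
score×loading expansion, which is algebraically identical to refitting.

VIP uses the standard weighted-weights formula
`VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = q_a² t_aᵀt_a`, so the mean of `VIP²` over the `p` retained
predictors is exactly 1; with all 24 retained (the default scenes) the
spec-level normalization over 24 predictors holds. Importance is
`VIP ≥ 0.8`. Note a consequence of the normalization: for a pure-noise
response roughly half the predictors exceed 0.8 by construction — the
meaningful null signature is the absence of a spatially coherent
important+signed pattern, which is what the null tests assert. With
`A = min(n−1, p)` components on full-rank data the PLS coefficients equal
the least-squares solution (checked to 1e-6).

## Orchestration

All thresholds (ratio thresholds 0.2/0.8/0.6, sparse-NDVI 0.1, MK alpha 0.1,
VIP 0.8, CV target 0.90, max components 10, min valid years 15) live in
`RunConfig`; stage code receives them as arguments. Outputs are NetCDF3
(xarray/scipy backend; int64/bool cast to int32/int8) plus CSV tables; the
manifest records a config hash, the seed, per-stage record counts and a
sha256 per output file, and reruns are byte-identical. Record counts are
conserved: every pixel-year is valid or carries exactly one invalid reason.

## Problem sizes and limitations

Tests and the acceptance script use the study-scale scene (20×20 × 25 years,
~10⁴ pixel-years; 25×25 for the 5×5-coarse-pixel driver-recovery run), which
keeps a full pipeline run in seconds while leaving every rate estimated from
thousands of records. The generator is deliberately idealized: one growing
season per year, no multi-modal or double-cropping curves, no spatial
autocorrelation in the noise, no missing composites, no geographic
projection, and snow only as negative spikes in December–March. Passing
tests therefore demonstrate correctness of the algorithms under known
structure, not robustness to every artifact of real composite archives
(orbital drift, aerosol contamination, mixed pixels). The detection rules
themselves are threshold-based and carry the composite grid's ~15-day
quantization; recovery is accordingly scored at ±1 composite.
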