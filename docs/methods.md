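# Methods

## Set-points and deviation convention

An individual's set-point band `T_set` is the 25th–75th percentile of its
laboratory thermal-gradient trace, with percentiles computed by linear
interpolation between order statistics (the numpy default; other methods are
selectable through `extract_tset(..., interpolation=...)`). Deviations
(`d_b`, `d_e`) use the distance-to-range convention: zero anywhere on the
closed band, otherwise the distance to the nearer bound. This is the
convention under which the effectiveness index `E = 1 − mean(d_b)/mean(d_e)`
has its usual reading (0 thermoconformity, 1 perfect regulation, negative
when good microsites are avoided). A distance-to-midpoint mode
(`mode="midpoint"`) is provided for sensitivity analysis only. For unimodal
traces the band need not contain the mean; only `Q1 ≤ Q3` is asserted.

Each individual's `d_e_i` is the deviation of the mean operative temperature
recorded **within the hour of its capture**, pooled across habitats — the
habitat mosaic an active animal actually samples. Habitat-specific thermal
quality (`d_e-sun`, `d_e-shade`) is computed separately over the full
deployment against the population-mean band. Group summaries (males,
females, juveniles, overall) average unrounded per-individual values;
recomputing `E` from rounded group means can differ by up to ~0.01.

`WT` and `TSM` use the grand mean `T_e` over the whole logger deployment.
Because the upper set-point lies below `CT_max` in any plausible dataset,
`TSM ≤ WT` is asserted as a pipeline invariant.

## Body condition

`b_SMA = sign(r)·sd(ln BW)/sd(ln SVL)` with the sample (ddof = 1) standard
deviations; the ratio is ddof-invariant, the sign convention handles
negative correlations, and an exactly zero or undefined correlation raises
rather than guessing a sign. The reference length `SVL_0` is the arithmetic
mean of the records used for the slope; juveniles are included by default
(`include_juveniles=False` restricts estimation to adults while still
scoring everyone).

## Circular statistics

Times of day map to angles at 15°/h. The mean direction comes from the
resultant vector; dispersion is `sqrt(−2 ln R)` radians, reported in degrees
and as an hh:mm duration (minutes rounded to the nearest integer). A zero
resultant (e.g. two sightings 12 h apart) raises: the mean direction is
genuinely undefined there, and silently returning one would corrupt
downstream summaries. Hour binning is half-open — a sighting at exactly
h:00 belongs to hour h.

## Contingency analysis

Goodness of fit against uniform expectation uses the plain Pearson
chi-square with `df = k − 1`. The deviation index is the relative deviation
`(O − E)/E`; its nominal −1…1 scale is exceeded when a category holds more
than twice its expectation, in which case the value is returned unchanged
with a warning (rescaling would destroy the ratio interpretation). The
r × c post hoc uses Haberman adjusted residuals
`z = (O − E)/sqrt(E(1 − p_row)(1 − p_col))`, two-sided p-values via
`z² ~ χ²₁`, and a Bonferroni per-cell level `α/(r·c)`. Cells in a zero
margin have undefined residuals and are reported as NaN, not dropped.

## Hours of activity and restriction

The daily primitives count whole hours in the activity window (default
08:00–19:00): an hour is *active* when air temperature lies in
[minimum field-active body temperature, voluntary thermal maximum]
(defaults 19.3 and 38.99 °C) and *restricted* when the sun-exposed operative
temperature exceeds the upper preferred set-point (default 38.4 °C). The
sun-operative curve is the air curve plus a half-sinusoid midday bump
(default amplitude 8 °C, matching the generator's sun excess). Restriction
is keyed to sun microsites deliberately: annual *air* maxima rarely reach
the set-point even on days animals demonstrably retreat, so an air-only
definition degenerates to a constant zero and no response curve exists.
All thresholds, the window and the bump are arguments.

## Richards curve fitting

The positive Richards form `h(T) = A(1 + m·e^{−k(T−i)})^{−1/m}` is evaluated
with a Gompertz fallback `A·exp(−e^{−k(T−i)})` for |m| < 1e−8 (the two agree
to < 1e−6·A over any realistic temperature grid). For m < 0 the bracket can
turn non-positive; evaluation raises rather than returning complex powers,
and the fitter penalizes such points. Negative rates k are legitimate
(decreasing responses) and are never sign-normalized.

Fitting is the common two-stage protocol: (1) estimate all four parameters
by Levenberg–Marquardt least squares from eight heuristic starts
(A ≈ max hours, i ≈ median T, k ∈ {±0.1, ±0.3}, m ∈ {0.5, 1}), keeping the
converged fit with the lowest SSE, ties broken by smaller |m|; (2) fix the
shape at its stage-1 value and refit (A, k, i). Confidence intervals are
asymptotic t intervals. When the shape was *estimated*, intervals come from
the stage-1 four-parameter covariance (df = n − 4): conditioning on a
shape that was itself fitted to the same data understates uncertainty —
in a 100-replicate simulation at n = 200 (noise sd 0.3) the conditional
intervals covered the true asymptote only ~85% of the time versus ~95% for
the joint ones. When the caller fixes the shape externally, the
three-parameter conditional covariance (df = n − 3) is used. Requirements:
n ≥ 8, hours in [0, 24], non-constant response.

Projections add a scalar warming offset to each day's maximum (defaults
+2.25 °C and +3.5 °C for the RCP 4.5 and 8.5 pathway mid-range) and average
the evaluated curves by calendar month of a 365-day year.

## Grid layers

Temperature grids are exchanged as ESRI ASCII (plain text, first data row
northernmost; parser validates the header and cell count). A `ClimateGrid`
holds 12 monthly layers with one shared nodata mask; applying a fitted curve
is strictly cellwise, so it commutes with cropping and preserves cellwise
monotonicity for k > 0. The optional suitability mask (annual h_a ≥ 6 h and
annual h_r ≤ 6 h by default) is a screening convenience, not a distribution
model.

## Synthetic data: what it emulates, what it does not

The generator reproduces *summary* structure: a 21-lizard single-day
campaign in an 08:00–19:00 window; sighting times from a two-peak truncated
Normal mixture (10:30 and 15:30, weights 0.7/0.3 — the documented morning
dominance); air temperature on a half-sinusoid from a 06:00 dawn minimum to
a 14:00 peak; humidity collapsing toward midday; `T_b` linear in air
temperature (slope 0.9, intercept 7.5 °C — free parameters, no published
regression exists) minus 0.05 °C per %RH anomaly plus Normal noise; nine
T_e models at 5-min cadence split across sun/shade-soil/shade-rock with an
8 °C midday sun excess; 37-reading gradient traces around individual means
from Normal(37.38, 1.53); tolerance endpoints redrawn until
CT_min < VT_max < CT_max; an annual daily-maximum cycle
24 ± 10 °C peaking in mid-January (austral summer, arid-desert amplitudes)
with sd 1.5 °C noise and a 14 °C diurnal range; and 30 × 20 toy grids with a
0.15 °C/cell gradient and a nodata border.

It does **not** emulate spatial autocorrelation of microhabitats,
serial correlation within logger series, behavioural
temperature-dependence of capture probability, or real georeferencing.
A green pipeline test therefore establishes internal consistency of the
estimators on data with known structure — not field realism, and not the
published field values, whose raw records are unavailable. Published
summary numbers are checked only where they are pure functions of printed
inputs (effectiveness from mean deviations, tolerance breadth, the
microhabitat chi-square, the degree-to-duration conversion, Richards-curve
evaluation at the published parameters).

## Numerical choices

- Percentiles: linear interpolation; selectable.
- s.e.m. with n = 1: reported missing (NaN), never 0.
- Boundary temperatures count as inside a closed band.
- Overflow in the Richards exponential is deliberately tolerated where the
  mathematical limit is exact (infinite bracket → 0 hours).
- Random streams are per-generator (`SeedSequence([seed, stream])`), so
  enlarging one table never perturbs another.

## Known limitations

- The restriction definition (sun-operative exceedance) is one defensible
  operationalization among several; published parameter values for these
  curves are not expected to be reproduced from synthetic weather.
- Monte-Carlo CI coverage was validated for the asymptote only, at one
  design (n = 200, uniform temperatures 5–40 °C, noise sd 0.3).
- No species-distribution modelling: the layers are model *inputs*.
- Circular confidence intervals and uniformity tests (Rayleigh/Watson) are
  out of scope.
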