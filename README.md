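# thermovuln

Thermal-ecophysiology toolkit for assessing the climate-change vulnerability
of small ectotherms (built around the field/lab workflow used for diurnal
lizards). It turns a one-day field campaign — cloacal body temperatures,
microclimate at capture sites, operative-temperature (T_e) loggers in sun and
shade, laboratory thermal-gradient trials and tolerance endpoints — into the
standard vulnerability summary, and projects activity budgets under warming.

## What it computes

**Thermoregulation indices (Hertz set-point framework).** Each individual's
preferred-temperature trace yields its set-point band `T_set` (interquartile
of the gradient readings). Deviations are distances to that band (zero
inside):

- `d_b` — accuracy of thermoregulation: mean deviation of field `T_b`;
- `d_e` — thermal quality of habitat: mean deviation of operative
  temperatures at the capture hour;
- `E = 1 − mean(d_b)/mean(d_e)` — effectiveness (~0 thermoconformer, ~1
  effective thermoregulator, negative when thermally good microsites are
  avoided).

**Vulnerability indices.** Warming tolerance `WT = mean CT_max − mean T_e`,
thermal safety margin `TSM = mean upper T_set − mean T_e`, and tolerance
breadth `CT_max − CT_min`.

**Body condition.** Scaled mass index
`M_i = BW_i (SVL_0 / SVL_i)^{b_SMA}` with the standardized-major-axis
exponent `b_SMA = sign(r)·sd(ln BW)/sd(ln SVL)`.

**Activity statistics.** Circular mean/dispersion of sighting times on the
24-h clock (15°/h), chi-square goodness of fit of microhabitat use against
uniformity, relative deviation indices, and an adjusted-residual
(Haberman) post hoc on the time × microhabitat contingency table with
Bonferroni-corrected per-cell levels.

**Hours of activity/restriction.** Daily hours of activity `h_a` and of
heat-forced restriction `h_r` respond sigmoidally to the day's maximum air
temperature and are fitted with the positive Richards curve

    h(T) = A · (1 + m·e^{−k(T−i)})^{−1/m}

(asymptote `A`, rate `k`, inflection `i`, shape `m`; Gompertz limit as
m → 0) via a two-stage nonlinear least-squares protocol (estimate all four,
fix the shape, refit the rest). Fitted curves are projected onto warmed
daily maxima (defaults +2.25 °C and +3.5 °C for the RCP 4.5/8.5 pathways)
and onto monthly temperature grids, producing the species-specific `h_a`/`h_r`
raster layers a distribution model can consume (ESRI ASCII format).

A seed-reproducible synthetic-data module generates campaign datasets with
the documented structure (bimodal diel activity, sun > shade operative
temperatures, T_b rising with air temperature and falling with humidity,
`T_pref` 37.38 ± 1.53 °C, ordered tolerance endpoints, a seasonal cycle of
daily maxima, toy climate grids), so the whole pipeline is testable without
any data download.

## Worked example

```sh
thermovuln simulate --out data --seed 42
thermovuln indices --captures data/captures.csv --te data/te_series.csv \
    --traces data/tpref_traces.csv --tolerance data/tolerance.csv
thermovuln activity --captures data/captures.csv
thermovuln fit-richards --weather data/weather.csv --out richards.json
thermovuln project --params richards.json --weather data/weather.csv
thermovuln layers --grid-dir data/grids --params richards.json --out layers
```

prints (seed 42):

```
overall: d_b=3.17 d_e=4.78 E=0.34 WT=12.82 TSM=7.08 breadth=31.90
mean activity 12.55 h, circ. s.d. 2h 28min = 36.954 deg; microhabitat chi2=6.00 (df=2, p=0.050)
h_a: A=12.132 k=0.413 i=21.000 m=-0.009
h_r: A=6.056 k=0.676 i=31.413 m=0.000
           h_a   h_r
scenario
present   6.76  1.06
rcp45     7.74  1.75
rcp85     8.35  2.10
```

Read: the simulated population thermoregulates moderately (E = 0.34) with
body temperatures on average 3.2 °C outside the preferred band; it sits
12.8 °C below lethal environmental temperatures (WT) and 7.1 °C below its
upper preferred set-point (TSM); mean sighting time is about 12:33 with a
circular s.d. of 2 h 28 min. Warming the daily maxima by 3.5 °C raises mean
daily activity from 6.8 to 8.4 h but also mean restriction from 1.1 to
2.1 h — hotter days buy morning activity and cost midday retreat. The
`layers/` directory holds the monthly and annual `h_a`/`h_r` grids plus a
screening suitability mask.

The same steps are available as library functions (`thermovuln.compute_indices`,
`richards_fit`, `project_monthly`, `grid_apply`, …).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the synthetic dataset at the given seed, runs the complete
pipeline (indices, body condition, activity statistics, Richards fits,
warming projections, grid layers), prints a one-line summary, and writes the
results manifest to `--out`.
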