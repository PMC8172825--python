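"""Seed-reproducible synthetic data with the structure of a one-day field campaign.

The generators emulate the statistical shape of a spring thermal-ecology
campaign on a small diurnal lizard in an arid Andean piedmont: field captures
with body/microclimate temperatures, operative-temperature (T_e) logger
series from sun and shade models, laboratory thermal-gradient traces and
tolerance endpoints, a one-year daily weather series, and a toy monthly
maximum-temperature grid. Only summary structure is targeted (moments,
diurnal shapes, orderings), not record-level realism: raw field data of this
kind are rarely deposited, so downstream stages are validated on simulated
inputs with known ground truth.

All randomness flows through ``numpy.random.default_rng(cfg.seed)``; an
identical :class:`SimConfig` yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "gen_field_campaign",
    "gen_te_series",
    "gen_lab_thermal",
    "gen_weather_year",
    "gen_climate_grid",
    "write_dataset",
]

MICROHABITATS = ("BS-sun", "BS-shade", "WR-shade")

# morphometric (mean, sd) per class: snout-vent length mm, body mass g
_MORPHO = {
    "male": {"svl": (63.8, 2.70), "bw": (8.00, 0.84)},
    "female": {"svl": (57.88, 1.02), "bw": (5.85, 0.47)},
    "juvenile": {"svl": (48.4, 5.50), "bw": (3.65, 1.45)},
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated world.

    Defaults reproduce the reported campaign conditions: 21 lizards sighted
    in a single late-spring day between 08:00 and 19:00, nine PVC operative
    temperature models logging every 5 min, preferred temperature
    37.38 +/- 1.53 degC, tolerance endpoints CT_min 11.76 +/- 1.10,
    VT_max 38.99 +/- 2.49, CT_max 43.44 +/- 1.44 degC, a bimodal diel
    activity pattern with a dominant late-morning peak, and an arid-desert
    seasonal cycle of daily maxima. The body-temperature regression slope on
    air temperature is a free parameter (no published value exists); the
    default 0.9 with intercept 7.5 degC places mean T_b near the reported
    32.9 degC for midday air temperatures around 28 degC.
    """

    seed: int = 42
    n_lizards: int = 21
    n_te_models: int = 9
    campaign_window: tuple[float, float] = (8.0, 19.0)
    # laboratory thermal gradient / tolerance endpoints (degC)
    tpref_mean: float = 37.38
    tpref_sd: float = 1.53
    trace_noise_sd: float = 0.8
    ct_min_mean: float = 11.76
    ct_min_sd: float = 1.10
    ct_max_mean: float = 43.44
    ct_max_sd: float = 1.44
    vt_max_mean: float = 38.99
    vt_max_sd: float = 2.49
    # field T_b regression on air temperature
    tb_slope: float = 0.9
    tb_intercept: float = 7.5
    tb_noise_sd: float = 2.0
    rh_effect: float = -0.05  # degC per %RH, applied to humidity anomaly
    # diel activity mixture (hours of day) and weights
    activity_peaks: tuple[float, float] = (10.5, 15.5)
    activity_weights: tuple[float, float] = (0.7, 0.3)
    activity_peak_sd: float = 1.2
    # diurnal air-temperature curve
    ta_min: float = 16.0
    ta_max: float = 32.0
    dawn_hour: float = 6.0
    peak_hour: float = 14.0
    # operative-temperature series
    sun_excess: float = 8.0  # midday excess of sun over shade models (degC)
    te_noise_sd: float = 1.0
    # annual daily-maximum cycle (southern hemisphere: warm around day 15)
    year_mean: float = 24.0
    year_amp: float = 10.0
    year_noise_sd: float = 1.5
    daily_range: float = 14.0
    # toy climate grid
    grid_nx: int = 30
    grid_ny: int = 20
    grid_lapse: float = 0.15  # degC per cell of the spatial gradient
    grid_nodata: float = -9999.0

    def __post_init__(self) -> None:
        lo, hi = self.campaign_window
        if not (0 <= lo < hi < 24):
            raise ValueError(f"campaign_window must satisfy 0 <= start < end < 24, got {self.campaign_window}")
        for name in ("tpref_sd", "trace_noise_sd", "ct_min_sd", "ct_max_sd",
                     "vt_max_sd", "tb_noise_sd", "te_noise_sd", "year_noise_sd",
                     "activity_peak_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.activity_weights) - 1.0) > 1e-9:
            raise ValueError("activity_weights must sum to 1")
        if self.ct_min_mean >= self.ct_max_mean:
            raise ValueError("ct_min_mean must be below ct_max_mean")
        if not (self.ct_min_mean < self.vt_max_mean <= self.ct_max_mean):
            raise ValueError("tolerance means must satisfy ct_min < vt_max <= ct_max")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so adding records to one table does
    # not perturb the others
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def diurnal_temperature(hour: np.ndarray | float, t_min: float, t_max: float,
                        dawn: float = 6.0, peak: float = 14.0) -> np.ndarray:
    """Half-sinusoid diurnal curve: minimum at dawn, maximum at ``peak``.

    ``T(h) = t_min + (t_max - t_min) * sin(pi/2 * (h - dawn)/(peak - dawn))``
    rises from dawn to the peak hour and declines symmetrically afterwards;
    hours before dawn are clamped to the minimum.
    """
    h = np.asarray(hour, dtype=float)
    phase = np.clip((h - dawn) / (peak - dawn), 0.0, 2.0)
    return t_min + (t_max - t_min) * np.sin(np.pi / 2.0 * phase)


def _humidity_curve(hour: np.ndarray, lo: float, hi: float,
                    window: tuple[float, float]) -> np.ndarray:
    """Relative humidity high at the window edges, collapsing toward midday."""
    start, end = window
    phase = (np.asarray(hour, dtype=float) - start) / (end - start)
    return hi - (hi - lo) * np.sin(np.pi * np.clip(phase, 0, 1))


def _sample_sighting_times(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Two-component truncated-Normal mixture on the clock, inside the window."""
    lo, hi = cfg.campaign_window
    comp = rng.choice(2, size=n, p=list(cfg.activity_weights))
    times = np.empty(n)
    for j in range(n):
        mu = cfg.activity_peaks[comp[j]]
        t = rng.normal(mu, cfg.activity_peak_sd)
        while not (lo <= t < hi):
            t = rng.normal(mu, cfg.activity_peak_sd)
        times[j] = t
    return times


def gen_field_campaign(cfg: SimConfig) -> pd.DataFrame:
    """One row per field-captured lizard.

    Columns: id, sex_age, time (hours of day), T_b, T_a, T_s (degC), RH (%),
    wind (m/s), microhabitat, SVL (mm), BW (g).

    Sighting times follow the bimodal activity mixture; air temperature at
    the sighting follows the diurnal curve; ``T_b = tb_intercept +
    tb_slope * T_a + rh_effect * (RH - mean RH) + Normal(0, tb_noise_sd)``,
    so body temperature rises with air temperature and falls with humidity
    excess. Microhabitat is drawn with the shade-biased frequencies typical
    of a hot campaign day (BS-sun : BS-shade : WR-shade = 3 : 13 : 5).
    """
    if cfg.n_lizards <= 0:
        raise ValueError("n_lizards must be positive")
    rng = _rng(cfg, 1)
    n = cfg.n_lizards

    times = _sample_sighting_times(cfg, n, rng)
    t_a = diurnal_temperature(times, cfg.ta_min, cfg.ta_max, cfg.dawn_hour, cfg.peak_hour)
    t_s = t_a + rng.normal(3.0, 1.0, n)  # substrate runs hotter than air
    rh = np.clip(_humidity_curve(times, 3.0, 40.0, cfg.campaign_window)
                 + rng.normal(0, 2.0, n), 0.0, 100.0)
    rh_anom = rh - rh.mean() if n > 1 else np.zeros(n)
    t_b = (cfg.tb_intercept + cfg.tb_slope * t_a + cfg.rh_effect * rh_anom
           + rng.normal(0, cfg.tb_noise_sd, n))
    wind = np.abs(rng.normal(1.5, 1.0, n))

    classes = rng.choice(["male", "female", "juvenile"], size=n, p=[9 / 21, 7 / 21, 5 / 21])
    svl = np.empty(n)
    bw = np.empty(n)
    for j, c in enumerate(classes):
        m = _MORPHO[c]
        svl[j] = max(rng.normal(*m["svl"]), 30.0)
        bw[j] = max(rng.normal(*m["bw"]), 0.5)
    micro = rng.choice(MICROHABITATS, size=n, p=[3 / 21, 13 / 21, 5 / 21])

    return pd.DataFrame({
        "id": [f"L{j + 1:03d}" for j in range(n)],
        "sex_age": classes,
        "time": times,
        "T_b": t_b,
        "T_a": t_a,
        "T_s": t_s,
        "RH": rh,
        "wind": wind,
        "microhabitat": micro,
        "SVL": svl,
        "BW": bw,
    })


def gen_te_series(cfg: SimConfig) -> pd.DataFrame:
    """Operative-temperature logger series at 5-min cadence.

    ``n_te_models`` physical models are split in thirds across the deployed
    microhabitats (BS-sun / BS-shade / WR-shade); the first third carries
    habitat class ``sun``, the rest ``shade``. Shade models track the diurnal
    air curve; sun models add a midday bump of amplitude ``sun_excess``.
    Columns: model_id, habitat, microhabitat, time, T_e.
    """
    rng = _rng(cfg, 2)
    lo, hi = cfg.campaign_window
    n_steps = int(round((hi - lo) * 12)) + 1  # inclusive endpoints
    times = lo + np.arange(n_steps) / 12.0

    shade_base = diurnal_temperature(times, cfg.ta_min, cfg.ta_max,
                                     cfg.dawn_hour, cfg.peak_hour)
    midday_bump = np.sin(np.pi * (times - lo) / (hi - lo))
    per_third = max(cfg.n_te_models // 3, 1)

    frames = []
    for m in range(cfg.n_te_models):
        third = min(m // per_third, 2)
        micro = MICROHABITATS[third]
        habitat = "sun" if third == 0 else "shade"
        te = shade_base + (cfg.sun_excess * midday_bump if habitat == "sun" else 0.0)
        te = te + rng.normal(0, cfg.te_noise_sd, n_steps)
        frames.append(pd.DataFrame({
            "model_id": f"M{m + 1:02d}",
            "habitat": habitat,
            "microhabitat": micro,
            "time": times,
            "T_e": te,
        }))
    return pd.concat(frames, ignore_index=True)


def gen_lab_thermal(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thermal-gradient traces and tolerance endpoints per individual.

    Returns ``(traces, tolerance)``. Each trace holds 37 readings (3 h at
    5-min cadence, endpoints inclusive) around an individual preferred mean
    drawn from Normal(tpref_mean, tpref_sd). Tolerance endpoints are redrawn
    per individual until ``CT_min < VT_max < CT_max`` holds, mirroring the
    physiological ordering (cold loss of righting < voluntary escape
    temperature < hot loss of righting).
    """
    rng = _rng(cfg, 3)
    n = cfg.n_lizards
    ids = [f"L{j + 1:03d}" for j in range(n)]

    mu = rng.normal(cfg.tpref_mean, cfg.tpref_sd, n)
    n_read = 37
    rows = []
    for j in range(n):
        trace = mu[j] + rng.normal(0, cfg.trace_noise_sd, n_read)
        rows.append(pd.DataFrame({
            "id": ids[j],
            "reading": np.arange(n_read),
            "minute": np.arange(n_read) * 5,
            "T_pref": trace,
        }))
    traces = pd.concat(rows, ignore_index=True)

    ct_min = np.empty(n)
    vt_max = np.empty(n)
    ct_max = np.empty(n)
    for j in range(n):
        while True:
            cmin = rng.normal(cfg.ct_min_mean, cfg.ct_min_sd)
            vmax = rng.normal(cfg.vt_max_mean, cfg.vt_max_sd)
            cmax = rng.normal(cfg.ct_max_mean, cfg.ct_max_sd)
            if cmin < vmax < cmax:
                ct_min[j], vt_max[j], ct_max[j] = cmin, vmax, cmax
                break
    tolerance = pd.DataFrame({
        "id": ids, "ct_min": ct_min, "vt_max": vt_max, "ct_max": ct_max,
    })
    return traces, tolerance


def gen_weather_year(cfg: SimConfig) -> tuple[pd.DataFrame, Callable[[int, np.ndarray], np.ndarray]]:
    """One year of daily extremes plus an intraday interpolator.

    The daily maximum follows a sinusoidal annual cycle peaking near mid
    January (austral summer): ``T_max(d) = year_mean + year_amp *
    cos(2 pi (d - 15)/365) + Normal(0, year_noise_sd)``; the daily minimum
    sits ``daily_range`` below it. The returned ``intraday(day, hours)``
    interpolates between the dawn minimum and the mid-afternoon maximum with
    the same half-sinusoid used for campaign air temperatures, so the curve
    attains exactly the day's maximum at the peak hour.
    """
    rng = _rng(cfg, 4)
    days = np.arange(1, 366)
    t_max = (cfg.year_mean
             + cfg.year_amp * np.cos(2 * np.pi * (days - 15) / 365.0)
             + rng.normal(0, cfg.year_noise_sd, days.size))
    t_min = t_max - cfg.daily_range + rng.normal(0, cfg.year_noise_sd / 2, days.size)
    weather = pd.DataFrame({"day": days, "t_a_max": t_max, "t_a_min": t_min})

    def intraday(day: int, hours: np.ndarray) -> np.ndarray:
        row = weather.loc[weather["day"] == day]
        if row.empty:
            raise KeyError(f"day {day} not in weather table")
        return diurnal_temperature(np.asarray(hours, dtype=float),
                                   float(row["t_a_min"].iloc[0]),
                                   float(row["t_a_max"].iloc[0]),
                                   cfg.dawn_hour, cfg.peak_hour)

    return weather, intraday


def gen_climate_grid(cfg: SimConfig, scenario_offsets: dict[str, float] | None = None):
    """Toy monthly maximum-temperature grids with a nodata border.

    Returns ``{scenario: ClimateGrid}`` including the ``present`` grid. Each
    of the 12 monthly layers combines the annual cycle evaluated mid-month
    with a smooth spatial gradient of ``grid_lapse`` degC per cell along the
    grid diagonal (a stand-in for elevation lapse). The one-cell border is
    nodata in every layer; scenario grids add a uniform offset to every
    valid cell and preserve the mask.
    """
    from thermovuln.layers import ClimateGrid

    if cfg.grid_nx < 1 or cfg.grid_ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    if scenario_offsets is None:
        scenario_offsets = {"rcp45": 2.25, "rcp85": 3.5}

    ny, nx = cfg.grid_ny, cfg.grid_nx
    rows, cols = np.mgrid[0:ny, 0:nx]
    gradient = cfg.grid_lapse * (rows + cols).astype(float)

    mid_month_days = (np.arange(12) + 0.5) * 365.0 / 12.0
    monthly_mean = cfg.year_mean + cfg.year_amp * np.cos(2 * np.pi * (mid_month_days - 15) / 365.0)

    mask = np.zeros((ny, nx), dtype=bool)
    if ny > 2 and nx > 2:
        mask[0, :] = mask[-1, :] = True
        mask[:, 0] = mask[:, -1] = True

    def build(offset: float) -> ClimateGrid:
        layers = []
        for m in range(12):
            layer = monthly_mean[m] + gradient + offset
            layer = np.where(mask, cfg.grid_nodata, layer)
            layers.append(layer)
        return ClimateGrid(layers=np.stack(layers), nodata=cfg.grid_nodata,
                           cell_size=1.0, origin=(0.0, 0.0))

    grids = {"present": build(0.0)}
    for name, off in scenario_offsets.items():
        grids[name] = build(off)
    return grids


def write_dataset(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic dataset and write it as plain-text files.

    Writes ``captures.csv``, ``te_series.csv``, ``tpref_traces.csv``,
    ``tolerance.csv``, ``weather.csv`` and one ESRI ASCII grid per month per
    scenario under ``grids/``. Returns a name -> path map.
    """
    from thermovuln.layers import write_ascii_grid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    captures = gen_field_campaign(cfg)
    te = gen_te_series(cfg)
    traces, tolerance = gen_lab_thermal(cfg)
    weather, _ = gen_weather_year(cfg)

    for name, frame in [("captures", captures), ("te_series", te),
                        ("tpref_traces", traces), ("tolerance", tolerance),
                        ("weather", weather)]:
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p

    grid_dir = out / "grids"
    grid_dir.mkdir(exist_ok=True)
    for scenario, grid in gen_climate_grid(cfg).items():
        for m in range(12):
            p = grid_dir / f"tmax_{scenario}_{m + 1:02d}.asc"
            write_ascii_grid(grid.layers[m], p, nodata=grid.nodata,
                             cell_size=grid.cell_size, origin=grid.origin)
            paths[f"grid_{scenario}_{m + 1:02d}"] = p
    return paths
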