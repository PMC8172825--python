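"""Thermoregulation indices, set-points and vulnerability indices.

Implements the Hertz set-point framework for field thermal ecology:

* ``T_set`` — the interquartile band (25th-75th percentile) of an
  individual's preferred body temperatures selected in a laboratory gradient;
* ``d_b`` — accuracy of thermoregulation, the mean absolute deviation of
  field body temperatures from the set-point band (zero inside the band);
* ``d_e`` — thermal quality of the habitat, the same deviation applied to
  operative temperatures (T_e) sampled by physical models;
* ``E = 1 - mean(d_b) / mean(d_e)`` — effectiveness of thermoregulation
  (~0 thermoconformer, ~1 effective thermoregulator, negative when animals
  avoid thermally good microsites);
* ``WT = mean CT_max - mean T_e`` (warming tolerance) and
  ``TSM = mean upper T_set - mean T_e`` (thermal safety margin).

Deviations use the distance-to-range convention: zero on the closed
interquartile interval, otherwise distance to the nearer bound. An optional
distance-to-midpoint mode is provided for sensitivity analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TsetSummary",
    "ThermoIndices",
    "extract_tset",
    "deviation_from_range",
    "effectiveness",
    "classify_vs_range",
    "warming_tolerance",
    "thermal_safety_margin",
    "tolerance_breadth",
    "aggregate_te",
    "thermal_quality_series",
    "calibrate_te_model",
    "compute_indices",
]


@dataclass(frozen=True)
class TsetSummary:
    """Per-individual preferred-temperature summary (degC)."""

    individual_id: str
    t_pref_mean: float
    t_set_lower: float
    t_set_upper: float

    def __post_init__(self) -> None:
        if self.t_set_lower > self.t_set_upper:
            raise ValueError("t_set_lower must not exceed t_set_upper")


@dataclass(frozen=True)
class ThermoIndices:
    """Thermoregulation and vulnerability indices for one group of lizards."""

    d_b: float
    d_e: float
    d_e_sun: float
    d_e_shade: float
    E: float
    WT: float
    TSM: float
    breadth: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def extract_tset(trace: Sequence[float], individual_id: str = "",
                 interpolation: str = "linear") -> TsetSummary:
    """Mean and interquartile set-points of a thermal-gradient trace.

    Percentiles use linear interpolation between order statistics by
    default; any method accepted by :func:`numpy.percentile` may be chosen.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 readings to form an interquartile band, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite readings")
    q1, q3 = np.percentile(x, [25, 75], method=interpolation)
    return TsetSummary(individual_id, float(x.mean()), float(q1), float(q3))


def deviation_from_range(x: float, lower: float, upper: float,
                         mode: str = "range") -> float:
    """Absolute deviation of a temperature from a set-point band.

    ``mode='range'`` (default): 0 on the closed interval [lower, upper],
    otherwise distance to the nearer bound. ``mode='midpoint'``: distance to
    the band midpoint.
    """
    if lower > upper:
        raise ValueError(f"inverted bounds: lower={lower} > upper={upper}")
    if mode == "midpoint":
        return abs(x - (lower + upper) / 2.0)
    if mode != "range":
        raise ValueError(f"unknown mode {mode!r}")
    if x < lower:
        return lower - x
    if x > upper:
        return x - upper
    return 0.0


def effectiveness(d_b_values: Iterable[float], d_e_values: Iterable[float]) -> float:
    """Effectiveness of thermoregulation, ``E = 1 - mean(d_b)/mean(d_e)``.

    Negative values indicate avoidance of thermally high-quality habitat
    (habitat deviations smaller than body deviations).
    """
    db = np.asarray(list(d_b_values), dtype=float)
    de = np.asarray(list(d_e_values), dtype=float)
    if db.size == 0 or de.size == 0:
        raise ValueError("empty deviation inputs")
    mean_de = de.mean()
    if mean_de <= 0:
        raise ZeroDivisionError("mean d_e must be positive; E is undefined for a "
                                "habitat with zero mean deviation")
    return float(1.0 - db.mean() / mean_de)


def classify_vs_range(values: Iterable[float], lower: float, upper: float):
    """Partition temperatures into below / within / above a closed band.

    Returns ``(n_below, n_within, n_above, (f_below, f_within, f_above))``.
    Boundary values count as within.
    """
    if lower > upper:
        raise ValueError("inverted bounds")
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    n_below = int(np.sum(x < lower))
    n_above = int(np.sum(x > upper))
    n_within = int(x.size - n_below - n_above)
    f = (n_below / x.size, n_within / x.size, n_above / x.size)
    return n_below, n_within, n_above, f


def warming_tolerance(mean_ct_max: float, mean_te: float) -> float:
    """WT: gap between the mean critical thermal maximum and mean T_e."""
    return float(mean_ct_max - mean_te)


def thermal_safety_margin(mean_upper_tpref: float, mean_te: float) -> float:
    """TSM: gap between the mean upper preferred set-point and mean T_e."""
    return float(mean_upper_tpref - mean_te)


def tolerance_breadth(mean_ct_max: float, mean_ct_min: float) -> float:
    """Thermal tolerance breadth, ``CT_max - CT_min``."""
    return float(mean_ct_max - mean_ct_min)


def aggregate_te(series: pd.DataFrame) -> pd.DataFrame:
    """Per-hour mean +/- s.e.m. of operative temperature by habitat class.

    ``series`` needs columns ``habitat``, ``time`` (hours of day), ``T_e``.
    Hours bin half-open: a reading at exactly h:00 belongs to hour h. With a
    single reading the s.e.m. is undefined and reported as NaN.
    """
    if series.empty:
        raise ValueError("empty T_e series")
    df = series.copy()
    df["hour"] = np.floor(df["time"].astype(float)).astype(int)
    out = (df.groupby(["hour", "habitat"], sort=True)["T_e"]
             .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
             .reset_index())
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    return out.drop(columns="sd")


def thermal_quality_series(series: pd.DataFrame, tset: TsetSummary,
                           mode: str = "range") -> pd.DataFrame:
    """Hourly habitat thermal quality: d_e-sun and d_e-shade.

    For each hour and habitat class, the mean over that hour's readings of
    the deviation of T_e from the set-point band. Low values mean the
    habitat offers temperatures inside the preferred band.
    """
    if series.empty:
        raise ValueError("empty T_e series")
    df = series.copy()
    df["hour"] = np.floor(df["time"].astype(float)).astype(int)
    df["dev"] = [deviation_from_range(t, tset.t_set_lower, tset.t_set_upper, mode)
                 for t in df["T_e"].astype(float)]
    out = (df.groupby(["hour", "habitat"], sort=True)["dev"]
             .mean().rename("d_e").reset_index())
    return out


def calibrate_te_model(pairs: Sequence[tuple[float, float]] | pd.DataFrame):
    """OLS calibration of a physical operative-temperature model against T_b.

    ``pairs`` holds (model temperature, lizard body temperature) readings.
    Returns ``(slope, intercept, adjusted_r2, (ci_lo, ci_hi))`` where the CI
    is the 95% t-interval on the slope and adjusted R^2 corrects for the
    single predictor: ``1 - (1 - R^2)(n - 1)/(n - 2)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 calibration pairs")
    x, y = arr[:, 0], arr[:, 1]
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    tcrit = stats.t.ppf(0.975, df=n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return float(res.slope), float(res.intercept), float(adj_r2), (float(ci[0]), float(ci[1]))


# ---------------------------------------------------------------------------
# pipeline


def _mean_te_by_hour(te_series: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    df = te_series.copy()
    df["hour"] = np.floor(df["time"].astype(float)).astype(int)
    if pooled:
        return df.groupby("hour")["T_e"].mean().rename("mean_te").reset_index()
    return df.groupby(["hour", "habitat"])["T_e"].mean().rename("mean_te").reset_index()


def compute_indices(captures: pd.DataFrame, te_series: pd.DataFrame,
                    traces: pd.DataFrame, tolerance: pd.DataFrame,
                    group_by: str | None = "sex_age",
                    deviation_mode: str = "range") -> dict[str, ThermoIndices]:
    """Full thermoregulation/vulnerability index pipeline.

    Each individual contributes ``d_b_i`` (deviation of its field T_b from
    its own set-point band) and ``d_e_i`` (deviation of the mean T_e
    recorded in the hour of its capture, pooled across habitats, from the
    same band). Group-level indices use unrounded per-individual values.
    WT and TSM use the grand mean T_e over the whole deployment and the
    group means of CT_max and upper T_set. Individuals without a laboratory
    trace are excluded (with their capture record) from index computation.

    Returns a mapping ``group -> ThermoIndices`` including an ``"overall"``
    entry.
    """
    tsets = {ind: extract_tset(g["T_pref"].to_numpy(), ind)
             for ind, g in traces.groupby("id")}
    hourly_te = _mean_te_by_hour(te_series, pooled=True).set_index("hour")["mean_te"]
    mean_te = float(te_series["T_e"].mean())
    tol = tolerance.set_index("id")

    rows = []
    for _, rec in captures.iterrows():
        ind = rec["id"]
        if ind not in tsets:
            continue
        ts = tsets[ind]
        hour = int(math.floor(float(rec["time"])))
        if hour not in hourly_te.index:
            # capture outside logger deployment: nearest recorded hour
            hour = int(hourly_te.index[np.argmin(np.abs(hourly_te.index - hour))])
        d_b_i = deviation_from_range(float(rec["T_b"]), ts.t_set_lower,
                                     ts.t_set_upper, deviation_mode)
        d_e_i = deviation_from_range(float(hourly_te.loc[hour]), ts.t_set_lower,
                                     ts.t_set_upper, deviation_mode)
        rows.append({
            "id": ind,
            "group": rec[group_by] if group_by else "overall",
            "d_b_i": d_b_i,
            "d_e_i": d_e_i,
            "t_set_upper": ts.t_set_upper,
            "ct_max": float(tol.loc[ind, "ct_max"]) if ind in tol.index else np.nan,
            "ct_min": float(tol.loc[ind, "ct_min"]) if ind in tol.index else np.nan,
        })
    per_ind = pd.DataFrame(rows)
    if per_ind.empty:
        raise ValueError("no capture records could be matched to laboratory traces")

    # habitat-specific thermal quality from the full deployment
    de_sun, de_shade = _habitat_quality(te_series, tsets, deviation_mode)

    def summarize(sub: pd.DataFrame) -> ThermoIndices:
        return ThermoIndices(
            d_b=float(sub["d_b_i"].mean()),
            d_e=float(sub["d_e_i"].mean()),
            d_e_sun=de_sun,
            d_e_shade=de_shade,
            E=effectiveness(sub["d_b_i"], sub["d_e_i"]),
            WT=warming_tolerance(float(sub["ct_max"].mean()), mean_te),
            TSM=thermal_safety_margin(float(sub["t_set_upper"].mean()), mean_te),
            breadth=tolerance_breadth(float(sub["ct_max"].mean()),
                                      float(sub["ct_min"].mean())),
            n=len(sub),
        )

    out = {"overall": summarize(per_ind)}
    if group_by:
        for g, sub in per_ind.groupby("group"):
            out[str(g)] = summarize(sub)
    return out


def _habitat_quality(te_series: pd.DataFrame, tsets: dict[str, TsetSummary],
                     mode: str) -> tuple[float, float]:
    """Population-level d_e by habitat: deviations against the mean band."""
    lo = float(np.mean([t.t_set_lower for t in tsets.values()]))
    hi = float(np.mean([t.t_set_upper for t in tsets.values()]))
    vals = {}
    for habitat, sub in te_series.groupby("habitat"):
        devs = [deviation_from_range(float(t), lo, hi, mode) for t in sub["T_e"]]
        vals[habitat] = float(np.mean(devs)) if devs else float("nan")
    return vals.get("sun", float("nan")), vals.get("shade", float("nan"))


def indices_to_json(indices: dict[str, ThermoIndices], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in indices.items()}, fh, indent=2)
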