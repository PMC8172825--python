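"""Hours of activity/restriction and the flexible Richards response curve.

Warm-adapted ectotherms lose foraging time in two ways: hours too cold to
reach activity temperatures and hours hot enough to force retreat into
shelter (hours of restriction, h_r). Both daily totals respond
sigmoidally to the day's maximum air temperature and are modelled with the
positive Richards curve

    h(T) = A * (1 + m * exp(-k (T - i)))**(-1/m)

with asymptote ``A`` (hours), rate ``k`` (per degC, signed), inflection
``i`` (degC) and shape ``m`` (dimensionless; the logistic at m = 1, the
Gompertz curve in the limit m -> 0). Fitting follows the common two-stage
protocol: estimate all four parameters by multi-start nonlinear least
squares, then fix the shape and refit (A, k, i) so the remaining parameters
behave as free parameters with well-conditioned asymptotic confidence
intervals. Warming projections simply re-evaluate the fitted curves on
offset daily maxima and average by month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy import stats

__all__ = [
    "RichardsParams",
    "daily_hours",
    "richards_eval",
    "richards_fit",
    "project_monthly",
    "hours_from_weather",
    "DEFAULT_SCENARIOS",
]

_GOMPERTZ_EPS = 1e-8

# warming offsets (degC) on daily maxima; projections to 2050/2070 reuse the
# same pathway offsets in this reduced, time-slab form
DEFAULT_SCENARIOS: dict[str, float] = {"present": 0.0, "rcp45": 2.25, "rcp85": 3.5}

_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


@dataclass(frozen=True)
class RichardsParams:
    """Fitted positive-Richards parameters with 95% confidence intervals."""

    A: float
    k: float
    i: float
    m: float
    ci95: dict = field(default_factory=dict)  # name -> (lower, upper); m fixed => absent

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("asymptote A must be positive")


def richards_eval(T, p: RichardsParams):
    """Evaluate the positive Richards curve at temperature(s) T.

    For |m| below 1e-8 the Gompertz limit ``A exp(-exp(-k (T - i)))`` is
    used. Raises if the bracket ``1 + m exp(-k(T-i))`` is non-positive
    anywhere (possible for m < 0), where the real-valued power is undefined.
    """
    t = np.asarray(T, dtype=float)
    with np.errstate(over="ignore"):  # inf bracket -> 0 hours, the correct limit
        if abs(p.m) < _GOMPERTZ_EPS:
            out = p.A * np.exp(-np.exp(-p.k * (t - p.i)))
        else:
            bracket = 1.0 + p.m * np.exp(-p.k * (t - p.i))
            if np.any(bracket <= 0):
                raise ValueError("Richards bracket 1 + m*exp(-k(T-i)) is non-positive "
                                 "over part of the evaluated domain")
            out = p.A * bracket ** (-1.0 / p.m)
    return float(out) if np.isscalar(T) else out


def daily_hours(intraday_temps, lower: float, upper: float) -> tuple[int, int]:
    """Count hours of activity and restriction in one day's window.

    ``intraday_temps`` are the hourly temperatures across the activity
    window. An hour is restricted (h_r) when its temperature exceeds
    ``upper`` (the upper preferred set-point by default: too hot to stay
    out); active (h_a) when it lies in the closed band [lower, upper].
    Hours below ``lower`` count toward neither.
    """
    if lower >= upper:
        raise ValueError("thresholds must satisfy lower < upper")
    t = np.asarray(intraday_temps, dtype=float)
    if t.size == 0:
        raise ValueError("empty window")
    h_r = int(np.sum(t > upper))
    h_a = int(np.sum((t >= lower) & (t <= upper)))
    return h_a, h_r


def _residual_fun(t: np.ndarray, hours: np.ndarray):
    def fun(theta):
        a, k, i, m = theta
        mm = m if abs(m) >= _GOMPERTZ_EPS else math.copysign(_GOMPERTZ_EPS, m or 1.0)
        with np.errstate(over="ignore"):
            bracket = 1.0 + mm * np.exp(np.clip(-k * (t - i), -700.0, 700.0))
            bad = bracket <= 0
            bracket = np.where(bad, 1e-12, bracket)
            pred = a * bracket ** (-1.0 / mm)
        resid = pred - hours
        # penalize domain violations instead of returning NaN to the solver
        resid = np.where(bad, resid + 1e3, resid)
        return resid
    return fun


def richards_fit(t_a_max, hours, fix_m: float | None = None) -> RichardsParams:
    """Two-stage nonlinear least-squares fit of the Richards curve.

    Stage 1 estimates (A, k, i, m) from several heuristic starts
    (A near max(hours), i near the median temperature, k in +/-{0.1, 0.3},
    m in {0.5, 1}); the converged fit with the lowest SSE wins, ties broken
    by smaller |m|. Stage 2 fixes m at the stage-1 estimate (or at
    ``fix_m``) and refits (A, k, i).

    95% CIs are Jacobian-based asymptotic t intervals. When m was estimated
    in stage 1 they come from the full four-parameter covariance
    (df = n - 4), so the sampling variability of the shape propagates into
    the intervals of the free parameters; conditioning on the refit alone
    systematically undercovers. When the caller fixes m externally the
    three-parameter conditional covariance (df = n - 3) applies.
    """
    t = np.asarray(t_a_max, dtype=float)
    h = np.asarray(hours, dtype=float)
    if t.size != h.size:
        raise ValueError("t_a_max and hours must have equal length")
    n = t.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    if np.any((h < 0) | (h > 24)):
        raise ValueError("hours must lie in [0, 24]")
    if np.ptp(h) == 0:
        raise ValueError("hours are constant; a sigmoid cannot be identified")

    fun = _residual_fun(t, h)
    a0 = max(h.max(), 1e-3)
    i0 = float(np.median(t))

    stage1 = None
    if fix_m is None:
        best = None
        for k0 in (0.1, -0.1, 0.3, -0.3):
            for m0 in (0.5, 1.0):
                try:
                    res = least_squares(fun, x0=[a0, k0, i0, m0], method="lm",
                                        max_nfev=5000)
                except Exception:
                    continue
                if not res.success:
                    continue
                key = (float(res.cost), abs(res.x[3]))
                if best is None or key < best[0]:
                    best = (key, res)
        if best is None:
            raise RuntimeError("Richards fit failed to converge from any start")
        stage1 = best[1]
        m_hat = float(stage1.x[3])
        x1 = stage1.x
    else:
        m_hat = float(fix_m)
        x1 = np.array([a0, 0.1, i0, m_hat])

    # stage 2: fix the shape, refit the free parameters
    def fun3(theta):
        return fun(np.r_[theta, m_hat])

    res2 = least_squares(fun3, x0=x1[:3], method="lm", max_nfev=5000)
    if not res2.success:
        raise RuntimeError(f"stage-2 refit did not converge: {res2.message}")
    a, k, i = res2.x
    if a <= 0:
        raise RuntimeError("fit converged to a non-positive asymptote")

    if stage1 is not None:
        names = ("A", "k", "i", "m")
        dof = n - 4
        centers = np.r_[res2.x, m_hat]
        se = _asymptotic_se(stage1.fun, stage1.jac, dof)
    else:
        names = ("A", "k", "i")
        dof = n - 3
        centers = res2.x
        se = _asymptotic_se(res2.fun, res2.jac, dof)
    tcrit = stats.t.ppf(0.975, dof)
    ci = {nm: (float(v - tcrit * e), float(v + tcrit * e))
          for nm, v, e in zip(names, centers, se)}
    return RichardsParams(A=float(a), k=float(k), i=float(i), m=m_hat, ci95=ci)


def _asymptotic_se(resid: np.ndarray, jac: np.ndarray, dof: int) -> np.ndarray:
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def hours_from_weather(weather: pd.DataFrame, lower: float = 19.3,
                       upper_activity: float = 38.99,
                       upper_restriction: float = 38.4,
                       sun_excess: float = 8.0,
                       window: tuple[float, float] = (8.0, 19.0),
                       dawn: float = 6.0, peak: float = 14.0) -> pd.DataFrame:
    """Daily h_a/h_r from a (day, t_a_max, t_a_min) table.

    Each day's hourly air temperatures across the activity window come from
    the half-sinusoid dawn-minimum-to-afternoon-peak interpolation. An hour
    is active when air temperature lies in [lower, upper_activity]
    (minimum field-active body temperature to voluntary thermal maximum);
    it is restricted when the sun-exposed operative temperature — air plus
    a midday bump of amplitude ``sun_excess`` — exceeds the upper preferred
    set-point ``upper_restriction``. Restriction is keyed to sun microsites
    because air maxima rarely reach the set-point even on days the animals
    demonstrably retreat. Returns (day, t_a_max, h_a, h_r).
    """
    from thermovuln.synthetic import diurnal_temperature

    hours_grid = np.arange(window[0], window[1] + 1e-9)
    bump = sun_excess * np.sin(np.pi * (hours_grid - window[0])
                               / (window[1] - window[0]))
    rows = []
    for _, rec in weather.iterrows():
        t_air = diurnal_temperature(hours_grid, float(rec["t_a_min"]),
                                    float(rec["t_a_max"]), dawn, peak)
        h_a, _ = daily_hours(t_air, lower, upper_activity)
        _, h_r = daily_hours(t_air + bump, lower, upper_restriction)
        rows.append({"day": int(rec["day"]), "t_a_max": float(rec["t_a_max"]),
                     "h_a": h_a, "h_r": h_r})
    return pd.DataFrame(rows)


def _month_of_day(day: np.ndarray) -> np.ndarray:
    edges = np.cumsum((0,) + _MONTH_LENGTHS)
    return np.searchsorted(edges, day, side="left").astype(int)  # 1..12


def project_monthly(p_ha: RichardsParams, p_hr: RichardsParams,
                    weather: pd.DataFrame,
                    scenarios: dict[str, float] | None = None) -> pd.DataFrame:
    """Monthly mean hours of activity/restriction under warming offsets.

    ``weather`` must cover a 365-day year with columns ``day`` (1..365) and
    ``t_a_max``. For each scenario the curves are evaluated at every day's
    maximum plus the scenario offset and averaged by calendar month.
    Returns a tidy frame (scenario, month, h_a, h_r).
    """
    if scenarios is None:
        scenarios = dict(DEFAULT_SCENARIOS)
    day = weather["day"].to_numpy()
    if day.size != 365:
        raise ValueError("weather table must hold exactly 365 days")
    t = weather["t_a_max"].to_numpy(dtype=float)
    month = _month_of_day(day)

    rows = []
    for name, delta in scenarios.items():
        ha = richards_eval(t + delta, p_ha)
        hr = richards_eval(t + delta, p_hr)
        frame = pd.DataFrame({"month": month, "h_a": ha, "h_r": hr})
        agg = frame.groupby("month", sort=True).mean().reset_index()
        agg.insert(0, "scenario", name)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)
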