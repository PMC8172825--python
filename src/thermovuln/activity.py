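"""Diel activity and microhabitat-use statistics.

Sighting times of day are treated as angles on the 24-h clock
(15 degrees per hour). The mean activity time is the direction of the
resultant vector; dispersion is the circular standard deviation
``sqrt(-2 ln R)`` (radians), reported both in degrees and as an hh:mm
duration. Microhabitat use is tested against a uniform expectation with a
chi-square goodness of fit, summarized per category with a relative
deviation index, and the joint time x microhabitat table is decomposed with
adjusted (Haberman) residuals under a Bonferroni-corrected per-cell level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ActivitySummary",
    "ContingencyResult",
    "circular_summary",
    "microhabitat_gof",
    "deviation_index",
    "contingency_posthoc",
]

DEG_PER_HOUR = 360.0 / 24.0


@dataclass(frozen=True)
class ActivitySummary:
    mean_time: float          # hours of day in [0, 24)
    mean_angle_deg: float     # degrees in [0, 360)
    resultant_R: float        # mean resultant length in [0, 1]
    circ_sd_deg: float        # circular standard deviation, degrees
    circ_sd_hhmm: str         # the same dispersion as "Hh Mmin"
    hourly_counts: dict = field(default_factory=dict)
    n: int = 0


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray | None = None
    adjusted_residuals: np.ndarray | None = None
    cell_p: np.ndarray | None = None
    alpha_adj: float | None = None


def _sd_to_hhmm(sd_deg: float) -> str:
    total_min = sd_deg / DEG_PER_HOUR * 60.0
    h, m = divmod(int(round(total_min)), 60)
    return f"{h}h {m:02d}min"


def circular_summary(times) -> ActivitySummary:
    """Circular mean and dispersion of sighting times of day.

    Raises if the resultant length is (numerically) zero, where the mean
    direction is undefined — e.g. two sightings 12 h apart.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("no sighting times")
    if np.any((t < 0) | (t >= 24)):
        raise ValueError("times must lie in [0, 24)")
    theta = np.deg2rad(t * DEG_PER_HOUR)
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    r = math.hypot(c, s)
    if r < 1e-12:
        raise ValueError("resultant length is zero: mean direction undefined")
    mean_angle = math.degrees(math.atan2(s, c)) % 360.0
    # guard against r marginally above 1 from rounding
    sd_rad = math.sqrt(max(-2.0 * math.log(min(r, 1.0)), 0.0))
    sd_deg = math.degrees(sd_rad)
    hours = np.floor(t).astype(int)
    counts = {int(h): int(n) for h, n in zip(*np.unique(hours, return_counts=True))}
    return ActivitySummary(
        mean_time=mean_angle / DEG_PER_HOUR,
        mean_angle_deg=mean_angle,
        resultant_R=min(r, 1.0),
        circ_sd_deg=sd_deg,
        circ_sd_hhmm=_sd_to_hhmm(sd_deg),
        hourly_counts=counts,
        n=int(t.size),
    )


def microhabitat_gof(observed) -> ContingencyResult:
    """Chi-square goodness of fit against uniform use of the categories."""
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    if obs.sum() <= 0 or np.any(obs < 0):
        raise ValueError("counts must be nonnegative with a positive total")
    chi2, p = stats.chisquare(obs)  # uniform expectation N/k by default
    expected = np.full(obs.size, obs.sum() / obs.size)
    return ContingencyResult(chi2=float(chi2), df=obs.size - 1, p=float(p),
                             expected=expected)


def deviation_index(observed: float, expected: float) -> float:
    """Relative deviation ``(O - E)/E`` of a category from its expectation.

    Nominally on a -1..1 scale (absence to doubling); values above 1 are
    possible when a category holds more than twice its expectation and are
    returned unchanged with a warning.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    d = (observed - expected) / expected
    if d > 1.0:
        warnings.warn(f"deviation index {d:.3f} exceeds the nominal [-1, 1] scale",
                      stacklevel=2)
    return float(d)


def contingency_posthoc(table, alpha: float = 0.05) -> ContingencyResult:
    """Pearson chi-square with adjusted-residual post hoc on an r x c table.

    Each cell's adjusted residual ``z = (O - E) / sqrt(E (1 - row/N)(1 - col/N))``
    is converted to a two-sided p-value via ``z^2 ~ chi-square(1)``; the
    per-cell significance level is Bonferroni-corrected by the number of
    cells (``alpha / (r c)``). Cells in a zero margin have undefined
    residuals and are reported as NaN.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_cells = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
        chi2 = float(chi2_cells.sum())
        denom = expected * (1.0 - row / n) * (1.0 - col / n)
        z = np.where(denom > 0, (obs - expected) / np.sqrt(denom), np.nan)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    cell_p = stats.chi2.sf(z ** 2, 1)
    return ContingencyResult(
        chi2=chi2, df=df, p=p, expected=expected,
        adjusted_residuals=z, cell_p=cell_p,
        alpha_adj=alpha / obs.size,
    )
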