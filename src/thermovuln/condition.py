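"""Scaled mass index of body condition via standardized major axis scaling.

The scaled mass index standardizes each individual's body mass to the mass
it would carry at the population's mean body length, using the allometric
scaling exponent estimated by standardized major axis (SMA) regression of
ln(mass) on ln(length):

    M_i = BW_i * (SVL_0 / SVL_i) ** b_SMA

where ``SVL_0`` is the arithmetic mean snout-vent length of the analyzed
population and ``b_SMA = sign(r) * sd(ln BW) / sd(ln SVL)``, with ``r`` the
Pearson correlation of the logs. Unlike residual-based condition indices,
M_i is comparable across groups that differ in size structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BodyConditionModel", "sma_slope", "scaled_mass_index", "fit_body_condition"]


@dataclass(frozen=True)
class BodyConditionModel:
    b_sma: float          # SMA scaling exponent, dimensionless
    svl_0: float          # reference length: population mean SVL (mm)

    def __post_init__(self) -> None:
        if not np.isfinite(self.b_sma):
            raise ValueError("b_sma must be finite")
        if self.svl_0 <= 0:
            raise ValueError("svl_0 must be positive")


def sma_slope(svl, bw) -> float:
    """SMA scaling exponent from log-log length/mass data.

    ``b = sign(r) * sd(ln bw) / sd(ln svl)``. Raises on nonpositive
    measurements, zero length variance, or an exactly zero correlation
    (the slope sign is then undefined).
    """
    x = np.log(_positive(svl, "svl"))
    y = np.log(_positive(bw, "bw"))
    if x.size != y.size:
        raise ValueError("svl and bw must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 individuals")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0:
        raise ValueError("zero variance in ln(svl); slope undefined")
    if sy == 0:
        _raise_zero_r()  # zero mass variance: r undefined
    r = np.corrcoef(x, y)[0, 1]
    if r == 0 or not np.isfinite(r):
        _raise_zero_r()
    return float(np.sign(r) * sy / sx)


def _raise_zero_r():
    raise ValueError("log length/mass correlation is zero or undefined; "
                     "SMA slope sign cannot be determined")


def _positive(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"all {name} values must be finite and positive")
    return arr


def scaled_mass_index(bw_i: float, svl_i: float, model: BodyConditionModel) -> float:
    """Scaled mass of one individual at the reference length (grams)."""
    if svl_i <= 0:
        raise ValueError("svl_i must be positive")
    return float(bw_i * (model.svl_0 / svl_i) ** model.b_sma)


def fit_body_condition(captures: pd.DataFrame, include_juveniles: bool = True
                       ) -> tuple[BodyConditionModel, pd.Series]:
    """Fit the SMA model on a capture table and score every individual.

    Uses columns ``SVL``, ``BW`` and (when ``include_juveniles`` is False)
    ``sex_age`` to restrict the slope/reference estimation to adults; the
    returned Series of M_i is indexed like ``captures`` and scores all rows
    against the fitted model either way.
    """
    fit_rows = captures
    if not include_juveniles:
        fit_rows = captures[captures["sex_age"] != "juvenile"]
    model = BodyConditionModel(
        b_sma=sma_slope(fit_rows["SVL"], fit_rows["BW"]),
        svl_0=float(fit_rows["SVL"].mean()),
    )
    mi = captures.apply(lambda r: scaled_mass_index(r["BW"], r["SVL"], model), axis=1)
    return model, mi.rename("M_i")
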