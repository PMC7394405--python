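"""Net relative regrowth, clipping calibration, and grazing-pressure inversion.

Net relative regrowth of a sward over a trial is

    r = ln(final height) - ln(initial height),

back-transformable to percentage growth 100 * (exp(r) - 1).  A clipping
experiment with known defoliation counts x yields a calibration line
r = slope * x + intercept by ordinary least squares; inverting that line at
the mean regrowth observed in a cattle camp estimates how many times a
sward was grazed there during the trial.

Negative regrowth values are shifted to non-negative before Gamma-GLM
comparison by adding the magnitude of the most negative value
(:func:`shift_transform`); the constant is returned so the transform is
invertible and reportable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SchemaError, SwardSeries


@dataclass(frozen=True)
class CalibrationLine:
    """OLS fit of relative regrowth against defoliation-event count."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise SchemaError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise SchemaError("a calibration line needs >= 2 points")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class GrazingEstimate:
    """Inverted grazing frequency: continuous and nearest-integer estimates."""

    x_continuous: float
    x_rounded: int
    negative: bool  # flagged when the continuous estimate is < 0


def relative_regrowth(series: SwardSeries) -> float:
    """ln(final height) - ln(initial height); may be negative."""
    h0, h1 = series.initial_height_cm, series.final_height_cm
    if h0 <= 0 or h1 <= 0:
        raise SchemaError("heights must be positive for relative regrowth")
    return math.log(h1) - math.log(h0)


def pct_growth(rel_regrowth: float) -> float:
    """Back-transform relative regrowth to percentage growth, 100*(e^r - 1)."""
    return 100.0 * math.expm1(rel_regrowth)


def relative_from_pct(pct: float) -> float:
    """Inverse of :func:`pct_growth`: ln(1 + pct/100)."""
    if pct <= -100:
        raise SchemaError("percentage growth must exceed -100%")
    return math.log1p(pct / 100.0)


def regrowth_frame(series_list: Iterable[SwardSeries]) -> pd.DataFrame:
    """Per-sward regrowth table: group, sward, defoliation count, r, %growth."""
    rows = []
    for s in series_list:
        r = relative_regrowth(s)
        rows.append({
            "sward_id": s.sward_id,
            "group": s.group,
            "n_defoliations": s.n_defoliations,
            "initial_height_cm": s.initial_height_cm,
            "final_height_cm": s.final_height_cm,
            "relative_regrowth": r,
            "pct_growth": pct_growth(r),
        })
    if not rows:
        raise SchemaError("no sward series supplied")
    return pd.DataFrame(rows)


def fit_calibration(
    clip_counts: Sequence[float], regrowths: Sequence[float]
) -> CalibrationLine:
    """OLS of relative regrowth on defoliation count.

    The unclipped (zero-event) treatment must be excluded upstream: the
    calibration describes swards that were actually defoliated.
    """
    x = np.asarray(clip_counts, dtype=float)
    y = np.asarray(regrowths, dtype=float)
    if x.size != y.size:
        raise SchemaError("clip_counts and regrowths must have equal length")
    if x.size < 2:
        raise SchemaError("calibration needs >= 2 points")
    if np.unique(x).size < 2:
        raise SchemaError("all clip counts identical: slope undefined")
    res = stats.linregress(x, y)
    # r^2 of a two-point or exact fit can come back as nan when residuals
    # are identically zero; an exact fit has r^2 = 1 by definition.
    r2 = float(res.rvalue ** 2)
    if math.isnan(r2):
        r2 = 1.0
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        n_points=int(x.size),
    )


def invert_grazing_frequency(
    line: CalibrationLine, rel_regrowth: float
) -> GrazingEstimate:
    """Solve the calibration line for the defoliation count x.

    x = (r - intercept) / slope.  The rounded estimate uses banker's
    rounding (ties to even).  A negative continuous estimate is returned
    but flagged — it means the observed regrowth exceeds the calibration's
    zero-grazing prediction.
    """
    if line.slope == 0:
        raise SchemaError("calibration slope is zero: inversion undefined")
    x = (rel_regrowth - line.intercept) / line.slope
    return GrazingEstimate(
        x_continuous=float(x),
        x_rounded=int(round(x)),
        negative=x < 0,
    )


def shift_transform(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Shift a collection to non-negative by adding |min| when min < 0.

    Returns ``(shifted, constant)`` where ``constant`` is the amount added
    (0 when the input was already non-negative), so the transform can be
    undone and reported.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise SchemaError("shift_transform needs a non-empty collection")
    lowest = arr.min()
    constant = float(-lowest) if lowest < 0 else 0.0
    return arr + constant, constant
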