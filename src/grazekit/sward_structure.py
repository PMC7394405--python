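"""Sward availability summaries: height heterogeneity and greenness.

Structural heterogeneity of the grass layer is measured as the coefficient
of variation of sward height, CV = 100 * sd / mean, computed per camp and
season from transect quadrats.  Greenness availability collapses Walker's
eight-point percent-green scale to four bins and reports the proportion of
quadrats in each bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GREENNESS4, WALKER_CLASSES, SchemaError

#: Walker eight-point class -> four-bin greenness category.
#: very brown 0-10%, mainly brown 11-50%, mainly green 51-90%,
#: very green 91-100%.
WALKER_TO_BIN4: dict[str, str] = {
    "0": "very brown",
    "1-10": "very brown",
    "11-25": "mainly brown",
    "26-50": "mainly brown",
    "51-75": "mainly green",
    "76-90": "mainly green",
    "91-99": "very green",
    "100": "very green",
}

assert set(WALKER_TO_BIN4) == set(WALKER_CLASSES)
assert set(WALKER_TO_BIN4.values()) == set(GREENNESS4)

GROUP_COLS = ["camp_id", "season"]


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Height summary of one camp x season group of quadrats."""

    camp_id: str
    season: str
    n_quadrats: int
    mean_height_cm: float
    min_height_cm: float
    max_height_cm: float
    cv_pct: float


def bin_greenness(walker_class: str) -> str:
    """Map a Walker eight-point class label to its four-bin category."""
    try:
        return WALKER_TO_BIN4[walker_class]
    except KeyError:
        raise SchemaError(
            f"unknown Walker greenness class {walker_class!r}; "
            f"expected one of {list(WALKER_CLASSES)}"
        ) from None


def cv_pct(values) -> float:
    """Coefficient of variation, 100 * sd / mean, with the sample (n-1) sd."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise SchemaError("CV needs at least two values")
    return 100.0 * arr.std(ddof=1) / arr.mean()


def heterogeneity(quadrats: pd.DataFrame) -> pd.DataFrame:
    """Per camp x season height summary: mean, min, max, CV.

    Parameters
    ----------
    quadrats
        Validated quadrat table (``camp_id, season, sward_height_cm`` used).

    Returns
    -------
    One row per camp x season with columns
    ``camp_id, season, n_quadrats, mean_height_cm, min_height_cm,
    max_height_cm, cv_pct``.
    """
    if quadrats.empty:
        raise SchemaError("no quadrats to summarize")
    rows = []
    for (camp, season), g in quadrats.groupby(GROUP_COLS, sort=True):
        h = g["sward_height_cm"].to_numpy(dtype=float)
        if h.size < 2:
            raise SchemaError(
                f"camp {camp!r} season {season!r}: CV undefined for < 2 quadrats"
            )
        rows.append(HeterogeneitySummary(
            camp_id=camp,
            season=season,
            n_quadrats=int(h.size),
            mean_height_cm=float(h.mean()),
            min_height_cm=float(h.min()),
            max_height_cm=float(h.max()),
            cv_pct=cv_pct(h),
        ))
    return pd.DataFrame([vars(r) for r in rows])


def greenness_availability(quadrats: pd.DataFrame) -> pd.DataFrame:
    """Proportion of quadrats in each four-bin greenness category.

    Returns a long frame with columns ``camp_id, season, greenness4,
    proportion``; within every camp x season the four proportions sum to 1
    (bins absent from the data appear with proportion 0).
    """
    if quadrats.empty:
        raise SchemaError("no quadrats to summarize")
    df = quadrats.copy()
    df["greenness4"] = df["greenness_pct_class"].map(bin_greenness)
    rows = []
    for (camp, season), g in df.groupby(GROUP_COLS, sort=True):
        counts = g["greenness4"].value_counts()
        total = int(counts.sum())
        for bin4 in GREENNESS4:
            rows.append({
                "camp_id": camp,
                "season": season,
                "greenness4": bin4,
                "proportion": counts.get(bin4, 0) / total,
            })
    return pd.DataFrame(rows)
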