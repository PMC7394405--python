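"""Gamma-GLM group comparisons, pairwise contrasts, and pooling.

Group differences in strictly positive responses (sward height, intake
rates, shifted regrowth) are tested with a Gamma GLM with log link and a
single categorical predictor.  The omnibus test is a likelihood-ratio
deviance test scaled by the Pearson-estimated dispersion, referred to a
chi-square distribution with (levels - 1) degrees of freedom; the
equivalent F-statistic and its p-value are reported alongside.

With a log link and a factor-only design the fitted group means equal the
arithmetic group means, so the model is a distribution-aware way of
comparing means, and the likelihood-ratio statistic is invariant to
rescaling the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import GREENNESS4, SchemaError
from .sward_structure import bin_greenness

logger = logging.getLogger("grazekit")

GREEN_BINS = ("mainly green", "very green")


@dataclass
class GlmResult:
    """Result surface of a one-factor Gamma/log GLM comparison."""

    response: str
    levels: tuple[str, ...]
    coefficients: dict[str, float]   # per-level coefficients on the log scale
    group_means: dict[str, float]    # response-scale fitted (= sample) means
    lr_chisq: float
    df: int
    p_value: float                   # chi-square reference
    f_stat: float
    p_value_f: float                 # F reference (dispersion-aware)
    dispersion: float
    zero_offset: float               # added to exact zeros before fitting
    _fit: object = field(default=None, repr=False)
    _cov: np.ndarray | None = field(default=None, repr=False)


def _as_arrays(values: Sequence[float], groups: Sequence[str]):
    y = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    if y.size != g.size:
        raise SchemaError("values and groups must have equal length")
    return y, g


def gamma_glm_compare(
    values: Sequence[float],
    groups: Sequence[str],
    response: str = "response",
) -> GlmResult:
    """Fit a Gamma/log GLM of ``values`` on the ``groups`` factor.

    Requires strictly positive values — regrowth data must pass through
    :func:`grazekit.regrowth.shift_transform` first.  Exact zeros produced
    by that shift are offset by half the smallest positive value (the
    offset is recorded in the result).  Each group needs >= 2 values and
    there must be >= 2 groups.
    """
    y, g = _as_arrays(values, groups)
    if np.any(y < 0):
        raise SchemaError(
            "negative values: apply grazekit.regrowth.shift_transform before "
            "fitting a Gamma GLM"
        )
    levels = tuple(sorted(set(g)))
    if len(levels) < 2:
        raise SchemaError("need >= 2 groups to compare (single group supplied)")
    for lev in levels:
        if (g == lev).sum() < 2:
            raise SchemaError(f"group {lev!r} has < 2 values")
    zero_offset = 0.0
    if np.any(y == 0):
        positive = y[y > 0]
        if positive.size == 0:
            raise SchemaError("all values are zero: Gamma GLM undefined")
        zero_offset = float(positive.min() / 2.0)
        y = np.where(y == 0, zero_offset, y)
        logger.info("gamma_glm_compare: offset %d zero value(s) by %g",
                    int((np.asarray(values) == 0).sum()), zero_offset)

    design = np.zeros((y.size, len(levels)))
    for j, lev in enumerate(levels):
        design[:, j] = (g == lev).astype(float)
    model = sm.GLM(y, design, family=sm.families.Gamma(sm.families.links.Log()))
    fit = model.fit()
    dispersion = float(fit.pearson_chi2 / fit.df_resid)
    df = len(levels) - 1
    lr = float((fit.null_deviance - fit.deviance) / dispersion)
    lr = max(lr, 0.0)
    f_stat = lr / df
    coefs = {lev: float(b) for lev, b in zip(levels, fit.params)}
    return GlmResult(
        response=response,
        levels=levels,
        coefficients=coefs,
        group_means={lev: float(np.exp(b)) for lev, b in coefs.items()},
        lr_chisq=lr,
        df=df,
        p_value=float(sps.chi2.sf(lr, df)),
        f_stat=float(f_stat),
        p_value_f=float(sps.f.sf(f_stat, df, fit.df_resid)),
        dispersion=dispersion,
        zero_offset=zero_offset,
        _fit=fit,
        _cov=np.asarray(fit.cov_params()),
    )


def pairwise_contrasts(result: GlmResult) -> pd.DataFrame:
    """All pairwise Wald tests between group levels on the log scale.

    Returns one row per pair with the log-scale difference, its standard
    error, z, the unadjusted p-value, and a Holm-adjusted column.  Needs
    >= 3 levels (with two, the omnibus test already is the pairwise test).
    """
    if len(result.levels) < 3:
        raise SchemaError("pairwise contrasts need >= 3 groups; "
                          "use the omnibus test for two")
    if result._cov is None:
        raise SchemaError("result does not carry a fitted model")
    cov = result._cov
    idx = {lev: j for j, lev in enumerate(result.levels)}
    rows = []
    for a, b in combinations(result.levels, 2):
        i, j = idx[a], idx[b]
        diff = result.coefficients[a] - result.coefficients[b]
        se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        z = diff / se if se > 0 else np.inf * np.sign(diff)
        p = float(2 * sps.norm.sf(abs(z)))
        rows.append({
            "level_a": a, "level_b": b,
            "log_ratio": float(diff), "se": se, "z": float(z),
            "ratio": float(np.exp(diff)), "p_unadjusted": p,
        })
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_unadjusted"], method="holm")[1]
    return out


def pool_groups(
    values: Sequence[float],
    groups: Sequence[str],
    to_pool: Sequence[str],
    pooled_label: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel the listed groups with one pooled label.

    The value multiset is untouched; only labels change.  Unknown labels
    in ``to_pool`` are an error.
    """
    y, g = _as_arrays(values, groups)
    present = set(g)
    unknown = [lab for lab in to_pool if lab not in present]
    if unknown:
        raise SchemaError(f"cannot pool unknown group label(s) {unknown}")
    pooled = np.where(np.isin(g, list(to_pool)), pooled_label, g)
    return y, pooled


def greenness_diet_proportions(bites: pd.DataFrame) -> pd.DataFrame:
    """Proportion of green bites per camp over {mainly green, very green}.

    Only the two green bins enter (the selective grazers feed from them);
    within each camp the two proportions sum to 1.  Accepts either a
    ``greenness4`` column or Walker classes in ``greenness_pct_class``.
    """
    df = bites.copy()
    if "greenness4" not in df.columns:
        df["greenness4"] = df["greenness_pct_class"].map(bin_greenness)
    df = df[df["greenness4"].isin(GREEN_BINS)]
    if df.empty:
        raise SchemaError("no bites in the mainly green / very green bins")
    rows = []
    for camp, g in df.groupby("camp_id", sort=True):
        total = len(g)
        for bin4 in GREEN_BINS:
            rows.append({
                "camp_id": camp,
                "greenness4": bin4,
                "n_bites": int((g["greenness4"] == bin4).sum()),
                "proportion": float((g["greenness4"] == bin4).sum() / total),
            })
    return pd.DataFrame(rows)


def glm_table(results: list[GlmResult]) -> pd.DataFrame:
    """Flatten GLM results into a report table."""
    rows = []
    for r in results:
        row = {
            "response": r.response,
            "levels": "|".join(r.levels),
            "lr_chisq": r.lr_chisq,
            "df": r.df,
            "p_value": r.p_value,
            "f_stat": r.f_stat,
            "p_value_f": r.p_value_f,
            "dispersion": r.dispersion,
            "zero_offset": r.zero_offset,
        }
        for lev, m in r.group_means.items():
            row[f"mean[{lev}]"] = m
        rows.append(row)
    return pd.DataFrame(rows)
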