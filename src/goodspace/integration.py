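"""Dimensional integration of value signals: variant comparisons and ANCOVA.

Value variables come in two variants: for juice-based offer values and the
chosen value, a cost-affected variant (includes the xi term for the low-cost
offer) and a cost-independent one (quantity terms only); for cost-based
offer values, a commodity-affected variant (includes rho) and a
commodity-independent one (raw quantities).  If a neuron's firing integrates
the determinant under test, the affected variant fits better and
dR2 = R2_affected - R2_independent is positive across the population.

Responses are identified without favoring either variant: each response is
credited with the larger of the two variant R2 per variable family, then
assigned by best fit.  A parallel-model ANCOVA (common slope, group
intercepts) provides the complementary test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import variables as V
from .task_core import Session

__all__ = [
    "VARIANT_FAMILIES",
    "variant_r2_table",
    "unbiased_identify",
    "delta_r2_population",
    "epoch_contrast",
    "AncovaResult",
    "ancova_parallel",
]

# Families with a variant contrast and their default analysis windows.
VARIANT_FAMILIES: dict[str, tuple[str, ...]] = {
    "offer value (juice)": ("post_offer",),
    "offer value (cost)": ("post_offer",),
    "chosen value": ("post_offer", "post_target"),
}


def variant_r2_table(session: Session, rmatrix, fit,
                     responses: Sequence[tuple[str, str]],
                     level: str = "type") -> pd.DataFrame:
    """Regress every response on the catalog under both variants.

    Returns one row per response x collapsed variable with columns
    r2_affected / r2_independent (raw R2 of the best component under each
    variant), the unbiased R2 (max of the two variants' effective R2), and
    explains flags.  Variables without variants have identical columns.
    """
    all_ids = list(V.CATALOG)
    reg_aff = V.regress_catalog(session, rmatrix, fit, responses,
                                variants={i: "affected" for i in all_ids}, level=level)
    reg_ind = V.regress_catalog(session, rmatrix, fit, responses,
                                variants={i: "independent" for i in all_ids}, level=level)
    rows = []
    key = ["neuron", "window", "variable_id"]
    aff = reg_aff.set_index(key)
    ind = reg_ind.set_index(key)
    for (neuron, window), grp in reg_aff.groupby(["neuron", "window"], sort=False):
        for parent, comp_ids in V.COLLAPSED.items():
            best_aff_raw, best_aff_eff = 0.0, 0.0
            best_ind_raw, best_ind_eff = 0.0, 0.0
            for vid in comp_ids:
                ra = aff.loc[(neuron, window, vid)]
                ri = ind.loc[(neuron, window, vid)]
                if ra.r2_raw > best_aff_raw:
                    best_aff_raw = float(ra.r2_raw)
                best_aff_eff = max(best_aff_eff, float(ra.r2_effective))
                if ri.r2_raw > best_ind_raw:
                    best_ind_raw = float(ri.r2_raw)
                best_ind_eff = max(best_ind_eff, float(ri.r2_effective))
            rows.append({
                "neuron": neuron, "window": window, "collapsed": parent,
                "r2_affected": best_aff_raw, "r2_independent": best_ind_raw,
                "r2_unbiased": max(best_aff_eff, best_ind_eff),
                "explains": max(best_aff_eff, best_ind_eff) > 0,
            })
    return pd.DataFrame(rows)


def unbiased_identify(variant_table: pd.DataFrame, family: str,
                      windows: Sequence[str] | None = None) -> pd.DataFrame:
    """Responses whose unbiased best fit is ``family`` within the given windows.

    Each response is credited with max(R2 over variants) per family
    (effective R2), then assigned to the family with the largest credit.
    Returns the family's rows with the dR2 column attached.
    """
    if windows is None:
        windows = VARIANT_FAMILIES.get(family, ("post_offer",))
    sub = variant_table[variant_table["window"].isin(windows)]
    picked = []
    for (neuron, window), grp in sub.groupby(["neuron", "window"], sort=False):
        g = grp.set_index("collapsed")["r2_unbiased"]
        best = V.best_fit_assignment(g.to_dict())
        if best == family:
            row = grp[grp["collapsed"] == family].iloc[0].to_dict()
            row["delta_r2"] = row["r2_affected"] - row["r2_independent"]
            picked.append(row)
    return pd.DataFrame(picked, columns=list(sub.columns) + ["delta_r2"])


def delta_r2_population(identified: pd.DataFrame, min_n: int = 6) -> dict:
    """Population mean dR2 and two-sided Wilcoxon signed-rank p vs 0."""
    d = identified["delta_r2"].to_numpy(float)
    d = d[np.isfinite(d)]
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} responses, got {d.size}")
    if np.allclose(d, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(d).pvalue)
    return {"mean_delta_r2": float(d.mean()), "p_signed_rank": p, "n": int(d.size)}


def epoch_contrast(early: pd.DataFrame | np.ndarray, late: pd.DataFrame | np.ndarray) -> dict:
    """mean(late dR2) - mean(early dR2) with a two-sample rank-sum test."""
    e = early["delta_r2"].to_numpy(float) if isinstance(early, pd.DataFrame) else np.asarray(early, float)
    l = late["delta_r2"].to_numpy(float) if isinstance(late, pd.DataFrame) else np.asarray(late, float)
    if e.size < 2 or l.size < 2:
        raise ValueError("both epochs need at least 2 responses")
    stat, p = stats.ranksums(l, e)
    return {"difference": float(l.mean() - e.mean()), "p_ranksum": float(p),
            "n_early": int(e.size), "n_late": int(l.size)}


@dataclass
class AncovaResult:
    slope: float
    slope_p: float
    group_p: float
    intercepts: dict
    n: int


def ancova_parallel(rates, values, groups) -> AncovaResult:
    """Parallel-model ANCOVA: common slope on the value, one intercept per group.

    The group factor is tested with a type-II F-test.  With a single group
    the model reduces to a simple linear regression (group_p = NaN).
    """
    y = np.asarray(rates, float)
    x = np.asarray(values, float)
    g = np.asarray(groups)
    if y.shape != x.shape or y.shape != g.shape:
        raise ValueError("rates, values, groups must align")
    levels = pd.unique(g)
    for lev in levels:
        if (g == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 points")
    if len(levels) == 1:
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        return AncovaResult(slope=float(res.params[1]), slope_p=float(res.pvalues[1]),
                            group_p=np.nan, intercepts={levels[0]: float(res.params[0])},
                            n=int(y.size))
    # dummy-code groups (first level = reference)
    codes = pd.Categorical(g, categories=levels).codes
    D = np.zeros((y.size, len(levels) - 1))
    for k in range(1, len(levels)):
        D[codes == k, k - 1] = 1.0
    X_full = np.column_stack([np.ones(y.size), x, D])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("singular ANCOVA design")
    res = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, np.column_stack([np.ones(y.size), x])).fit()
    df_g = len(levels) - 1
    F = ((red.ssr - res.ssr) / df_g) / (res.ssr / res.df_resid)
    group_p = float(stats.f.sf(F, df_g, res.df_resid))
    base = float(res.params[0])
    intercepts = {levels[0]: base}
    for k in range(1, len(levels)):
        intercepts[levels[k]] = base + float(res.params[1 + k])
    return AncovaResult(slope=float(res.params[1]), slope_p=float(res.pvalues[1]),
                        group_p=group_p, intercepts=intercepts, n=int(y.size))
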