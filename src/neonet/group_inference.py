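"""Cross-sectional group comparisons of network metrics.

The workhorse is a one-way ANCOVA: an ordinary linear model of a metric
on the birth-age group factor plus the covariates (PMA at scan, sex,
mean DVARS), with the group effect tested by a Type-II F — the
full-model residual sum of squares against the model with the group
dummies dropped.  Post-hoc pairwise contrasts use the Tukey-Kramer
studentized-range procedure on the covariate-adjusted group means.
Multiple testing across costs or across the 90 regions is handled with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("pma_scan", "sex", "mean_dvars")


@dataclass
class ANCOVAResult:
    """Group-effect F test from a covariate-adjusted linear model."""

    factor_df: int
    residual_df: int
    f_value: float
    p_value: float
    covariate_terms: list[tuple[str, float, float]]  # (name, F, p)
    group_levels: list[str] = field(default_factory=list)
    group_counts: dict[str, int] = field(default_factory=dict)
    group_coefficients: dict[str, float] = field(default_factory=dict)
    coefficient_cov: np.ndarray | None = None
    mse: float = float("nan")


@dataclass(frozen=True)
class PairwiseComparison:
    """One Tukey-Kramer contrast between covariate-adjusted group means."""

    group_a: str
    group_b: str
    difference: float  # adjusted mean of b minus adjusted mean of a
    p_value: float


def _encode_covariates(table: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        s = table[cov]
        if cov == "sex" or s.dtype == object:
            levels = sorted(s.unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {cov} has more than two levels: {levels}")
            cols[cov] = (s == levels[-1]).astype(float)
        else:
            cols[cov] = s.astype(float)
    return pd.DataFrame(cols, index=table.index)


def ancova_group_effect(
    table: pd.DataFrame,
    response: str,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "group",
) -> ANCOVAResult:
    """One-way ANCOVA of ``response`` on the group factor plus covariates.

    The group F is Type II: (RSS_reduced - RSS_full) / df_group over the
    full-model mean squared error, where the reduced model keeps the
    covariates but drops the group dummies.  Covariate F tests drop each
    covariate from the full model in turn.
    """
    data = table.dropna(subset=[response]).copy()
    groups = data[group_col].astype(str)
    levels = [g for g in pd.unique(groups)]
    counts = groups.value_counts()
    # singleton groups are tolerated (their dummy absorbs one point); the
    # post-hoc stage excludes them from pairwise contrasts
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")

    y = data[response].to_numpy(float)
    cov_df = _encode_covariates(data, covariates)
    dummies = pd.get_dummies(groups, prefix="group", dtype=float).iloc[:, 1:]
    X_full = pd.concat(
        [pd.Series(1.0, index=data.index, name="intercept"), dummies, cov_df], axis=1
    )
    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        acc = np.empty((len(data), 0))
        for name in X_full.columns:
            cand = np.column_stack([acc, X_full[name].to_numpy()])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                bad.append(name)
            else:
                acc = cand
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    full = sm.OLS(y, X_full.to_numpy()).fit()

    def rss(cols: list[str]) -> float:
        X = X_full[cols].to_numpy()
        return float(sm.OLS(y, X).fit().ssr)

    all_cols = list(X_full.columns)
    group_cols = list(dummies.columns)
    cov_cols = list(cov_df.columns)
    rss_full = float(full.ssr)
    df_resid = int(full.df_resid)
    mse = rss_full / df_resid

    df_group = len(group_cols)
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = rss_full <= 1e-12 * max(tss, 1.0)
    if degenerate:
        # response fits exactly (constant, or a pure covariate function):
        # any leftover sums of squares are numerical noise, not group signal
        f_group, p_group = 0.0, 1.0
        cov_terms = [(cov, 0.0, 1.0) for cov in cov_cols]
    else:
        rss_nogroup = rss(["intercept"] + cov_cols)
        f_group = max(((rss_nogroup - rss_full) / df_group) / mse, 0.0)
        p_group = float(stats.f.sf(f_group, df_group, df_resid))
        cov_terms = []
        for cov in cov_cols:
            others = [c for c in all_cols if c != cov]
            f_cov = max(((rss(others) - rss_full) / 1) / mse, 0.0)
            cov_terms.append((cov, float(f_cov), float(stats.f.sf(f_cov, 1, df_resid))))

    coefs = dict(zip(all_cols, full.params))
    group_coef = {levels[0]: 0.0}
    for lvl in levels[1:]:
        group_coef[lvl] = float(coefs.get(f"group_{lvl}", 0.0))
    # covariance of the group-dummy coefficients (reference row/col are zero)
    idx = {name: i for i, name in enumerate(all_cols)}
    k = len(levels)
    cov_mat = np.zeros((k, k))
    vc = np.asarray(full.cov_params())
    for a, la in enumerate(levels):
        for b, lb in enumerate(levels):
            ia = idx.get(f"group_{la}")
            ib = idx.get(f"group_{lb}")
            if ia is not None and ib is not None:
                cov_mat[a, b] = vc[ia, ib]

    return ANCOVAResult(
        factor_df=df_group,
        residual_df=df_resid,
        f_value=float(f_group),
        p_value=p_group,
        covariate_terms=cov_terms,
        group_levels=levels,
        group_counts={g: int(counts[g]) for g in levels},
        group_coefficients=group_coef,
        coefficient_cov=cov_mat,
        mse=mse,
    )


def tukey_hsd(result: ANCOVAResult, alpha: float = 0.05) -> list[PairwiseComparison]:
    """Tukey-Kramer pairwise contrasts on covariate-adjusted group means.

    Differences of adjusted means equal differences of group-dummy
    coefficients (covariates held at their sample values).  The
    studentized-range statistic is q = |diff| / sqrt(var(diff) / 2) with
    the variance taken from the fitted model, referred to the
    studentized-range distribution with k groups and the model residual
    df.  Groups with a single observation are excluded with a warning.
    """
    levels = [g for g in result.group_levels if result.group_counts.get(g, 0) >= 2]
    dropped = set(result.group_levels) - set(levels)
    if dropped:
        warnings.warn(f"groups with n=1 excluded from Tukey HSD: {sorted(dropped)}",
                      stacklevel=2)
    k = len(levels)
    if k < 2:
        return []
    idx = {g: i for i, g in enumerate(result.group_levels)}
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            ga, gb = levels[a], levels[b]
            ia, ib = idx[ga], idx[gb]
            diff = result.group_coefficients[gb] - result.group_coefficients[ga]
            vc = result.coefficient_cov
            var = vc[ia, ia] + vc[ib, ib] - 2 * vc[ia, ib]
            if var <= 0:
                p = 1.0
            else:
                q = abs(diff) / np.sqrt(var / 2.0)
                p = float(stats.studentized_range.sf(q, k, result.residual_df))
            out.append(PairwiseComparison(ga, gb, float(diff), min(max(p, 0.0), 1.0)))
    return out


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns the rejection mask and the threshold p* (the largest
    rejected p value), or None when nothing is rejected.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), None
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    p_star = float(p[reject].max()) if reject.any() else None
    return reject, p_star


def nodal_group_maps(
    nodal_table: pd.DataFrame,
    metric: str,
    covariates=DEFAULT_COVARIATES,
    q: float = 0.05,
    group_col: str = "group",
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Per-region group ANCOVAs with FDR across regions.

    Expects a long-format nodal table at a single cost.  Returns
    ``(map, p_star, f_threshold)`` where the map has one row per region
    with (F, p, reject) and ``f_threshold`` is the smallest F among
    rejected regions — the F value at which the FDR line is crossed.
    Regions whose model cannot be fitted are excluded and logged.
    """
    if nodal_table["cost"].nunique() > 1:
        raise ValueError("nodal_group_maps expects a table at a single cost")
    regions, fvals, pvals = [], [], []
    for region, sub in nodal_table.groupby("region", sort=True, observed=True):
        try:
            res = ancova_group_effect(sub, metric, covariates, group_col)
        except ValueError as err:
            logger.warning("region %s excluded from nodal maps: %s", region, err)
            continue
        regions.append(region)
        fvals.append(res.f_value)
        pvals.append(res.p_value)
    reject, p_star = fdr_bh(pvals, q=q)
    table = pd.DataFrame(
        {"region": regions, "f_value": fvals, "p_value": pvals, "reject": reject}
    )
    f_threshold = float(table.loc[table["reject"], "f_value"].min()) if reject.any() else None
    return table, p_star, f_threshold


def costwise_group_tests(
    metric_table: pd.DataFrame,
    metrics=("strength", "clustering", "path_length", "global_efficiency"),
    covariates=DEFAULT_COVARIATES,
    q: float = 0.05,
    group_col: str = "group",
    correct_within_metric: bool = False,
) -> pd.DataFrame:
    """Group ANCOVA for every (cost, metric) cell with BH-FDR.

    By default the correction spans the whole cost-by-metric grid (40
    cells on the default sweep); ``correct_within_metric`` applies BH
    separately within each metric's cost profile instead.
    """
    rows = []
    for cost, sub in metric_table.groupby("cost", sort=True, observed=True):
        for metric in metrics:
            res = ancova_group_effect(sub, metric, covariates, group_col)
            rows.append({"cost": float(cost), "metric": metric,
                         "f_value": res.f_value, "df": res.factor_df,
                         "df_resid": res.residual_df, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    if correct_within_metric:
        out["reject"] = False
        out["p_adjusted"] = np.nan
        for metric in metrics:
            mask = out["metric"] == metric
            rej, _, p_adj, _ = multipletests(out.loc[mask, "p_value"], alpha=q,
                                             method="fdr_bh")
            out.loc[mask, "reject"] = rej
            out.loc[mask, "p_adjusted"] = p_adj
    else:
        rej, _, p_adj, _ = multipletests(out["p_value"], alpha=q, method="fdr_bh")
        out["reject"] = rej
        out["p_adjusted"] = p_adj
    return out


def sex_effect_ancova(
    table: pd.DataFrame,
    response: str,
    age_col: str = "pma_scan",
    interaction: bool = False,
) -> dict[str, float]:
    """Sex term of the covariate-adjusted model, optionally with sex x age.

    Used on the preterm subsample to test sex differences in each
    metric; returns the sex F and p, plus the interaction F and p when
    requested.
    """
    data = table.copy()
    sex = (data["sex"] == "male").astype(float).to_numpy()
    age = data[age_col].to_numpy(float)
    y = data[response].to_numpy(float)
    X = np.column_stack([np.ones_like(age), age, sex])
    names = ["intercept", age_col, "sex"]
    if interaction:
        X = np.column_stack([X, sex * (age - age.mean())])
        names.append("sex_x_age")
    full = sm.OLS(y, X).fit()
    out = {}
    for term in (["sex", "sex_x_age"] if interaction else ["sex"]):
        j = names.index(term)
        keep = [i for i in range(X.shape[1]) if i != j]
        red = sm.OLS(y, X[:, keep]).fit()
        f = max((red.ssr - full.ssr) / (full.ssr / full.df_resid), 0.0)
        out[f"{term}_f"] = float(f)
        out[f"{term}_p"] = float(stats.f.sf(f, 1, full.df_resid))
    return out


def kendall_trend(values, ordinal, increasing: bool = True) -> tuple[float, float]:
    """One-sided Kendall rank trend of ``values`` against an ordinal axis.

    Returns (tau, one-sided p for the stated direction).  Used to test
    that group-mean network properties rise (or fall) across the seven
    birth-age groups.
    """
    res = stats.kendalltau(np.asarray(ordinal, float), np.asarray(values, float))
    tau, p_two = float(res.statistic), float(res.pvalue)
    aligned = tau > 0 if increasing else tau < 0
    p_one = p_two / 2 if aligned else 1 - p_two / 2
    return tau, p_one
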