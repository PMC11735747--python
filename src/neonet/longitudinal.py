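"""Paired first-scan vs term-equivalent-scan comparisons for preterm groups.

For each preterm group and each network metric, the difference between
the term-equivalent (second) and early (first) scan is tested with a
paired t-test when the differences look normal (Shapiro-Wilk at
alpha = 0.05) and with the Wilcoxon signed-rank test otherwise.  Effect
sizes are Cohen's d = mean(diff) / sd(diff) for the t-test and
r = |Z| / sqrt(n) for Wilcoxon, where Z comes from the normal
approximation and n counts the pairs remaining after zero differences
are dropped (signed-rank convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import PRETERM_GROUPS

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("strength", "clustering", "path_length", "global_efficiency")


@dataclass(frozen=True)
class PairedResult:
    """One paired test between first and second scans."""

    group: str
    metric: str
    n_pairs: int
    test: str            # "paired_t", "wilcoxon" or "degenerate"
    statistic: float     # t, or the signed-rank sum of positive differences V
    p_value: float
    effect_size: float   # Cohen's d (t) or r = |Z|/sqrt(n) (Wilcoxon)
    normality_p: float
    mean_difference: float


def _wilcoxon(diff: np.ndarray) -> tuple[float, float, float, int]:
    """Signed-rank V (positive-rank sum), p, |Z|-based r; zeros dropped."""
    nz = diff[diff != 0]
    n = len(nz)
    if n == 0:
        return 0.0, 1.0, 0.0, 0
    ranks = stats.rankdata(np.abs(nz))
    v = float(ranks[nz > 0].sum())
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         method="approx", correction=False)
    z = float(res.zstatistic)
    r = min(abs(z) / np.sqrt(n), 1.0)
    return v, float(res.pvalue), r, n


def paired_comparison(
    first,
    second,
    group: str = "",
    metric: str = "",
    force_test: str | None = None,
    normality_alpha: float = 0.05,
) -> PairedResult:
    """Compare paired scans; the normality of the differences picks the test.

    Differences are second minus first.  ``force_test`` ("paired_t" or
    "wilcoxon") bypasses the Shapiro-Wilk gate.  With fewer than 5 pairs
    a warning notes that the normality test is unreliable.  Zero spread
    with a nonzero mean yields an infinite Cohen's d (flagged by the
    value itself); identical scans yield t = 0, p = 1.
    """
    first = np.asarray(first, float)
    second = np.asarray(second, float)
    if first.shape != second.shape:
        raise ValueError("first and second scans must be paired (equal length)")
    n = len(first)
    if n < 2:
        raise ValueError("need at least two pairs")
    if n < 5:
        warnings.warn(f"only {n} pairs; the normality test is unreliable", stacklevel=2)
    diff = second - first

    if np.all(diff == 0):
        return PairedResult(group, metric, n, "degenerate", 0.0, 1.0, 0.0,
                            float("nan"), 0.0)

    if np.ptp(diff) == 0 or n < 3:
        # constant differences or too few for Shapiro: treat as non-normal
        normality_p = 0.0
    else:
        normality_p = float(stats.shapiro(diff).pvalue)

    test = force_test or ("paired_t" if normality_p > normality_alpha else "wilcoxon")
    if test == "paired_t":
        sd = diff.std(ddof=1)
        if sd == 0:
            t_stat = np.inf * np.sign(diff.mean())
            p = 0.0
            d = float(np.inf * np.sign(diff.mean()))
        else:
            res = stats.ttest_rel(second, first)
            t_stat, p = float(res.statistic), float(res.pvalue)
            d = float(diff.mean() / sd)
        return PairedResult(group, metric, n, "paired_t", t_stat, p, d,
                            normality_p, float(diff.mean()))
    if test == "wilcoxon":
        v, p, r, _ = _wilcoxon(diff)
        return PairedResult(group, metric, n, "wilcoxon", v, p, r,
                            normality_p, float(diff.mean()))
    raise ValueError(f"force_test must be 'paired_t' or 'wilcoxon', got {force_test!r}")


def groupwise_longitudinal(
    paired_metrics,
    metrics=GLOBAL_METRICS,
    groups=PRETERM_GROUPS,
    force_test: str | None = None,
) -> list[PairedResult]:
    """One paired test per (preterm group, metric).

    ``paired_metrics`` is a table with one row per subject carrying a
    ``group`` column and ``<metric>_first`` / ``<metric>_second`` value
    pairs (the longitudinal pair layout with metrics joined on).  Groups
    with fewer than two pairs are skipped with a log entry.
    """
    results: list[PairedResult] = []
    for group in groups:
        sub = paired_metrics[paired_metrics["group"].astype(str) == group]
        if len(sub) < 2:
            logger.info("group %s has %d pair(s); skipped", group, len(sub))
            continue
        for metric in metrics:
            results.append(
                paired_comparison(
                    sub[f"{metric}_first"], sub[f"{metric}_second"],
                    group=group, metric=metric, force_test=force_test,
                )
            )
    return results


def longitudinal_table(results: list[PairedResult]):
    """Tidy table of paired results (one row per group x metric)."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
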