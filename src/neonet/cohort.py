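"""Subject metadata, quality control and sample selection.

A cohort is a table with one row per scan session.  Each row carries the
subject and session identifiers, gestational age at birth (GA, weeks),
postmenstrual age at scan (PMA, weeks), sex, a mean DVARS head-motion
score and an integer radiology score (1-5, where 1-2 means no significant
incidental findings).

Birth-age groups follow the WHO preterm strata and the ACOG at-term
strata, realised here as half-open intervals on continuous weeks so that
the seven labels partition the whole plausible GA range:

=================== ==============
extremely_preterm   [20, 28)
very_preterm        [28, 32)
late_preterm        [32, 37)
early_term          [37, 39)
full_term           [39, 41)
late_term           [41, 42)
postterm            [42, 45]
=================== ==============
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GA_MIN = 20.0
GA_MAX = 45.0

#: the seven birth-age groups, ordered from earliest to latest birth
GROUP_ORDER = (
    "extremely_preterm",
    "very_preterm",
    "late_preterm",
    "early_term",
    "full_term",
    "late_term",
    "postterm",
)

PRETERM_GROUPS = GROUP_ORDER[:3]
TERM_GROUPS = GROUP_ORDER[3:]

#: left edges of the half-open group intervals (the last group is closed at GA_MAX)
_GROUP_EDGES = np.array([20.0, 28.0, 32.0, 37.0, 39.0, 41.0, 42.0])

#: columns required in a metadata table
METADATA_COLUMNS = (
    "subject_id",
    "session_id",
    "ga_birth",
    "pma_scan",
    "sex",
    "mean_dvars",
    "radiology_score",
)

SEX_LEVELS = ("male", "female")

#: default term-equivalent scan window in weeks PMA (closed at both ends)
TERM_EQUIVALENT_WINDOW = (37.0, 44.0)


@dataclass(frozen=True)
class SubjectRecord:
    """One scan session's metadata.

    ``group`` is derived from ``ga_birth`` and never supplied directly.
    """

    subject_id: str
    session_id: str
    ga_birth: float
    pma_scan: float
    sex: str
    mean_dvars: float
    radiology_score: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.ga_birth) or not (GA_MIN <= self.ga_birth <= GA_MAX):
            raise ValueError(
                f"ga_birth={self.ga_birth} outside the plausible range "
                f"[{GA_MIN}, {GA_MAX}] weeks"
            )
        if not np.isfinite(self.pma_scan) or self.pma_scan < self.ga_birth:
            raise ValueError(
                f"pma_scan={self.pma_scan} must be finite and >= ga_birth={self.ga_birth}"
            )
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if not np.isfinite(self.mean_dvars) or self.mean_dvars < 0:
            raise ValueError(f"mean_dvars={self.mean_dvars} must be a nonnegative real")
        if int(self.radiology_score) != self.radiology_score or not (
            1 <= self.radiology_score <= 5
        ):
            raise ValueError(
                f"radiology_score={self.radiology_score} must be an integer in 1..5"
            )

    @property
    def group(self) -> str:
        return assign_birth_group(self.ga_birth)


def assign_birth_group(ga_birth: float) -> str:
    """Map a gestational age at birth (weeks) to its WHO/ACOG group label."""
    ga = float(ga_birth)
    if not np.isfinite(ga) or not (GA_MIN <= ga <= GA_MAX):
        raise ValueError(
            f"gestational age at birth {ga_birth!r} is outside [{GA_MIN}, {GA_MAX}] weeks"
        )
    idx = int(np.searchsorted(_GROUP_EDGES, ga, side="right")) - 1
    return GROUP_ORDER[idx]


def assign_birth_groups(ga_birth: pd.Series | np.ndarray) -> pd.Series:
    """Vectorised :func:`assign_birth_group`; returns an ordered categorical."""
    ga = np.asarray(ga_birth, dtype=float)
    if not np.all(np.isfinite(ga)) or ga.min() < GA_MIN or ga.max() > GA_MAX:
        bad = ga[~(np.isfinite(ga) & (ga >= GA_MIN) & (ga <= GA_MAX))]
        raise ValueError(f"gestational ages outside [{GA_MIN}, {GA_MAX}]: {bad[:5]}")
    idx = np.searchsorted(_GROUP_EDGES, ga, side="right") - 1
    labels = pd.Categorical.from_codes(idx, categories=list(GROUP_ORDER), ordered=True)
    out = pd.Series(labels)
    if isinstance(ga_birth, pd.Series):
        out.index = ga_birth.index
    return out


def add_group_column(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``records`` with a derived ``group`` column."""
    out = records.copy()
    out["group"] = assign_birth_groups(out["ga_birth"])
    return out


def filter_quality(
    records: pd.DataFrame,
    dvars_sd_limit: float = 2.0,
    max_radiology_score: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the radiology-score and DVARS head-motion exclusions.

    A scan is excluded when its radiology score exceeds
    ``max_radiology_score``, or when its mean DVARS exceeds the cohort
    mean by more than ``dvars_sd_limit`` standard deviations.  The DVARS
    mean and SD are computed in a single pass over all score-eligible
    scans (not iteratively re-estimated after exclusions).

    Returns ``(kept, excluded)``; ``excluded`` gains an ``exclusion_reason``
    column.  The two frames partition the input.
    """
    if len(records) == 0:
        warnings.warn("filter_quality called with zero records", stacklevel=2)
        empty = records.copy()
        excluded = records.copy()
        excluded["exclusion_reason"] = pd.Series(dtype=str)
        return empty, excluded

    score_ok = records["radiology_score"] <= max_radiology_score
    eligible_dvars = records.loc[score_ok, "mean_dvars"].astype(float)

    if len(eligible_dvars) >= 2:
        mean = eligible_dvars.mean()
        sd = eligible_dvars.std(ddof=1)
    else:
        mean, sd = (eligible_dvars.mean() if len(eligible_dvars) else np.nan), 0.0
    threshold = mean + dvars_sd_limit * sd
    # sd == 0 (all DVARS identical) disables motion exclusion by construction
    dvars_ok = records["mean_dvars"] <= threshold if np.isfinite(threshold) else True

    keep = score_ok & dvars_ok
    kept = records.loc[keep].copy()
    excluded = records.loc[~keep].copy()
    reasons = []
    for _, row in excluded.iterrows():
        why = []
        if row["radiology_score"] > max_radiology_score:
            why.append(f"radiology_score={row['radiology_score']}")
        if np.isfinite(threshold) and row["mean_dvars"] > threshold:
            why.append(f"mean_dvars={row['mean_dvars']:.3g}>{threshold:.3g}")
        reasons.append(";".join(why))
    excluded["exclusion_reason"] = reasons
    logger.info(
        "quality filter: kept %d, excluded %d (DVARS threshold %.4g)",
        len(kept), len(excluded), threshold,
    )
    return kept, excluded


def select_term_equivalent(
    records: pd.DataFrame,
    window: tuple[float, float] = TERM_EQUIVALENT_WINDOW,
    keep: str = "latest",
) -> pd.DataFrame:
    """Cross-sectional sample: one scan per subject inside the PMA window.

    The window is closed at both ends.  Subjects with more than one scan
    in the window contribute their latest one by default (``keep="earliest"``
    selects the first instead).
    """
    if keep not in ("latest", "earliest"):
        raise ValueError("keep must be 'latest' or 'earliest'")
    lo, hi = window
    in_window = records[(records["pma_scan"] >= lo) & (records["pma_scan"] <= hi)]
    in_window = in_window.sort_values(["subject_id", "pma_scan"], kind="mergesort")
    picked = in_window.groupby("subject_id", sort=False, observed=True).nth(
        -1 if keep == "latest" else 0
    )
    return picked.sort_index()


def select_longitudinal_pairs(
    records: pd.DataFrame,
    window: tuple[float, float] = TERM_EQUIVALENT_WINDOW,
) -> pd.DataFrame:
    """Pair each subject's earliest preterm-age scan with a term-equivalent scan.

    The first scan is the subject's earliest with ``pma_scan`` below the
    window; the second is the earliest falling inside the (closed) window.
    Subjects lacking either scan are dropped.  Returns one row per subject
    with ``_first`` / ``_second`` suffixed columns.
    """
    lo, hi = window
    rows = []
    for subject, scans in records.groupby("subject_id", sort=True, observed=True):
        if len(scans) < 2:
            continue
        scans = scans.sort_values("pma_scan", kind="mergesort")
        early = scans[scans["pma_scan"] < lo]
        late = scans[(scans["pma_scan"] >= lo) & (scans["pma_scan"] <= hi)]
        if early.empty or late.empty:
            continue
        first = early.iloc[0]
        second = late.iloc[0]
        row = {"subject_id": subject}
        for col in records.columns:
            if col == "subject_id":
                continue
            row[f"{col}_first"] = first[col]
            row[f"{col}_second"] = second[col]
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty and "ga_birth_first" in out:
        out["group"] = assign_birth_groups(out["ga_birth_first"])
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read a cohort metadata table (CSV or TSV by extension; TSV default).

    Missing values in any required column are rejected, as are unknown
    sex codes and out-of-range ages/scores.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "session_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata table {path} lacks columns: {missing_cols}")
    if df[list(METADATA_COLUMNS)].isna().any().any():
        bad = df[list(METADATA_COLUMNS)].isna().any()
        raise ValueError(f"missing values in metadata columns: {list(bad[bad].index)}")
    if not df["sex"].isin(SEX_LEVELS).all():
        raise ValueError(f"sex must be coded {SEX_LEVELS}")
    # row-level validation through the record dataclass
    for rec in df[list(METADATA_COLUMNS)].itertuples(index=False):
        SubjectRecord(*rec)
    return add_group_column(df)


def write_metadata(records: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    cols = [c for c in list(METADATA_COLUMNS) + ["group"] if c in records.columns]
    records[cols].to_csv(path, sep=sep, index=False, float_format="%.10g")
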