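"""Functional connectome construction and proportional thresholding.

Each scan's network is the Pearson correlation between the BOLD time
series of every pair of atlas regions (90 regions of the neonate AAL
atlas by default).  To keep the number of connections constant across
scans, matrices are thresholded at a connection *cost* (density) kappa:
the strongest proportion kappa of the R(R-1)/2 possible edges is
retained with its weight, the rest are zeroed.  A cost sweep over
kappa = 0.05 ... 0.50 in steps of 0.05 guards against single-threshold
bias.

"Strongest" means the largest signed correlation by default, and
negative weights are never retained (downstream path lengths require
positive weights); ranking by absolute value is available via
``rank_by="absolute"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default cost grid: 5% to 50% of connections in 5% steps
DEFAULT_COST_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))

_AAL_BASE = (
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup",
    "Temporal_Pole_Sup", "Temporal_Mid", "Temporal_Pole_Mid",
    "Temporal_Inf",
)

#: the 90 cortical/subcortical region names of the (neonate) AAL atlas,
#: interleaved left/right as in the standard ordering
AAL90_LABELS = tuple(f"{name}_{side}" for name in _AAL_BASE for side in ("L", "R"))

N_REGIONS_DEFAULT = 90


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounded up."""
    return int(np.floor(x + 0.5))


@dataclass
class ConnectivityMatrix:
    """Region-by-region Pearson correlation weights with a zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...]
    session_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.labels) != w.shape[0]:
            raise ValueError("labels length must match matrix size")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.nanmax(np.abs(w)) > 1 + 1e-8:
            raise ValueError("correlation weights must lie in [-1, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdedGraph:
    """Weighted adjacency retained at connection cost ``cost``."""

    weights: np.ndarray
    cost: float
    labels: tuple[str, ...] = field(default_factory=tuple)
    session_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("thresholded graph weights must be nonnegative")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def retained_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))


def correlation_matrix(
    timeseries: pd.DataFrame | np.ndarray,
    session_id: str = "",
    labels: tuple[str, ...] | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation between every pair of region time series.

    ``timeseries`` is T x R (rows are timepoints).  Constant columns are
    rejected by name — a flat signal has no defined correlation.
    """
    if isinstance(timeseries, pd.DataFrame):
        values = timeseries.to_numpy(dtype=float)
        if labels is None:
            labels = tuple(str(c) for c in timeseries.columns)
    else:
        values = np.asarray(timeseries, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValueError("time series must be T x R with T >= 3")
    if labels is None:
        labels = tuple(f"ROI_{i + 1:02d}" for i in range(values.shape[1]))
    if np.isnan(values).any():
        raise ValueError("time series contains missing values")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        flat = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for region(s): {flat}")
    corr = np.corrcoef(values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix(corr, tuple(labels), session_id=session_id)


def _edge_ranking(weights: np.ndarray, rank_by: str) -> tuple[np.ndarray, ...]:
    """Upper-triangle edge indices sorted strongest-first.

    Ties are broken by lexicographic (i, j) index order so the retained
    edge set is deterministic.
    """
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    vals = weights[iu, ju]
    key = np.abs(vals) if rank_by == "absolute" else vals
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order], vals[order]


def proportional_threshold(
    matrix: ConnectivityMatrix,
    cost: float,
    rank_by: str = "signed",
) -> ThresholdedGraph:
    """Keep the strongest proportion ``cost`` of possible connections.

    The target edge count is m = round_half_up(cost * R(R-1)/2).  If fewer
    than m correlations are positive, only the positive ones are kept and
    a warning is emitted; negative weights are never retained.
    """
    if not (0 < cost <= 1):
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    if rank_by not in ("signed", "absolute"):
        raise ValueError("rank_by must be 'signed' or 'absolute'")
    R = matrix.n_regions
    n_pairs = R * (R - 1) // 2
    m = round_half_up(cost * n_pairs)
    iu, ju, vals = _edge_ranking(matrix.weights, rank_by)
    take_i, take_j, take_v = iu[:m], ju[:m], vals[:m]
    positive = take_v > 0
    if positive.sum() < m:
        warnings.warn(
            f"only {int(positive.sum())} of the requested {m} edges are positive "
            f"at cost {cost}; negative weights are not retained",
            stacklevel=2,
        )
        take_i, take_j, take_v = take_i[positive], take_j[positive], take_v[positive]
    out = np.zeros_like(matrix.weights)
    out[take_i, take_j] = take_v
    out[take_j, take_i] = take_v
    return ThresholdedGraph(out, float(cost), matrix.labels, matrix.session_id)


def cost_sweep(
    matrix: ConnectivityMatrix,
    costs: tuple[float, ...] = DEFAULT_COST_GRID,
    rank_by: str = "signed",
) -> list[ThresholdedGraph]:
    """Threshold one matrix at every cost of the grid (strictly increasing)."""
    costs = tuple(float(c) for c in costs)
    if any(b <= a for a, b in zip(costs, costs[1:])):
        raise ValueError("costs must be strictly increasing")
    return [proportional_threshold(matrix, c, rank_by=rank_by) for c in costs]


def write_matrix(matrix: ConnectivityMatrix | ThresholdedGraph, path) -> None:
    """Write a matrix as TSV with a header of region labels.

    The cost (for thresholded graphs) is recorded in a leading comment line.
    """
    with open(path, "w") as fh:
        cost = getattr(matrix, "cost", None)
        if cost is not None:
            fh.write(f"# cost={cost}\n")
        fh.write(f"# session_id={matrix.session_id}\n")
        pd.DataFrame(matrix.weights, columns=list(matrix.labels)).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_matrix(path) -> ConnectivityMatrix | ThresholdedGraph:
    """Read a matrix written by :func:`write_matrix`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    labels = tuple(df.columns)
    session = meta.get("session_id", "")
    if "cost" in meta:
        return ThresholdedGraph(df.to_numpy(float), float(meta["cost"]), labels, session)
    return ConnectivityMatrix(df.to_numpy(float), labels, session_id=session)
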