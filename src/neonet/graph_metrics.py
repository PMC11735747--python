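"""Weighted graph-theory metrics on thresholded connectomes.

Four global properties summarise each network:

* node strength  S_i = sum_j w_ij (the network value is the node mean);
* clustering coefficient  CC = mean_i 2 t_i / (D_i (D_i - 1)),
  with t_i the triangle count through node i on the binarised adjacency
  (segregation);
* characteristic path length  d = mean shortest-path length over
  connected ordered pairs, after mapping each weight to a length
  f(w) = 1/w (integration; lower is more integrated);
* global efficiency  Eglobal = mean of 1/d_ij over ordered pairs, with
  unreachable pairs contributing zero (integration; higher is better).

Nodal (per-region) metrics are strength, clustering and local
efficiency — the global efficiency of the subgraph induced by a node's
neighbours, weights preserved.

The clustering default is the binary triangle-density form; a weighted
variant using the geometric mean of the normalised triangle weights
(Onnela) is available with ``mode="weighted"``.  The weight-to-length
mapping defaults to the inverse; ``-ln(w)`` can be selected for weights
in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import ThresholdedGraph

GLOBAL_METRICS = ("strength", "clustering", "path_length", "global_efficiency")
NODAL_METRICS = ("strength", "clustering", "local_efficiency")


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network summary of one thresholded graph."""

    strength: float            # mean node strength
    clustering: float          # mean clustering coefficient
    path_length: float         # characteristic path length (nan if fully disconnected)
    global_efficiency: float
    connected_fraction: float  # share of ordered node pairs with a finite path


def _weights(graph: ThresholdedGraph | np.ndarray) -> np.ndarray:
    w = graph.weights if isinstance(graph, ThresholdedGraph) else np.asarray(graph, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("graph weights must be square")
    return w


def node_strength(graph: ThresholdedGraph | np.ndarray) -> np.ndarray:
    """Per-node sum of edge weights (weighted degree)."""
    return _weights(graph).sum(axis=1)


def clustering_coefficients(
    graph: ThresholdedGraph | np.ndarray, mode: str = "binary"
) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean over all nodes.

    Binary mode: C_i = 2 t_i / (D_i (D_i - 1)) on the binarised
    adjacency; nodes with fewer than two neighbours get 0.  Weighted
    mode: the Onnela geometric-mean-of-weights triangle form on weights
    normalised by the maximum weight.
    """
    w = _weights(graph)
    a = (w > 0).astype(float)
    deg = a.sum(axis=1)
    denom = deg * (deg - 1)
    if mode == "binary":
        tri = np.diag(a @ a @ a) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    elif mode == "weighted":
        wmax = w.max()
        wn = np.cbrt(w / wmax) if wmax > 0 else w
        tri_w = np.diag(wn @ wn @ wn) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(denom > 0, 2.0 * tri_w / denom, 0.0)
    else:
        raise ValueError("mode must be 'binary' or 'weighted'")
    return c, float(c.mean()) if len(c) else float("nan")


def shortest_path_matrix(
    graph: ThresholdedGraph | np.ndarray, mapping: str = "inverse"
) -> np.ndarray:
    """All-pairs shortest-path lengths after mapping weights to lengths.

    ``mapping="inverse"`` uses l = 1/w (the standard choice for
    correlation weights); ``mapping="neglog"`` uses l = -ln(w), valid
    only for weights in (0, 1].  Unreachable pairs are +inf; the
    diagonal is 0.
    """
    w = _weights(graph)
    if np.any(w < 0):
        raise ValueError("negative weight encountered; thresholded graphs must be nonnegative")
    mask = w > 0
    lengths = np.zeros_like(w)
    if mapping == "inverse":
        lengths[mask] = 1.0 / w[mask]
    elif mapping == "neglog":
        if np.any(w[mask] > 1):
            raise ValueError("-ln(w) mapping requires weights <= 1")
        lengths[mask] = -np.log(w[mask])
    else:
        raise ValueError("mapping must be 'inverse' or 'neglog'")
    sparse = csr_matrix(np.where(mask, lengths, 0.0))
    dist = dijkstra(sparse, directed=False)
    return dist


def characteristic_path_length(dist: np.ndarray) -> tuple[float, float]:
    """Mean shortest-path length over connected ordered pairs.

    Returns ``(d, connected_fraction)`` where the fraction counts finite
    ordered pairs i != j among all n(n-1).  A fully disconnected graph
    has no finite pair and raises.
    """
    n = dist.shape[0]
    if n < 2:
        raise ValueError("path length needs at least two nodes")
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("graph is fully disconnected; characteristic path length undefined")
    d = float(dist[finite].mean())
    return d, n_finite / (n * (n - 1))


def global_efficiency(dist: np.ndarray) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, np.inf), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(
    graph: ThresholdedGraph | np.ndarray, mapping: str = "inverse"
) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph.

    Edge weights are preserved on the subgraph.  Nodes with fewer than
    two neighbours get 0.
    """
    w = _weights(graph)
    n = w.shape[0]
    out = np.zeros(n)
    adj = w > 0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(shortest_path_matrix(sub, mapping=mapping))
    return out


def compute_global_metrics(
    graph: ThresholdedGraph | np.ndarray,
    clustering_mode: str = "binary",
    mapping: str = "inverse",
) -> GlobalMetrics:
    """All four global properties of one graph in a single pass."""
    s = node_strength(graph)
    _, cc = clustering_coefficients(graph, mode=clustering_mode)
    dist = shortest_path_matrix(graph, mapping=mapping)
    try:
        d, frac = characteristic_path_length(dist)
    except ValueError:
        d, frac = float("nan"), 0.0
    eg = global_efficiency(dist)
    return GlobalMetrics(float(s.mean()), cc, d, eg, frac)


def compute_nodal_metrics(
    graph: ThresholdedGraph,
    clustering_mode: str = "binary",
    mapping: str = "inverse",
) -> pd.DataFrame:
    """Long-format per-region metrics for one graph."""
    s = node_strength(graph)
    c, _ = clustering_coefficients(graph, mode=clustering_mode)
    el = local_efficiency(graph, mapping=mapping)
    labels = list(graph.labels) if graph.labels else [f"ROI_{i+1:02d}" for i in range(len(s))]
    return pd.DataFrame(
        {
            "session_id": graph.session_id,
            "cost": graph.cost,
            "region": labels,
            "strength": s,
            "clustering": c,
            "local_efficiency": el,
        }
    )


def global_metric_table(
    graphs: list[ThresholdedGraph],
    metadata: pd.DataFrame | None = None,
    clustering_mode: str = "binary",
    mapping: str = "inverse",
) -> pd.DataFrame:
    """One row per (session, cost) with the four global metrics.

    If ``metadata`` is given (one row per session_id), its columns are
    joined onto the result.
    """
    rows = []
    for g in graphs:
        gm = compute_global_metrics(g, clustering_mode=clustering_mode, mapping=mapping)
        rows.append(
            {
                "session_id": g.session_id,
                "cost": g.cost,
                "strength": gm.strength,
                "clustering": gm.clustering,
                "path_length": gm.path_length,
                "global_efficiency": gm.global_efficiency,
                "connected_fraction": gm.connected_fraction,
            }
        )
    table = pd.DataFrame(rows)
    if metadata is not None:
        table = table.merge(metadata, on="session_id", how="left", validate="many_to_one")
    return table


def nodal_metric_table(
    graphs: list[ThresholdedGraph],
    metadata: pd.DataFrame | None = None,
    clustering_mode: str = "binary",
    mapping: str = "inverse",
) -> pd.DataFrame:
    """Long-format nodal metrics for many graphs, optionally with metadata."""
    table = pd.concat(
        [compute_nodal_metrics(g, clustering_mode, mapping) for g in graphs],
        ignore_index=True,
    )
    if metadata is not None:
        table = table.merge(metadata, on="session_id", how="left", validate="many_to_one")
    return table
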