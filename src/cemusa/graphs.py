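"""Step 2: spatial adjacency, per-labeling edge codes, and severity weights.

Both the ground truth Y0 and the matched clustering Ỹ1 are laid over one
shared spatial adjacency.  Each adjacent pair gets a code: k when both
endpoints carry domain label k, 0 when their labels disagree.  Each pair
also gets a non-negative severity weight W — either expression-based
(similar profiles split across clusters, or dissimilar profiles merged,
are the severe errors) or looked up from an explicit misclassification
cost table (e.g. false negatives costlier than false positives in tumor
calling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class AdjacencyStructure:
    """Unordered spot-index pairs (u < v), with the construction recorded."""

    pairs: np.ndarray  # (m, 2) int, u < v, unique, no self-pairs
    method: str
    param: float
    n: int


def _unique_pairs(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    lo = np.minimum(u, v)
    hi = np.maximum(u, v)
    keep = lo != hi
    pairs = np.unique(np.stack([lo[keep], hi[keep]], axis=1), axis=0)
    return pairs.astype(np.int64)


def _knn_pairs(coords: np.ndarray, k: int) -> np.ndarray:
    """Symmetrized kNN: the pair u-v is kept if either is among the other's
    k nearest, with distance ties broken toward the smaller index."""
    n = coords.shape[0]
    tree = cKDTree(coords)
    kk = min(n, k + 9)
    while True:
        dist, idx = tree.query(coords, k=kk)
        # kth kept distance must be strictly below the last queried distance,
        # otherwise unseen equidistant candidates could win the index tie-break
        if kk == n:
            break
        kth = dist[:, min(k, kk - 1)]
        if np.all(dist[:, -1] > kth + 1e-12):
            break
        kk = min(n, kk * 2)
    rows = []
    cols = []
    for i in range(n):
        d, j = dist[i], idx[i]
        mask = j != i
        d, j = d[mask], j[mask]
        order = np.lexsort((j, np.round(d, 12)))
        chosen = j[order[:k]]
        rows.append(np.full(len(chosen), i))
        cols.append(chosen)
    return _unique_pairs(np.concatenate(rows), np.concatenate(cols))


def build_adjacency(
    coords: np.ndarray, method: str = "knn", param: float = 6
) -> AdjacencyStructure:
    """Build the shared spatial adjacency.

    method is one of:

    * ``knn`` — symmetrized k-nearest-neighbor graph (param = k, default 6,
      matching hexagonal Visium packing);
    * ``radius`` — all pairs within distance param;
    * ``delaunay`` — Delaunay-triangulation edges (param ignored).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValidationError("need an n x 2 coordinate array with n >= 2")
    n = coords.shape[0]

    if method == "knn":
        k = int(param)
        if not 1 <= k < n:
            raise ValidationError(f"knn requires 1 <= k < n, got k={k}, n={n}")
        pairs = _knn_pairs(coords, k)
    elif method == "radius":
        tree = cKDTree(coords)
        raw = tree.query_pairs(float(param), output_type="ndarray")
        pairs = _unique_pairs(raw[:, 0], raw[:, 1]) if raw.size else np.empty((0, 2), int)
        isolated = np.setdiff1d(np.arange(n), np.unique(pairs))
        if isolated.size:
            warnings.warn(
                f"radius {param} leaves {isolated.size} isolated spot(s); kept",
                stacklevel=2,
            )
    elif method == "delaunay":
        try:
            tri = Delaunay(coords)
        except QhullError as exc:
            raise ValidationError(f"degenerate geometry for Delaunay: {exc}") from exc
        simplices = tri.simplices
        u = np.concatenate([simplices[:, i] for i in (0, 0, 1)])
        v = np.concatenate([simplices[:, i] for i in (1, 2, 2)])
        pairs = _unique_pairs(u, v)
    else:
        raise ConfigurationError(f"unknown adjacency method {method!r}")

    return AdjacencyStructure(pairs=pairs, method=method, param=float(param), n=n)


@dataclass(frozen=True)
class LabeledGraph:
    """Adjacency plus per-edge label codes and severity weights for one labeling."""

    adjacency: AdjacencyStructure
    edge_codes: np.ndarray  # (m,) int in {0, 1..K}
    weights: np.ndarray  # (m,) non-negative float


def labeled_graph(
    adj: AdjacencyStructure, labels: np.ndarray, weights: np.ndarray | None = None
) -> LabeledGraph:
    """Bundle one labeling's edge codes and severity weights over ``adj``."""
    codes = label_edges(adj, labels)
    if weights is None:
        weights = np.ones(len(adj.pairs))
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(adj.pairs):
        raise ValidationError("one weight per adjacent pair required")
    if np.any(weights < 0):
        raise ValidationError("edge weights must be non-negative")
    return LabeledGraph(adjacency=adj, edge_codes=codes, weights=weights)


def label_edges(adj: AdjacencyStructure, labels: np.ndarray) -> np.ndarray:
    """Edge code per adjacent pair: shared label k, or 0 on disagreement."""
    labels = np.asarray(labels)
    if labels.shape[0] != adj.n:
        raise ValidationError("labels must cover all nodes")
    if np.any(labels < 1):
        raise ValidationError("label code 0 is reserved for mismatched edges")
    lu = labels[adj.pairs[:, 0]]
    lv = labels[adj.pairs[:, 1]]
    return np.where(lu == lv, lu, 0).astype(np.int64)


def scaled_cosine(x_u: np.ndarray, x_v: np.ndarray) -> float:
    """Cosine similarity rescaled from [-1, 1] onto [0, 1]."""
    x_u = np.asarray(x_u, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    nu, nv = np.linalg.norm(x_u), np.linalg.norm(x_v)
    if nu == 0 or nv == 0:
        raise ValidationError("scaled cosine is undefined for a zero vector")
    return float((x_u @ x_v / (nu * nv) + 1.0) / 2.0)


def expression_weights(
    adj: AdjacencyStructure,
    edge_codes: np.ndarray,
    X: np.ndarray,
    sim: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> np.ndarray:
    """Expression-similarity severity weights.

    Same-label pairs get Sim(x_u, x_v); adjacent mismatched pairs get
    1 - Sim(x_u, x_v).  ``sim`` defaults to scaled cosine; any callable on
    two profiles returning a value in [0, 1] may be substituted.
    """
    if X is None:
        raise ConfigurationError(
            "expression weights need an expression matrix; use cost_weights "
            "or uniform weights otherwise"
        )
    X = np.asarray(X, dtype=float)
    u, v = adj.pairs[:, 0], adj.pairs[:, 1]
    if sim is None:
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValidationError("scaled cosine is undefined for a zero profile")
        cos = np.einsum("ij,ij->i", X[u], X[v]) / (norms[u] * norms[v])
        sims = (np.clip(cos, -1.0, 1.0) + 1.0) / 2.0
    else:
        sims = np.array([sim(X[a], X[b]) for a, b in adj.pairs])
    return np.where(edge_codes != 0, sims, 1.0 - sims)


def cost_weights(
    adj: AdjacencyStructure,
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    cost_table: Mapping[tuple[int, int], float],
) -> np.ndarray:
    """Cost-table severity weights.

    Each spot's cost is looked up from its (true class, predicted class)
    confusion status; a pair's weight is the mean of its endpoint costs.
    Concordant classes default to cost 1 when absent from the table; a
    missing discordant entry is a configuration error.
    """
    true = np.asarray(true_labels)
    pred = np.asarray(pred_labels)
    costs = np.empty(adj.n, dtype=float)
    for i in range(adj.n):
        key = (int(true[i]), int(pred[i]))
        if key in cost_table:
            costs[i] = float(cost_table[key])
        elif key[0] == key[1]:
            costs[i] = 1.0
        else:
            raise ConfigurationError(
                f"cost table has no entry for (true={key[0]}, predicted={key[1]})"
            )
        if costs[i] <= 0:
            raise ValidationError(f"cost for {key} must be positive")
    return (costs[adj.pairs[:, 0]] + costs[adj.pairs[:, 1]]) / 2.0


def read_cost_table(path: str | Path) -> dict[tuple[int, int], float]:
    """Load a cost table CSV with columns true_class, predicted_class, cost."""
    df = pd.read_csv(path)
    needed = {"true_class", "predicted_class", "cost"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(
            f"cost table must have columns {sorted(needed)}, got {list(df.columns)}"
        )
    return {
        (int(r.true_class), int(r.predicted_class)): float(r.cost)
        for r in df.itertuples()
    }
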