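"""Step 1: align predicted cluster labels with the ground-truth label space.

Each predicted cluster u and true domain v are compared by the Jaccard
coefficient of their spot sets, J[u, v] = |C_u ∩ C_v| / |C_u ∪ C_v|, and the
Hungarian algorithm picks the assignment maximizing total similarity.  When
the cluster count K1 differs from the domain count K the matrix is padded
with zero rows/columns and the dummy assignments are resolved:

* K1 > K — a cluster matched to a dummy column takes the true label with the
  highest Jaccard in its row (many-to-one mapping).
* K1 < K — for each true label matched to a dummy row, the cluster with the
  highest Jaccard against that label is re-matched to it, but only if its
  spots are spatially closer (mean distance to the domain's spot centroid)
  to that domain than to the cluster's currently matched domain.

The result converts predictions Y1 over an arbitrary alphabet into labels
Ỹ1 in {1..K}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError


@dataclass
class MatchResult:
    """Outcome of cluster-to-domain matching.

    mapping is predicted-code -> true-code (many-to-one allowed when K1 != K);
    remapped_labels is the prediction expressed in the truth label space.
    """

    jaccard: np.ndarray
    mapping: dict[int, int]
    remapped_labels: np.ndarray
    rematched_clusters: list[int] = field(default_factory=list)


def jaccard_matrix(pred_labels: np.ndarray, true_labels: np.ndarray) -> np.ndarray:
    """K1 x K matrix of Jaccard coefficients between cluster and domain spot sets."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValidationError(
            f"label length mismatch: {pred.shape} vs {true.shape}"
        )
    k1, k = int(pred.max()), int(true.max())
    inter = np.zeros((k1, k), dtype=float)
    np.add.at(inter, (pred - 1, true - 1), 1.0)
    size_u = np.bincount(pred - 1, minlength=k1).astype(float)
    size_v = np.bincount(true - 1, minlength=k).astype(float)
    union = size_u[:, None] + size_v[None, :] - inter
    return inter / union


def hungarian_assign(J: np.ndarray) -> np.ndarray:
    """Column index per row maximizing the summed score over a square matrix.

    Among optima, returns the lexicographically smallest assignment (row 0
    gets the smallest feasible column, then row 1, ...).
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValidationError(f"hungarian_assign needs a square matrix, got {J.shape}")
    if not np.all(np.isfinite(J)):
        raise ValidationError("assignment matrix must be finite")
    m = J.shape[0]
    rows, cols = linear_sum_assignment(-J)
    best = J[rows, cols].sum()
    tol = 1e-12 * max(1.0, abs(best))

    # Greedy lexicographic refinement: fix each row to the smallest column
    # that still permits an optimal completion of the remaining subproblem.
    assignment = np.empty(m, dtype=int)
    free_cols = list(range(m))
    partial = 0.0
    for r in range(m):
        for c in free_cols:
            rest_rows = np.arange(r + 1, m)
            rest_cols = [cc for cc in free_cols if cc != c]
            sub = J[np.ix_(rest_rows, rest_cols)] if len(rest_cols) else np.zeros((0, 0))
            sub_best = 0.0
            if sub.size:
                ri, ci = linear_sum_assignment(-sub)
                sub_best = sub[ri, ci].sum()
            if partial + J[r, c] + sub_best >= best - tol:
                assignment[r] = c
                partial += J[r, c]
                free_cols.remove(c)
                break
    return assignment


def match_clusters(
    pred_labels: np.ndarray, true_labels: np.ndarray, coords: np.ndarray
) -> MatchResult:
    """Full matching step: Jaccard matrix, padded Hungarian, dummy resolution."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    coords = np.asarray(coords, dtype=float)
    J = jaccard_matrix(pred, true)
    k1, k = J.shape
    m = max(k1, k)
    padded = np.zeros((m, m))
    padded[:k1, :k] = J
    assign = hungarian_assign(padded)

    mapping: dict[int, int] = {}
    for u in range(k1):
        v = assign[u]
        if v < k:
            mapping[u + 1] = v + 1
        else:
            # K1 > K: cluster hit a dummy column; take its best true label.
            row = J[u]
            if row.max() <= 0.0:
                warnings.warn(
                    f"cluster {u + 1} shares no spots with any domain; "
                    "assigning true label 1 by tie-break",
                    stacklevel=2,
                )
            mapping[u + 1] = int(np.argmax(row)) + 1

    rematched: list[int] = []
    if k1 < k:
        assigned_cols = set(assign[:k1])
        dummy_truths = [v for v in range(k) if v not in assigned_cols]
        centroids = np.stack(
            [coords[true == v + 1].mean(axis=0) for v in range(k)]
        )
        for v in sorted(dummy_truths):
            col = J[:, v]
            if col.max() <= 0.0:
                warnings.warn(
                    f"no cluster overlaps true label {v + 1}; "
                    "tie-break to the smallest cluster index",
                    stacklevel=2,
                )
            u = int(np.argmax(col)) + 1
            spots = coords[pred == u]
            cur = mapping[u] - 1
            dist_new = np.linalg.norm(spots - centroids[v], axis=1).mean()
            dist_cur = np.linalg.norm(spots - centroids[cur], axis=1).mean()
            if dist_new < dist_cur:
                mapping[u] = v + 1
                rematched.append(u)

    remapped = relabel(pred, mapping)
    return MatchResult(
        jaccard=J, mapping=mapping, remapped_labels=remapped,
        rematched_clusters=rematched,
    )


def relabel(pred_labels: np.ndarray, mapping: dict[int, int] | MatchResult) -> np.ndarray:
    """Apply a cluster -> domain mapping, producing labels in {1..K}."""
    if isinstance(mapping, MatchResult):
        mapping = mapping.mapping
    pred = np.asarray(pred_labels)
    table = np.zeros(int(pred.max()) + 1, dtype=np.int64)
    for u, v in mapping.items():
        table[u] = v
    seen = np.unique(pred)
    missing = [int(u) for u in seen if u >= len(table) or table[u] == 0]
    if missing:
        raise ValidationError(f"predicted labels {missing} not covered by the mapping")
    return table[pred]
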