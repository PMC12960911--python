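"""Comparison metrics: five external panel metrics plus CHAOS and PAS.

External metrics (ARI, NMI, pair-counting Jaccard, FMI, V-measure) score
label agreement against ground truth and ignore geometry; CHAOS and PAS are
internal spatial-continuity indices that ignore ground truth.  Together they
provide the contrast panel against which the discrepancy score is compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.spatial import cKDTree
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    normalized_mutual_info_score,
    v_measure_score,
)
from sklearn.metrics.cluster import contingency_matrix

from .errors import ValidationError


@dataclass
class MetricPanel:
    """Named metric values with their quality directions."""

    values: dict[str, float]
    directions: dict[str, str]  # higher_better | lower_better

    def __post_init__(self) -> None:
        for name, val in self.values.items():
            if not np.isfinite(val):
                raise ValidationError(f"metric {name!r} is not finite")
            if name not in self.directions:
                raise ValidationError(f"metric {name!r} has no declared direction")


def pair_jaccard(true_labels: np.ndarray, pred_labels: np.ndarray) -> float:
    """Pair-counting Jaccard index: pairs co-clustered in both labelings over
    pairs co-clustered in at least one."""
    cont = contingency_matrix(true_labels, pred_labels)
    together_both = comb(cont, 2).sum()
    together_true = comb(cont.sum(axis=1), 2).sum()
    together_pred = comb(cont.sum(axis=0), 2).sum()
    denom = together_true + together_pred - together_both
    return float(together_both / denom) if denom else 1.0


def external_panel(true_labels: np.ndarray, pred_labels: np.ndarray) -> MetricPanel:
    """The five standard external clustering metrics (all higher-is-better)."""
    true = np.asarray(true_labels)
    pred = np.asarray(pred_labels)
    if true.shape != pred.shape:
        raise ValidationError("label length mismatch")
    values = {
        "ARI": float(adjusted_rand_score(true, pred)),
        "NMI": float(normalized_mutual_info_score(true, pred)),
        "Jaccard": pair_jaccard(true, pred),
        "FMI": float(fowlkes_mallows_score(true, pred)),
        "V-measure": float(v_measure_score(true, pred)),
    }
    return MetricPanel(values, {k: "higher_better" for k in values})


def chaos(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean distance to the nearest same-cluster neighbor on standardized
    coordinates (lower = better spatial continuity).  Singleton clusters are
    skipped with a warning."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    std = coords.std(axis=0)
    std[std == 0] = 1.0
    z = (coords - coords.mean(axis=0)) / std
    dists = []
    for lab in np.unique(labels):
        pts = z[labels == lab]
        if len(pts) < 2:
            warnings.warn(f"cluster {lab} is a singleton; skipped in CHAOS", stacklevel=2)
            continue
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        dists.append(d[:, 1])
    if not dists:
        raise ValidationError("CHAOS needs at least one cluster with >= 2 spots")
    return float(np.concatenate(dists).mean())


def pas(
    coords: np.ndarray, labels: np.ndarray, k: int = 10, threshold: int = 6
) -> float:
    """Fraction of spots whose k spatial nearest neighbors mostly disagree.

    A spot is abnormal when more than ``threshold`` of its k nearest
    neighbors carry a different label.  Neighbors tied at the k-th distance
    are counted fractionally (each tie contributes (k - closer)/ties), which
    keeps the index exactly invariant under isometries of the layout.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if k >= n:
        raise ValidationError(f"PAS requires k < n, got k={k}, n={n}")
    tree = cKDTree(coords)
    kk = min(n, 2 * k + 9)
    while True:
        dist, idx = tree.query(coords, k=kk)
        if kk == n or np.all(dist[:, -1] > dist[:, k] + 1e-12):
            break
        kk = min(n, kk * 2)
    abnormal = 0
    for i in range(n):
        d, j = dist[i][1:], idx[i][1:]  # drop self
        d = np.round(d, 12)
        dk = d[k - 1]
        closer = j[d < dk]
        ties = j[d == dk]
        diff = float(np.sum(labels[closer] != labels[i]))
        if len(ties):
            frac = (k - len(closer)) / len(ties)
            diff += frac * float(np.sum(labels[ties] != labels[i]))
        if diff > threshold:
            abnormal += 1
    return abnormal / n


def internal_panel(coords: np.ndarray, labels: np.ndarray) -> MetricPanel:
    """Topology-only internal metrics (both lower-is-better)."""
    values = {
        "CHAOS": chaos(coords, labels),
        "PAS": pas(coords, labels),
    }
    return MetricPanel(values, {k: "lower_better" for k in values})


def full_panel(
    coords: np.ndarray, true_labels: np.ndarray, pred_labels: np.ndarray
) -> MetricPanel:
    ext = external_panel(true_labels, pred_labels)
    internal = internal_panel(coords, pred_labels)
    return MetricPanel(
        {**ext.values, **internal.values}, {**ext.directions, **internal.directions}
    )


def normalize_panel(table: pd.DataFrame, directions: dict[str, str]) -> pd.DataFrame:
    """Min-max scale each metric column to [0, 1] so larger is always better.

    ``table`` is methods x metrics.  Lower-is-better metrics are inverted;
    a constant column maps to 0.5 everywhere with a warning.
    """
    if len(table) < 2:
        raise ValidationError("normalization needs at least 2 methods per metric")
    out = table.copy().astype(float)
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        if hi == lo:
            warnings.warn(f"metric {col!r} is constant across methods; set to 0.5",
                          stacklevel=2)
            out[col] = 0.5
            continue
        scaled = (out[col] - lo) / (hi - lo)
        if directions.get(col) == "lower_better":
            scaled = 1.0 - scaled
        out[col] = scaled
    return out
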