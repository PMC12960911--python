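"""Step 3: one-hot edge encodings, severity adjustment, and the edge-attribute KDE.

Every spatially adjacent pair contributes one row: a shared-label-k edge maps
to the unit vector e_k in R^K, a mismatched edge to the zero vector.  Rows
are scaled by their severity weights and the resulting point cloud is modeled
with an isotropic Gaussian kernel density estimate of bandwidth h, from which
sample batches are drawn for the discrepancy step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError


def one_hot_encode(edge_codes: np.ndarray, K: int) -> np.ndarray:
    """(m, K) binary matrix: code k > 0 -> e_k, code 0 -> zero row."""
    codes = np.asarray(edge_codes)
    if codes.size and codes.max() > K:
        raise ValidationError(f"edge code {codes.max()} exceeds K={K}")
    if codes.size and codes.min() < 0:
        raise ValidationError("edge codes must be non-negative")
    Z = np.zeros((len(codes), K), dtype=float)
    pos = codes > 0
    Z[np.nonzero(pos)[0], codes[pos] - 1] = 1.0
    return Z


def decode(Z: np.ndarray) -> np.ndarray:
    """Inverse of one_hot_encode on exact one-hot rows (0 for zero rows)."""
    Z = np.asarray(Z)
    codes = np.argmax(Z, axis=1) + 1
    codes[Z.max(axis=1) == 0] = 0
    return codes


def weight_adjust(Z: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scale each encoding row by its edge weight (Z̃ = Z ⊙ Ŵ)."""
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != Z.shape[0]:
        raise ValidationError("one weight per encoding row required")
    if np.any(w < 0):
        raise ValidationError("edge weights must be non-negative")
    return Z * w[:, None]


@dataclass(frozen=True)
class AttributeDensity:
    """Isotropic Gaussian KDE over weighted edge encodings in R^K."""

    support_points: np.ndarray  # (m, K)
    bandwidth: float

    @property
    def dimension(self) -> int:
        return self.support_points.shape[1]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Density at query points (proper K-dim normalization, integrates to 1)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m, K = self.support_points.shape
        h = self.bandwidth
        sq = cdist(pts, self.support_points, "sqeuclidean")
        norm = m * (h ** K) * (2.0 * np.pi) ** (K / 2.0)
        return np.exp(-sq / (2.0 * h * h)).sum(axis=1) / norm


def fit_kde(Z_weighted: np.ndarray, h: float) -> AttributeDensity:
    """Center one Gaussian of scale h at every weighted encoding row."""
    Z = np.atleast_2d(np.asarray(Z_weighted, dtype=float))
    if Z.shape[0] < 1:
        raise ValidationError("KDE needs at least one support point")
    if not h > 0:
        raise ValidationError(f"bandwidth must be positive, got {h}")
    return AttributeDensity(support_points=Z, bandwidth=float(h))


@dataclass(frozen=True)
class SampleBatch:
    """One i.i.d. draw of batch_size points from an AttributeDensity."""

    points: np.ndarray  # (b, K)
    source: str  # "truth" | "clustering"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.points.shape[0] < 2:
            raise ValidationError("a sample batch needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("sampled points must be finite")


def sample_batches(
    density: AttributeDensity,
    n_batches: int,
    batch_size: int,
    seed,
    source: str = "truth",
) -> list[SampleBatch]:
    """Draw n_batches empirical distributions from the KDE mixture.

    Each point is a uniformly chosen support row plus isotropic Gaussian
    jitter of scale h; fully reproducible given the seed (an int or a
    numpy SeedSequence).
    """
    if n_batches < 1 or batch_size < 1:
        raise ValidationError("n_batches and batch_size must be >= 1")
    m = density.support_points.shape[0]
    if m == 0:
        raise ValidationError("cannot sample from an empty support")
    rng = np.random.default_rng(seed)
    idx = rng.integers(m, size=(n_batches, batch_size))
    jitter = rng.standard_normal((n_batches, batch_size, density.dimension))
    pts = density.support_points[idx] + density.bandwidth * jitter
    seed_rec = seed if isinstance(seed, int) else None
    return [SampleBatch(points=pts[i], source=source, seed=seed_rec) for i in range(n_batches)]
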