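"""Synthetic evaluation scenarios on regular grids.

Each generator emulates one of the simulation designs the metric is meant to
discriminate: pure label agreement (two results differing only in mislabel
count), mislabel location (boundary vs core mislabels with an expression
gradient so peripheral spots genuinely resemble the adjacent domain), and
error severity (mirror-symmetric false positives vs false negatives whose
topology is identical).  A fourth generator produces the 360-spot series
with a growing number of mislabels for sensitivity analysis, and a stress
generator produces random / inverted / constant labelings for bound checks.

All layouts are regular grids with synthetic two-class Gaussian expression
profiles; the documented spot and mislabel counts are the fixed study
conditions, not tunables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import SpatialDataset


@dataclass
class ScenarioPair:
    """A ground truth plus two competing clustering results.

    expected_order records which result the design makes superior:
    ``I_better``, ``II_better``, or ``equal_under_symmetric_weights``.
    """

    dataset_truth: SpatialDataset
    result_I: np.ndarray
    result_II: np.ndarray
    expected_order: str

    def dataset_I(self) -> SpatialDataset:
        return self.dataset_truth.with_predictions(self.result_I)

    def dataset_II(self) -> SpatialDataset:
        return self.dataset_truth.with_predictions(self.result_II)


def _grid(n_cols: int, n_rows: int) -> np.ndarray:
    """Row-major unit grid coordinates, (n_cols * n_rows, 2)."""
    xs, ys = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    return np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)


def _two_class_expression(
    truth: np.ndarray, n_genes: int, noise: float, seed: int
) -> np.ndarray:
    """Well-separated nonnegative Gaussian class profiles (classes 1 and 2)."""
    mu1 = np.concatenate([np.full(n_genes // 2, 4.0), np.full(n_genes - n_genes // 2, 0.5)])
    mu2 = np.concatenate([np.full(n_genes // 2, 0.5), np.full(n_genes - n_genes // 2, 4.0)])
    rng = np.random.default_rng(seed)
    means = np.where(truth[:, None] == 1, mu1, mu2)
    return np.clip(means + noise * rng.standard_normal((len(truth), n_genes)), 0.01, None)


def scenario_label_agreement() -> ScenarioPair:
    """Two-domain layout: 3 domain-1 spots at the upper margin, 339 domain-2.

    Result I mislabels the 47 domain-2 spots nearest the margin as domain 1;
    Result II mislabels the complementary 292 domain-2 spots.  Both results
    have near-identical spatial continuity (a color-swap pair), so only the
    mislabel count separates them: Result I is better.
    """
    n_cols, n_rows = 18, 19  # 342 spots
    coords = _grid(n_cols, n_rows)
    truth = np.full(len(coords), 2, dtype=int)
    top = coords[:, 1] == n_rows - 1
    margin_idx = np.nonzero(top)[0][7:10]  # 3 central spots on the top row
    truth[margin_idx] = 1

    domain2 = np.nonzero(truth == 2)[0]
    # order domain-2 spots from the margin downward (row-major within a row)
    order = domain2[np.lexsort((coords[domain2, 0], -coords[domain2, 1]))]
    band_I = order[:47]  # contiguous band at the margin
    band_II = order[47:]  # the complementary 292 spots (color-swap mirror)

    result_I = truth.copy()
    result_I[band_I] = 1
    result_II = truth.copy()
    result_II[band_II] = 1

    X = _two_class_expression(truth, n_genes=12, noise=0.05, seed=20240613)
    ds = SpatialDataset.from_arrays(coords, truth, truth, expression=X)
    return ScenarioPair(ds, result_I, result_II, expected_order="I_better")


def scenario_mislabel_location() -> ScenarioPair:
    """Layer-6 band over a WM band with a boundary-proximal expression gradient.

    Both results mislabel exactly 29 WM spots as layer 6 — Result I the
    boundary row, Result II a core row — so every external metric ties.
    Peripheral WM profiles interpolate toward the layer-6 class mean, making
    the boundary mislabels biologically milder: Result I is better.
    """
    n_cols, n_rows = 29, 10
    coords = _grid(n_cols, n_rows)
    y = coords[:, 1]
    truth = np.where(y <= 3, 1, 2)  # 1 = layer 6 (116 spots), 2 = WM (174 spots)

    g = 12
    mu6 = np.concatenate([np.full(g // 2, 4.0), np.full(g - g // 2, 0.5)])
    muWM = np.concatenate([np.full(g // 2, 0.5), np.full(g - g // 2, 4.0)])
    X = np.empty((len(coords), g))
    rng = np.random.default_rng(20240612)  # fixed: the gradient IS the design
    for i in range(len(coords)):
        if truth[i] == 1:
            mean = mu6
        else:
            t = 0.5 * (n_rows - 1 - y[i]) / (n_rows - 1 - 4)  # 0.5 at boundary row
            mean = (1 - t) * muWM + t * mu6
        X[i] = np.clip(mean + 0.05 * rng.standard_normal(g), 0.01, None)

    result_I = truth.copy()
    result_I[y == 4] = 1  # 29 boundary WM spots
    result_II = truth.copy()
    result_II[y == 7] = 1  # 29 core WM spots

    ds = SpatialDataset.from_arrays(coords, truth, truth, expression=X)
    return ScenarioPair(ds, result_I, result_II, expected_order="I_better")


def scenario_error_severity() -> ScenarioPair:
    """Mirror-symmetric normal/cancer blocks: 12 FPs (Result I) vs 12 FNs (Result II).

    The two mislabel sets are reflections of each other across the block
    boundary, so topology and every count-based metric are identical; only a
    cost table with FN > FP separates them (Result I better).
    """
    n_cols, n_rows = 8, 6  # 24 + 24 spots
    coords = _grid(n_cols, n_rows)
    x = coords[:, 0]
    truth = np.where(x <= 3, 1, 2)  # 1 = connective tissue, 2 = cancer in situ

    result_I = truth.copy()
    result_I[(x == 2) | (x == 3)] = 2  # 12 normal spots called cancer (FP)
    result_II = truth.copy()
    result_II[(x == 4) | (x == 5)] = 1  # 12 cancer spots called normal (FN)

    ds = SpatialDataset.from_arrays(coords, truth, truth)
    return ScenarioPair(ds, result_I, result_II, expected_order="I_better")


def fn_fp_cost_table(
    fn_cost: float = 2.0, fp_cost: float = 1.0, cancer_label: int = 2, normal_label: int = 1
) -> dict[tuple[int, int], float]:
    """Cost table penalizing missed cancer (FN) above over-calling (FP)."""
    return {
        (cancer_label, normal_label): fn_cost,
        (normal_label, cancer_label): fp_cost,
        (cancer_label, cancer_label): 1.0,
        (normal_label, normal_label): 1.0,
    }


DEFAULT_SENSITIVITY_COUNTS = tuple(
    int(c) for c in np.round(np.linspace(9, 95, 10))
)


def sensitivity_series(
    mislabel_counts=None, seed: int = 0
) -> list[SpatialDataset]:
    """360-spot two-domain series with a growing number of mislabels.

    180 breast-gland and 180 cancerous spots on an 18 x 20 grid with
    well-separated Gaussian class profiles (20 genes, sd 0.1).  Dataset m
    flips that many randomly chosen breast-gland spots to the cancer label,
    so its error rate is exactly m / 360.
    """
    if mislabel_counts is None:
        mislabel_counts = DEFAULT_SENSITIVITY_COUNTS
    counts = [int(c) for c in mislabel_counts]
    if any(c < 0 or c > 180 for c in counts):
        raise ValidationError("mislabel counts must lie in [0, 180]")

    n_cols, n_rows = 20, 18  # 360 spots
    coords = _grid(n_cols, n_rows)
    truth = np.where(coords[:, 0] <= 9, 1, 2)  # 1 = breast gland, 2 = cancer

    g = 20
    mu1 = np.concatenate([np.full(g // 2, 3.0), np.full(g - g // 2, 0.5)])
    mu2 = np.concatenate([np.full(g // 2, 0.5), np.full(g - g // 2, 3.0)])
    ss = np.random.SeedSequence(seed).spawn(1 + len(counts))
    rng = np.random.default_rng(ss[0])
    X = np.clip(
        np.where(truth[:, None] == 1, mu1, mu2) + 0.1 * rng.standard_normal((360, g)),
        0.01,
        None,
    )

    gland = np.nonzero(truth == 1)[0]
    out = []
    for m, child in zip(counts, ss[1:]):
        rng_m = np.random.default_rng(child)
        flip = rng_m.choice(gland, size=m, replace=False)
        pred = truth.copy()
        pred[flip] = 2
        out.append(SpatialDataset.from_arrays(coords, truth, pred, expression=X))
    return out


def striped_truth(n_side: int, n_domains: int) -> tuple[np.ndarray, np.ndarray]:
    """Square grid with horizontal striped domains; every domain non-empty."""
    if n_side < 4 or not 2 <= n_domains <= n_side:
        raise ValidationError("need n_side >= 4 and 2 <= n_domains <= n_side")
    coords = _grid(n_side, n_side)
    stripes = (coords[:, 1].astype(int) * n_domains) // n_side + 1
    return coords, stripes


def random_labeling_suite(
    n_side: int, n_domains: int, seeds
) -> list[SpatialDataset]:
    """Stress predictions on striped grid truths: random, inverted, constant.

    For each seed, three datasets share the same truth: a uniform random
    labeling (all domains forced non-empty), the stripe inversion
    (label k -> K + 1 - k, error rate 1 for even stripe counts), and the
    constant labeling (single cluster).
    """
    coords, truth = striped_truth(n_side, n_domains)
    n = len(truth)
    out = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        rand = rng.integers(1, n_domains + 1, size=n)
        rand[:n_domains] = np.arange(1, n_domains + 1)  # guarantee non-empty
        inverted = n_domains + 1 - truth
        constant = np.ones(n, dtype=int)
        for pred in (rand, inverted, constant):
            out.append(SpatialDataset.from_arrays(coords, truth, pred))
    return out
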