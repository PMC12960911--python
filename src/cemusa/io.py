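"""Data model and table I/O for spatial clustering evaluation.

A :class:`SpatialDataset` holds everything the metric consumes: 2-D spot
coordinates, ground-truth domain labels, predicted cluster labels, and an
optional spots x genes expression matrix used for severity weights.  Label
alphabets (strings or arbitrary integers) are recoded internally to dense
1-based integer codes — edge label codes index domain types downstream — and
the original names are kept for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .errors import ConfigurationError, ParseError, ValidationError

DEFAULT_COLUMNS = {
    "spot_id": "spot_id",
    "x": "x",
    "y": "y",
    "truth": "truth",
    "pred": "pred",
}


def _dense_recode(values: np.ndarray) -> tuple[np.ndarray, dict[int, object]]:
    """Map an arbitrary label alphabet onto {1..K}, sorted by original name.

    Returns the 1-based codes and a code -> original-name table.
    """
    names, inverse = np.unique(values, return_inverse=True)
    codes = inverse.astype(np.int64) + 1
    return codes, {i + 1: names[i] for i in range(len(names))}


@dataclass(frozen=True)
class SpatialDataset:
    """Validated per-spot data for one slide and one clustering result.

    Attributes
    ----------
    coords : (n, 2) float array, slide coordinates (dimensionless Euclidean).
    true_labels : (n,) int array with dense codes in {1..K}.
    pred_labels : (n,) int array with dense codes in {1..K1}.
    spot_ids : (n,) array of unique identifiers.
    expression : optional (n, g) non-negative float array.
    true_label_names / pred_label_names : code -> original-name tables.
    """

    coords: np.ndarray
    true_labels: np.ndarray
    pred_labels: np.ndarray
    spot_ids: np.ndarray
    expression: np.ndarray | None = None
    true_label_names: dict[int, object] = field(default_factory=dict)
    pred_label_names: dict[int, object] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_domains(self) -> int:
        """Number of ground-truth domain types K."""
        return int(self.true_labels.max())

    @property
    def n_clusters(self) -> int:
        """Number of predicted clusters K1."""
        return int(self.pred_labels.max())

    @classmethod
    def from_arrays(
        cls,
        coords: np.ndarray,
        true_labels: Sequence,
        pred_labels: Sequence,
        spot_ids: Sequence | None = None,
        expression: np.ndarray | None = None,
    ) -> "SpatialDataset":
        """Build a validated dataset, recoding both label alphabets densely."""
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError(f"coords must be n x 2, got shape {coords.shape}")
        n = coords.shape[0]
        if n < 2:
            raise ValidationError(f"need at least 2 spots, got {n}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")

        truth = np.asarray(true_labels)
        pred = np.asarray(pred_labels)
        if len(truth) != n or len(pred) != n:
            raise ValidationError(
                f"label lengths ({len(truth)}, {len(pred)}) do not match n={n}"
            )
        if pd.isna(truth).any() or pd.isna(pred).any():
            raise ValidationError("missing truth/prediction labels are rejected")
        t_codes, t_names = _dense_recode(truth)
        p_codes, p_names = _dense_recode(pred)

        if spot_ids is None:
            spot_ids = np.array([f"spot{i}" for i in range(n)])
        else:
            spot_ids = np.asarray(spot_ids)
            if len(spot_ids) != n:
                raise ValidationError("spot_ids length does not match n")
            if len(np.unique(spot_ids)) != n:
                raise ValidationError("duplicate spot_ids")

        if expression is not None:
            expression = np.asarray(expression, dtype=float)
            if expression.ndim != 2 or expression.shape[0] != n:
                raise ValidationError(
                    f"expression must have n={n} rows, got shape {expression.shape}"
                )
            if expression.shape[1] < 1:
                raise ValidationError("expression needs at least one gene column")
            if np.any(expression < 0):
                raise ValidationError("expression entries must be non-negative")

        return cls(
            coords=coords,
            true_labels=t_codes,
            pred_labels=p_codes,
            spot_ids=spot_ids,
            expression=expression,
            true_label_names=t_names,
            pred_label_names=p_names,
        )

    def with_predictions(self, pred_labels: Sequence) -> "SpatialDataset":
        """Same slide and truth, different clustering result."""
        return SpatialDataset.from_arrays(
            self.coords,
            np.array([self.true_label_names[c] for c in self.true_labels]),
            pred_labels,
            spot_ids=self.spot_ids,
            expression=self.expression,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": self.spot_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "truth": [self.true_label_names[c] for c in self.true_labels],
                "pred": [self.pred_label_names[c] for c in self.pred_labels],
            }
        )

    def write_table(self, path: str | Path) -> None:
        """Write the per-spot table as TSV (round-trips via read_spatial_table)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_spatial_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> SpatialDataset:
    """Load a delimited per-spot table (TSV or CSV, header required).

    ``column_map`` maps the canonical names spot_id/x/y/truth/pred onto the
    file's column names; unmapped names fall back to themselves.  spot_id is
    optional in the file.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={cols["spot_id"]: str})
    for key in ("x", "y", "truth", "pred"):
        if cols[key] not in df.columns:
            raise ConfigurationError(
                f"column '{cols[key]}' (for '{key}') not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    coords = np.empty((len(df), 2), dtype=float)
    for j, key in enumerate(("x", "y")):
        parsed = pd.to_numeric(df[cols[key]], errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        if bad.size:
            raise ParseError(
                f"non-numeric '{key}' value {df[cols[key]].iloc[bad[0]]!r} "
                f"at data row {bad[0] + 1} of {path.name}"
            )
        coords[:, j] = parsed.to_numpy()
    spot_ids = df[cols["spot_id"]].to_numpy() if cols["spot_id"] in df.columns else None
    return SpatialDataset.from_arrays(
        coords,
        df[cols["truth"]].to_numpy(),
        df[cols["pred"]].to_numpy(),
        spot_ids=spot_ids,
    )


def read_expression(
    path: str | Path,
    dataset: SpatialDataset,
    format: str | None = None,
    row_ids: str | Path | None = None,
) -> SpatialDataset:
    """Attach an expression matrix to ``dataset``.

    ``format`` is ``"dense"`` (CSV, spots x genes) or ``"mtx"`` (MatrixMarket
    coordinate triplet with a one-id-per-line row sidecar); inferred from the
    file suffix when omitted.  Rows are reordered to match ``dataset.spot_ids``
    when identifiers are available, otherwise taken positionally.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "dense"

    if format == "mtx":
        raw = mmread(path)
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        sidecar = Path(row_ids) if row_ids else path.with_suffix(".rows")
        order = None
        if sidecar.exists():
            ids = np.array(sidecar.read_text().split())
            order = _row_order(ids, dataset.spot_ids)
    elif format == "dense":
        df = pd.read_csv(path)
        order = None
        first = df.columns[0]
        if df[first].dtype == object or first in ("spot_id", "id"):
            order = _row_order(df[first].astype(str).to_numpy(), dataset.spot_ids)
            df = df.drop(columns=[first])
        mat = df.to_numpy(dtype=float)
    else:
        raise ConfigurationError(f"unknown expression format {format!r}")

    if mat.shape[0] != dataset.n:
        raise ValidationError(
            f"expression has {mat.shape[0]} rows but dataset has {dataset.n} spots"
        )
    if order is not None:
        mat = mat[order]
    return replace(dataset, expression=_validate_expression(mat, dataset.n))


def _validate_expression(mat: np.ndarray, n: int) -> np.ndarray:
    if np.any(mat < 0):
        raise ValidationError("expression entries must be non-negative")
    if mat.shape[1] < 1:
        raise ValidationError("expression needs at least one gene column")
    return mat


def _row_order(file_ids: np.ndarray, spot_ids: np.ndarray) -> np.ndarray:
    """Index array reordering file rows into dataset spot order."""
    lookup = {str(s): i for i, s in enumerate(file_ids)}
    try:
        return np.array([lookup[str(s)] for s in spot_ids])
    except KeyError as exc:
        raise ValidationError(f"expression rows missing spot id {exc.args[0]!r}") from exc


@dataclass
class EvaluationReport:
    """Final score plus its three MMD terms and the resolved configuration.

    ``score == terms[0] + terms[1] - terms[2]`` on the estimator's own scale
    (terms are within-truth, within-clustering, and the doubled cross term).
    """

    score: float
    terms: tuple[float, float, float]
    config_echo: dict
    benchmark_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValidationError("report score must be finite")
        resid = abs(self.score - (self.terms[0] + self.terms[1] - self.terms[2]))
        if resid > 1e-9:
            raise ValidationError(
                f"score does not decompose into its terms (residual {resid:.2e})"
            )


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Serialize an EvaluationReport as JSON (lossless round-trip)."""
    payload = {
        "score": report.score,
        "terms": list(report.terms),
        "config_echo": report.config_echo,
        "benchmark_scores": report.benchmark_scores,
    }
    try:
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> EvaluationReport:
    payload = json.loads(Path(path).read_text())
    return EvaluationReport(
        score=payload["score"],
        terms=tuple(payload["terms"]),
        config_echo=payload["config_echo"],
        benchmark_scores=payload["benchmark_scores"],
    )
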