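"""Expression-matrix containers, TSV readers and array-level preprocessing.

Arrays arrive as feature-by-sample signal matrices together with per-array
absence/presence detection calls.  Preprocessing removes probes that were
never detected above background (and, optionally, probes not annotated to
the target species), then quantile-normalizes each platform so that all
sample distributions coincide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "DetectionCalls",
    "parse_sample_id",
    "read_expression_table",
    "read_detection_table",
    "filter_undetected",
    "quantile_normalize",
]

_SAMPLE_ID_RE = re.compile(r"^(?P<genotype>[A-Za-z0-9.]+)_(?P<timepoint>[A-Za-z0-9.]+)_(?P<replicate>\d+)$")


def parse_sample_id(sample_id: str) -> tuple[str, str, int]:
    """Decode ``<genotype>_<timepoint>_<rep>`` into its three components."""
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise ValueError(f"malformed sample id {sample_id!r}; expected <genotype>_<timepoint>_<rep>")
    return m.group("genotype"), m.group("timepoint"), int(m.group("replicate"))


@dataclass
class ExpressionMatrix:
    """Features x samples signal table with metadata decoded from sample ids.

    ``values`` is indexed by feature id with one column per sample id of the
    form ``<genotype>_<timepoint>_<rep>``.  Signals are linear-scale,
    finite and non-negative.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and (not np.isfinite(arr.astype(float)).all() or (arr < 0).any()):
            raise ValueError("expression values must be finite and non-negative")
        self.values.index.name = "feature_id"
        for s in self.values.columns:
            parse_sample_id(s)  # raises on malformed metadata

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_meta(self) -> pd.DataFrame:
        rows = [parse_sample_id(s) for s in self.values.columns]
        return pd.DataFrame(rows, columns=["genotype", "timepoint", "replicate"], index=self.values.columns)

    def group_columns(self, genotype: str, timepoint: str) -> list[str]:
        """Sample ids belonging to one genotype x timepoint group."""
        meta = self.sample_meta
        mask = (meta["genotype"] == genotype) & (meta["timepoint"] == timepoint)
        return list(meta.index[mask])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass
class DetectionCalls:
    """Boolean present/absent flag per (feature, sample); True means present."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(bool)

    def matches(self, matrix: ExpressionMatrix) -> bool:
        return self.calls.index.equals(matrix.values.index) and self.calls.columns.equals(matrix.values.columns)

    def to_tsv(self, path) -> None:
        out = self.calls.map(lambda b: "P" if b else "A")
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def read_expression_table(path) -> ExpressionMatrix:
    """Read a feature-by-sample TSV (first column ``feature_id``)."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    return ExpressionMatrix(values)


def read_detection_table(path) -> DetectionCalls:
    """Read a P/A detection-call TSV in the same dialect as the matrices."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id", dtype=str)
    bad = sorted(set(df.to_numpy().ravel()) - {"P", "A"})
    if bad:
        raise ValueError(f"detection calls must be 'P' or 'A'; found {bad}")
    for s in df.columns:
        parse_sample_id(s)
    return DetectionCalls(df == "P")


def filter_undetected(
    matrix: ExpressionMatrix,
    calls: DetectionCalls,
    species_annotation: dict[str, str] | None = None,
    species: str = "mouse",
) -> ExpressionMatrix:
    """Drop features never detected above background in any array.

    When a ``species_annotation`` mapping (feature id -> species label) is
    supplied, features not annotated to ``species`` are removed as well.
    Feature order is preserved; the operation is idempotent.
    """
    if not calls.matches(matrix):
        raise ValueError("detection calls do not match the expression matrix shape")
    keep = calls.calls.any(axis=1)
    if species_annotation is not None:
        annotated = pd.Series(
            [species_annotation.get(f) == species for f in matrix.values.index],
            index=matrix.values.index,
        )
        keep &= annotated
    return ExpressionMatrix(matrix.values.loc[keep])


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-sorted-columns distribution.

    Each sample's k-th smallest value is replaced by the across-sample mean
    of k-th smallest values.  Ties within a sample receive the mean of the
    quantile values they span, so within-sample rank order is preserved and
    tied inputs stay tied.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.size == 0:
        return ExpressionMatrix(matrix.values.copy())
    if not np.isfinite(vals).all():
        raise ValueError("quantile normalization requires complete, finite values")
    ref = np.sort(vals, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        rmin = rankdata(col, method="min").astype(int)
        rmax = rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return ExpressionMatrix(pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns))
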