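"""Reading, pre-filtering, label encoding, augmentation and auto-scaling of
abundance tables.

An abundance table is a samples × features matrix of non-negative counts (or
processed floats) with one categorical outcome label per sample. Before the
fuzzy-rule stage the table is optionally reduced to the most informative
features with a random-forest importance ranking, the string labels are
coerced to integer factors, and the numeric label column is appended to the
matrix ("augmentation").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "AbundanceTable",
    "AugmentedMatrix",
    "read_abundance",
    "encode_labels",
    "decode_labels",
    "prefilter_features",
    "augment",
    "autoscale",
]


@dataclass
class AbundanceTable:
    """Samples × features abundance matrix with per-sample outcome labels."""

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("abundance values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance matrix contains NaN or infinite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


@dataclass
class AugmentedMatrix:
    """Abundance matrix with the numeric label factor appended as last column."""

    values: np.ndarray
    feature_names: list[str]
    label_map: dict[str, int]
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        """Number of input features (label column excluded)."""
        return self.values.shape[1] - 1

    @property
    def features(self) -> np.ndarray:
        return self.values[:, :-1]

    @property
    def label_column(self) -> np.ndarray:
        return self.values[:, -1]


def encode_labels(labels: list[str]) -> tuple[list[int], dict[str, int]]:
    """Convert string labels to integer factors 1..K, lexicographic order.

    Returns the per-sample integer factors and the label → level map.
    Mirrors factor coercion in R, where class strings are levelled
    alphabetically before being treated as numeric.
    """
    distinct = sorted(set(labels))
    if len(distinct) < 2:
        raise ValueError(
            f"need at least 2 distinct labels for an outcome contrast, got {distinct!r}"
        )
    label_map = {lab: i + 1 for i, lab in enumerate(distinct)}
    return [label_map[lab] for lab in labels], label_map


def decode_labels(factors: list[int], label_map: dict[str, int]) -> list[str]:
    inverse = {v: k for k, v in label_map.items()}
    return [inverse[f] for f in factors]


def read_abundance(
    path: str | Path,
    orientation: str = "samples",
    label_column: str | None = None,
    label_file: str | Path | None = None,
    sep: str | None = None,
) -> AbundanceTable:
    """Read a delimited abundance table and resolve per-sample labels.

    Parameters
    ----------
    path
        TSV/CSV file; header row of feature names, first column sample ids
        (or feature ids when ``orientation="features"``).
    orientation
        ``"samples"`` if samples are rows, ``"features"`` if features are
        rows (the table is transposed to samples × features).
    label_column
        Name of the column inside the table holding the outcome label.
    label_file
        Two-column delimited file mapping sample id → label; alternative to
        ``label_column``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)

    if orientation not in {"samples", "features"}:
        raise ValueError("orientation must be 'samples' or 'features'")
    if orientation == "features":
        df = df.T

    labels_series: pd.Series | None = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        labels_series = df[label_column].astype(str)
        df = df.drop(columns=[label_column])
    elif label_file is not None:
        lf = Path(label_file)
        lsep = "\t" if lf.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
        meta = pd.read_csv(lf, sep=lsep, index_col=0)
        meta.index = meta.index.astype(str)
        missing = [s for s in df.index if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing a label: {missing}")
        labels_series = meta.iloc[:, 0].reindex(df.index).astype(str)
    else:
        raise ValueError("either label_column or label_file must be given")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return AbundanceTable(
        values=numeric.values.astype(float),
        sample_ids=list(df.index),
        feature_names=[str(c) for c in df.columns],
        labels=list(labels_series),
    )


def prefilter_features(
    table: AbundanceTable,
    n_top: int = 100,
    n_trees: int = 500,
    seed: int = 0,
) -> AbundanceTable:
    """Keep the ``n_top`` features with the highest random-forest importance.

    A classification forest is trained on (values, labels) and features are
    ranked by decreasing mean-decrease-in-impurity importance; ties are broken
    by original column order. Deterministic for a given seed.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    factors, _ = encode_labels(table.labels)
    # fit on name-canonical column order so the ranking is invariant to how
    # the input columns happen to be arranged
    canon = np.argsort(np.asarray(table.feature_names, dtype=object), kind="stable")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(table.values[:, canon], np.asarray(factors))
    importance = np.empty(table.n_features)
    importance[canon] = rf.feature_importances_
    # stable sort on -importance keeps original column order among ties
    order = np.argsort(-importance, kind="stable")[: min(n_top, table.n_features)]
    return AbundanceTable(
        values=table.values[:, order],
        sample_ids=table.sample_ids,
        feature_names=[table.feature_names[i] for i in order],
        labels=table.labels,
    )


def augment(table: AbundanceTable) -> AugmentedMatrix:
    """Append the numeric label factor as the last matrix column."""
    factors, label_map = encode_labels(table.labels)
    values = np.column_stack([table.values, np.asarray(factors, dtype=float)])
    return AugmentedMatrix(
        values=values,
        feature_names=list(table.feature_names),
        label_map=label_map,
        sample_ids=list(table.sample_ids),
    )


def autoscale(matrix: np.ndarray) -> np.ndarray:
    """Centre and scale each column to mean 0, sample standard deviation 1.

    Constant columns map to all-zero columns (with a warning) so downstream
    column indexing stays stable.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot autoscale an empty matrix")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros(matrix.shape[1])
    constant = sd < 1e-15
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant column(s) scaled to zeros", stacklevel=2
        )
    safe_sd = np.where(constant, 1.0, sd)
    out = (matrix - mean) / safe_sd
    out[:, constant] = 0.0
    return out
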