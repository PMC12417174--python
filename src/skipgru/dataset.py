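"""Tabular clinical dataset container and CSV I/O.

The central container is :class:`TabularDataset`: a numeric feature matrix
(rows = patients), 0-based integer class labels, and a per-column declaration
of *zero-coded missingness* — the clinical-data convention where a recorded
value of 0 in a column such as serum insulin or BMI means "not measured"
rather than a true zero.  Missingness is therefore encoded, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TabularDataset",
    "DatasetError",
    "NonNumericFeatureError",
    "LabelColumnError",
    "UnknownMissingColumnError",
    "load_dataset",
    "save_dataset",
]


class DatasetError(ValueError):
    """Base class for dataset loading/validation failures."""


class NonNumericFeatureError(DatasetError):
    """A feature cell failed to parse as a number."""


class LabelColumnError(DatasetError):
    """The declared label column is absent from the CSV header."""


class UnknownMissingColumnError(DatasetError):
    """A declared zero-coded column does not exist among the features."""


@dataclass(frozen=True)
class TabularDataset:
    """Feature matrix + class labels + zero-as-missing policy.

    Attributes
    ----------
    features:
        ``(n_samples, n_features)`` float array.  Never contains NaN;
        missing entries are encoded as 0 in the columns listed in
        ``missing_columns``.
    labels:
        ``(n_samples,)`` integer class indices in ``[0, n_classes)``.
    feature_names, class_names:
        Column and class labels; feature names are unique.
    missing_columns:
        Names of features where the value 0 encodes "missing".
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    class_names: tuple[str, ...]
    missing_columns: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labs = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labs)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "class_names", tuple(self.class_names))
        object.__setattr__(self, "missing_columns", frozenset(self.missing_columns))
        if feats.ndim != 2 or feats.shape[0] < 1:
            raise DatasetError("features must be a 2-D matrix with at least one row")
        if np.isnan(feats).any():
            raise DatasetError("features contain NaN; missingness must be zero-coded")
        if len(self.feature_names) != feats.shape[1]:
            raise DatasetError("feature_names length does not match feature count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DatasetError("feature_names must be unique")
        if labs.shape != (feats.shape[0],):
            raise DatasetError("labels must be one class index per row")
        if labs.min(initial=0) < 0 or labs.max(initial=0) >= len(self.class_names):
            raise DatasetError("labels out of range [0, n_classes)")
        unknown = self.missing_columns - set(self.feature_names)
        if unknown:
            raise UnknownMissingColumnError(
                f"missing_columns not among features: {sorted(unknown)}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise DatasetError(f"unknown feature {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.column_index(name)]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_samples, n_features)`` mask of zero-coded entries."""
        mask = np.zeros(self.features.shape, dtype=bool)
        for name in self.missing_columns:
            j = self.column_index(name)
            mask[:, j] = self.features[:, j] == 0.0
        return mask

    # -- functional updates ---------------------------------------------
    def with_features(self, features: np.ndarray) -> "TabularDataset":
        return replace(self, features=np.asarray(features, dtype=float))

    def take_rows(self, idx: np.ndarray) -> "TabularDataset":
        return replace(self, features=self.features[idx], labels=self.labels[idx])

    def select_columns(self, selected: Iterable[int]) -> "TabularDataset":
        sel = list(selected)
        names = tuple(self.feature_names[j] for j in sel)
        return TabularDataset(
            features=self.features[:, sel],
            labels=self.labels,
            feature_names=names,
            class_names=self.class_names,
            missing_columns=self.missing_columns & set(names),
        )


def load_dataset(
    path: str | Path,
    label_column: str,
    missing_columns: Iterable[str] = (),
) -> TabularDataset:
    """Read a header-row CSV into a :class:`TabularDataset`.

    Labels are factorized to 0-based indices in first-appearance order,
    which keeps the encoding deterministic and stable under row order.
    Row order is preserved; no rows are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if label_column not in frame.columns:
        raise LabelColumnError(
            f"label column {label_column!r} not in header {list(frame.columns)}"
        )
    feature_cols = [c for c in frame.columns if c != label_column]
    unknown = set(missing_columns) - set(feature_cols)
    if unknown:
        raise UnknownMissingColumnError(
            f"missing_columns not among features: {sorted(unknown)}"
        )
    values = np.empty((len(frame), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna()
        if bad.any() or parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise NonNumericFeatureError(
                f"non-numeric value {frame[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        values[:, j] = parsed.to_numpy()
    codes, uniques = pd.factorize(frame[label_column].to_numpy(), sort=False)
    return TabularDataset(
        features=values,
        labels=codes,
        feature_names=tuple(feature_cols),
        class_names=tuple(str(u) for u in uniques),
        missing_columns=frozenset(missing_columns),
    )


def save_dataset(dataset: TabularDataset, path: str | Path, label_column: str = "label") -> None:
    """Write the dataset back to CSV (header row, original row order)."""
    frame = pd.DataFrame(dataset.features, columns=list(dataset.feature_names))
    frame[label_column] = [dataset.class_names[i] for i in dataset.labels]
    frame.to_csv(path, index=False)
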