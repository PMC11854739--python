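"""Dataset loading, label encoding, standardization and class partitioning.

Datasets are samples-by-features matrices with one integer class label per
sample.  Two on-disk dialects are supported: delimited text (CSV/TSV with an
optional header and a label column) and MAT containers holding variables
``X`` (n x d) and ``Y`` (n x 1), the convention used by public
feature-selection benchmark repositories.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import loadmat


class DatasetError(ValueError):
    """Raised when a dataset fails to parse or violates an invariant."""


@dataclass
class DataMatrix:
    """An n x d numeric matrix of samples by features with class labels.

    Labels are contiguous integers ``1..r``.  Feature names are synthesized
    (``f0001``, ``f0002``, ...) when not supplied.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise DatasetError(f"need at least 2 samples and 2 features, got {n}x{d}")
        if self.labels.shape != (n,):
            raise DatasetError("labels must have one entry per sample")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("values contain NaN/Inf")
        r = int(self.labels.max(initial=0))
        if self.labels.min(initial=1) < 1 or r < 1:
            raise DatasetError("labels must be in 1..r")
        present = np.unique(self.labels)
        if len(present) != r:
            missing = sorted(set(range(1, r + 1)) - set(present.tolist()))
            raise DatasetError(f"classes with zero samples: {missing}")
        if not self.feature_names:
            width = max(4, len(str(d)))
            self.feature_names = [f"f{j + 1:0{width}d}" for j in range(d)]
        if len(self.feature_names) != d:
            raise DatasetError("feature_names length must equal number of features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def class_counts(self) -> np.ndarray:
        """Per-class sample counts, indexed by class id - 1."""
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]


def remap_labels(raw: Sequence) -> np.ndarray:
    """Remap arbitrary label values to contiguous 1..r by first appearance."""
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        key = v.item() if isinstance(v, np.generic) else v
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        out[i] = mapping[key]
    return out


def one_hot(labels: np.ndarray, r: int) -> np.ndarray:
    """Binary n x r indicator matrix with Y[i, c-1] = 1 iff sample i has class c."""
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=1) < 1 or labels.max(initial=1) > r:
        raise ValueError(f"label ids must lie in 1..{r}")
    n = labels.shape[0]
    Y = np.zeros((n, r), dtype=float)
    Y[np.arange(n), labels - 1] = 1.0
    return Y


def _sniff_table(path: Path) -> pd.DataFrame:
    text = path.read_text()
    first = text.splitlines()[0] if text else ""
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    # header detection: a fully numeric first row means no header
    tokens = [t.strip() for t in first.split(sep)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = None if all(_numeric(t) for t in tokens if t != "") else 0
    return pd.read_csv(_io.StringIO(text), sep=sep, header=header)


def read_dataset(
    path: str | Path,
    format: str = "delimited",
    label_column: str | int = "label",
) -> DataMatrix:
    """Read a dataset from delimited text or a MAT container.

    Labels are remapped to contiguous ``1..r`` preserving first-appearance
    order, so the one-hot indicator columns are reproducible.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if format == "mat":
        return _read_mat(path)
    if format != "delimited":
        raise DatasetError(f"unknown format {format!r}")

    df = _sniff_table(path)
    if isinstance(label_column, int):
        if label_column < 0 or label_column >= df.shape[1]:
            raise DatasetError(f"label column index {label_column} out of range")
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise DatasetError(f"label column {label_column!r} not found")
        label_name = label_column
    raw_labels = df[label_name].to_numpy()
    feats = df.drop(columns=[label_name])
    try:
        values = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"non-numeric cell in feature columns: {exc}") from exc
    names = [str(c) for c in feats.columns] if isinstance(feats.columns[0], str) else []
    return DataMatrix(values=values, labels=remap_labels(raw_labels), feature_names=names)


def _read_mat(path: Path) -> DataMatrix:
    data = loadmat(path)
    if "X" not in data or "Y" not in data:
        raise DatasetError("MAT container must hold variables X and Y")
    values = np.asarray(data["X"], dtype=float)
    raw = np.asarray(data["Y"]).ravel()
    return DataMatrix(values=values, labels=remap_labels(raw))


def write_dataset(X: DataMatrix, path: str | Path, label_column: str = "label") -> None:
    """Write a DataMatrix as delimited text (lossless to ~1e-12 round-trip)."""
    path = Path(path)
    df = pd.DataFrame(X.values, columns=X.feature_names)
    df[label_column] = X.labels
    df.to_csv(path, index=False, float_format="%.17g")


def standardize(X: DataMatrix, mode: str = "zscore") -> DataMatrix:
    """Per-feature rescaling; constant features map to zeros (no div-by-zero)."""
    if mode == "none":
        return DataMatrix(X.values.copy(), X.labels.copy(), list(X.feature_names))
    V = X.values
    if mode == "zscore":
        mean = V.mean(axis=0)
        sd = V.std(axis=0, ddof=1)
        out = np.where(sd > 0, (V - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    elif mode == "minmax":
        lo, hi = V.min(axis=0), V.max(axis=0)
        rng = hi - lo
        out = np.where(rng > 0, (V - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return DataMatrix(out, X.labels.copy(), list(X.feature_names))


def split_by_class(X: DataMatrix) -> list[np.ndarray]:
    """Partition rows by class label, preserving within-class sample order."""
    return [X.values[X.labels == c] for c in range(1, X.n_classes + 1)]


def write_ranking(
    path: str | Path,
    ranking: np.ndarray,
    scores: np.ndarray,
    feature_names: Sequence[str],
) -> None:
    """Write a ranking TSV: rank, feature_index (0-based), feature_name, score."""
    with open(path, "w") as fh:
        fh.write("rank\tfeature_index\tfeature_name\tscore\n")
        for rank, j in enumerate(ranking, start=1):
            fh.write(f"{rank}\t{j}\t{feature_names[j]}\t{scores[j]:.17g}\n")


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
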