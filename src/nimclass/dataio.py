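"""Labeled expression matrices on disk and in memory.

The on-disk format is plain delimited text (CSV/TSV): one header row,
first column the sample id, one designated label column (default
``label``), an optional ``split`` column with values ``train``/``test``,
and every remaining column a numeric feature. Samples are rows and
genes/features are columns; gene-in-rows files can be read with
``transpose=True``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_SPLIT_VALUES = {"train", "test"}


@dataclass
class ExpressionDataset:
    """A samples x features numeric matrix with optional per-sample labels.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    feature_ids : list of str
        Unique feature (gene) identifiers, one per matrix column.
    values : ndarray of shape (n_samples, n_features)
        Finite expression values.
    labels : list of (str or None), optional
        Per-sample class labels. ``None`` marks an unlabeled sample,
        which is only legal for samples flagged ``test``.
    split : list of str, optional
        Per-sample flag in ``{"train", "test"}``.
    classes : list of str, optional
        Declared class order; defaults to order of first appearance in
        ``labels``. The order matters for tie-breaking in prediction.
    """

    sample_ids: list
    feature_ids: list
    values: np.ndarray
    labels: Optional[list] = None
    split: Optional[list] = None
    classes: Optional[list] = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if m != len(self.feature_ids):
            raise ValueError(
                f"matrix has {m} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValueError("labels length does not match sample count")
            self.labels = [None if lb is None else str(lb) for lb in self.labels]
        if self.split is not None:
            if len(self.split) != n:
                raise ValueError("split length does not match sample count")
            bad = set(self.split) - _SPLIT_VALUES
            if bad:
                raise ValueError(f"invalid split values: {sorted(bad)}")
            if self.labels is not None:
                for sid, lb, sp in zip(self.sample_ids, self.labels, self.split):
                    if lb is None and sp == "train":
                        raise ValueError(f"training sample {sid!r} is unlabeled")
        if self.classes is None:
            if self.labels is not None:
                seen = []
                for lb in self.labels:
                    if lb is not None and lb not in seen:
                        seen.append(lb)
                self.classes = seen or None
        else:
            self.classes = [str(c) for c in self.classes]
            if self.labels is not None:
                declared = set(self.classes)
                for sid, lb in zip(self.sample_ids, self.labels):
                    if lb is not None and lb not in declared:
                        raise ValueError(
                            f"label {lb!r} of sample {sid!r} not in declared classes"
                        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Row subset preserving order; labels/split subset alongside."""
        idx = list(indices)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx, :].copy(),
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            split=None if self.split is None else [self.split[i] for i in idx],
            classes=None if self.classes is None else list(self.classes),
        )

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return replace(self, values=np.asarray(values, dtype=float))

    def train_test_split(self):
        """Return (train, test) datasets from the ``split`` flags."""
        if self.split is None:
            raise ValueError("dataset carries no split flags")
        tr = [i for i, s in enumerate(self.split) if s == "train"]
        te = [i for i, s in enumerate(self.split) if s == "test"]
        return self.subset(tr), self.subset(te)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )
        df.index.name = "sample_id"
        if self.labels is not None:
            df.insert(0, "label", [lb if lb is not None else "" for lb in self.labels])
        if self.split is not None:
            df.insert(0, "split", list(self.split))
        return df


def _delimiter_for(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_dataset(
    path,
    label_column: str = "label",
    delimiter: Optional[str] = None,
    split_column: str = "split",
    transpose: bool = False,
    labeled: bool = True,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    The first column is taken as the sample id. ``label_column`` and
    ``split_column`` are popped out of the feature block if present;
    with ``labeled=True`` a missing label column is an error.
    Non-numeric or non-finite feature cells raise with the offending
    sample and feature named.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")

    labels = None
    if label_column in df.columns:
        raw = df.pop(label_column)
        labels = [str(v) if str(v) != "" else None for v in raw]
    elif labeled:
        raise ValueError(f"label column {label_column!r} not found in {path}")

    split = None
    if split_column in df.columns:
        split = [str(v) for v in df.pop(split_column)]

    raw = df.to_numpy(dtype=str)
    try:
        # numpy's str->float casting is correctly rounded, so text written
        # with shortest repr round-trips exactly
        values = raw.astype(np.float64)
    except ValueError:
        values = None
    if values is None or not np.all(np.isfinite(values)):
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    ok = np.isfinite(float(raw[i, j]))
                except ValueError:
                    ok = False
                if not ok:
                    raise ValueError(
                        f"non-numeric value {df.iat[i, j]!r} at sample "
                        f"{sample_ids[i]!r}, feature {df.columns[j]!r}"
                    ) from None
    return ExpressionDataset(
        sample_ids=sample_ids,
        feature_ids=[str(c) for c in df.columns],
        values=values,
        labels=labels,
        split=split,
    )


def write_dataset(dataset: ExpressionDataset, path, delimiter: Optional[str] = None) -> None:
    """Write a dataset as delimited text, re-readable by :func:`read_dataset`.

    Floats are written with shortest round-trip repr, so a write/read
    cycle is lossless.
    """
    if dataset.n_samples == 0:
        raise ValueError("refusing to write an empty dataset (0 samples)")
    sep = _delimiter_for(path, delimiter)
    dataset.to_frame().to_csv(path, sep=sep)
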