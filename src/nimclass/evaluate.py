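"""LOOCV / holdout evaluation and bandwidth grid sweeps.

Leave-one-out cross-validation holds out each sample in turn. Because
the pipeline is transductive — normalization statistics and the
similarity graph are computed over all N samples jointly, and a fold
only relabels one node as "test" — the graph and the influence vector
are identical across folds, so the default implementation computes
them once and re-scores each held-out node (``cache=True``). The
literal per-fold recomputation is available with ``cache=False`` and
agrees to floating-point accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from nimclass.classifier import NIMConfig, PredictionResult, nim1, nim2, predict_label
from nimclass.dataio import ExpressionDataset
from nimclass.graph import WeightedGraph, distance_matrix, similarity
from nimclass.influence import node_influence
from nimclass.preprocess import minmax_normalize


@dataclass
class EvaluationReport:
    """Accuracy and per-fold predictions for one evaluation run."""

    protocol: str  # "loocv" or "holdout"
    n_correct: int
    n_total: int
    accuracy: float
    predictions: pd.DataFrame
    config: NIMConfig
    n_errored_folds: int = 0

    def __post_init__(self):
        if self.n_total > 0:
            assert self.accuracy == self.n_correct / self.n_total


@dataclass
class GridResult:
    """Accuracy surface over a bandwidth grid.

    For NIM1 the grid is the 1-D ``delta1_axis``; for NIM2 it is the
    Cartesian product ``delta1_axis x delta2_axis`` and ``accuracy``
    has shape (len(delta1_axis), len(delta2_axis)).
    """

    variant: str
    delta1_axis: np.ndarray
    delta2_axis: Optional[np.ndarray]
    accuracy: np.ndarray
    best_points: list = field(default_factory=list)
    best_accuracy: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: delta1 [, delta2], accuracy."""
        if self.delta2_axis is None:
            return pd.DataFrame(
                {"delta": self.delta1_axis, "accuracy": self.accuracy}
            )
        d1, d2 = np.meshgrid(self.delta1_axis, self.delta2_axis, indexing="ij")
        return pd.DataFrame(
            {
                "delta1": d1.ravel(),
                "delta2": d2.ravel(),
                "accuracy": self.accuracy.ravel(),
            }
        )


def _run_variant(train, test, config: NIMConfig) -> PredictionResult:
    return nim1(train, test, config) if config.variant == "nim1" else nim2(train, test, config)


def _fold_class_order(labels, skip: int) -> list:
    order = []
    for i, lb in enumerate(labels):
        if i != skip and lb not in order:
            order.append(lb)
    return order


def loocv(dataset: ExpressionDataset, config: NIMConfig, cache: bool = True) -> EvaluationReport:
    """Leave-one-out cross-validation of NIM1/NIM2 on a labeled dataset.

    Folds whose held-out sample empties a class are recorded as errored
    and excluded from the accuracy denominator, with a warning.
    """
    if dataset.labels is None or any(lb is None for lb in dataset.labels):
        raise ValueError("LOOCV requires every sample to be labeled")
    n = dataset.n_samples
    if n < 2:
        raise ValueError("LOOCV requires at least 2 samples")

    rows = []
    n_correct = 0
    n_total = 0
    n_errored = 0

    if cache:
        normed = minmax_normalize(dataset)
        d = distance_matrix(normed, metric=config.metric)
        dg, ds = config.bandwidths()
        w1 = similarity(d, dg, exponent=config.exponent)
        np.fill_diagonal(w1, 0.0 if config.diagonal_policy == "zero" else 1.0)
        infl = node_influence(WeightedGraph(dataset.sample_ids, w1, delta=dg)).values
        w2 = similarity(d, ds, exponent=config.exponent)
        np.fill_diagonal(w2, 0.0 if config.diagonal_policy == "zero" else 1.0)
        labels = np.array(dataset.labels, dtype=object)

        for i in range(n):
            classes = _fold_class_order(dataset.labels, skip=i)
            if len(classes) < len(set(dataset.labels)):
                n_errored += 1
                rows.append((dataset.sample_ids[i], dataset.labels[i], None, False, True))
                continue
            scores = {}
            for c in classes:
                mask = labels == c
                mask[i] = False
                wc = infl[mask]
                scores[c] = float(w2[i, mask] @ wc / wc.sum())
            pred = predict_label(scores, tie_break=config.tie_break, class_order=classes)
            ok = pred == dataset.labels[i]
            n_correct += ok
            n_total += 1
            rows.append((dataset.sample_ids[i], dataset.labels[i], pred, ok, False))
    else:
        for i in range(n):
            train = dataset.subset([j for j in range(n) if j != i])
            test = dataset.subset([i])
            try:
                result = _run_variant(train, test, config)
            except ValueError:
                n_errored += 1
                rows.append((dataset.sample_ids[i], dataset.labels[i], None, False, True))
                continue
            pred = result.predicted[0]
            ok = pred == dataset.labels[i]
            n_correct += ok
            n_total += 1
            rows.append((dataset.sample_ids[i], dataset.labels[i], pred, ok, False))

    if n_errored:
        warnings.warn(
            f"{n_errored} LOOCV fold(s) had an empty class and were excluded",
            stacklevel=2,
        )
    predictions = pd.DataFrame(
        rows, columns=["sample_id", "actual", "predicted", "correct", "errored"]
    )
    accuracy = n_correct / n_total if n_total else 0.0
    return EvaluationReport(
        protocol="loocv",
        n_correct=int(n_correct),
        n_total=n_total,
        accuracy=accuracy,
        predictions=predictions,
        config=config,
        n_errored_folds=n_errored,
    )


def holdout(train: ExpressionDataset, test: ExpressionDataset, config: NIMConfig) -> EvaluationReport:
    """Single train/test evaluation; the test set must be labeled."""
    if test.n_samples == 0:
        raise ValueError("empty test set")
    if test.labels is None or any(lb is None for lb in test.labels):
        raise ValueError("holdout evaluation requires labeled test samples")
    result = _run_variant(train, test, config)
    ok = [p == a for p, a in zip(result.predicted, test.labels)]
    predictions = pd.DataFrame(
        {
            "sample_id": test.sample_ids,
            "actual": test.labels,
            "predicted": result.predicted,
            "correct": ok,
            "errored": False,
        }
    )
    n_correct = int(sum(ok))
    return EvaluationReport(
        protocol="holdout",
        n_correct=n_correct,
        n_total=test.n_samples,
        accuracy=n_correct / test.n_samples,
        predictions=predictions,
        config=config,
    )


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    if lo <= 0 or step <= 0 or hi < lo:
        raise ValueError(f"invalid grid bounds: min={lo}, max={hi}, step={step}")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def grid_search(
    dataset: Optional[ExpressionDataset] = None,
    *,
    train: Optional[ExpressionDataset] = None,
    test: Optional[ExpressionDataset] = None,
    variant: str = "nim1",
    delta_min: float,
    delta_max: float,
    step: float,
    delta2_min: Optional[float] = None,
    delta2_max: Optional[float] = None,
    step2: Optional[float] = None,
    config: Optional[NIMConfig] = None,
) -> GridResult:
    """Sweep bandwidths and report the accuracy surface and its argmax.

    With ``dataset`` the protocol is LOOCV; with ``train``/``test`` it
    is holdout. For NIM2 the grid is the product of the delta1 axis
    (``delta_min..delta_max``) and the delta2 axis (defaulting to the
    same bounds).
    """
    if (dataset is None) == (train is None):
        raise ValueError("pass either dataset (LOOCV) or train+test (holdout)")
    base = config or NIMConfig(variant="nim1", delta=1.0)

    def evaluate(cfg: NIMConfig) -> float:
        if dataset is not None:
            return loocv(dataset, cfg).accuracy
        return holdout(train, test, cfg).accuracy

    axis1 = _axis(delta_min, delta_max, step)
    if variant == "nim1":
        acc = np.array(
            [
                evaluate(
                    NIMConfig(
                        variant="nim1",
                        delta=float(d),
                        metric=base.metric,
                        diagonal_policy=base.diagonal_policy,
                        exponent=base.exponent,
                        tie_break=base.tie_break,
                    )
                )
                for d in axis1
            ]
        )
        best = float(acc.max())
        points = [(float(axis1[i]),) for i in np.flatnonzero(acc == best)]
        return GridResult("nim1", axis1, None, acc, points, best)
    if variant != "nim2":
        raise ValueError(f"unknown variant {variant!r}")
    axis2 = _axis(
        delta_min if delta2_min is None else delta2_min,
        delta_max if delta2_max is None else delta2_max,
        step if step2 is None else step2,
    )
    acc = np.empty((len(axis1), len(axis2)))
    for i, d1 in enumerate(axis1):
        for j, d2 in enumerate(axis2):
            acc[i, j] = evaluate(
                NIMConfig(
                    variant="nim2",
                    delta1=float(d1),
                    delta2=float(d2),
                    metric=base.metric,
                    diagonal_policy=base.diagonal_policy,
                    exponent=base.exponent,
                    tie_break=base.tie_break,
                )
            )
    best = float(acc.max())
    points = [
        (float(axis1[i]), float(axis2[j]))
        for i, j in np.argwhere(acc == best)
    ]
    return GridResult("nim2", axis1, axis2, acc, points, best)
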