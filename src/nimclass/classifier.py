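"""The NIM1/NIM2 influence-weighted similarity classifiers.

Both classifiers are transductive: training and test samples are
jointly min-max normalized, embedded in one dense Gaussian similarity
graph, and the node-influence centrality is computed over that full
graph. Each training sample's influence weight measures how central it
is among *all* samples, labeled or not; a test sample is then assigned
to the class whose members are most similar to it on average, with
each member's similarity weighted by its influence:

    score(x_test, C) = sum_{x in C} Sim(x_test, x) w(x) / sum_{x in C} w(x)

NIM1 uses a single bandwidth ``delta`` for both the influence graph
and the scoring similarities; NIM2 decouples them into ``delta1``
(influence graph) and ``delta2`` (scoring), and reduces exactly to
NIM1 when ``delta1 == delta2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from nimclass.dataio import ExpressionDataset
from nimclass.graph import (
    DIAGONAL_POLICIES,
    EXPONENT_CONVENTIONS,
    METRICS,
    WeightedGraph,
    distance_matrix,
    similarity,
)
from nimclass.influence import InfluenceVector, node_influence
from nimclass.preprocess import minmax_normalize

TIE_BREAKS = ("first_class",)


@dataclass
class NIMConfig:
    """Classifier configuration.

    ``variant="nim1"`` needs ``delta``; ``variant="nim2"`` needs
    ``delta1`` (influence-graph bandwidth) and ``delta2`` (class-score
    bandwidth). Remaining fields select the distance metric, the
    diagonal policy of the similarity graph, the kernel exponent
    convention, and the tie-break rule for equal class scores.
    """

    variant: str = "nim1"
    delta: Optional[float] = None
    delta1: Optional[float] = None
    delta2: Optional[float] = None
    metric: str = "euclidean"
    diagonal_policy: str = "zero"
    exponent: str = "squared"
    tie_break: str = "first_class"

    def __post_init__(self):
        self.variant = self.variant.lower()
        if self.variant not in ("nim1", "nim2"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.diagonal_policy not in DIAGONAL_POLICIES:
            raise ValueError(f"unknown diagonal policy {self.diagonal_policy!r}")
        if self.exponent not in EXPONENT_CONVENTIONS:
            raise ValueError(f"unknown exponent convention {self.exponent!r}")
        if self.tie_break not in TIE_BREAKS:
            raise ValueError(f"unknown tie-break rule {self.tie_break!r}")
        for name, val in (("delta", self.delta), ("delta1", self.delta1),
                          ("delta2", self.delta2)):
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.variant == "nim1" and self.delta is None:
            raise ValueError("nim1 requires delta")
        if self.variant == "nim2" and (self.delta1 is None or self.delta2 is None):
            raise ValueError("nim2 requires delta1 and delta2")

    def bandwidths(self) -> tuple:
        """(influence-graph bandwidth, class-score bandwidth)."""
        if self.variant == "nim1":
            return self.delta, self.delta
        return self.delta1, self.delta2

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "NIMConfig":
        allowed = {f for f in cls.__dataclass_fields__}
        bad = set(mapping) - allowed
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**dict(mapping))


@dataclass
class PredictionResult:
    """Per-test-sample class scores and predicted labels."""

    test_sample_ids: list
    class_order: list
    scores: np.ndarray  # (n_test, n_classes), each in (0, 1]
    predicted: list

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)

    def class_scores(self, sample_id) -> dict:
        i = self.test_sample_ids.index(str(sample_id))
        return dict(zip(self.class_order, self.scores[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.test_sample_ids,
            columns=[f"score_{c}" for c in self.class_order],
        )
        df.index.name = "sample_id"
        df["predicted"] = self.predicted
        return df


def predict_label(class_scores: Mapping, tie_break: str = "first_class",
                  class_order: Optional[list] = None):
    """Argmax over class scores; exact ties go to the earliest class.

    ``class_order`` defaults to the mapping's own order.
    """
    if not class_scores:
        raise ValueError("empty class-score map")
    if tie_break not in TIE_BREAKS:
        raise ValueError(f"unknown tie-break rule {tie_break!r}")
    order = list(class_order) if class_order is not None else list(class_scores)
    best = order[0]
    for c in order[1:]:
        if class_scores[c] > class_scores[best]:
            best = c
    return best


def class_similarity(
    test_node,
    class_label,
    graph2: WeightedGraph,
    weights: InfluenceVector,
    train_labels: Mapping,
) -> float:
    """Influence-weighted mean similarity of a test node to a class.

    ``graph2`` holds the scoring similarities (the delta-graph for NIM1,
    the delta2-graph for NIM2); ``weights`` is the node-influence vector
    of the full graph; ``train_labels`` maps training node ids to class
    labels. Only training nodes enter the sum.
    """
    t = graph2.index_of(test_node)
    num = 0.0
    den = 0.0
    found = False
    for node_id, label in train_labels.items():
        if str(label) != str(class_label):
            continue
        found = True
        j = graph2.index_of(node_id)
        w = weights[node_id]
        num += graph2.weights[t, j] * w
        den += w
    if not found:
        raise ValueError(f"class {class_label!r} has no training samples")
    return num / den


def _validate_train_test(train: ExpressionDataset, test: ExpressionDataset):
    if train.labels is None or any(lb is None for lb in train.labels):
        raise ValueError("every training sample must be labeled")
    if train.feature_ids != test.feature_ids:
        raise ValueError("train and test feature ids differ")
    if test.n_samples == 0:
        raise ValueError("test set is empty")
    overlap = set(train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise ValueError(f"sample ids appear in both train and test: {sorted(overlap)[:3]}")
    classes = list(train.classes)
    present = set(lb for lb in train.labels)
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"declared classes with no training samples: {missing}")
    return classes


def _pipeline(
    train: ExpressionDataset,
    test: ExpressionDataset,
    delta_graph: float,
    delta_score: float,
    config: NIMConfig,
) -> PredictionResult:
    classes = _validate_train_test(train, test)
    n_train = train.n_samples

    combined = ExpressionDataset(
        sample_ids=list(train.sample_ids) + list(test.sample_ids),
        feature_ids=list(train.feature_ids),
        values=np.vstack([train.values, test.values]),
        labels=list(train.labels) + [None] * test.n_samples,
        split=["train"] * n_train + ["test"] * test.n_samples,
        classes=classes,
    )
    normed = minmax_normalize(combined)
    d = distance_matrix(normed, metric=config.metric)
    if combined.n_samples > 1 and np.all(d[~np.eye(len(d), dtype=bool)] == 0):
        warnings.warn("all samples are identical after normalization", stacklevel=3)

    w1 = similarity(d, delta_graph, exponent=config.exponent)
    np.fill_diagonal(w1, 0.0 if config.diagonal_policy == "zero" else 1.0)
    graph1 = WeightedGraph(combined.sample_ids, w1, delta=delta_graph)
    influence = node_influence(graph1)

    w2 = similarity(d, delta_score, exponent=config.exponent)
    np.fill_diagonal(w2, 0.0 if config.diagonal_policy == "zero" else 1.0)
    graph2 = WeightedGraph(combined.sample_ids, w2, delta=delta_score)

    train_labels = dict(zip(train.sample_ids, train.labels))
    scores = np.empty((test.n_samples, len(classes)))
    predicted = []
    for ti, sid in enumerate(test.sample_ids):
        for ci, c in enumerate(classes):
            scores[ti, ci] = class_similarity(sid, c, graph2, influence, train_labels)
        predicted.append(
            predict_label(
                dict(zip(classes, scores[ti])),
                tie_break=config.tie_break,
                class_order=classes,
            )
        )
    return PredictionResult(
        test_sample_ids=list(test.sample_ids),
        class_order=classes,
        scores=scores,
        predicted=predicted,
    )


def nim1(train: ExpressionDataset, test: ExpressionDataset,
         config: Optional[NIMConfig] = None, **kwargs) -> PredictionResult:
    """Classify test samples with a single bandwidth delta."""
    if config is None:
        config = NIMConfig(variant="nim1", **kwargs)
    if config.variant != "nim1":
        raise ValueError("config.variant must be 'nim1'")
    dg, ds = config.bandwidths()
    return _pipeline(train, test, dg, ds, config)


def nim2(train: ExpressionDataset, test: ExpressionDataset,
         config: Optional[NIMConfig] = None, **kwargs) -> PredictionResult:
    """Classify with separate influence (delta1) and scoring (delta2) bandwidths."""
    if config is None:
        config = NIMConfig(variant="nim2", **kwargs)
    if config.variant != "nim2":
        raise ValueError("config.variant must be 'nim2'")
    dg, ds = config.bandwidths()
    return _pipeline(train, test, dg, ds, config)
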