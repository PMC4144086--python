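"""Synthetic expression data in the microarray regime, and the six-node
worked-example network.

The generator emulates the data regime the classifiers target: many
features (thousands of genes), few samples (tens to a couple hundred),
2-7 classes, and unbalanced class sizes. Samples are drawn from
Gaussian class-conditional bumps: a small block of informative features
carries class-specific means whose pairwise distance is
``class_separation``; every feature (informative or not) carries
i.i.d. Gaussian noise of standard deviation ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from nimclass.dataio import ExpressionDataset
from nimclass.graph import WeightedGraph

#: the six-node example network: edges 1-2, 2-3, 2-4, 3-4, 4-5, 5-6
_EXAMPLE_EDGES = [(1, 2), (2, 3), (2, 4), (3, 4), (4, 5), (5, 6)]


def example_graph() -> WeightedGraph:
    """The six-node 0/1 worked-example graph (degrees 1, 3, 2, 3, 2, 1).

    Connected and non-bipartite (triangle 2-3-4), so its walk-ratio
    centrality converges; node 4's influence is ~0.2517.
    """
    a = np.zeros((6, 6))
    for i, j in _EXAMPLE_EDGES:
        a[i - 1, j - 1] = a[j - 1, i - 1] = 1.0
    return WeightedGraph(node_ids=[str(i) for i in range(1, 7)], weights=a)


@dataclass
class SynthSpec:
    """Parameters of the Gaussian class-bump generator.

    Defaults mirror a typical two-class tumor/normal microarray study:
    62 samples (22 vs 40), 2000 genes of which 50 are informative,
    unit noise, class means 5 noise-SDs apart.
    """

    n_classes: int = 2
    samples_per_class: Sequence[int] = (22, 40)
    n_features: int = 2000
    n_informative: int = 50
    class_separation: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0
    test_fraction: float = 0.0

    def __post_init__(self):
        self.samples_per_class = list(self.samples_per_class)
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError(
                f"samples_per_class has {len(self.samples_per_class)} entries "
                f"for {self.n_classes} classes"
            )
        if any(c < 1 for c in self.samples_per_class):
            raise ValueError("every class needs at least one sample")
        if not (0 < self.n_informative <= self.n_features):
            raise ValueError("need 0 < n_informative <= n_features")
        if self.class_separation <= 0 or self.noise_sd <= 0:
            raise ValueError("class_separation and noise_sd must be positive")
        if not 0 <= self.test_fraction < 1:
            raise ValueError("test_fraction must be in [0, 1)")


def _class_means(spec: SynthSpec) -> np.ndarray:
    """(n_classes, n_features) mean matrix.

    With n_informative >= n_classes the informative block is split into
    one group of features per class and each class mean is constant on
    its own group (a scaled simplex), so every pair of class means is
    exactly class_separation apart and every informative feature
    carries signal; otherwise the means are spread along the first
    informative feature with adjacent spacing class_separation.
    """
    mu = np.zeros((spec.n_classes, spec.n_features))
    if spec.n_informative >= spec.n_classes:
        groups = np.array_split(np.arange(spec.n_informative), spec.n_classes)
        for c, g in enumerate(groups):
            mu[c, g] = spec.class_separation / np.sqrt(2.0 * len(g))
    else:
        for c in range(spec.n_classes):
            mu[c, 0] = c * spec.class_separation
    return mu


def generate(spec: SynthSpec) -> ExpressionDataset:
    """Draw a labeled dataset from the spec; deterministic given the seed.

    Classes are named C1..Cn. With ``test_fraction > 0`` the last
    fraction of each class (rounded down, at least one sample kept for
    training) is flagged ``test``; otherwise all samples are ``train``.
    """
    rng = np.random.default_rng(spec.seed)
    mu = _class_means(spec)
    blocks = []
    labels = []
    split = []
    for c, n_c in enumerate(spec.samples_per_class):
        x = mu[c] + rng.normal(0.0, spec.noise_sd, size=(n_c, spec.n_features))
        blocks.append(x)
        labels += [f"C{c + 1}"] * n_c
        n_test = min(int(np.floor(spec.test_fraction * n_c)), n_c - 1)
        split += ["train"] * (n_c - n_test) + ["test"] * n_test
    values = np.vstack(blocks)
    n = values.shape[0]
    return ExpressionDataset(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        feature_ids=[f"g{j + 1}" for j in range(spec.n_features)],
        values=values,
        labels=labels,
        split=split,
        classes=[f"C{c + 1}" for c in range(spec.n_classes)],
    )
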