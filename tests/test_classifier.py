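import numpy as np
import pytest

from conftest import TEST_XY, TRAIN_LABELS, TRAIN_XY
from nimclass.classifier import (
    NIMConfig,
    class_similarity,
    nim1,
    nim2,
    predict_label,
)
from nimclass.dataio import ExpressionDataset
from nimclass.graph import WeightedGraph, similarity
from nimclass.influence import InfluenceVector
from nimclass.synth import SynthSpec, generate
from oracles import loop_nim


def _ds(values, labels=None, prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        sample_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        feature_ids=[f"g{j}" for j in range(values.shape[1])],
        values=values,
        labels=labels,
    )


class TestConfig:
    def test_nim1_requires_delta(self):
        with pytest.raises(ValueError, match="delta"):
            NIMConfig(variant="nim1")

    def test_nim2_requires_both_deltas(self):
        with pytest.raises(ValueError, match="delta1 and delta2"):
            NIMConfig(variant="nim2", delta1=1.0)

    @pytest.mark.parametrize("bad", [0.0, -2.0])
    def test_nonpositive_delta_rejected(self, bad):
        with pytest.raises(ValueError, match="positive"):
            NIMConfig(variant="nim1", delta=bad)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            NIMConfig.from_mapping({"variant": "nim1", "delta": 1.0, "sigma": 2})


class TestPredictLabel:
    def test_strict_max(self):
        assert predict_label({"C1": 0.3, "C2": 0.9}) == "C2"

    def test_tie_goes_to_earliest_class(self):
        assert predict_label({"C1": 0.5, "C2": 0.5}) == "C1"
        assert predict_label({"C1": 0.5, "C2": 0.5}, class_order=["C2", "C1"]) == "C2"

    def test_empty_map_errors(self):
        with pytest.raises(ValueError):
            predict_label({})

    def test_matches_linear_scan(self, rng):
        for _ in range(20):
            scores = {f"C{i}": float(rng.random()) for i in range(5)}
            best = None
            for c, s in scores.items():
                if best is None or s > scores[best]:
                    best = c
            assert predict_label(scores) == best


class TestClassSimilarity:
    def _setup(self, rng, n=5):
        w = rng.uniform(0.05, 1.0, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        ids = [f"n{i}" for i in range(n)]
        graph = WeightedGraph(ids, w)
        infl = rng.uniform(0.05, 1.0, size=n)
        infl /= infl.sum()
        weights = InfluenceVector(ids, infl)
        return graph, weights

    def test_single_member_class_weights_cancel(self, rng):
        graph, weights = self._setup(rng)
        got = class_similarity("n4", "A", graph, weights, {"n0": "A", "n1": "B"})
        assert got == pytest.approx(graph.weights[4, 0], abs=1e-15)

    def test_three_member_weighted_mean_oracle(self, rng):
        graph, weights = self._setup(rng)
        labels = {"n0": "A", "n1": "A", "n2": "A", "n3": "B"}
        num = sum(graph.weights[4, j] * weights.values[j] for j in range(3))
        den = sum(weights.values[j] for j in range(3))
        got = class_similarity("n4", "A", graph, weights, labels)
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_empty_class_errors(self, rng):
        graph, weights = self._setup(rng)
        with pytest.raises(ValueError, match="no training samples"):
            class_similarity("n4", "Z", graph, weights, {"n0": "A"})


class TestNim1:
    def test_coincident_test_sample_scores_one(self):
        # test point coincides with class-A's only training point and is
        # far from class B: score(A) = 1, prediction A
        train = _ds([[0.0, 0.0], [1.0, 1.0]], labels=["A", "B"])
        test = _ds([[0.0, 0.0]], prefix="t")
        res = nim1(train, test, delta=0.5)
        assert res.predicted == ["A"]
        assert res.class_scores("t0")["A"] == pytest.approx(1.0)
        assert res.class_scores("t0")["B"] < 1.0

    def test_label_equivariance(self, rng):
        values = rng.random((8, 3))
        labels = ["A", "A", "B", "B", "A", "B", "A", "B"]
        swapped = ["B" if lb == "A" else "A" for lb in labels]
        test = _ds(rng.random((3, 3)), prefix="t")
        r1 = nim1(_ds(values, labels), test, delta=1.0)
        r2 = nim1(_ds(values, swapped), test, delta=1.0)
        assert [
            {"A": "B", "B": "A"}[p] for p in r1.predicted
        ] == r2.predicted
        for sid in test.sample_ids:
            s1, s2 = r1.class_scores(sid), r2.class_scores(sid)
            assert s1["A"] == s2["B"] and s1["B"] == s2["A"]

    def test_scores_in_unit_interval(self, rng):
        train = _ds(rng.random((10, 4)), labels=["A", "B"] * 5)
        test = _ds(rng.random((4, 4)), prefix="t")
        res = nim1(train, test, delta=0.8)
        assert np.all(res.scores > 0) and np.all(res.scores <= 1)
        # predicted label attains the max score
        for i, p in enumerate(res.predicted):
            assert res.scores[i, res.class_order.index(p)] == res.scores[i].max()

    def test_full_pipeline_matches_loop_oracle(self, planar_split):
        train, test = planar_split
        res = nim1(train, test, delta=1.0)
        scores, predicted = loop_nim(TRAIN_XY, TRAIN_LABELS, TEST_XY, 1.0, 1.0)
        assert res.predicted == predicted == ["A", "B"]
        for i, sid in enumerate(test.sample_ids):
            for c in ("A", "B"):
                assert res.class_scores(sid)[c] == pytest.approx(
                    scores[i][c], abs=1e-12
                )

    def test_unlabeled_training_sample_rejected(self):
        train = _ds([[0.0], [1.0]], labels=["A", None])
        with pytest.raises(ValueError, match="labeled"):
            nim1(train, _ds([[0.5]], prefix="t"), delta=1.0)

    def test_declared_class_without_training_samples_rejected(self):
        train = ExpressionDataset(
            sample_ids=["a", "b"],
            feature_ids=["g0"],
            values=[[0.0], [1.0]],
            labels=["A", "A"],
            classes=["A", "B"],
        )
        with pytest.raises(ValueError, match="no training samples"):
            nim1(train, _ds([[0.5]], prefix="t"), delta=1.0)

    def test_identical_samples_flagged(self):
        train = _ds([[1.0], [1.0], [1.0]], labels=["A", "A", "B"])
        test = _ds([[1.0]], prefix="t")
        with pytest.warns(UserWarning, match="identical"):
            res = nim1(train, test, delta=1.0)
        assert res.predicted[0] == "A"  # tie broken to first class


class TestNim2:
    def test_equal_bandwidths_reduce_to_nim1(self, rng):
        # scores and labels agree bit-for-bit when delta1 == delta2
        for seed in range(10):
            ds = generate(
                SynthSpec(2, (4, 7), 30, 6, 3.0, 1.0, seed, test_fraction=0.3)
            )
            train, test = ds.train_test_split()
            delta = 0.5 + 0.2 * seed
            r1 = nim1(train, test, delta=delta)
            r2 = nim2(train, test, delta1=delta, delta2=delta)
            assert np.array_equal(r1.scores, r2.scores)
            assert r1.predicted == r2.predicted

    def test_large_delta2_flattens_scores(self, planar_split):
        train, test = planar_split
        res = nim2(train, test, delta1=1.0, delta2=1e9)
        np.testing.assert_allclose(res.scores, 1.0, atol=1e-12)
        assert res.predicted == ["A", "A"]  # ties -> first class

    def test_matches_loop_oracle(self, rng):
        ds = generate(SynthSpec(3, (4, 5, 3), 6, 3, 4.0, 1.0, 11, test_fraction=0.3))
        train, test = ds.train_test_split()
        res = nim2(train, test, delta1=0.5, delta2=2.0)
        scores, predicted = loop_nim(
            train.values.tolist(), train.labels, test.values.tolist(), 0.5, 2.0
        )
        assert res.predicted == predicted
        for i, sid in enumerate(test.sample_ids):
            for c in res.class_order:
                assert res.class_scores(sid)[c] == pytest.approx(
                    scores[i][c], abs=1e-12
                )

    def test_overlapping_sample_ids_rejected(self):
        train = _ds([[0.0], [1.0]], labels=["A", "B"])
        test = _ds([[0.5], [0.6]])  # same "s0"/"s1" ids
        with pytest.raises(ValueError, match="both train and test"):
            nim2(train, test, delta1=1.0, delta2=1.0)
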