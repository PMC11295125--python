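"""Split, augmentation, random forest, model selection, and bias machinery."""

import numpy as np
import pandas as pd
import pytest

import flowim as f
from flowim.classify import ConfusionMatrix, LabeledLibrary


def feature_library(n_per_class=60, seed=0, informative="minor_axis_length"):
    """Two Gaussian feature clouds separated along one feature."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls, mu in (("small", 3.0), ("large", 9.0)):
        for _ in range(n_per_class):
            row = {name: rng.normal(0, 1) for name in f.FEATURE_NAMES}
            row[informative] = rng.normal(mu, 0.5)
            rows.append(row)
            labels.append(cls)
    return LabeledLibrary(items=rows, labels=labels, classes=("small", "large"))


class TestTrainTestSplit:
    def test_1000_item_class_gets_150_test(self):
        lib = LabeledLibrary(items=list(range(1000)), labels=["a"] * 1000,
                             classes=("a",))
        out = f.train_test_split(lib, seed=1)
        assert int(np.sum(out.split == "test")) == 150
        assert int(np.sum(out.split == "train")) == 850

    def test_20_item_class_gets_3_test(self):
        lib = LabeledLibrary(items=list(range(20)), labels=["a"] * 20,
                             classes=("a",))
        out = f.train_test_split(lib, seed=1)
        assert int(np.sum(out.split == "test")) == 3

    def test_stratified_per_class(self):
        lib = LabeledLibrary(
            items=list(range(300)),
            labels=["a"] * 100 + ["b"] * 200,
            classes=("a", "b"),
        )
        out = f.train_test_split(lib, seed=2)
        labels = np.asarray(out.labels, dtype=object)
        assert int(np.sum((out.split == "test") & (labels == "a"))) == 15
        assert int(np.sum((out.split == "test") & (labels == "b"))) == 30

    def test_seed_determinism(self):
        lib = feature_library()
        a = f.train_test_split(lib, seed=5).split
        b = f.train_test_split(lib, seed=5).split
        c = f.train_test_split(lib, seed=6).split
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_train_test_disjoint_cover(self):
        out = f.train_test_split(feature_library(), seed=3)
        assert set(out.split) == {"train", "test"}
        assert len(out.subset("train")) + len(out.subset("test")) == len(out)

    def test_tiny_class_rejected(self):
        lib = LabeledLibrary(items=[1], labels=["a"], classes=("a",))
        with pytest.raises(ValueError):
            f.train_test_split(lib)


class TestAugment8Fold:
    def test_count_is_8n(self):
        rng = np.random.default_rng(0)
        crops = [rng.random((12, 12)) for _ in range(5)]
        assert len(f.augment_8fold(crops)) == 40

    def test_identity_included_and_orbit_closed(self):
        rng = np.random.default_rng(1)
        img = rng.random((10, 10))
        variants = f.augment_8fold([img])
        keys = {v.tobytes() for v in variants}
        assert img.tobytes() in keys
        assert len(keys) == 8  # generic image: all distinct
        # applying the transform set again stays inside the orbit
        again = {v.tobytes() for v in f.augment_8fold(variants)}
        assert again == keys

    def test_uniform_crop_collapses(self):
        variants = f.augment_8fold([np.full((6, 6), 0.5)])
        assert len({v.tobytes() for v in variants}) == 1

    def test_nonsquare_padded(self):
        out = f.augment_8fold([np.ones((4, 7))])
        assert all(v.shape == (7, 7) for v in out)


class TestRandomForest:
    def test_separable_clouds_perfect_accuracy(self):
        lib = f.train_test_split(feature_library(seed=4), seed=4)
        tr, te = lib.subset("train"), lib.subset("test")
        X = pd.DataFrame(tr.items)
        model, imp = f.train_random_forest(X, tr.labels, search_budget=3, seed=0)
        cm = f.evaluate(model, pd.DataFrame(te.items), te.labels, lib.classes)
        assert cm.overall_accuracy == 1.0

    def test_importances_sum_to_one_and_rank_informative_first(self):
        lib = feature_library(seed=5, informative="minor_axis_length")
        X = pd.DataFrame(lib.items)
        model, imp = f.train_random_forest(X, lib.labels, search_budget=0, seed=0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()
        assert imp.index[0] == "minor_axis_length"

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((10, 3)),
                         columns=list("abc"))
        with pytest.raises(ValueError):
            f.train_random_forest(X, ["x"] * 10, search_budget=0)


class TestConfusionMatrix:
    def test_row_sums_and_trace(self):
        y_true = ["a"] * 6 + ["b"] * 4
        y_pred = ["a"] * 5 + ["b"] + ["b"] * 3 + ["a"]
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, ("a", "b"))
        assert cm.counts.sum(axis=1).tolist() == [6, 4]
        assert cm.overall_accuracy == pytest.approx(0.8)
        assert cm.per_class_accuracy["a"] == pytest.approx(5 / 6)


class TestSelectModel:
    def _cm(self, acc_a, acc_b, n=100):
        ca = int(round(acc_a * n))
        cb = int(round(acc_b * n))
        counts = pd.DataFrame(
            [[ca, n - ca], [n - cb, cb]], index=["a", "b"], columns=["a", "b"]
        )
        return ConfusionMatrix(counts=counts)

    def test_single_candidate(self):
        assert f.select_model(["m"], [self._cm(0.9, 0.9)]) == 0

    def test_penalizes_interclass_variability(self):
        stable = self._cm(0.95, 0.95)        # acc .95, spread 0
        unstable = self._cm(1.0, 0.92)       # acc .96, spread .04
        assert f.select_model(["A", "B"], [stable, unstable]) == 0

    def test_tie_breaks_to_lower_index(self):
        cms = [self._cm(0.9, 0.9)] * 3
        assert f.select_model(list("xyz"), cms) == 0


class TestBias:
    def _flip_predictor(self, e12, e21, seed=0):
        rng = np.random.default_rng(seed)

        def predict(labels):
            labels = np.asarray(labels, dtype=object)
            out = labels.copy()
            r = rng.random(len(labels))
            out[(labels == "A") & (r < e12)] = "B"
            out[(labels == "B") & (r < e21)] = "A"
            return out

        return predict

    def test_perfect_classifier_zero_bias(self):
        mixtures = [
            (p, np.array(["A"] * int(p * 200) + ["B"] * (200 - int(p * 200))))
            for p in (0.0, 0.5, 1.0)
        ]
        curve = f.quantify_bias(lambda x: np.asarray(x), mixtures, "A")
        assert curve.bias == [0.0, 0.0, 0.0]

    def test_known_confusion_matches_closed_form(self):
        e12, e21 = 0.07, 0.02
        n = 20000
        predict = self._flip_predictor(e12, e21, seed=1)
        mixtures = [
            (p, np.array(["A"] * int(p * n) + ["B"] * (n - int(p * n))))
            for p in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        curve = f.quantify_bias(predict, mixtures, "A")
        for p, phat in zip(curve.true_proportions, curve.predicted_proportions):
            closed = p * (1 - e12) + (1 - p) * e21
            se = np.sqrt(max(closed * (1 - closed), 1e-9) / n)
            assert abs(phat - closed) <= 2 * se + 1e-12

    def test_monotone_in_true_proportion(self):
        e12, e21 = 0.1, 0.05
        preds = [p * (1 - e12) + (1 - p) * e21 for p in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(preds, preds[1:]))

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            f.quantify_bias(lambda x: x, [(0.5, [])], "A")


class TestCorrectBias:
    def test_identity_confusion_unchanged(self):
        p = np.array([0.3, 0.7])
        out = f.correct_bias(p, np.eye(2))
        assert np.allclose(out, p)

    def test_exact_inversion_noise_free(self):
        C = np.array([[0.93, 0.07], [0.02, 0.98]])
        p = np.array([0.3, 0.7])
        q = C.T @ p
        assert np.allclose(f.correct_bias(q, C), p, atol=1e-6)

    def test_output_is_probability_vector(self):
        C = np.array([[0.9, 0.1], [0.2, 0.8]])
        out = f.correct_bias([0.55, 0.45], C)
        assert out.sum() == pytest.approx(1.0)
        assert (out >= 0).all()

    def test_singular_confusion_rejected(self):
        with pytest.raises(ValueError):
            f.correct_bias([0.5, 0.5], np.array([[0.5, 0.5], [0.5, 0.5]]))
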