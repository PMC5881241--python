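"""Classification: features, weighted margins, nested CV, OVO voting, metrics."""

import numpy as np
import pytest

import oddballerp as ob
from oddballerp.classify import confusion_counts, grid_search_C, ovo_predict

from conftest import make_epochs


def pseudo_epochs(rng, n_trials=20, n_channels=8):
    data = rng.normal(size=(n_trials, n_channels, 25))
    return make_epochs(data, rate=25.0, t0=0.0,
                       labels=tuple(f"xd{i+1}" for i in range(n_channels)))


class TestFeatures:
    def test_eight_pseudo_channels_give_48(self, rng):
        fm = ob.extract_features(pseudo_epochs(rng, n_channels=8), "early")
        assert fm.n_features == 48

    def test_one_pseudo_channel_gives_6(self, rng):
        fm = ob.extract_features(pseudo_epochs(rng, n_channels=1), "late")
        assert fm.n_features == 6

    def test_late_window_samples_indices_15_to_20(self, rng):
        ep = pseudo_epochs(rng, n_trials=2, n_channels=1)
        fm = ob.extract_features(ep, (600.0, 800.0))
        np.testing.assert_array_equal(fm.X, ep.data[:, 0, 15:21])
        times = [t for _, t in fm.provenance]
        assert times == [600.0, 640.0, 680.0, 720.0, 760.0, 800.0]

    def test_channel_major_flattening(self, rng):
        ep = pseudo_epochs(rng, n_trials=1, n_channels=2)
        fm = ob.extract_features(ep, "early")
        np.testing.assert_array_equal(fm.X[0, :6], ep.data[0, 0, 10:16])
        np.testing.assert_array_equal(fm.X[0, 6:], ep.data[0, 1, 10:16])


class TestNormalization:
    def test_train_standardised(self, rng):
        fm = ob.extract_features(pseudo_epochs(rng, 50, 2), "early")
        stats = ob.fit_norm(fm)
        Z = ob.apply_norm(fm, stats)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_scale_fallback(self):
        X = np.column_stack([np.full(10, 4.0), np.arange(10.0)])
        stats = ob.fit_norm(X)
        assert stats.scale[0] == 1.0
        assert ob.apply_norm(X, stats)[:, 0] == pytest.approx(0.0)

    def test_test_set_shift_preserved(self, rng):
        X = rng.normal(size=(40, 3))
        stats = ob.fit_norm(X)
        shift = ob.apply_norm(X + 2.0, stats) - ob.apply_norm(X, stats)
        np.testing.assert_allclose(
            shift, np.broadcast_to(2.0 / stats.scale, shift.shape), atol=1e-9)


class TestWeightedLinear:
    def test_separable_toy_zero_training_error(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [3.0, 0.0], [4.0, 0.0]])
        y = np.array(["standard", "standard", "target", "target"], dtype=object)
        model = ob.train_weighted_linear(X, y, C=1.0)
        assert list(model.predict(X)) == list(y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ob.train_weighted_linear(np.zeros((3, 2)),
                                     np.array(["a"] * 3, dtype=object), 1.0)

    def test_minority_weight_improves_minority_recall(self, rng):
        """1:12 imbalance with weight 2 on the minority raises its TPR."""
        def sample(n_min, n_maj, rs):
            Xm = rs.normal(loc=1.2, size=(n_min, 4))
            XM = rs.normal(loc=0.0, size=(n_maj, 4))
            X = np.vstack([Xm, XM])
            y = np.array(["target"] * n_min + ["standard"] * n_maj, dtype=object)
            return X, y

        Xtr, ytr = sample(30, 360, np.random.default_rng(1))
        Xte, yte = sample(500, 500, np.random.default_rng(2))
        tprs = {}
        for name, wm in [("weighted", {"target": 2.0, "standard": 1.0}),
                         ("flat", {"target": 1.0, "standard": 1.0})]:
            model = ob.train_weighted_linear(Xtr, ytr, 0.1, wm)
            cm = confusion_counts(yte, model.predict(Xte), ["target", "standard"])
            tprs[name] = ob.metrics(cm, ["target", "standard"])["tpr"]["target"]
        assert tprs["weighted"] >= tprs["flat"]

    def test_duplicated_trials_same_predictions(self, rng):
        X = np.vstack([rng.normal(loc=1.5, size=(20, 3)),
                       rng.normal(loc=-1.5, size=(20, 3))])
        y = np.array(["target"] * 20 + ["standard"] * 20, dtype=object)
        grid = rng.normal(size=(200, 3))
        m1 = ob.train_weighted_linear(X, y, 1.0)
        m2 = ob.train_weighted_linear(np.vstack([X, X]),
                                      np.concatenate([y, y]), 1.0)
        # the weighted objective is (near-)invariant to duplication; allow the
        # solver a few flips right at the margin
        agreement = np.mean(m1.predict(grid) == m2.predict(grid))
        assert agreement >= 0.98

    def test_default_weight_map_rules(self):
        labels = np.array(["target"] * 60 + ["standard"] * 720, dtype=object)
        assert ob.default_weight_map(labels, ("target", "standard")) == {
            "target": 2.0, "standard": 1.0}
        near = np.array(["target"] * 60 + ["deviant"] * 55, dtype=object)
        assert ob.default_weight_map(near, ("target", "deviant")) == {
            "target": 1.0, "deviant": 1.0}


class TestGridSearch:
    def test_single_value_grid(self, rng):
        X = rng.normal(size=(50, 2))
        y = np.array(["a", "b"] * 25, dtype=object)
        assert grid_search_C(X, y, grid=[1e-3]) == 1e-3

    def test_degenerate_features_tie_returns_largest(self):
        X = np.zeros((40, 2))
        y = np.array(["a", "b"] * 20, dtype=object)
        assert grid_search_C(X, y) == 1.0

    def test_separable_data_ties_resolve_to_one(self, rng):
        X = np.vstack([rng.normal(loc=8, size=(25, 2)),
                       rng.normal(loc=-8, size=(25, 2))])
        y = np.array(["a"] * 25 + ["b"] * 25, dtype=object)
        assert grid_search_C(X, y) == 1.0


class TestMetrics:
    def test_printed_multiclass_worked_examples(self):
        """Mean of per-class TPRs reproduces the printed multiclass bACC."""
        classes = ["standard", "target", "deviant"]
        for tprs, expected in [((0.93, 0.77, 0.50), 0.73),
                               ((0.88, 0.71, 0.54), 0.71),
                               ((0.91, 0.69, 0.42), 0.67)]:
            counts = np.array([7000, 463, 628], dtype=float)
            cm = np.diag(tprs * counts)
            off = counts - np.diag(cm)
            cm[0, 1] = off[0]
            cm[1, 0] = off[1]
            cm[2, 0] = off[2]
            m = ob.metrics(cm, classes)
            assert round(m["bacc"], 2) == expected

    def test_acc_from_printed_counts(self):
        """ACC recomputed from TPRs and pooled trial counts gives 0.89."""
        counts = np.array([7000, 463, 628], dtype=float)
        tprs = np.array([0.93, 0.77, 0.50])
        correct = float(np.sum(tprs * counts))
        acc = correct / counts.sum()
        assert abs(acc - 0.89) <= 0.01

    def test_perfect_confusion(self):
        m = ob.metrics(np.diag([10, 20, 30]), ["a", "b", "c"])
        assert m["bacc"] == 1.0 and m["acc"] == 1.0

    def test_binary_bacc_is_mean_of_tpr_tnr(self):
        cm = np.array([[8, 2], [30, 70]])
        m = ob.metrics(cm, ["target", "standard"])
        assert m["bacc"] == pytest.approx((0.8 + 0.7) / 2)
        assert m["tnr"] == pytest.approx(0.7)

    def test_bacc_invariant_to_class_subsampling_acc_not(self):
        cm = np.array([[90, 10], [40, 160]], dtype=float)
        m = ob.metrics(cm, ["pos", "neg"])
        sub = cm.copy()
        sub[1] = sub[1] / 4.0  # shrink the negative class, rates fixed
        m_sub = ob.metrics(sub, ["pos", "neg"])
        assert m_sub["bacc"] == pytest.approx(m["bacc"])
        assert m_sub["acc"] != pytest.approx(m["acc"])


class TestOvo:
    def _model(self, w, b, pair):
        from oddballerp.classify import ClassifierModel

        return ClassifierModel(weights=np.asarray(w, float), bias=float(b),
                               classes=pair, C=1.0, weight_map={})

    def test_unanimous_vote(self):
        # all three models favour "target" on x = [1]
        models = [
            self._model([1.0], 0.0, ("standard", "target")),
            self._model([1.0], 0.0, ("deviant", "target")),
            self._model([1.0], 0.0, ("deviant", "standard")),
        ]
        pred = ovo_predict(models, np.array([[1.0]]),
                           ["standard", "target", "deviant"])
        assert pred[0] == "target"

    def test_circular_tie_resolved_by_summed_scores(self):
        # one vote each; summed signed confidences decide
        models = [
            self._model([1.0], 0.0, ("standard", "target")),   # +x → target (score x)
            self._model([1.0], 0.0, ("target", "deviant")),    # +x → deviant
            self._model([1.0], 0.0, ("deviant", "standard")),  # +x → standard
        ]
        x = np.array([[2.0]])
        # votes: target 1, deviant 1, standard 1
        # confidences: target: +2 (m1) −2 (m2) = 0; deviant: +2 (m2) −2 (m3) = 0;
        # standard: −2 (m1) +2 (m3) = 0 → full tie → lexicographic: "deviant"
        assert ovo_predict(models, x, ["standard", "target", "deviant"])[0] == "deviant"
        # break the symmetry: make the t/st model much more confident
        models[0] = self._model([3.0], 0.0, ("standard", "target"))
        assert ovo_predict(models, x, ["standard", "target", "deviant"])[0] == "target"

    def test_confusion_conserves_trials(self, rng):
        y_true = rng.choice(["a", "b", "c"], size=50)
        y_pred = rng.choice(["a", "b", "c"], size=50)
        assert confusion_counts(y_true, y_pred, ["a", "b", "c"]).sum() == 50


class TestCrossValidation:
    def _oracle_epochs(self, rng, n_min=30, n_maj=120, separation=4.0):
        """Pseudo-epochs whose window samples perfectly separate the classes."""
        labels = np.array(["target"] * n_min + ["standard"] * n_maj, dtype=object)
        data = rng.normal(size=(n_min + n_maj, 2, 25))
        bump = np.zeros(25)
        bump[10:16] = separation
        data[:n_min, 0] += bump
        ep = make_epochs(data, rate=25.0, labels=("c1", "c2"),
                         trial_labels=labels)
        return ep

    def test_oracle_feature_gives_perfect_bacc(self, rng):
        ep = self._oracle_epochs(rng, separation=50.0)
        res = ob.crossvalidate(ep, pair=("target", "standard"), window="early",
                               n_components=1, n_repetitions=1, n_folds=5, seed=0)
        assert res.bacc > 0.99

    def test_permuted_labels_give_chance(self, rng):
        ep = self._oracle_epochs(rng, n_min=60, n_maj=120, separation=3.0)
        ep.labels = rng.permutation(ep.labels)
        res = ob.crossvalidate(ep, pair=("target", "standard"), window="early",
                               n_components=1, n_repetitions=2, n_folds=5, seed=1)
        assert abs(res.bacc - 0.5) < 0.12

    def test_same_seed_reproduces_exactly(self, rng):
        ep = self._oracle_epochs(rng)
        kwargs = dict(pair=("target", "standard"), window="early",
                      n_components=1, n_repetitions=2, n_folds=4, seed=9)
        r1 = ob.crossvalidate(ep, **kwargs)
        r2 = ob.crossvalidate(ep, **kwargs)
        assert r1.bacc == r2.bacc and r1.acc == r2.acc and r1.tpr == r2.tpr

    def test_too_few_trials_to_stratify(self, rng):
        ep = self._oracle_epochs(rng, n_min=5, n_maj=100)
        with pytest.raises(ValueError, match="stratify"):
            ob.crossvalidate(ep, pair=("target", "standard"), n_folds=10)

    def test_multiclass_chance_on_permuted_labels(self, rng):
        labels = np.array(["standard"] * 120 + ["target"] * 30 + ["deviant"] * 30,
                          dtype=object)
        data = rng.normal(size=(180, 2, 25))
        ep = make_epochs(data, rate=25.0, labels=("c1", "c2"), trial_labels=labels)
        res = ob.multiclass_ovo(ep, window="early", n_components=1,
                                n_repetitions=1, n_folds=5, seed=2)
        assert abs(res.bacc - 1 / 3) < 0.15
        assert res.kind == "multiclass"


class TestTransfer:
    def test_degenerate_transfer_matches_resubstitution(self, rng):
        labels = np.array(["target"] * 40 + ["standard"] * 160, dtype=object)
        data = rng.normal(size=(200, 2, 25))
        data[:40, 0, 10:16] += 6.0
        ep = make_epochs(data, rate=25.0, labels=("c1", "c2"), trial_labels=labels)
        res = ob.transfer_evaluate(ep, ep, pair=("target", "standard"),
                                   window="early", n_components=1, seed=0)
        assert res.bacc > 0.95  # near-separable: resubstitution is near-perfect

    def test_shared_structure_transfers_above_chance(self, rng):
        def condition(shift):
            labels = np.array(["target"] * 40 + ["standard"] * 160, dtype=object)
            data = rng.normal(size=(200, 2, 25))
            data[:40, 0, 10:16] += 4.0
            data[:, 1] += shift  # condition-specific nuisance on the other channel
            return make_epochs(data, rate=25.0, labels=("c1", "c2"),
                               trial_labels=labels)

        res = ob.transfer_evaluate(condition(0.0), condition(2.0),
                                   pair=("target", "standard"), window="early",
                                   n_components=1, seed=0)
        assert res.bacc > 0.8

    def test_direction_recorded_in_fingerprint(self, rng):
        labels = np.array(["target"] * 30 + ["standard"] * 90, dtype=object)
        a = make_epochs(rng.normal(size=(120, 1, 25)), rate=25.0,
                        labels=("c1",), trial_labels=labels)
        b = make_epochs(rng.normal(size=(120, 1, 25)), rate=25.0,
                        labels=("c1",), trial_labels=labels)
        a.condition, b.condition = "simple", "dual"
        r_ab = ob.transfer_evaluate(a, b, pair=("target", "standard"),
                                    window="early", n_components=1)
        r_ba = ob.transfer_evaluate(b, a, pair=("target", "standard"),
                                    window="early", n_components=1)
        assert r_ab.config["transfer"] == "simple->dual"
        assert r_ba.config["transfer"] == "dual->simple"
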