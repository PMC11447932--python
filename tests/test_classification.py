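import numpy as np
import pandas as pd
import pytest

from pepperhsi.classification import (EvaluationReport,
                                      GradientBoostedTileClassifier,
                                      ModelConfig, SplitSpec,
                                      classification_report,
                                      confusion_matrix, evaluate,
                                      grid_search, predict_image,
                                      split_scenes, train_classifier)


def _make_manifest(n_per_class):
    rows = []
    for cls in ("UC", "MP", "FO"):
        for i in range(n_per_class):
            rows.append({"scene_id": f"{cls}_{i}", "class": cls})
    return pd.DataFrame(rows)


class TestSplitScenes:
    def test_seventy_thirty_per_class(self):
        train, test = split_scenes(_make_manifest(10), SplitSpec(seed=0))
        assert len(train) == 21 and len(test) == 9
        for cls in ("UC", "MP", "FO"):
            assert sum(s.startswith(cls) for s in train) == 7
            assert sum(s.startswith(cls) for s in test) == 3

    def test_deterministic_and_disjoint(self):
        m = _make_manifest(7)
        a = split_scenes(m, SplitSpec(seed=5))
        b = split_scenes(m, SplitSpec(seed=5))
        assert a == b
        assert not set(a[0]) & set(a[1])
        assert set(a[0]) | set(a[1]) == set(m["scene_id"])

    def test_tiny_class_rejected(self):
        m = pd.DataFrame({"scene_id": ["a", "b", "c"],
                          "class": ["UC", "UC", "MP"]})
        with pytest.raises(ValueError):
            split_scenes(m)


def _toy_table(n_scenes_per_class=6, tiles_per_scene=5, sep=3.0, seed=0,
               classes=("UC", "MP", "FO")):
    """Linearly separable toy features: class k centered at k*sep."""
    rng = np.random.default_rng(seed)
    rows = []
    for k, cls in enumerate(classes):
        for s in range(n_scenes_per_class):
            for t in range(tiles_per_scene):
                rows.append({
                    "scene_id": f"{cls}_{s}", "class": cls,
                    "tile_row": t, "tile_col": 0, "leaf_fraction": 1.0,
                    "f_0001": k * sep + rng.normal(0, 0.2),
                    "f_0002": rng.normal(0, 1.0),
                })
    return pd.DataFrame(rows)


class TestClassifier:
    def test_separable_training_accuracy_is_one(self):
        table = _toy_table()
        model = train_classifier(table)
        X = table[["f_0001", "f_0002"]].to_numpy()
        assert (model.predict(X) == table["class"]).mean() == 1.0

    def test_probabilities_sum_to_one(self):
        table = _toy_table()
        model = train_classifier(table)
        proba = model.predict_proba(table[["f_0001", "f_0002"]].to_numpy())
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_single_class_rejected(self):
        table = _toy_table(classes=("UC",))
        with pytest.raises(ValueError):
            train_classifier(table)

    def test_reproducible_under_seed(self):
        table = _toy_table()
        a = train_classifier(table, ModelConfig(seed=3))
        b = train_classifier(table, ModelConfig(seed=3))
        X = table[["f_0001", "f_0002"]].to_numpy()
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_class_order_is_canonical(self):
        model = train_classifier(_toy_table())
        assert list(model.classes_) == ["UC", "MP", "FO"]

    def test_sklearn_get_set_params(self):
        clf = GradientBoostedTileClassifier(n_trees=7)
        assert clf.get_params()["n_trees"] == 7
        clf.set_params(max_depth=3)
        assert clf.max_depth == 3

    def test_shuffled_labels_give_chance_accuracy(self):
        """Permutation null: with labels shuffled, held-out image accuracy
        averages ~1/k over repetitions."""
        rng = np.random.default_rng(12)
        accs = []
        for rep in range(8):
            table = _toy_table(n_scenes_per_class=8, seed=rep)
            perm = rng.permutation(len(table))
            table = table.assign(
                **{"class": table["class"].to_numpy()[perm]})
            # relabel whole scenes to keep scene-consistent labels
            scene_lab = table.groupby("scene_id")["class"].first()
            table["class"] = table["scene_id"].map(scene_lab)
            manifest = table.groupby("scene_id", as_index=False)[
                "class"].first()
            try:
                train_ids, test_ids = split_scenes(
                    manifest, SplitSpec(seed=rep))
                model = train_classifier(
                    table[table["scene_id"].isin(train_ids)],
                    ModelConfig(seed=rep))
                rep_report = evaluate(
                    model, table[table["scene_id"].isin(test_ids)])
                accs.append(rep_report.accuracy)
            except ValueError:
                continue  # degenerate shuffle (single-class training set)
        assert 0.1 < np.mean(accs) < 0.6  # chance is 1/3


class TestGridSearch:
    def test_single_config_returned(self):
        table = _toy_table()
        cfg = ModelConfig(n_trees=10, max_depth=2)
        assert grid_search(table, [cfg], k_folds=2) == cfg

    def test_tie_breaks_toward_smaller_model(self):
        """Equal-loss configurations resolve to fewer trees, then smaller
        depth, then grid order."""
        from pepperhsi.classification import _select_best
        grid = [ModelConfig(n_trees=50, max_depth=4),
                ModelConfig(n_trees=20, max_depth=4),
                ModelConfig(n_trees=20, max_depth=2)]
        assert _select_best(grid, [0.5, 0.5, 0.5]).max_depth == 2
        assert _select_best(grid, [0.5, 0.5, 0.5]).n_trees == 20
        assert _select_best(grid, [0.1, 0.5, 0.5]).n_trees == 50
        grid2 = [ModelConfig(n_trees=20, max_depth=4, seed=1),
                 ModelConfig(n_trees=20, max_depth=4, seed=2)]
        assert _select_best(grid2, [0.5, 0.5]).seed == 1

    def test_selects_lowest_cv_loss(self):
        """The selected config attains the minimal cross-validated loss on
        clearly separable data (bigger model wins over a one-tree stump)."""
        table = _toy_table()
        grid = [ModelConfig(n_trees=1, max_depth=1,
                            learning_rate=0.01),
                ModelConfig(n_trees=50, max_depth=4)]
        best = grid_search(table, grid, k_folds=2)
        assert best.n_trees == 50

    def test_deterministic(self):
        table = _toy_table()
        grid = [ModelConfig(n_trees=10), ModelConfig(n_trees=20)]
        assert grid_search(table, grid, k_folds=2, seed=4) == \
            grid_search(table, grid, k_folds=2, seed=4)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(_toy_table(), [])


class TestPredictImage:
    def _unanimous_model(self):
        model = train_classifier(_toy_table(sep=50.0))
        return model

    def test_unanimous_tiles(self):
        model = self._unanimous_model()
        table = _toy_table(sep=50.0)
        tiles = table[table["scene_id"] == "MP_0"]
        label, proba = predict_image(model, tiles)
        assert label == "MP"
        assert proba[list(model.classes_).index("MP")] > 0.9

    def test_tie_resolves_to_uc(self):
        """Mean probability (0.5, 0.5, 0) ties between UC and MP -> UC."""
        model = self._unanimous_model()

        class Stub:
            classes_ = model.classes_
            def predict_proba(self, X):
                return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        label, proba = predict_image(Stub(), np.zeros((2, 2)))
        assert label == "UC"
        np.testing.assert_allclose(proba, [0.5, 0.5, 0.0])

    def test_single_tile_image(self):
        model = self._unanimous_model()
        table = _toy_table(sep=50.0)
        tiles = table[table["scene_id"] == "FO_0"].iloc[:1]
        label, _ = predict_image(model, tiles)
        assert label == "FO"

    def test_zero_tiles_rejected(self):
        with pytest.raises(ValueError):
            predict_image(self._unanimous_model(), np.zeros((0, 2)))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = ["UC", "MP", "FO", "UC"]
        cm = confusion_matrix(y, y, ("UC", "MP", "FO"))
        assert cm.sum() == 4
        assert np.all(cm == np.diag(np.diag(cm)))

    def test_antidiagonal(self):
        cm = confusion_matrix(["UC", "MP"], ["MP", "UC"], ("UC", "MP"))
        np.testing.assert_array_equal(cm, [[0, 1], [1, 0]])

    def test_row_sums_are_supports(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(["UC", "MP", "FO"], size=60)
        y_pred = rng.choice(["UC", "MP", "FO"], size=60)
        cm = confusion_matrix(y_true, y_pred, ("UC", "MP", "FO"))
        for i, cls in enumerate(("UC", "MP", "FO")):
            assert cm[i].sum() == (y_true == cls).sum()


class TestClassificationReport:
    def test_two_class_mp_block(self):
        """Confusion matrix consistent with the published two-class
        aphid-vs-control results (supports 32/32)."""
        r = classification_report(np.array([[26, 6], [3, 29]]),
                                  ("UC", "MP")).rounded()
        assert r["classes"]["UC"] == {"precision": 0.90, "recall": 0.81,
                                      "f1": 0.85, "support": 32}
        assert r["classes"]["MP"] == {"precision": 0.83, "recall": 0.91,
                                      "f1": 0.87, "support": 32}
        assert r["accuracy"] == 0.86
        assert r["macro_avg"] == {"precision": 0.86, "recall": 0.86,
                                  "f1": 0.86}

    def test_two_class_fo_block(self):
        r = classification_report(np.array([[30, 0], [5, 25]]),
                                  ("UC", "FO")).rounded()
        assert r["classes"]["UC"] == {"precision": 0.86, "recall": 1.00,
                                      "f1": 0.92, "support": 30}
        assert r["classes"]["FO"] == {"precision": 1.00, "recall": 0.83,
                                      "f1": 0.91, "support": 30}
        assert r["accuracy"] == 0.92

    def test_three_class_leaf_block(self):
        cm = np.array([[26, 2, 3], [1, 30, 0], [2, 0, 29]])
        r = classification_report(cm, ("UC", "FO", "MP")).rounded()
        assert r["accuracy"] == 0.91
        assert r["classes"]["UC"]["precision"] == 0.90
        assert r["classes"]["UC"]["recall"] == 0.84
        assert r["classes"]["FO"]["precision"] == 0.94
        assert r["classes"]["FO"]["recall"] == 0.97
        assert r["classes"]["MP"]["precision"] == 0.91
        assert r["classes"]["MP"]["recall"] == 0.94

    def test_diagonal_matrix_all_ones(self):
        for support in ([5, 5, 5], [3, 17, 2]):
            r = classification_report(np.diag(support), ("UC", "FO", "MP"))
            np.testing.assert_allclose(r.precision, 1.0)
            np.testing.assert_allclose(r.recall, 1.0)
            np.testing.assert_allclose(r.f1, 1.0)
            assert r.accuracy == 1.0

    def test_macro_equals_weighted_at_equal_supports(self):
        rng = np.random.default_rng(8)
        cm = rng.integers(1, 20, size=(3, 3))
        # force equal row sums
        cm = cm + np.diag(cm.sum(axis=1).max() - cm.sum(axis=1))
        r = classification_report(cm, ("UC", "FO", "MP"))
        for key in ("precision", "recall", "f1"):
            assert r.macro_avg[key] == pytest.approx(r.weighted_avg[key])

    def test_matches_sklearn(self):
        """Cross-check against sklearn's implementation of the same
        metrics on random predictions."""
        from sklearn.metrics import (accuracy_score,
                                     precision_recall_fscore_support)
        rng = np.random.default_rng(21)
        y_true = rng.choice(["UC", "MP", "FO"], size=200)
        y_pred = rng.choice(["UC", "MP", "FO"], size=200)
        order = ("UC", "MP", "FO")
        cm = confusion_matrix(y_true, y_pred, order)
        r = classification_report(cm, order)
        p, rec, f1, sup = precision_recall_fscore_support(
            y_true, y_pred, labels=list(order), zero_division=0)
        np.testing.assert_allclose(r.precision, p)
        np.testing.assert_allclose(r.recall, rec)
        np.testing.assert_allclose(r.f1, f1)
        np.testing.assert_array_equal(r.support, sup)
        assert r.accuracy == pytest.approx(accuracy_score(y_true, y_pred))

    def test_zero_column_precision_is_zero(self):
        r = classification_report(np.array([[4, 0], [2, 0]]), ("UC", "MP"))
        assert r.precision[1] == 0.0
        assert r.f1[1] == 0.0

    def test_rounding_is_half_up(self):
        # 0.845 -> 0.85 under half-up (banker's rounding would give 0.84)
        from pepperhsi.classification import _round2
        assert _round2(0.845) == 0.85
        assert _round2(0.125) == 0.13

    def test_report_text_renders(self):
        r = classification_report(np.diag([3, 3]), ("UC", "MP"))
        text = r.to_text()
        assert "precision" in text and "UC" in text and "1.00" in text
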