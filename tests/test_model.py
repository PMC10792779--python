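"""Label adjudication, splitting, hyperparameter search, training, metrics."""

import itertools

import numpy as np
import pytest

import svjudge as sj
from svjudge.features import FeatureMatrix
from svjudge.model import SearchSpace, cv_score


class TestAdjudication:
    def test_any_dissent_is_false_positive_over_all_small_multisets(self):
        for size in (2, 3, 4):
            for combo in itertools.product(["TP", "FP"], repeat=size):
                expected = "TP" if all(c == "TP" for c in combo) else "FP"
                assert sj.adjudicate_labels(list(combo)) == expected

    def test_single_reviewer_insufficient(self):
        with pytest.raises(ValueError, match="insufficient review"):
            sj.adjudicate_labels(["TP"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sj.adjudicate_labels(["TP", "maybe"])


class TestSplit:
    def test_1131_items_give_904_train_227_test(self):
        data = list(range(1131))
        labels = [i % 5 < 2 for i in data]  # ~38:62 mix
        train, test = sj.split_dataset(data, seed=0, labels=labels)
        assert (len(train), len(test)) == (904, 227)
        assert sorted(train + test) == data

    def test_five_items_give_4_1(self):
        train, test = sj.split_dataset(list(range(5)), seed=1)
        assert (len(train), len(test)) == (4, 1)

    def test_partitions_disjoint_and_exhaustive(self):
        data = list(range(100))
        train, test = sj.split_dataset(data, seed=3)
        assert set(train) | set(test) == set(data)
        assert not set(train) & set(test)

    def test_train_membership_frequency_near_four_fifths(self):
        hits = 0
        n_seeds = 400
        for seed in range(n_seeds):
            train, _ = sj.split_dataset(list(range(50)), seed=seed)
            hits += 17 in train
        freq = hits / n_seeds
        # binomial(400, 0.8): 3 SD band
        assert abs(freq - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n_seeds)

    def test_stratified_split_preserves_class_mix(self):
        labels = [1] * 40 + [0] * 60
        train, test = sj.split_dataset(list(range(100)), seed=5, labels=labels)
        train_pos = sum(labels[i] for i in train)
        assert train_pos == 32  # 0.8 * 40 exactly

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            sj.split_dataset([1, 2, 3])


class TestMetrics:
    def test_printed_fusion_recall_values(self):
        # 76/77, 6/7 and 3/3 confirmed fusions recovered
        r_alk = sj.compute_metrics(sj.ConfusionMatrix(TP=76, FP=0, TN=0, FN=1)).recall
        r_ret = sj.compute_metrics(sj.ConfusionMatrix(TP=6, FP=0, TN=0, FN=1)).recall
        r_ros1 = sj.compute_metrics(sj.ConfusionMatrix(TP=3, FP=0, TN=0, FN=0)).recall
        assert round(100 * r_alk, 2) == 98.70
        assert round(100 * r_ret, 2) == 85.71
        assert 100 * r_ros1 == 100.0

    def test_perfect_classifier_all_ones(self):
        m = sj.compute_metrics(sj.ConfusionMatrix(TP=10, FP=0, TN=10, FN=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_hand_arithmetic_case(self):
        m = sj.compute_metrics(sj.ConfusionMatrix(TP=3, FP=1, TN=4, FN=2))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / 3, abs=1e-4)

    def test_undefined_metrics_reported_as_none_not_zero(self):
        m = sj.compute_metrics(sj.ConfusionMatrix(TP=0, FP=0, TN=5, FN=0))
        assert m.precision is None and m.recall is None and m.f1 is None
        assert m.accuracy == 1.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            sj.compute_metrics(sj.ConfusionMatrix(0, 0, 0, 0))

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = sj.compute_metrics(sj.ConfusionMatrix(int(tp), int(fp), int(tn), int(fn)))
            assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12
            for v in (m.accuracy, m.precision, m.recall, m.f1):
                assert 0 <= v <= 1


@pytest.fixture(scope="module")
def small_table():
    fm, y = sj.synth_feature_table(150, 150, 2.0, seed=21)
    return fm, y


def _tiny_space(**overrides):
    base = {
        "n_estimators": [20],
        "max_features": ["sqrt"],
        "max_depth": [5],
        "min_samples_split": [2],
        "min_samples_leaf": [1],
        "bootstrap": [True],
    }
    base.update(overrides)
    return SearchSpace(base)


class TestSearch:
    def test_default_spaces_have_stated_shapes(self):
        r = SearchSpace.broad_random_stage()
        assert len(r.candidates["n_estimators"]) == 60
        assert r.candidates["n_estimators"][0] == 50 and r.candidates["n_estimators"][-1] == 3000
        assert len(r.candidates["max_depth"]) == 51 and r.candidates["max_depth"][0] is None
        g = SearchSpace.refining_grid_stage()
        assert g.candidates["n_estimators"] == list(range(180, 221))
        assert g.candidates["max_depth"] == list(range(30, 51))
        assert g.candidates["min_samples_split"] == [3, 4, 5, 6, 7]
        # grid is a refinement around the random stage's best point
        b = sj.RANDOM_STAGE_BEST
        assert b.n_estimators in g.candidates["n_estimators"]
        assert b.max_depth in g.candidates["max_depth"]
        assert b.min_samples_split in g.candidates["min_samples_split"]

    def test_singleton_space_returned_unchanged(self, small_table):
        fm, y = small_table
        hp = sj.random_search(fm, y, _tiny_space(), n_draws=5, folds=3, seed=0)
        assert hp == sj.HyperParams(n_estimators=20, max_features="sqrt", max_depth=5,
                                    min_samples_split=2, min_samples_leaf=1, bootstrap=True)

    def test_random_search_winner_attains_max_cv_score(self, small_table):
        fm, y = small_table
        space = _tiny_space(n_estimators=[5, 25], max_depth=[2, 8], min_samples_leaf=[1, 4])
        hp = sj.random_search(fm, y, space, n_draws=8, folds=3, seed=2)
        scores = {h: cv_score(fm, y, h, folds=3, seed=2) for h in space.enumerate()}
        assert scores[hp] == max(scores.values())

    def test_grid_search_winner_matches_exhaustive_rescoring(self, small_table):
        fm, y = small_table
        space = _tiny_space(n_estimators=[5, 15, 30], max_depth=[2, 4, 8])
        hp = sj.grid_search(fm, y, space, folds=3, seed=1)
        best = None
        for cand in space.enumerate():
            s = cv_score(fm, y, cand, folds=3, seed=1)
            if best is None or s > best[1]:
                best = (cand, s)
        assert hp == best[0]

    def test_grid_1x1_returns_sole_point(self, small_table):
        fm, y = small_table
        assert sj.grid_search(fm, y, _tiny_space(), folds=3, seed=0) == _tiny_space().point(0)


class TestTrainPredict:
    def test_fixed_seed_identical_predictions(self, small_table):
        fm, y = small_table
        hp = sj.HyperParams(n_estimators=30)
        a = sj.train(fm, y, hp, folds=3, seed=7)
        b = sj.train(fm, y, hp, folds=3, seed=7)
        pa = sj.predict(a, fm)
        pb = sj.predict(b, fm)
        assert (pa["probability"] == pb["probability"]).all()

    def test_default_ten_folds_recorded(self, small_table):
        fm, y = small_table
        bundle = sj.train(fm, y, sj.HyperParams(n_estimators=20), seed=0)
        assert len(bundle.cv_scores) == 10

    def test_single_class_rejected(self, small_table):
        fm, _ = small_table
        with pytest.raises(ValueError, match="degenerate labels"):
            sj.train(fm, np.ones(len(fm), dtype=int), sj.HyperParams(n_estimators=5), folds=2)

    def test_empty_matrix_gives_empty_predictions(self, small_table):
        fm, y = small_table
        bundle = sj.train(fm, y, sj.HyperParams(n_estimators=10), folds=3, seed=0)
        empty = FeatureMatrix(data=fm.data.iloc[:0], schema_hash=fm.schema_hash)
        assert len(sj.predict(bundle, empty)) == 0

    def test_threshold_extremes_and_monotone_flips(self, small_table):
        fm, y = small_table
        bundle = sj.train(fm, y, sj.HyperParams(n_estimators=30), folds=3, seed=0)
        prev_tp = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0 + 1e-9):
            bundle.threshold = thr
            labels = sj.predict(bundle, fm)["label"]
            n_tp = int((labels == "TP").sum())
            if thr == 0.0:
                assert n_tp == len(fm)  # everything passes at threshold 0
            if prev_tp is not None:
                assert n_tp <= prev_tp  # raising threshold never creates a TP
            prev_tp = n_tp
        assert n_tp == 0

    def test_schema_mismatch_refused_naming_both_hashes(self, small_table):
        fm, y = small_table
        bundle = sj.train(fm, y, sj.HyperParams(n_estimators=5), folds=2, seed=0)
        alien = FeatureMatrix(data=fm.data, schema_hash="deadbeef0123")
        with pytest.raises(ValueError, match="deadbeef0123") as exc:
            sj.predict(bundle, alien)
        assert bundle.schema_hash in str(exc.value)

    def test_bundle_save_load_round_trip(self, small_table, tmp_path):
        fm, y = small_table
        bundle = sj.train(fm, y, sj.HyperParams(n_estimators=15), folds=3, seed=3)
        p = str(tmp_path / "model.svj")
        bundle.save(p)
        back = sj.ModelBundle.load(p)
        assert back.hyperparams == bundle.hyperparams
        assert back.schema_hash == bundle.schema_hash
        assert back.cv_scores == bundle.cv_scores
        assert (sj.predict(back, fm)["probability"] == sj.predict(bundle, fm)["probability"]).all()

    def test_separated_classes_recovered_on_held_out_data(self):
        fm, y = sj.synth_feature_table(300, 300, 3.0, seed=9)
        idx = list(range(len(y)))
        train_idx, test_idx = sj.split_dataset(idx, seed=2, labels=y)
        bundle = sj.train(
            FeatureMatrix(fm.data.iloc[train_idx], fm.schema_hash), y[train_idx],
            sj.HyperParams(n_estimators=60), folds=5, seed=0,
        )
        preds = sj.predict(bundle, FeatureMatrix(fm.data.iloc[test_idx], fm.schema_hash))
        acc = np.mean((preds["label"] == "TP").astype(int) == y[test_idx])
        assert acc >= 0.95
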