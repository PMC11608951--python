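"""PLS-DA fitting, LV selection, metric formulas and benchmark runs."""

import numpy as np
import pandas as pd
import pytest

from chemfinger.fingerprints import (default_profiles, generate_ftir,
                                     make_split)
from chemfinger.plsda import (DATA_TYPES, explained_variance, fit_plsda,
                              one_hot, run_experiment, score_classification,
                              select_lv)

RNG = np.random.default_rng(31)


class TestOneHot:
    def test_single_and_multi_label_rows(self):
        np.testing.assert_array_equal(one_hot(["H"]), [[1, 0, 0]])
        np.testing.assert_array_equal(one_hot(["L", "M"]),
                                      [[0, 0, 1], [0, 1, 0]])

    def test_rows_sum_to_one(self):
        labels = RNG.choice(list("HML"), size=50)
        np.testing.assert_array_equal(one_hot(labels).sum(axis=1), 1)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            one_hot(["H", "Q"])


def two_blob_data(n=30, d=10, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(size=(n, d)), rng.normal(size=(n, d)) + gap])
    y = np.array(["H"] * n + ["L"] * n)
    return X, y


class TestFitPlsda:
    def test_separable_blobs_classified_perfectly(self):
        X, y = two_blob_data()
        model = fit_plsda(X, one_hot(y), n_lv=2)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_full_rank_fit_matches_least_squares(self):
        # with as many components as feature rank, PLS prediction equals OLS
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        Y = one_hot(rng.choice(list("HML"), size=12))
        model = fit_plsda(X, Y, n_lv=4)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)
        ols_pred = Xc @ beta + Y.mean(axis=0)
        np.testing.assert_allclose(model.decision_scores(X), ols_pred,
                                   atol=1e-6)

    def test_sample_order_invariance(self):
        X, y = two_blob_data(seed=5)
        perm = np.random.default_rng(0).permutation(len(y))
        m1 = fit_plsda(X, one_hot(y), 3)
        m2 = fit_plsda(X[perm], one_hot(y[perm]), 3)
        probe = RNG.normal(size=(7, X.shape[1]))
        np.testing.assert_allclose(m1.decision_scores(probe),
                                   m2.decision_scores(probe), atol=1e-9)

    def test_excessive_components_reduced_with_warning(self):
        X, y = two_blob_data(n=5, d=3)
        with pytest.warns(UserWarning):
            model = fit_plsda(X, one_hot(y), n_lv=50)
        assert model.n_lv <= 3


class TestSelectLv:
    def test_null_data_cv_accuracy_near_chance(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 20))
            y = one_hot(np.repeat(list("HML"), 20))
            _, curves = select_lv(X, y, max_lv=4, folds=5, seed=seed)
            accs.append(curves["cv_accuracy"].mean())
        assert np.mean(accs) == pytest.approx(1.0 / 3.0, abs=0.08)

    def test_candidate_range_covers_reported_choices(self):
        X, y = two_blob_data(n=40, d=30, gap=2.0, seed=1)
        best, curves = select_lv(X, one_hot(y), max_lv=15, folds=5, seed=0)
        assert set(range(5, 16)) <= set(curves["LV"])  # includes 5..15
        assert 1 <= best <= 15

    def test_same_seed_reproduces_curves(self):
        X, y = two_blob_data(seed=2)
        a = select_lv(X, one_hot(y), max_lv=3, folds=5, seed=9)
        b = select_lv(X, one_hot(y), max_lv=3, folds=5, seed=9)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_folds_exceeding_class_count_raise(self):
        X, y = two_blob_data(n=4)
        with pytest.raises(ValueError):
            select_lv(X, one_hot(y), max_lv=2, folds=10)


class TestExplainedVariance:
    def test_rank_one_data_fully_explained_by_one_lv(self):
        t = RNG.normal(size=(20, 1))
        X = t @ RNG.normal(size=(1, 6))
        y = one_hot(np.where(t[:, 0] > 0, "H", "L"))
        ev = explained_variance(fit_plsda(X, y, 1))
        assert ev["X_cumulative"].iloc[-1] == pytest.approx(1.0, abs=1e-9)

    def test_cumulative_fractions_monotone_and_bounded(self):
        X = RNG.normal(size=(30, 12))
        y = one_hot(RNG.choice(list("HML"), size=30))
        ev = explained_variance(fit_plsda(X, y, 6))
        assert (np.diff(ev["X_cumulative"]) >= -1e-12).all()
        assert (np.diff(ev["Y_cumulative"]) >= -1e-12).all()
        assert ev["X_cumulative"].iloc[-1] <= 1.0 + 1e-9
        assert ev["Y_cumulative"].iloc[-1] <= 1.0 + 1e-9

    def test_x_fractions_match_independent_projection(self):
        X = RNG.normal(size=(25, 8))
        y = one_hot(RNG.choice(list("HML"), size=25))
        model = fit_plsda(X, y, 4)
        ev = explained_variance(model)
        Xc = X - X.mean(axis=0)
        T, P = model.pls.x_scores_, model.pls.x_loadings_
        resid = Xc - T @ P.T
        total = 1.0 - np.sum(resid ** 2) / np.sum(Xc ** 2)
        assert ev["X_cumulative"].iloc[-1] == pytest.approx(total, abs=1e-9)


class TestScoreClassification:
    def test_perfect_prediction(self):
        y = list("HHMMLL")
        mt = score_classification(y, y)
        for m in ("SEN", "SPE", "PRE", "ACC", "F1"):
            np.testing.assert_allclose(mt.per_grade[m], 1.0)
        assert np.all(mt.confusion == np.diag([2, 2, 2]))
        assert mt.overall_accuracy == 1.0

    def test_hand_counted_single_error_toy(self):
        # six samples, one M mistaken for L
        y_true = list("HHMMLL")
        y_pred = list("HHMLLL")
        mt = score_classification(y_true, y_pred)
        row = mt.per_grade.set_index("Grade")
        assert row.loc["M", "SEN"] == pytest.approx(0.5)
        assert row.loc["M", "PRE"] == pytest.approx(1.0)
        assert row.loc["M", "F1"] == pytest.approx(2.0 / 3.0)
        assert row.loc["L", "SEN"] == pytest.approx(1.0)
        assert row.loc["L", "PRE"] == pytest.approx(2.0 / 3.0)
        assert row.loc["H", "SEN"] == 1.0 and row.loc["H", "SPE"] == 1.0
        # one-vs-rest ACC counts true negatives: both M and L get 5/6
        assert row.loc["M", "ACC"] == pytest.approx(5.0 / 6.0)
        assert row.loc["L", "ACC"] == pytest.approx(5.0 / 6.0)
        assert mt.overall_accuracy == pytest.approx(5.0 / 6.0)

    def test_brute_force_recount_on_random_predictions(self):
        rng = np.random.default_rng(17)
        y_true = rng.choice(list("HML"), size=1000)
        y_pred = rng.choice(list("HML"), size=1000)
        mt = score_classification(y_true, y_pred)
        cm = mt.confusion
        assert cm.sum() == 1000
        for i, g in enumerate("HML"):
            assert cm[i].sum() == np.sum(y_true == g)
            tp = np.sum((y_true == g) & (y_pred == g))
            fp = np.sum((y_true != g) & (y_pred == g))
            fn = np.sum((y_true == g) & (y_pred != g))
            tn = 1000 - tp - fp - fn
            row = mt.per_grade.set_index("Grade").loc[g]
            assert row["SEN"] == pytest.approx(tp / (tp + fn))
            assert row["SPE"] == pytest.approx(tn / (tn + fp))
            assert row["PRE"] == pytest.approx(tp / (tp + fp))
            assert row["ACC"] == pytest.approx((tp + tn) / 1000)
            # F1 identity and bound
            f1 = 2 * row["PRE"] * row["SEN"] / (row["PRE"] + row["SEN"])
            assert row["F1"] == pytest.approx(f1, abs=1e-12)
            assert row["F1"] <= min(2 * row["PRE"], 2 * row["SEN"]) + 1e-12

    def test_absent_grade_reported_missing_and_excluded_from_macro(self):
        with pytest.warns(UserWarning):
            mt = score_classification(list("HHMM"), list("HHMM"))
        row = mt.per_grade.set_index("Grade")
        assert np.isnan(row.loc["L", "SEN"])
        assert mt.macro["SEN"] == pytest.approx(1.0)

    def test_roc_curves_present_with_scores(self):
        y = list("HHMMLL")
        scores = one_hot(y) * 0.8 + 0.1
        mt = score_classification(y, y, scores)
        assert set(mt.roc) == {"H", "M", "L"}
        assert all(v["auc"] == pytest.approx(1.0) for v in mt.roc.values())


@pytest.fixture(scope="module")
def ftir_sets():
    profiles = default_profiles()
    real, gen = [], []
    for k, g in enumerate("HML"):
        real += generate_ftir(profiles[g], 12, seed=60 + k, length=128)
        gen += generate_ftir(profiles[g], 25, seed=80 + k, length=128)
    split = make_split(real, gen, test_fraction=0.3, seed=0)
    return real, gen, split


class TestRunExperiment:
    def test_data_type_names_match_benchmark(self):
        assert DATA_TYPES == ["HPLC", "FTIR", "HPLC-FTIR", "HPLC-TimeVQVAE",
                              "FTIR-TimeVQVAE", "HPLC-FTIR-TimeVQVAE"]

    def test_augmented_run_uses_more_training_samples(self, ftir_sets):
        real, gen, split = ftir_sets
        plain = run_experiment("FTIR", real, [], split, n_lv=3)
        aug = run_experiment("FTIR-TimeVQVAE", real, gen, split, n_lv=3)
        n_plain = plain.train_metrics.confusion.sum()
        n_aug = aug.train_metrics.confusion.sum()
        assert n_aug > n_plain

    def test_report_rows_shape(self, ftir_sets):
        real, gen, split = ftir_sets
        res = run_experiment("FTIR", real, [], split, n_lv=3)
        rows = res.table_rows()
        assert list(rows["Grade"].unique()) == ["H", "M", "L", "Average"]
        assert set(rows["Split"]) == {"Train", "Test"}

    def test_unknown_data_type_rejected(self, ftir_sets):
        real, gen, split = ftir_sets
        with pytest.raises(ValueError):
            run_experiment("NMR", real, gen, split, n_lv=2)


def test_separability_monotone_in_effect_size():
    """PLS-DA accuracy does not decrease as grade band differences grow."""
    mean_acc = []
    for effect in (0.0, 0.7, 2.0):
        accs = []
        for seed in range(5):
            profiles = default_profiles(effect=effect, noise_sd=0.05,
                                        height_jitter_sd=0.3)
            fps = []
            for k, g in enumerate("HML"):
                fps += generate_ftir(profiles[g], 15, seed=seed * 10 + k,
                                     length=128)
            split = make_split(fps, [], test_fraction=0.3, seed=seed)
            res = run_experiment("FTIR", fps, [], split, n_lv=3)
            accs.append(res.test_metrics.overall_accuracy)
        mean_acc.append(np.mean(accs))
    assert mean_acc[0] <= mean_acc[1] + 1e-9
    assert mean_acc[1] <= mean_acc[2] + 1e-9


def test_augmentation_does_not_degrade_scarce_real_test_accuracy(
        augmentation_study):
    """Mean real-test accuracy with augmentation stays within two points of
    the unaugmented baseline under moderate class overlap."""
    unaug = np.mean([r["unaug_acc"] for r in augmentation_study])
    aug = np.mean([r["aug_acc"] for r in augmentation_study])
    assert aug >= unaug - 0.02
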