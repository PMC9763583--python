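import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micropod.otu_io import OtuTable, OtuTableError, to_relative_abundance
from micropod.rfcv import (
    ClassifierModel,
    PodScores,
    RfcvCurve,
    choose_feature_count,
    compute_pod,
    cv_error_curve,
    default_feature_grid,
    load_model,
    roc_analysis,
    save_model,
    train_final,
    validate_external,
)


def pod_series(values, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return PodScores(pd.Series(values, index=ids, name="pod"), mode="external")


class TestChooseFeatureCount:
    def test_min_rule_tie_to_fewer(self):
        c = RfcvCurve(ks=[2, 4, 8, 16], mean_errors=[.30, .10, .10, .12],
                      sd_errors=[0.02] * 4)
        assert choose_feature_count(c, "min") == 4

    def test_flat_curve_smallest_k(self):
        c = RfcvCurve(ks=[1, 2, 4], mean_errors=[.2, .2, .2],
                      sd_errors=[0.01] * 3)
        assert choose_feature_count(c, "min") == 1

    def test_one_se_rule(self):
        c = RfcvCurve(ks=[2, 4, 8], mean_errors=[.30, .12, .10],
                      sd_errors=[.02, .02, .02])
        assert choose_feature_count(c, "one-se") == 4

    def test_unknown_rule(self):
        c = RfcvCurve(ks=[1], mean_errors=[.1], sd_errors=[.0])
        with pytest.raises(ValueError):
            choose_feature_count(c, "aic")

    def test_empty_curve(self):
        with pytest.raises(ValueError):
            choose_feature_count(RfcvCurve([], [], []))


class TestFeatureGrid:
    def test_small_counts_covered(self):
        assert default_feature_grid(23) == [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 23]

    def test_tiny(self):
        assert default_feature_grid(2) == [1, 2]


def noise_table(n=40, p=20, seed=0):
    rng = np.random.default_rng(seed)
    t = OtuTable([f"s{i}" for i in range(n)], [f"o{j}" for j in range(p)],
                 rng.integers(1, 100, size=(n, p)))
    labels = np.array(["case"] * (n // 2) + ["control"] * (n - n // 2))
    return t, labels


class TestCvErrorCurve:
    def test_pure_noise_error_near_chance(self):
        errs = []
        for seed in range(3):
            t, labels = noise_table(seed=seed)
            c = cv_error_curve(t, labels, t.otu_ids, folds=5, repeats=2,
                               n_trees=50, seed=seed, grid=[5, 20])
            errs.extend(c.mean_errors)
        assert abs(np.mean(errs) - 0.5) < 0.12

    def test_errors_in_unit_interval(self):
        t, labels = noise_table(seed=1)
        c = cv_error_curve(t, labels, t.otu_ids, folds=4, repeats=1,
                           n_trees=30, seed=1, grid=[2, 10])
        assert all(0 <= e <= 1 for e in c.mean_errors)

    def test_too_many_folds_error(self):
        t, _ = noise_table(n=8)
        labels = ["case"] * 4 + ["control"] * 4
        with pytest.raises(ValueError, match="folds"):
            cv_error_curve(t, labels, t.otu_ids, folds=5, repeats=1, seed=0)

    def test_recovery_on_default_cohort(self, default_cohort):
        table, meta, _, truth = default_cohort
        labels = meta["group"].to_numpy()
        rel = to_relative_abundance(table)
        from micropod.screen import ScreenConfig, select_candidates
        sres = select_candidates(rel, table, labels,
                                 ScreenConfig(n_trees=150, seed=1))
        c = cv_error_curve(rel, labels, sres.candidates, folds=5, repeats=2,
                           n_trees=100, seed=1)
        k = choose_feature_count(c, "min")
        err_k = c.mean_errors[c.ks.index(k)]
        err_1 = c.mean_errors[c.ks.index(1)]
        assert 6 <= k <= 12
        assert err_k < err_1


class TestTrainFinal:
    def test_perfect_feature_zero_training_error(self):
        t, labels = noise_table(seed=2)
        counts = t.counts.copy()
        counts[:20, 0] += 1000
        t2 = OtuTable(t.sample_ids, t.otu_ids, counts)
        m = train_final(t2, labels, ["o0", "o1"], n_trees=100, seed=0,
                        positive_label="case")
        pred = m.forest.predict(m.training_matrix)
        assert np.mean(pred != labels) == 0.0

    def test_refit_same_seed_identical_importances(self):
        t, labels = noise_table(seed=3)
        m1 = train_final(t, labels, t.otu_ids[:5], n_trees=80, seed=4)
        m2 = train_final(t, labels, t.otu_ids[:5], n_trees=80, seed=4)
        pd.testing.assert_frame_equal(m1.importances, m2.importances)

    def test_missing_panel_feature_error(self):
        t, labels = noise_table()
        with pytest.raises(OtuTableError, match="absent"):
            train_final(t, labels, ["nope"], seed=0)

    def test_below_floor_reported(self, default_cohort):
        table, meta, _, truth = default_cohort
        labels = meta["group"].to_numpy()
        rel = to_relative_abundance(table)
        m = train_final(rel, labels, truth.effect_otus, n_trees=200, seed=1,
                        positive_label="case")
        assert len(m.below_floor) <= 2  # planted effects carry importance

    def test_empty_panel(self):
        t, labels = noise_table()
        with pytest.raises(ValueError):
            train_final(t, labels, [], seed=0)


class TestComputePod:
    def test_single_tree_pod_binary(self):
        t, labels = noise_table(seed=5)
        m = train_final(t, labels, t.otu_ids[:4], n_trees=1, seed=0,
                        positive_label="case")
        pod = compute_pod(m, t, mode="external")
        assert set(np.round(pod.scores.to_numpy(), 6)) <= {0.0, 1.0}

    def test_external_high_pod_on_case_profile(self, default_cohort):
        table, meta, _, truth = default_cohort
        labels = meta["group"].to_numpy()
        rel = to_relative_abundance(table)
        m = train_final(rel, labels, truth.effect_otus, n_trees=300, seed=1,
                        positive_label="case")
        pod = compute_pod(m, rel, mode="external")
        assert pod.scores[labels == "case"].mean() >= 0.9

    def test_cross_validated_null_balanced(self):
        diffs = []
        for seed in range(3):
            t, labels = noise_table(n=40, p=10, seed=seed + 10)
            m = train_final(t, labels, t.otu_ids, n_trees=60, seed=seed)
            pod = compute_pod(m, t, labels=labels, mode="cross-validated",
                              folds=5, repeats=2)
            diffs.append(pod.scores[labels == "case"].mean()
                         - pod.scores[labels == "control"].mean())
        assert abs(np.mean(diffs)) < 0.1

    def test_cross_validated_needs_labels(self):
        t, labels = noise_table()
        m = train_final(t, labels, t.otu_ids[:3], n_trees=20, seed=0)
        with pytest.raises(ValueError):
            compute_pod(m, t, mode="cross-validated")

    def test_missing_panel_otu_error_and_fill(self):
        t, labels = noise_table()
        m = train_final(t, labels, t.otu_ids[:3], n_trees=20, seed=0)
        t2 = t.select_otus(t.otu_ids[1:])
        with pytest.raises(OtuTableError, match="o0"):
            compute_pod(m, t2, mode="external")
        pod = compute_pod(m, t2, mode="external", fill_missing="zero")
        assert len(pod.scores) == t2.n_samples


class TestRoc:
    def test_perfect_separation(self):
        pod = pod_series([0.9, 0.8, 0.2, 0.1])
        res = roc_analysis(pod, ["case", "case", "control", "control"], "case")
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 0.2 < res.cutoff <= 0.8

    def test_auc_equals_mannwhitney_u(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(5, 15, size=2)
            scores = np.round(rng.random(n1 + n2), 2)  # with ties
            labels = ["case"] * n1 + ["control"] * n2
            res = roc_analysis(pod_series(scores), labels, "case")
            u = stats.mannwhitneyu(scores[:n1], scores[n1:],
                                   alternative="two-sided").statistic
            assert res.auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_null_auc_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(1000):
            scores = rng.random(20)
            labels = rng.permutation(["case"] * 10 + ["control"] * 10)
            aucs.append(roc_analysis(pod_series(scores), labels, "case").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(16)
        labels = ["case"] * 8 + ["control"] * 8
        a = roc_analysis(pod_series(scores), labels, "case")
        b = roc_analysis(pod_series(scores**3), labels, "case")
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_cutoff_consistent_with_curve(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = rng.permutation(["case"] * 15 + ["control"] * 15)
        res = roc_analysis(pod_series(scores), labels, "case")
        # recompute sens/spec at the stored cut-off from raw data
        is_case = np.array(labels) == "case"
        pred = scores >= res.cutoff
        sens = np.mean(pred[is_case])
        spec = np.mean(~pred[~is_case])
        assert sens == pytest.approx(res.sensitivity, abs=1e-12)
        assert spec == pytest.approx(res.specificity, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_analysis(pod_series([0.5, 0.6]), ["case", "case"], "case")


class TestExternalValidation:
    def test_overlap_rejected(self):
        t, labels = noise_table()
        m = train_final(t, labels, t.otu_ids[:4], n_trees=20, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            validate_external(m, t, labels)

    def test_training_data_auc_at_least_cv(self, default_cohort):
        table, meta, _, truth = default_cohort
        labels = meta["group"].to_numpy()
        rel = to_relative_abundance(table)
        m = train_final(rel, labels, truth.effect_otus, n_trees=200, seed=1,
                        positive_label="case")
        cv_auc = roc_analysis(
            compute_pod(m, rel, labels=labels, mode="cross-validated",
                        repeats=2),
            labels, "case").auc
        clone = OtuTable([f"x_{s}" for s in rel.sample_ids], rel.otu_ids,
                         table.counts)
        ext_auc = validate_external(m, to_relative_abundance(clone), labels).auc
        assert ext_auc >= cv_auc - 1e-9

    def test_shuffled_labels_auc_near_half(self, default_cohort):
        table, meta, _, truth = default_cohort
        labels = meta["group"].to_numpy()
        rel = to_relative_abundance(table)
        m = train_final(rel, labels, truth.effect_otus, n_trees=100, seed=1,
                        positive_label="case")
        clone = OtuTable([f"x_{s}" for s in rel.sample_ids], rel.otu_ids,
                         table.counts)
        rng = np.random.default_rng(0)
        aucs = [validate_external(m, to_relative_abundance(clone),
                                  rng.permutation(labels)).auc
                for _ in range(20)]
        assert abs(np.mean(aucs) - 0.5) < 0.12


class TestModelPersistence:
    def test_round_trip_identical_predictions(self, tmp_path):
        t, labels = noise_table(seed=6)
        m = train_final(t, labels, t.otu_ids[:5], n_trees=50, seed=3,
                        positive_label="case")
        p = tmp_path / "model.json"
        save_model(m, p)
        m2 = load_model(p)
        assert m2.panel == m.panel
        pod1 = compute_pod(m, t, mode="external").scores
        pod2 = compute_pod(m2, t, mode="external").scores
        pd.testing.assert_series_equal(pod1, pod2)
        pd.testing.assert_frame_equal(
            m2.importances.astype(float), m.importances.astype(float))
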