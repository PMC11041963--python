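"""Fusion dataset assembly, classifiers, Shapley attribution, statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from pulsetherm import fusion, sim
from pulsetherm.sim import StudyEffectProfile


def tiny_dataset(n=12, seed=0, **profile_kw):
    prof = StudyEffectProfile(**profile_kw) if profile_kw else None
    return sim.generate_labeled_study(n, "stress", effect_profile=prof, seed=seed)


class TestAssemble:
    def make_inputs(self, n=10):
        idx = [f"S{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        rppg = pd.DataFrame(rng.normal(size=(n, 3)), index=idx,
                            columns=["d_hr", "d_sdnn", "d_rmssd"])
        therm = pd.DataFrame(rng.normal(size=(n, 2)), index=idx,
                             columns=["roi_30", "roi_58"])
        labels = pd.Series(rng.integers(0, 2, n), index=idx)
        return rppg, therm, labels

    def test_complete_subjects_all_joined(self):
        r, t, y = self.make_inputs()
        ds = fusion.assemble_features(r, t, y)
        assert len(ds.X) == 10
        assert ds.modality["d_hr"] == "rppg" and ds.modality["roi_30"] == "thermal"

    def test_subject_missing_one_modality_flagged(self):
        r, t, y = self.make_inputs()
        ds = fusion.assemble_features(r, t.drop(index="S3"), y)
        assert len(ds.X) == 9
        assert "S3" in ds.incomplete_subjects

    def test_duplicate_ids_rejected(self):
        r, t, y = self.make_inputs()
        bad = pd.concat([r, r.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            fusion.assemble_features(bad, t, y)

    def test_empty_labels_rejected(self):
        r, t, _ = self.make_inputs()
        with pytest.raises(ValueError):
            fusion.assemble_features(r, t, pd.Series(dtype=float))


class TestTrainEval:
    def test_separable_dataset_perfect_accuracy(self):
        ds = tiny_dataset(14, seed=1, hr_shift_bpm=60.0, between_sd_scale=0.05,
                          within_sd_scale=0.05)
        for model in ("svm", "rf"):
            r = fusion.train_eval(ds, "rppg", model, cv_folds=5, seed=1)
            assert r.avg_accuracy == 1.0

    def test_deterministic_given_seed(self):
        ds = tiny_dataset(12, seed=2)
        a = fusion.train_eval(ds, "rppg", "svm", 5, seed=3)
        b = fusion.train_eval(ds, "rppg", "svm", 5, seed=3)
        assert a.avg_accuracy == b.avg_accuracy and a.avg_f1 == b.avg_f1
        assert np.array_equal(a.fold_assignments, b.fold_assignments)

    def test_fold_assignments_partition_subject_level(self):
        ds = tiny_dataset(15, seed=0)
        r = fusion.train_eval(ds, "thermal", "svm", 5, seed=0)
        assert set(r.fold_assignments) == set(range(5))
        for subj in np.unique(ds.subjects):
            folds = r.fold_assignments[ds.subjects == subj]
            assert len(set(folds)) == 1  # both records share the fold

    def test_single_class_rejected(self):
        ds = tiny_dataset(10, seed=0)
        bad = fusion.FusionDataset(X=ds.X, y=np.zeros(len(ds.X), dtype=int),
                                   subjects=ds.subjects, modality=ds.modality)
        with pytest.raises(ValueError):
            fusion.train_eval(bad, "rppg", "svm", 5, seed=0)


class TestFusionStrategies:
    def test_early_fusion_feature_order_invariance(self):
        ds = tiny_dataset(12, seed=4)
        shuffled = fusion.FusionDataset(
            X=ds.X[list(ds.X.columns[::-1])], y=ds.y, subjects=ds.subjects,
            modality=ds.modality,
        )
        a = fusion.early_fusion_eval(ds, "svm", 5, seed=4)
        b = fusion.early_fusion_eval(shuffled, "svm", 5, seed=4)
        assert a.avg_accuracy == pytest.approx(b.avg_accuracy)

    def test_early_fusion_requires_both_modalities(self):
        ds = tiny_dataset(10, seed=0)
        only_rppg = fusion.FusionDataset(
            X=ds.features("rppg"), y=ds.y, subjects=ds.subjects,
            modality={c: "rppg" for c in ds.feature_names("rppg")},
        )
        with pytest.raises(ValueError, match="thermal"):
            fusion.early_fusion_eval(only_rppg, "svm", 5, 0)

    def test_late_fusion_agreeing_correct_bases_is_perfect(self):
        # strong effects in both modalities -> both base models correct
        ds = tiny_dataset(14, seed=5, hr_shift_bpm=60.0,
                          thermal_effects_c={"lip": 5.0, "cheek": 5.0},
                          between_sd_scale=0.05, within_sd_scale=0.05)
        r = fusion.late_fusion_eval(ds, seed=5)
        assert r.avg_accuracy == 1.0

    def test_late_fusion_follows_the_informative_modality(self):
        # rppg informative, thermal pure noise: the tree learns to trust rppg
        ds = tiny_dataset(20, seed=6, hr_shift_bpm=60.0, thermal_effects_c={},
                          between_sd_scale=0.05, within_sd_scale=0.05)
        r = fusion.late_fusion_eval(ds, seed=6)
        assert r.avg_accuracy >= 0.9


class TestShapley:
    def test_unused_feature_gets_exactly_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        y = (X["a"] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        rep = fusion.shapley_importance(tree, X, seed=0)
        tbl = rep.table.set_index("feature")
        assert tbl.loc["b", "mean_abs_shap"] == 0.0
        assert tbl.loc["a", "rank"] == 1

    def test_single_feature_ranks_first(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"only": rng.normal(size=40)})
        y = (X["only"] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        rep = fusion.shapley_importance(tree, X, seed=1)
        assert rep.top_feature == "only"

    def test_rank_invariant_to_column_order(self):
        ds = tiny_dataset(20, seed=7, hr_shift_bpm=40.0, thermal_effects_c={},
                          within_sd_scale=0.3)
        model = fusion.fit_model(ds, "rppg", "rf", seed=7)
        a = fusion.shapley_importance(model, ds.features("rppg"), seed=7)
        ds2 = fusion.FusionDataset(X=ds.X[list(ds.X.columns[::-1])], y=ds.y,
                                   subjects=ds.subjects, modality=ds.modality)
        model2 = fusion.fit_model(ds2, "rppg", "rf", seed=7)
        b = fusion.shapley_importance(model2, ds2.features("rppg"), seed=11)
        assert a.top_feature == b.top_feature


class TestQualitySweep:
    @staticmethod
    def paired_table(n=40, noise_with_quality=False, seed=0):
        rng = np.random.default_rng(seed)
        q = rng.uniform(0.2, 0.6, n)
        rows = {"quality": q}
        for m in ("hr_mean_bpm", "sdnn_ms"):
            ref = rng.normal(70, 10, n)
            noise = rng.normal(0, 1, n) * (10 * (q - 0.15) if noise_with_quality else 0)
            rows[f"ref_{m}"] = ref
            rows[f"rppg_{m}"] = ref + noise
        return pd.DataFrame(rows)

    def test_identical_pairs_give_unit_correlation(self):
        tbl = self.paired_table()
        out = fusion.quality_sweep(tbl, [0.6, 0.4], measures=("hr_mean_bpm", "sdnn_ms"))
        assert np.allclose(out[["r_hr_mean_bpm", "r_sdnn_ms"]], 1.0)

    def test_n_monotone_in_threshold(self):
        tbl = self.paired_table(noise_with_quality=True)
        out = fusion.quality_sweep(tbl, [0.6, 0.5, 0.4, 0.3, 0.25],
                                   measures=("hr_mean_bpm",))
        assert (np.diff(out["n"]) <= 0).all()

    def test_insufficient_threshold_marked(self):
        tbl = self.paired_table()
        out = fusion.quality_sweep(tbl, [0.01], measures=("hr_mean_bpm",))
        assert bool(out.loc[0, "insufficient"])
        assert np.isnan(out.loc[0, "r_hr_mean_bpm"])


class TestStatistics:
    def test_exact_anticorrelation(self):
        rng = np.random.default_rng(0)
        hrv_d = pd.DataFrame({"hr": rng.normal(size=10)}, index=range(10))
        therm = pd.DataFrame({30: -hrv_d["hr"]}, index=range(10))
        r, p, sig = fusion.correlation_map(hrv_d, therm)
        assert r.loc["hr", 30] == pytest.approx(-1.0)

    def test_two_subjects_rejected(self):
        hrv_d = pd.DataFrame({"hr": [1.0, 2.0]}, index=[0, 1])
        with pytest.raises(ValueError):
            fusion.correlation_map(hrv_d, hrv_d)

    def test_constant_column_missing(self):
        hrv_d = pd.DataFrame({"hr": [1.0, 2.0, 3.0, 4.0]})
        therm = pd.DataFrame({30: [5.0, 5.0, 5.0, 5.0]})
        r, p, sig = fusion.correlation_map(hrv_d, therm)
        assert np.isnan(r.loc["hr", 30])

    def test_large_effect_detected(self):
        rng = np.random.default_rng(2)
        deltas = pd.DataFrame({"hr": rng.normal(0.5, 0.1, 30)})
        out = fusion.change_tests(deltas)
        assert out.loc[0, "p"] < 1e-3

    def test_zero_variance_undefined(self):
        out = fusion.change_tests(pd.DataFrame({"hr": [0.0] * 10}))
        assert np.isnan(out.loc[0, "t"]) and np.isnan(out.loc[0, "p"])
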