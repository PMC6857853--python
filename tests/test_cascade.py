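"""Cascade risk stratification: split, Test 1, Test 2, prediction, learners."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import oralcyto as oc
from oralcyto.cascade import (CascadeRiskModel, cascade_predict,
                              compare_learners, derive_test2_cutoff,
                              features_frame, split_cohort, train_test1)
from oralcyto.synthetic import CohortSpec, DEFAULT_CLASS_SPECS


def make_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "label", "n_cells",
                                       "pct_atypical", "mean_all",
                                       "mean_atypical"])


def separable_frame(n=10, seed=0):
    """OSCC far from the rest in both Test-1 features."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append((f"O{i}", "OSCC", 200, rng.uniform(35, 45),
                     rng.uniform(0.38, 0.45), rng.uniform(0.72, 0.8)))
        rows.append((f"H{i}", "HGD", 200, rng.uniform(10, 18),
                     rng.uniform(0.15, 0.22), rng.uniform(0.6, 0.68)))
        rows.append((f"L{i}", "LGD", 200, rng.uniform(8, 14),
                     rng.uniform(0.12, 0.2), rng.uniform(0.52, 0.58)))
    return make_frame(rows)


@pytest.fixture(scope="module")
def default_cohort():
    return features_frame(oc.generate_score_cohort(CohortSpec(seed=77)))


class TestSplit:
    def test_sixty_patients_split_30_30(self, default_cohort):
        train, test = split_cohort(default_cohort, 0.5, seed=0)
        assert len(train) == 30 and len(test) == 30
        assert set(train["patient_id"]).isdisjoint(test["patient_id"])

    def test_same_seed_identical(self, default_cohort):
        a1, b1 = split_cohort(default_cohort, 0.5, seed=9)
        a2, b2 = split_cohort(default_cohort, 0.5, seed=9)
        assert a1["patient_id"].tolist() == a2["patient_id"].tolist()
        assert b1["patient_id"].tolist() == b2["patient_id"].tolist()

    def test_stratified_proportions(self, default_cohort):
        train, _ = split_cohort(default_cohort, 0.5, seed=3)
        for cls, grp in default_cohort.groupby("label"):
            k = (train["label"] == cls).sum()
            assert abs(k - math.ceil(0.5 * len(grp))) <= 1

    def test_small_class_rejected(self):
        df = separable_frame(n=4)
        df = pd.concat([df, make_frame([("B0", "BNG", 200, 5.0, 0.1, np.nan)])])
        with pytest.raises(ValueError, match="BNG"):
            split_cohort(df, 0.5, seed=0)

    def test_fraction_bounds(self, default_cohort):
        with pytest.raises(ValueError):
            split_cohort(default_cohort, 1.0, seed=0)


class TestTest1:
    def test_separable_cohort_perfect_training_accuracy(self):
        df = separable_frame()
        m = train_test1(df)
        pred = m.predict_positive(df["mean_all"], df["pct_atypical"])
        assert np.array_equal(pred, (df["label"] == "OSCC").to_numpy())

    def test_heldout_sensitivity_on_published_distributions(self):
        """Cohorts from the published class score statistics give median
        held-out Test-1 sensitivity >= 0.85 over 20 seeded replicates."""
        sens = []
        for s in range(20):
            df = features_frame(oc.generate_score_cohort(CohortSpec(seed=800 + s)))
            train, test = split_cohort(df, 0.5, seed=s)
            m = train_test1(train, seed=s)
            pred = m.predict_positive(test["mean_all"], test["pct_atypical"])
            truth = (test["label"] == "OSCC").to_numpy()
            sens.append((pred & truth).sum() / truth.sum())
        assert np.median(sens) >= 0.85

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(13)
        accs = []
        for s in range(10):
            df = features_frame(oc.generate_score_cohort(CohortSpec(seed=900 + s)))
            df = df.copy()
            df["label"] = rng.permutation(df["label"].to_numpy())
            try:
                train, test = split_cohort(df, 0.5, seed=s)
                m = train_test1(train, seed=s)
            except ValueError:
                continue
            pred = m.predict_positive(test["mean_all"], test["pct_atypical"])
            truth = (test["label"] == "OSCC").to_numpy()
            accs.append((pred == truth).mean())
        assert accs and abs(np.mean(accs) - 0.5) < 0.2

    def test_single_class_rejected(self):
        df = separable_frame()
        with pytest.raises(ValueError):
            train_test1(df[df["label"] == "OSCC"])

    def test_undefined_features_rejected(self):
        df = separable_frame()
        df.loc[df.index[0], "mean_all"] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            train_test1(df)


class TestTest2:
    def test_cutoff_between_separated_groups(self):
        df = make_frame([
            ("O1", "OSCC", 200, 40, 0.4, 0.8), ("O2", "OSCC", 200, 40, 0.4, 0.9),
            ("L1", "LGD", 200, 10, 0.2, 0.55), ("L2", "LGD", 200, 10, 0.2, 0.6),
        ])
        t2 = derive_test2_cutoff(df)
        assert 0.6 < t2.cutoff < 0.8
        assert t2.youden_j == pytest.approx(1.0)

    def test_interleaved_scores_non_informative(self):
        df = make_frame([
            ("O1", "OSCC", 200, 40, 0.4, 0.6), ("O2", "OSCC", 200, 40, 0.4, 0.8),
            ("L1", "LGD", 200, 10, 0.2, 0.7), ("L2", "LGD", 200, 10, 0.2, 0.9),
        ])
        t2 = derive_test2_cutoff(df)
        assert t2.youden_j <= 0.5

    def test_missing_class_rejected(self):
        df = separable_frame()
        with pytest.raises(ValueError):
            derive_test2_cutoff(df[df["label"] != "LGD"])

    def test_identical_scores_rejected(self):
        df = make_frame([
            ("O1", "OSCC", 200, 40, 0.4, 0.7), ("L1", "LGD", 200, 10, 0.2, 0.7),
        ])
        with pytest.raises(ValueError, match="no discriminative cutoff"):
            derive_test2_cutoff(df)

    def test_cutoff_recovery_between_class_means(self):
        """With LGD and HGD atypical means >= 2 SD apart, the learned cutoff
        lands between them (20 seeds)."""
        specs = {k: dataclasses.replace(v) for k, v in DEFAULT_CLASS_SPECS.items()}
        specs["LGD"] = dataclasses.replace(specs["LGD"], mean_atypical=0.62,
                                           n_patients=8)
        specs["BNG"] = dataclasses.replace(specs["BNG"], mean_atypical=0.62)
        specs["HGD"] = dataclasses.replace(specs["HGD"], mean_atypical=0.76)
        specs["OSCC"] = dataclasses.replace(specs["OSCC"], mean_atypical=0.80)
        ok = 0
        for s in range(20):
            df = features_frame(oc.generate_score_cohort(
                CohortSpec(classes=specs, seed=2000 + s)))
            res = CascadeRiskModel(df).fit(seed=s)
            ok += 0.62 < res.model.test2.cutoff < 0.76
        assert ok >= 18


class TestCascadePredict:
    @staticmethod
    def fitted(df=None, seed=0):
        df = separable_frame() if df is None else df
        return CascadeRiskModel(df).fit(seed=seed)

    def test_test1_positive_short_circuits(self):
        res = self.fitted()
        row = {"mean_all": 0.45, "pct_atypical": 45.0, "mean_atypical": 0.0}
        before = res.model.test2_evaluations
        assert cascade_predict({**row, "mean_atypical": 0.99}, res.model) == "OSCC_risk"
        assert res.model.test2_evaluations == before  # Test 2 never ran

    def test_undefined_mean_atypical_is_negative(self):
        res = self.fitted()
        row = {"mean_all": 0.1, "pct_atypical": 0.0, "mean_atypical": float("nan")}
        assert cascade_predict(row, res.model) == "LGD_or_benign"

    def test_above_cutoff_is_hgd_risk(self):
        res = self.fitted()
        row = {"mean_all": 0.18, "pct_atypical": 12.0,
               "mean_atypical": res.model.test2.cutoff + 0.01}
        assert cascade_predict(row, res.model) == "HGD_risk"

    def test_strata_partition_cohort(self, default_cohort):
        res = CascadeRiskModel(default_cohort).fit(seed=1)
        pred = res.predict(default_cohort)
        counts = pred["stratum"].value_counts()
        assert counts.sum() == len(default_cohort)
        assert set(counts.index) <= {"OSCC_risk", "HGD_risk", "LGD_or_benign"}

    def test_results_summary_mentions_key_quantities(self, default_cohort):
        res = CascadeRiskModel(default_cohort).fit(seed=1)
        text = res.summary()
        assert "Test 1" in text and "cutoff" in text and "held-out" in text

    def test_model_serialisation_round_trip(self, default_cohort):
        from oralcyto.cascade import Test1Model

        res = CascadeRiskModel(default_cohort).fit(seed=2)
        d = res.to_dict()
        t1 = Test1Model.from_dict(d["test1"])
        x = default_cohort["mean_all"].to_numpy()
        y = default_cohort["pct_atypical"].to_numpy()
        assert np.allclose(t1.margin(x, y), res.model.test1.margin(x, y))


class TestCompareLearners:
    def test_separable_cohort_all_learners_perfect(self):
        train = separable_frame(seed=1)
        test = separable_frame(seed=2)
        table = compare_learners(train, test, seed=0)
        assert (table["accuracy"] == 100.0).all()

    def test_table_shape_and_columns(self, default_cohort):
        train, test = split_cohort(default_cohort, 0.5, seed=4)
        table = compare_learners(train, test, seed=4)
        assert len(table) == 5
        assert {"sensitivity", "specificity", "accuracy"} <= set(table.columns)
        assert table["error"].isna().all() or (table["error"].isnull()).all()

    def test_deterministic_given_seed(self, default_cohort):
        train, test = split_cohort(default_cohort, 0.5, seed=5)
        t1 = compare_learners(train, test, seed=5)
        t2 = compare_learners(train, test, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestFeatureCorrelation:
    def test_generator_defaults_reproduce_strong_correlation(self):
        """Pooled Pearson r between mean_all and pct_atypical exceeds 0.9 on
        generator-default cohorts."""
        from oralcyto.evaluation import pearson_correlation

        rs = []
        for s in range(5):
            df = features_frame(oc.generate_score_cohort(CohortSpec(seed=400 + s)))
            rs.append(pearson_correlation(df["mean_all"], df["pct_atypical"])[0])
        assert np.median(rs) > 0.9
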