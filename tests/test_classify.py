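import itertools

import numpy as np
import pandas as pd
import pytest

import plasticlass as pl
from plasticlass.anova import AnovaResult
from plasticlass.classify import CLASS_I, CLASS_I_EXCLUDED, CLASS_II, ROBUST


def _anova_from_q(q_env, q_int):
    ids = [f"g{i + 1}" for i in range(len(q_env))]
    table = pd.DataFrame(
        {
            "q_env": q_env, "q_int": q_int, "q_sex": 1.0,
            "p_env": q_env, "p_int": q_int, "p_sex": 1.0,
            "F_env": 1.0, "F_int": 1.0, "F_sex": 1.0,
        },
        index=ids,
    )
    return AnovaResult(table=table, df_resid=10, mse=pd.Series(1.0, index=ids))


class TestAssignClass1:
    def test_rule_truth_table(self):
        res = _anova_from_q(q_env=[0.01, 0.01, 0.5, 0.5], q_int=[0.5, 0.01, 0.01, 0.5])
        classes = pl.assign_class1(res, q_level=0.05)
        assert classes.table["label"].tolist() == [
            CLASS_I, CLASS_I_EXCLUDED, ROBUST, ROBUST
        ]
        assert classes.counts[CLASS_I] == 1
        assert classes.counts[CLASS_I_EXCLUDED] == 1

    def test_recovers_planted_class1(self, sim400, run400):
        _, _, truth, _ = sim400
        found = set(run400.classes.ids(CLASS_I))
        planted = set(truth.ids(CLASS_I))
        assert len(planted & found) / len(planted) >= 0.9


def _profile(cvme_f, cvme_m, mean=10.0):
    ids = [f"g{i + 1}" for i in range(len(cvme_f))]
    rows = []
    for gid, cf, cm in zip(ids, cvme_f, cvme_m):
        rows.append((gid, "female", mean, cf))
        rows.append((gid, "male", mean, cm))
    df = pd.DataFrame(rows, columns=["transcript", "sex", "mean", "CVME"])
    return df.set_index(["transcript", "sex"])


class TestCvmeThreshold:
    def test_order_statistic_convention(self):
        cvme = list(range(1, 101))
        prof = _profile(cvme, cvme)
        thr = pl.class1_cvme_threshold(prof, [f"g{i + 1}" for i in range(100)])
        # linear interpolation between the 95th and 96th order statistics
        expected = np.quantile(np.arange(1.0, 101.0), 0.95, method="linear")
        assert thr == {"female": pytest.approx(expected), "male": pytest.approx(expected)}
        assert 95.0 <= thr["female"] <= 96.0

    def test_all_equal_gives_that_value(self):
        prof = _profile([7.0] * 25, [7.0] * 25)
        thr = pl.class1_cvme_threshold(prof, [f"g{i + 1}" for i in range(25)])
        assert thr == {"female": 7.0, "male": 7.0}

    def test_monotone_under_adding_larger_values(self):
        base = list(np.linspace(1, 10, 30))
        t1 = pl.class1_cvme_threshold(
            _profile(base, base), [f"g{i + 1}" for i in range(30)]
        )
        bigger = base + [50.0] * 5
        t2 = pl.class1_cvme_threshold(
            _profile(bigger, bigger), [f"g{i + 1}" for i in range(35)]
        )
        assert t2["female"] > t1["female"]

    def test_too_few_class1_errors(self):
        prof = _profile([1.0] * 5, [1.0] * 5)
        with pytest.raises(ValueError, match="too few"):
            pl.class1_cvme_threshold(prof, [f"g{i + 1}" for i in range(5)])


class TestAssignClass2:
    def _setup(self):
        # g1: high CVME both sexes, low genetic variance -> classII both
        # g2: high CVME, genetically variable -> robust
        # g3: high CVME female only -> classII female_only
        # g4: already Class I -> stays Class I (overlap removal)
        # g5: low CVME -> robust
        prof = _profile(
            cvme_f=[20.0, 20.0, 20.0, 20.0, 1.0], cvme_m=[20.0, 20.0, 1.0, 20.0, 1.0]
        )
        genetic_q = pd.DataFrame(
            {"female": [0.9, 1e-6, 0.9, 0.9, 0.9], "male": [0.9, 1e-6, 0.9, 0.9, 0.9]},
            index=[f"g{i + 1}" for i in range(5)],
        )
        res = _anova_from_q(
            q_env=[0.5, 0.5, 0.5, 0.01, 0.5], q_int=[0.5, 0.5, 0.5, 0.5, 0.5]
        )
        classes = pl.assign_class1(res)
        thresholds = {"female": 10.0, "male": 10.0}
        return pl.assign_class2(prof, thresholds, genetic_q, classes)

    def test_filter_cascade_rules(self):
        classes = self._setup()
        labels = classes.table["label"]
        assert labels["g1"] == CLASS_II
        assert labels["g2"] == ROBUST  # genetically variable: filtered out
        assert labels["g3"] == CLASS_II
        assert labels["g4"] == CLASS_I  # overlap removed
        assert labels["g5"] == ROBUST
        assert classes.table.loc["g1", "classII_sex"] == "both"
        assert classes.table.loc["g3", "classII_sex"] == "female_only"

    def test_sex_category_counts_sum_to_total(self):
        classes = self._setup()
        assert sum(classes.classII_sex_counts.values()) == classes.counts[CLASS_II]

    def test_recovers_planted_class2(self, sim400, run400):
        _, _, truth, _ = sim400
        found = set(run400.classes.ids(CLASS_II))
        planted = set(truth.ids(CLASS_II))
        assert len(planted & found) / len(planted) >= 0.8


class TestPartitionProperty:
    def test_labels_cover_every_transcript_once(self, run400):
        table = run400.classes.table
        assert table["label"].isin([ROBUST, CLASS_I, CLASS_I_EXCLUDED, CLASS_II]).all()
        sets = [set(run400.classes.ids(lab)) for lab in
                (ROBUST, CLASS_I, CLASS_I_EXCLUDED, CLASS_II)]
        assert sum(len(s) for s in sets) == len(table)
        assert set.union(*sets) == set(table.index)


def brute_force_bipartition_ss(x):
    n = len(x)
    best = np.inf
    # element 0 fixed in group A; bits 0..n-2 place elements 1..n-1
    for mask in range(2 ** (n - 1) - 1):  # all-ones mask would empty group B
        a = [x[0]] + [x[i] for i in range(1, n) if (mask >> (i - 1)) & 1]
        b = [x[i] for i in range(1, n) if not ((mask >> (i - 1)) & 1)]
        if not b:
            continue
        a, b = np.array(a), np.array(b)
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        best = min(best, ss)
    return best


class TestOptimalBipartition:
    def test_hand_case(self):
        labels, ss = pl.optimal_bipartition([1.0, 2.0, 10.0, 11.0])
        assert list(labels) == ["low", "low", "high", "high"]
        assert ss == pytest.approx(1.0)

    def test_two_points(self):
        labels, ss = pl.optimal_bipartition([0.0, 10.0])
        assert list(labels) == ["low", "high"]
        assert ss == 0.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(2, 13))
            x = rng.normal(0, 3, n)
            _, ss = pl.optimal_bipartition(x)
            assert ss == pytest.approx(brute_force_bipartition_ss(list(x)), abs=1e-9)

    def test_all_identical_deterministic(self):
        labels1, ss1 = pl.optimal_bipartition([5.0] * 6)
        labels2, ss2 = pl.optimal_bipartition([5.0] * 6)
        assert list(labels1) == list(labels2)
        assert ss1 == ss2

    def test_group_labels_by_mean(self):
        labels, _ = pl.optimal_bipartition([11.0, 1.0, 2.0, 10.0])
        assert list(labels) == ["high", "low", "low", "high"]

    def test_class2_expression_split_populated(self, run400):
        table = run400.classes.table
        class2 = table["label"] == CLASS_II
        if class2.sum() >= 2:
            assert table.loc[class2, "classII_expr_female"].isin(["high", "low"]).all()
            assert table.loc[class2, "classII_expr_male"].isin(["high", "low"]).all()
        assert (table.loc[~class2, "classII_expr_female"] == "n/a").all()


class TestDimorphismRelation:
    def _sym_profile(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(5, 10, 20)
        ids = [f"g{i + 1}" for i in range(20)]
        rows = []
        for gid, v in zip(ids, vals):
            for sex in ("female", "male"):
                rows.append((gid, sex, v, v / 2))
        prof = pd.DataFrame(rows, columns=["transcript", "sex", "mean", "CVME"])
        return prof.set_index(["transcript", "sex"]), ids

    def test_identical_sexes_give_zero_dimorphism(self):
        prof, ids = self._sym_profile()
        res = _anova_from_q([0.5] * 20, [0.5] * 20)
        classes = pl.assign_class1(res)
        per_transcript, _ = pl.dimorphism_relation(prof, classes)
        assert (per_transcript["mean_dimorphism"] == 0).all()
        assert (per_transcript["plasticity_dimorphism"] == 0).all()

    def test_sex_swap_negates_axes_keeps_correlation(self, run400):
        per_transcript, per_class = pl.dimorphism_relation(
            run400.profile, run400.classes
        )
        swapped = run400.profile.rename(
            {"female": "male", "male": "female"}, level="sex"
        ).sort_index()
        pt_sw, pc_sw = pl.dimorphism_relation(swapped, run400.classes)
        np.testing.assert_allclose(
            pt_sw["mean_dimorphism"], -per_transcript["mean_dimorphism"], atol=1e-12
        )
        np.testing.assert_allclose(
            pc_sw["spearman_rho"], per_class["spearman_rho"], atol=1e-12
        )

    def test_planted_anticorrelation_detected(self, run400):
        # generator anti-correlates Class II sex bias of the mean with the
        # per-sex plasticity amplitude
        _, per_class = pl.dimorphism_relation(run400.profile, run400.classes)
        assert per_class.loc[CLASS_II, "spearman_rho"] < 0
        assert per_class.loc[CLASS_II, "p"] < 0.01
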