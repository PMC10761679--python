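"""Classification harness, AUC, sensitivity/specificity, combos, two-step rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from slipir.classify import (
    ModelConfig,
    enumerate_combos,
    one_vs_rest,
    repeat_harness,
    roc_auc,
    sens_spec,
    two_step_diagnosis,
)
from slipir.simulate import SimConfig, gen_count_matrix


def auc_oracle(scores, labels):
    """O(n^2) pairwise concordance with half-credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 20
            scores = np.round(rng.uniform(size=n), 1)  # induces ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSensSpec:
    def idx(self, n):
        return [f"x{i}" for i in range(n)]

    def test_discovery_cohort_arithmetic(self):
        # 139 cases (134 high), 106 controls (3 high): 137 high in total
        scores = pd.Series([1.0] * 134 + [0.0] * 5 + [1.0] * 3 + [0.0] * 103, index=self.idx(245))
        labels = pd.Series(["LC"] * 139 + ["NOR"] * 106, index=self.idx(245))
        sens, spec = sens_spec(scores, labels, "LC")
        assert round(100 * sens, 2) == 96.40
        assert round(100 * spec, 2) == 97.81

    def test_validation_cohort_arithmetic(self):
        # 26 cases all high, 7 of 27 controls high: 26/33 precision-style
        scores = pd.Series([1.0] * 26 + [1.0] * 7 + [0.0] * 20, index=self.idx(53))
        labels = pd.Series(["LC"] * 26 + ["NOR"] * 27, index=self.idx(53))
        sens, spec = sens_spec(scores, labels, "LC")
        assert round(100 * sens, 2) == 100.0
        assert round(100 * spec, 2) == 78.79

    def test_no_high_scores_gives_nan_specificity(self):
        scores = pd.Series([0.1, 0.2], index=self.idx(2))
        labels = pd.Series(["LC", "NOR"], index=self.idx(2))
        sens, spec = sens_spec(scores, labels, "LC")
        assert sens == 0.0 and np.isnan(spec)


class TestCombos:
    def test_five_types_give_31(self):
        assert len(enumerate_combos(["m", "mi", "sn", "sno", "ts"])) == 31

    def test_small_counts(self):
        assert len(enumerate_combos(["a"])) == 1
        assert len(enumerate_combos(["a", "b", "c"])) == 7

    def test_deterministic_order(self):
        combos = enumerate_combos(["b", "a"])
        assert combos == [("a",), ("b",), ("a", "b")]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            enumerate_combos([])


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=9, n_samples_per_class=25, planted_log2fc=2.0,
                    n_features_per_type={"mRNA": 55}, de_fraction=5 / 55)
    matrix, truth = gen_count_matrix(cfg)
    return matrix.log2rpm().T, matrix.sample_class, sorted(truth.planted_features["case"])


class TestRepeatHarness:
    def test_separable_panel_perfect_auc(self, planted):
        X, labels, panel = planted
        cfg = ModelConfig(n_repeats=10, lr_cv=3, seed=1)
        rep = repeat_harness(X, labels, panel, "lr", "case", cfg)
        assert np.median(rep.test_auc) == 1.0
        # out-of-fold scores only: each sample held out <= n_repeats times
        assert all(len(v) <= 10 for v in rep.sample_scores.values())

    def test_permuted_labels_auc_near_chance(self):
        # cohort-sized null: permutation kills the planted signal
        cfg_sim = SimConfig(seed=16, n_samples_per_class=60, planted_log2fc=2.0,
                            n_features_per_type={"mRNA": 55}, de_fraction=5 / 55)
        matrix, truth = gen_count_matrix(cfg_sim)
        X = matrix.log2rpm().T
        panel = sorted(truth.planted_features["case"])
        rng = np.random.default_rng(5)
        perm = pd.Series(rng.permutation(matrix.sample_class.to_numpy()),
                         index=X.index)
        cfg = ModelConfig(n_repeats=30, lr_cv=3, seed=2)
        rep = repeat_harness(X, perm, panel, "lr", "case", cfg)
        assert 0.4 <= np.median(rep.test_auc) <= 0.6

    def test_deterministic_rerun(self, planted):
        X, labels, panel = planted
        cfg = ModelConfig(n_repeats=5, lr_cv=3, seed=3)
        r1 = repeat_harness(X, labels, panel, "lr", "case", cfg)
        r2 = repeat_harness(X, labels, panel, "lr", "case", cfg)
        assert np.array_equal(r1.test_auc, r2.test_auc)
        assert r1.sample_scores == r2.sample_scores

    def test_svm_reports_no_risk_scores(self, planted):
        X, labels, panel = planted
        rep = repeat_harness(X, labels, panel, "svm", "case",
                             ModelConfig(n_repeats=3, seed=4))
        assert not rep.probabilistic
        assert all(len(v) == 0 for v in rep.sample_scores.values())

    def test_missing_panel_feature_error(self, planted):
        X, labels, _ = planted
        with pytest.raises(ValueError, match="missing"):
            repeat_harness(X, labels, ["nope"], "lr", "case", ModelConfig(n_repeats=2))


@pytest.fixture(scope="module")
def multiclass():
    cfg = SimConfig(seed=33, n_samples_per_class=20, planted_log2fc=2.5,
                    classes=("NOR", "LC", "GC"), de_fraction=0.05,
                    n_features_per_type={"mRNA": 100}, n_common_features=5)
    return gen_count_matrix(cfg)


class TestOneVsRestAndTwoStep:
    def test_scores_track_true_class(self, multiclass):
        matrix, truth = multiclass
        X = matrix.log2rpm().T
        panels = {cls: sorted(truth.planted_features[cls] - truth.planted_features["__common__"])
                  for cls in ("LC", "GC")}
        common = sorted(truth.planted_features["__common__"])
        cfg = ModelConfig(n_repeats=10, lr_cv=3, seed=6)
        reports, scores = one_vs_rest(X, matrix.sample_class, panels, "NOR",
                                      cfg, common_panel=common)
        assert set(scores.columns) == {"LC", "GC", "cancers"}
        labels = matrix.sample_class
        cancer = scores.loc[labels != "NOR", ["LC", "GC"]].dropna()
        top = cancer.idxmax(axis=1)
        agreement = (top == labels[cancer.index]).mean()
        assert agreement >= 0.9
        # controls score low everywhere
        assert (scores.loc[labels == "NOR"].median() < 0.5).all()

    def test_two_step_rule(self):
        assert two_step_diagnosis(0.9, {"LC": 0.3, "GC": 0.2}) == ("negative", [])
        assert two_step_diagnosis(0.9, {"LC": 0.8}) == ("positive", ["LC"])
        assert two_step_diagnosis(0.4, {"LC": 0.9}) == ("negative", [])

    def test_two_step_never_increases_positives(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            common = rng.uniform()
            types = {t: rng.uniform() for t in ("a", "b", "c")}
            single = common >= 0.5
            call, _ = two_step_diagnosis(common, types)
            assert not (call == "positive" and not single)


def test_noise_type_cannot_inflate_null_auc():
    """Adding pure-noise features to a null panel leaves median AUC ~0.5."""
    cfg_sim = SimConfig(seed=17, n_samples_per_class=60, planted_log2fc=0.0,
                        n_features_per_type={"mRNA": 55}, de_fraction=0.0)
    matrix, _ = gen_count_matrix(cfg_sim)
    X = matrix.log2rpm().T
    labels = matrix.sample_class
    nulls = [c for c in X.columns][:5]
    noisy = nulls + [c for c in X.columns][5:10]
    cfg = ModelConfig(n_repeats=30, lr_cv=3, seed=9)
    auc_small = np.median(repeat_harness(X, labels, nulls, "lr", "case", cfg).test_auc)
    auc_big = np.median(repeat_harness(X, labels, noisy, "lr", "case", cfg).test_auc)
    assert auc_big - auc_small <= 0.05
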