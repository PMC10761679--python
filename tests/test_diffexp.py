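"""NB Wald differential expression: oracles, calibration, candidate rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slipir.diffexp import (
    DEResults,
    bh_fdr,
    candidate_filter,
    cumulative_sum_compare,
    nb_wald_test,
    size_factors,
)
from slipir.simulate import SimConfig, gen_count_matrix


def median_of_ratios_oracle(counts: pd.DataFrame) -> np.ndarray:
    mat = counts.to_numpy(float)
    keep = (mat > 0).all(axis=1)
    geo = np.exp(np.log(mat[keep]).mean(axis=1))
    return np.median(mat[keep] / geo[:, None], axis=0)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"A": [10, 20, 5], "B": [10, 20, 5]})
        f = size_factors(counts)
        assert np.allclose(f, 1.0)

    def test_doubled_column_factor_ratio(self):
        counts = pd.DataFrame({"A": [10, 20, 5, 7], "B": [20, 40, 10, 14]})
        f = size_factors(counts)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_matches_direct_formula_on_random_matrix(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.3, size=(200, 8)) + 1)
        assert np.allclose(size_factors(counts), median_of_ratios_oracle(counts))

    def test_no_common_feature_error_without_fallback(self):
        counts = pd.DataFrame({"A": [1, 0], "B": [0, 1]})
        with pytest.raises(ValueError):
            size_factors(counts, allow_fallback=False)
        # fallback path still returns positive factors
        assert (size_factors(counts, allow_fallback=True) > 0).all()


class TestBhFdr:
    def test_hand_computation(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.04] * 5), 0.04)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_step_up_oracle(self):
        """Independent step-up computation: q_(i) = min_{j>=i} m p_(j)/j."""
        rng = np.random.default_rng(9)
        p = rng.uniform(size=40)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_fdr(p), oracle)

    def test_na_passthrough_and_range_check(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])


class TestNbWald:
    def test_identical_groups_give_zero_lfc(self):
        rng = np.random.default_rng(10)
        block = rng.negative_binomial(5, 0.3, size=(50, 4)) + 1
        counts = pd.DataFrame(np.hstack([block, block]),
                              columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        labels = pd.Series({f"a{i}": "ctrl" for i in range(4)} | {f"b{i}": "case" for i in range(4)})
        res = nb_wald_test(counts, labels, "case", "ctrl")
        assert np.allclose(res.table["log2FC"], 0.0, atol=1e-8)
        assert np.allclose(res.table["p"], 1.0, atol=1e-6)

    def test_planted_log2fc_recovered(self):
        cfg = SimConfig(seed=6, n_samples_per_class=50, planted_log2fc=2.0,
                        de_fraction=0.05, n_features_per_type={"mRNA": 1000})
        m, truth = gen_count_matrix(cfg)
        res = nb_wald_test(m.counts, m.sample_class, "case", "control")
        planted = sorted(truth.planted_features["case"])
        med = res.table.loc[planted, "log2FC"].median()
        assert med == pytest.approx(2.0, abs=0.2)

    def test_all_zero_feature_excluded_from_fdr(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.poisson(20, size=(20, 8)),
                              columns=[f"s{i}" for i in range(8)])
        counts.iloc[0] = 0
        labels = pd.Series({f"s{i}": ("case" if i < 4 else "ctrl") for i in range(8)})
        res = nb_wald_test(counts, labels, "case", "ctrl")
        assert np.isnan(res.table.iloc[0]["p"])
        assert np.isnan(res.table.iloc[0]["q"])

    def test_group_too_small(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]})
        labels = pd.Series({"a": "x", "b": "x", "c": "y"})
        with pytest.raises(ValueError):
            nb_wald_test(counts, labels, "x", "y")


class TestCandidateFilter:
    def make_de(self, q, lfc, mean_raw):
        table = pd.DataFrame({
            "baseMean": [mean_raw], "meanRawCount": [mean_raw],
            "log2FC": [lfc], "SE": [0.1], "stat": [1.0], "p": [q / 2], "q": [q],
        }, index=["f"])
        return DEResults(table, pd.Series(dtype=float), pd.Series(dtype=float), "case", "ctrl")

    def test_all_criteria_met(self):
        assert candidate_filter(self.make_de(0.05, 1.0, 50)).iloc[0]

    def test_mean_boundary_strict(self):
        assert not candidate_filter(self.make_de(0.05, 1.0, 9)).iloc[0]
        assert not candidate_filter(self.make_de(0.05, 1.0, 10)).iloc[0]
        assert candidate_filter(self.make_de(0.05, 1.0, 10.001)).iloc[0]

    def test_log2fc_boundary_strict(self):
        assert not candidate_filter(self.make_de(0.05, 0.8, 50)).iloc[0]
        assert candidate_filter(self.make_de(0.05, 0.8001, 50)).iloc[0]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame({
            "baseMean": rng.uniform(0, 100, 200),
            "meanRawCount": rng.uniform(0, 100, 200),
            "log2FC": rng.normal(0, 1.5, 200),
            "SE": 0.1, "stat": 0.0,
            "p": rng.uniform(0, 1, 200), "q": rng.uniform(0, 1, 200),
        }, index=[f"f{i}" for i in range(200)])
        de = DEResults(table, pd.Series(dtype=float), pd.Series(dtype=float), "c", "n")
        loose = candidate_filter(de, min_mean_count=5, min_log2fc=0.5)
        tight = candidate_filter(de, min_mean_count=20, min_log2fc=1.0)
        assert set(table.index[tight]) <= set(table.index[loose])


class TestCumulativeSum:
    def test_welch_matches_closed_form(self):
        a = np.array([12.0, 15.0, 11.0, 14.0, 13.0])
        b = np.array([10.0, 9.0, 11.0, 10.5])
        matrix = pd.DataFrame([np.concatenate([a, b])],
                              index=["f1"],
                              columns=[f"s{i}" for i in range(9)])
        groups = pd.Series({f"s{i}": ("A" if i < 5 else "B") for i in range(9)})
        sums, tests = cumulative_sum_compare(matrix, ["f1"], groups)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 4
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 3)
        row = tests.iloc[0]
        assert row["t"] == pytest.approx(t_oracle, rel=1e-12)
        assert row["df"] == pytest.approx(df_oracle, rel=1e-12)

    def test_planted_effect_dominance(self):
        cfg = SimConfig(seed=14, n_samples_per_class=30, planted_log2fc=2.0,
                        de_fraction=0.1, n_features_per_type={"mRNA": 200})
        m, truth = gen_count_matrix(cfg)
        planted = sorted(truth.planted_features["case"])
        sums, tests = cumulative_sum_compare(m.rpm(), planted, m.sample_class)
        case_med = sums[m.sample_class == "case"].median()
        ctrl_med = sums[m.sample_class == "control"].median()
        assert case_med > ctrl_med
        assert tests.iloc[0]["p"] < 1e-4

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            cumulative_sum_compare(pd.DataFrame(), [], pd.Series(dtype=object))
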