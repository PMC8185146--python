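"""Paired tests, effect sizes, normality gate and Cohen's kappa."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ultistate import (
    DegenerateSampleError,
    classify_effect_size,
    cohen_kappa,
    cohens_d_groups,
    cohens_d_paired,
    compare_winners_losers,
    effect_size_d,
    normality_gate,
    paired_t,
    paired_t_from_summary,
    wilcoxon_signed_rank,
)
from ultistate.inferential import compare_paired
import pandas as pd


class TestPairedT:
    @pytest.mark.parametrize(
        "mean, sd, n, expected",
        [
            (6.09, 12.44, 14, 1.832),
            (-7.29, 11.35, 14, -2.403),
        ],
    )
    def test_summary_statistics_exact_to_3dp(self, mean, sd, n, expected):
        t, df, p = paired_t_from_summary(mean, sd, n)
        assert df == n - 1
        assert round(t, 3) == expected

    def test_zero_mean_gives_t_zero(self):
        t, df, p = paired_t([1, -1, 1, -1])
        assert t == 0.0
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_raw_differences(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.4, 1.0, size=14)
        t, df, p = paired_t(d)
        ref = stats.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateSampleError):
            paired_t([2.0, 2.0, 2.0])


def exact_sign_permutation_p(diffs):
    """Independent oracle: enumerate all sign assignments of the
    nonzero differences and compute the two-tailed tail probability of
    the positive-rank-sum deviation."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    observed = abs(ranks[d > 0].sum() - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=len(ranks)):
        t_plus = sum(r for r, s in zip(ranks, signs) if s)
        if abs(t_plus - mu) >= observed - 1e-12:
            count += 1
    return count / 2 ** len(ranks)


class TestWilcoxon:
    def test_all_zero_differences_error(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_single_nonzero_difference(self):
        z, p = wilcoxon_signed_rank([3.0])
        assert p == pytest.approx(1.0)
        assert z == 0.0

    def test_example_against_enumeration(self):
        d = [1, 2, 3, -4, 5, 6, 7, 8]
        z, p_exact = wilcoxon_signed_rank(d, method="exact")
        assert p_exact == pytest.approx(exact_sign_permutation_p(d))
        _, p_approx = wilcoxon_signed_rank(d)
        assert p_approx == pytest.approx(p_exact, abs=0.02)
        # T+ = 32 > mu = 18: positive deviation
        assert z > 0

    def test_z_sign_follows_rank_sum_deviation(self):
        z_pos, _ = wilcoxon_signed_rank([1, 2, 3, -1.5])
        z_neg, _ = wilcoxon_signed_rank([-1, -2, -3, 1.5])
        assert z_pos > 0 > z_neg
        assert z_pos == pytest.approx(-z_neg)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-8, max_value=8).filter(lambda v: v != 0),
            min_size=3,
            max_size=10,
        )
    )
    def test_exact_method_matches_oracle(self, diffs):
        z, p = wilcoxon_signed_rank(diffs, method="exact")
        assert p == pytest.approx(exact_sign_permutation_p(diffs))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_approx_close_to_exact_for_small_n(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.5, 1.0, size=10)
        _, p_approx = wilcoxon_signed_rank(d)
        _, p_exact = wilcoxon_signed_rank(d, method="exact")
        assert p_approx == pytest.approx(p_exact, abs=0.05)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1.0, size=25)
        z, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue)
        assert abs(z) == pytest.approx(abs(ref.zstatistic))


class TestEffectSizes:
    def test_dz_is_mean_over_sd_of_differences(self):
        rng = np.random.default_rng(3)
        d = rng.normal(1.0, 2.0, size=30)
        assert cohens_d_paired(d) == pytest.approx(d.mean() / d.std(ddof=1))

    def test_printed_quotient(self):
        # M = 6.09, SD = 12.44 -> dz = 0.49
        assert round(6.09 / 12.44, 2) == 0.49
        d = np.array([6.09 - 12.44, 6.09, 6.09 + 12.44])
        # constructed sample with that mean and SD
        assert cohens_d_paired(d) == pytest.approx(6.09 / 12.44)

    def test_equal_group_means_give_zero(self):
        x = [1.0, 2.0, 3.0]
        y = [3.0, 2.0, 1.0]
        assert cohens_d_groups(x, y) == 0.0

    @pytest.mark.parametrize(
        "d, label",
        [(0.0, "trivial"), (0.19, "trivial"), (0.2, "small"), (-0.49, "small"),
         (0.54, "medium"), (-0.79, "medium"), (0.83, "large"), (-2.3, "large")],
    )
    def test_magnitude_bands(self, d, label):
        assert classify_effect_size(d) == label

    def test_effect_size_dispatch(self):
        d = [1.0, 2.0, 3.0]
        assert effect_size_d(differences=d, variant="dz") == cohens_d_paired(d)
        assert effect_size_d(
            groups=([1, 2, 3], [2, 3, 4]), variant="pooled_groups"
        ) == cohens_d_groups([1, 2, 3], [2, 3, 4])
        with pytest.raises(ValueError):
            effect_size_d(differences=d, variant="median")


class TestNormalityGate:
    def test_normal_samples_mostly_pass(self):
        passed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            if normality_gate(rng.normal(size=14)):
                passed += 1
        assert passed >= 90

    def test_extreme_outlier_fails(self):
        sample = [0.0] * 13 + [1e6]
        assert normality_gate(sample) is False

    def test_constant_sample_is_degenerate(self):
        assert normality_gate([2.0] * 14) is False

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestCompareWinnersLosers:
    def _null_tables(self, rng, n_games=14, cols=("x", "y")):
        w = pd.DataFrame({c: rng.normal(size=n_games) for c in cols})
        l = pd.DataFrame({c: rng.normal(size=n_games) for c in cols})
        return w, l

    def test_identical_columns_never_flagged(self):
        rng = np.random.default_rng(0)
        w, _ = self._null_tables(rng)
        results = compare_winners_losers(w, w.copy())
        assert all(not r.significant for r in results)
        assert all(r.test_used is None for r in results)

    def test_planted_shift_detected(self):
        # one variable shifted by 1 SD: flagged in >= 80% of replicates
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            w, l = self._null_tables(rng)
            w["x"] = l["x"] + 1.0 + rng.normal(size=14)
            results = {r.variable: r for r in compare_winners_losers(w, l)}
            if results["x"].significant:
                detected += 1
        assert detected >= 80

    def test_skewed_variable_routed_to_wilcoxon(self):
        rng = np.random.default_rng(1)
        w, l = self._null_tables(rng)
        w["x"] = l["x"] + np.concatenate([np.zeros(13) + 0.01, [50.0]])  # heavy skew
        results = {r.variable: r for r in compare_winners_losers(w, l)}
        assert results["x"].test_used == "wilcoxon"

    def test_type_i_error_near_nominal(self):
        # null generator: winner and loser columns iid; rejection rate
        # of the gated battery must be near alpha = 0.05 per variable
        n_reps = 1000
        rejections = {"x": 0, "y": 0}
        rng = np.random.default_rng(99)
        for _ in range(n_reps):
            for col in rejections:
                r = compare_paired(col, rng.normal(size=14), rng.normal(size=14))
                rejections[col] += r.significant
        for col, count in rejections.items():
            assert 0.01 <= count / n_reps <= 0.10

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            compare_winners_losers(pd.DataFrame({"x": [1, 2]}), pd.DataFrame({"x": [1]}))

    def test_df_and_test_choice_book_keeping(self):
        rng = np.random.default_rng(5)
        w, l = self._null_tables(rng)
        for r in compare_winners_losers(w, l):
            assert r.n_pairs == 14
            if r.test_used == "paired_t":
                assert r.df == 13
            else:
                assert r.df is None
            assert 0 <= r.p_two_tailed <= 1


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(list("abcabc"), list("abcabc")).kappa == 1.0

    def test_constant_identical_raters(self):
        # p_e = 1 degenerate case: defined as perfect agreement
        assert cohen_kappa(["x", "x", "x"], ["x", "x", "x"]).kappa == 1.0

    def test_balanced_disagreement_is_zero(self):
        # p_o = 0.5 = p_e by the marginal product
        res = cohen_kappa(["x", "x", "y", "y"], ["x", "y", "x", "y"])
        assert res.kappa == pytest.approx(0.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, size=10_000)
        b = rng.integers(0, 3, size=10_000)
        assert abs(cohen_kappa(a, b).kappa) < 0.05

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, size=500)
        b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 4, size=500))
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=2, max_size=40))
    def test_relabeling_invariance(self, labels_a):
        rng = np.random.default_rng(sum(labels_a) + len(labels_a))
        labels_b = rng.integers(0, 4, size=len(labels_a))
        mapping = {0: "w", 1: "x", 2: "y", 3: "z"}
        k1 = cohen_kappa(labels_a, labels_b).kappa
        k2 = cohen_kappa(
            [mapping[v] for v in labels_a], [mapping[int(v)] for v in labels_b]
        ).kappa
        assert k1 == pytest.approx(k2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 2], [1])
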