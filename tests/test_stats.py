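import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crocmotion.core_io import ValidationError
from crocmotion.stats import (
    bartlett_sphericity,
    exact_wilcoxon_rank_sum,
    exact_wilcoxon_signed_rank,
    holm_adjust,
    icc_oneway,
    model_ready_table,
    movement_pca,
    pca_two_variable,
    transform_positive_sqrt,
)
from crocmotion.synthetic import make_correlated_pair


def brute_force_signed_rank_p(x, y):
    """Enumerate all 2^m sign assignments of the nonzero |d| midranks."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    e_t = ranks.sum() / 2.0
    dev_obs = abs(t_obs - e_t)
    hits = 0
    for signs in itertools.product([0, 1], repeat=m):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if abs(t - e_t) >= dev_obs - 1e-12:
            hits += 1
    return hits / 2**m


def brute_force_rank_sum_p(a, b):
    """Enumerate all C(n, n_a) assignments of the pooled midranks."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a = a.size
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n_a].sum()
    e_w = n_a * (ranks.size + 1) / 2.0
    dev_obs = abs(w_obs - e_w)
    total = hits = 0
    for combo in itertools.combinations(range(ranks.size), n_a):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - e_w) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestPca:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pca_two_variable(x, 3.0 * x + 1.0)
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-12)
        assert res.loadings == pytest.approx([1.0, 1.0], abs=1e-12)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_closed_form_across_correlations(self):
        # r = 0 is excluded: the axis is then undefined up to rotation and
        # covered by test_uncorrelated_deterministic_axis
        for seed, r in enumerate([-0.8, -0.3, 0.4, 0.91, 0.99]):
            x, y = make_correlated_pair(60, r, seed=seed)
            res = pca_two_variable(x, y)
            assert res.eigenvalues[0] == pytest.approx(1 + abs(r), abs=1e-9)
            assert res.eigenvalues[1] == pytest.approx(1 - abs(r), abs=1e-9)
            assert abs(res.loadings[0]) == pytest.approx(
                math.sqrt((1 + abs(r)) / 2), abs=1e-9
            )

    def test_eigenvalues_sum_to_two_and_loading_identity(self):
        x, y = make_correlated_pair(50, 0.6, seed=4)
        res = pca_two_variable(x, y)
        assert res.eigenvalues.sum() == pytest.approx(2.0, abs=1e-9)
        assert (res.loadings**2).sum() == pytest.approx(
            res.eigenvalues[0], abs=1e-9
        )

    def test_scores_match_projection(self):
        x, y = make_correlated_pair(40, 0.7, seed=2)
        res = pca_two_variable(x, y)
        assert res.scores.var(ddof=1) == pytest.approx(res.eigenvalues[0], abs=1e-9)

    def test_uncorrelated_deterministic_axis(self):
        x, y = make_correlated_pair(30, 0.0, seed=0)
        res = pca_two_variable(x, y)
        assert res.eigenvalues == pytest.approx([1.0, 1.0], abs=1e-9)
        assert (res.loadings >= 0).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pca_two_variable(np.ones(10), np.arange(10.0))

    def test_movement_pca_from_table(self):
        x, y = make_correlated_pair(20, 0.5, seed=1)
        df = pd.DataFrame(
            {"total_walking_px": x, "total_head_movement_px": y}
        )
        res = movement_pca(df)
        assert res.correlation == pytest.approx(0.5, abs=1e-12)
        with pytest.raises(ValidationError):
            movement_pca(df.rename(columns={"total_walking_px": "w"}))


class TestBartlett:
    def test_zero_correlation(self):
        res = bartlett_sphericity(0.0, 100)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        res = bartlett_sphericity(0.5, 100)
        assert res.statistic == pytest.approx(97.5 * -math.log(0.75), abs=1e-9)
        assert res.df == 1

    def test_two_variables_always_df_one(self):
        assert bartlett_sphericity(0.91, 132).df == 1

    def test_singular_rejected(self):
        with pytest.raises(ValidationError):
            bartlett_sphericity(1.0, 50)


class TestTransformPositiveSqrt:
    def test_shift_and_root(self):
        out = transform_positive_sqrt(np.array([-4.0, 0.0, 5.0]))
        assert out == pytest.approx([0.0, 2.0, 3.0])

    def test_all_positive_no_shift(self):
        assert transform_positive_sqrt(np.array([1.0, 4.0])) == pytest.approx(
            [1.0, 2.0]
        )

    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=100, derandomize=True)
    def test_minimum_maps_to_zero_when_negative(self, values):
        v = np.asarray(values)
        out = transform_positive_sqrt(v)
        assert np.isfinite(out).all()
        if v.min() < 0:
            assert out.min() == pytest.approx(0.0, abs=1e-12)


class TestSignedRank:
    def test_identical_pairs(self):
        with pytest.warns(UserWarning):
            res = exact_wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p == 1.0 and res.statistic == 0.0

    def test_three_positive_differences(self):
        res = exact_wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.p == pytest.approx(0.25)

    def test_zeros_dropped_and_flagged(self):
        res = exact_wilcoxon_signed_rank([1.0, 5.0, 7.0], [1.0, 2.0, 3.0])
        assert res.zeros_dropped == 1

    @pytest.mark.parametrize("n", [4, 7, 11, 12])
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(8):
            # half-integer values force ties and zero differences
            x = np.round(rng.normal(0, 2, n) * 2) / 2
            y = np.round(rng.normal(0, 2, n) * 2) / 2
            res = exact_wilcoxon_signed_rank(x, y)
            assert res.p == pytest.approx(brute_force_signed_rank_p(x, y), abs=1e-12)

    def test_two_sided_symmetry_under_swap(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        a = exact_wilcoxon_signed_rank(x, y)
        b = exact_wilcoxon_signed_rank(y, x)
        assert a.p == pytest.approx(b.p, abs=1e-12)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)

    def test_matches_scipy_without_ties(self):
        from scipy.stats import wilcoxon

        rng = np.random.default_rng(12)
        x = rng.normal(size=11)
        y = rng.normal(size=11)
        # reflection two-sided p equals scipy's doubled one-tail for the
        # symmetric tie-free null
        ours = exact_wilcoxon_signed_rank(x, y)
        ref = wilcoxon(x, y, mode="exact", alternative="two-sided")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestRankSum:
    def test_disjoint_groups(self):
        res = exact_wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.p == pytest.approx(2.0 / 6.0)

    def test_identical_groups_full_ties(self):
        res = exact_wilcoxon_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.p == 1.0 and res.statistic == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            exact_wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(3, 4), (5, 5), (6, 6), (4, 8)])
    def test_matches_brute_force_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(6):
            a = np.round(rng.normal(0, 2, n_a) * 2) / 2
            b = np.round(rng.normal(0, 2, n_b) * 2) / 2
            res = exact_wilcoxon_rank_sum(a, b)
            assert res.p == pytest.approx(brute_force_rank_sum_p(a, b), abs=1e-12)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=7)
        b = rng.normal(size=9)
        assert exact_wilcoxon_rank_sum(a, b).p == pytest.approx(
            exact_wilcoxon_rank_sum(b, a).p, abs=1e-12
        )

    def test_rank_sum_expectation_closed_form(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=12)
        n_a = 5
        e_w = n_a * (vals.size + 1) / 2
        # average W over all assignments equals the closed form
        from scipy.stats import rankdata

        ranks = rankdata(vals)
        ws = [
            ranks[list(c)].sum()
            for c in itertools.combinations(range(vals.size), n_a)
        ]
        assert np.mean(ws) == pytest.approx(e_w)


class TestIcc:
    def test_perfect_repeatability(self):
        res = icc_oneway([1.0, 5.0, 9.0], [1.0, 5.0, 9.0])
        assert res.icc == pytest.approx(1.0)

    def test_hand_computed_anova(self):
        res = icc_oneway([1.0, 3.0, 5.0], [2.0, 4.0, 6.0])
        assert res.icc == pytest.approx(7.5 / 8.5, abs=1e-12)
        assert res.F == pytest.approx(16.0, abs=1e-12)
        assert (res.df1, res.df2) == (2, 3)

    def test_negative_icc_bounded(self):
        # identical subject means, nonzero within-pair spread
        res = icc_oneway([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert -1.0 <= res.icc < 0.0

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        p1 = rng.normal(size=15)
        p2 = p1 + rng.normal(0, 0.8, size=15)
        res = icc_oneway(p1, p2)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile([1, 2], 15),
                "score": np.column_stack([p1, p2]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        icc1 = ref.loc[ref.Type.str.startswith("ICC1") | (ref.Type == "ICC(1,1)"),
                       "ICC"].iloc[0]
        assert res.icc == pytest.approx(icc1, abs=1e-9)

    def test_variance_ratio_recovery(self):
        rng = np.random.default_rng(42)
        n, sb, sw = 200, 2.0, 1.0
        subj = rng.normal(0, math.sqrt(sb), n)
        p1 = subj + rng.normal(0, math.sqrt(sw), n)
        p2 = subj + rng.normal(0, math.sqrt(sw), n)
        res = icc_oneway(p1, p2)
        truth = sb / (sb + sw)
        assert res.icc == pytest.approx(truth, abs=0.1)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            icc_oneway([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_pair(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=9)
        ours = holm_adjust(p)
        ref = multipletests(p, method="holm")[1]
        assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=15))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_bounded(self, pvals):
        adj = holm_adjust(pvals)
        assert ((adj >= np.asarray(pvals) - 1e-15) & (adj <= 1.0)).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.2])


class TestModelReadyTable:
    def test_adds_transformed_component(self):
        x, y = make_correlated_pair(24, 0.8, seed=6)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(24)],
                "total_walking_px": x,
                "total_head_movement_px": y,
            }
        )
        out = model_ready_table(df)
        assert "movement_component" in out and "movement_component_sqrt" in out
        assert (out["movement_component_sqrt"] >= 0).all()
        assert out["movement_component_sqrt"].min() == pytest.approx(0.0, abs=1e-12)
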