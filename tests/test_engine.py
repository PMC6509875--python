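"""Core BASE statistic: cumulative functions, score, permutation null, FDR."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from basetf.core import BindingCountMatrix, DifferentiationProfile, ExpressionPair
from basetf.engine import (
    DegenerateDirectionError,
    adjust_fdr,
    base_cdfs,
    base_score,
    diff_expression,
    permutation_pvalue,
    run_base,
)


def brute_force_exact_p(d_dir, b):
    """Independent oracle: re-derive f0/f1/delta per pairing from scratch."""
    d_dir = list(map(float, d_dir))
    b = list(map(float, b))
    n = len(d_dir)
    order = sorted(range(n), key=lambda i: (-d_dir[i], i))
    d_sorted = [d_dir[i] for i in order]
    total = sum(d_sorted)
    f0 = [sum(d_sorted[: i + 1]) / total for i in range(n)]
    # gaps are compared at the close of each run of tied d values
    ends = [i for i in range(n) if i == n - 1 or d_sorted[i] != d_sorted[i + 1]]

    def delta_for(b_vec):
        w = [d_sorted[i] * b_vec[i] for i in range(n)]
        wt = sum(w)
        if wt <= 0:
            return 0.0
        f1 = [sum(w[: i + 1]) / wt for i in range(n)]
        return max(f1[i] - f0[i] for i in ends)

    observed = delta_for([b[i] for i in order])
    null = [delta_for(list(perm)) for perm in permutations(b)]
    p = sum(1 for s in null if s > observed + 1e-12) / len(null)
    return observed, p


class TestDiffExpression:
    def test_equal_abundance_gives_zero(self):
        pair = ExpressionPair(["a", "b"], np.array([2.0, 5.0]), np.array([2.0, 5.0]))
        prof = diff_expression(pair)
        assert np.all(prof.d == 0) and np.all(prof.d_up == 0) and np.all(prof.d_down == 0)

    def test_e_fold_change_is_one(self):
        pair = ExpressionPair(["a"], np.array([3.0]), np.array([3.0 * math.e]))
        assert diff_expression(pair).d[0] == pytest.approx(1.0)

    def test_directional_split(self):
        pair = ExpressionPair(["a", "b"], np.array([1.0, 1.0]), np.array([2.0, 0.5]))
        prof = diff_expression(pair)
        np.testing.assert_allclose(prof.d, [math.log(2), -math.log(2)])
        np.testing.assert_allclose(prof.d_up, [math.log(2), 0.0])
        np.testing.assert_allclose(prof.d_down, [0.0, math.log(2)])

    def test_nonpositive_genes_dropped(self):
        pair = ExpressionPair(["a", "b", "c"], np.array([1.0, 0.0, 2.0]),
                              np.array([2.0, 1.0, 0.0]))
        prof = diff_expression(pair)
        assert prof.gene_ids == ["a"]

    def test_all_dropped_raises(self):
        pair = ExpressionPair(["a"], np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            diff_expression(pair)


class TestCdfsAndScore:
    def test_constant_weights_collapse(self):
        d = np.array([3.0, 1.0, 2.0])
        f0, f1 = base_cdfs(d, np.full(3, 7.0))
        np.testing.assert_allclose(f0, f1)
        assert base_score(f0, f1) == pytest.approx(0.0)

    def test_hand_cumulative_two_genes(self):
        f0, f1 = base_cdfs(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        np.testing.assert_allclose(f0, [0.5, 1.0])
        np.testing.assert_allclose(f1, [1.0, 1.0])

    def test_hand_cumulative_three_genes(self):
        f0, f1 = base_cdfs(np.array([3.0, 2.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(f0, [0.5, 5.0 / 6.0, 1.0])
        np.testing.assert_allclose(f1, [1.0, 1.0, 1.0])
        assert base_score(f0, f1) == pytest.approx(0.5)

    def test_cdf_invariants(self, rng):
        for _ in range(20):
            d = np.abs(rng.normal(size=30))
            b = rng.poisson(1.0, 30).astype(float)
            if (d * b).sum() == 0:
                continue
            f0, f1 = base_cdfs(d, b)
            for f in (f0, f1):
                assert f[-1] == pytest.approx(1.0, abs=1e-12)
                assert np.all(np.diff(f) >= -1e-12)

    def test_negative_gap_floors_at_later_max(self):
        # f1 below f0 early but equal at the end: max gap is 0
        assert base_score(np.array([0.5, 1.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_no_differentiation_raises(self):
        with pytest.raises(DegenerateDirectionError):
            base_cdfs(np.zeros(3), np.ones(3))

    def test_zero_weight_overlap_raises(self):
        with pytest.raises(DegenerateDirectionError):
            base_cdfs(np.array([1.0, 0.0]), np.array([0.0, 5.0]))


class TestPermutationPvalue:
    def test_exact_middle_weight(self):
        res = permutation_pvalue(np.array([3.0, 2.0, 1.0]), np.array([0.0, 1.0, 0.0]),
                                 exact=True)
        assert res.delta == pytest.approx(1.0 / 6.0)
        assert res.p_value == pytest.approx(2.0 / 6.0)
        np.testing.assert_allclose(
            sorted(res.null_scores), [0, 0, 1 / 6, 1 / 6, 0.5, 0.5], atol=1e-12
        )

    def test_exact_top_weight_is_extreme(self):
        res = permutation_pvalue(np.array([3.0, 2.0, 1.0]), np.array([1.0, 0.0, 0.0]),
                                 exact=True)
        assert res.delta == pytest.approx(0.5)
        assert res.p_value == 0.0

    def test_constant_b_degenerate(self):
        res = permutation_pvalue(np.array([3.0, 2.0, 1.0]), np.full(3, 2.0), exact=True)
        assert res.delta == pytest.approx(0.0)
        assert res.p_value == 0.0
        assert np.allclose(res.null_scores, 0.0)

    def test_exact_mode_rejects_large_n(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.arange(1.0, 10.0), np.ones(9), exact=True)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7])
    def test_exact_matches_brute_force_oracle(self, n, rng):
        for _ in range(3):
            d = np.round(np.abs(rng.normal(size=n)), 3)
            b = rng.poisson(1.2, n).astype(float)
            if d.sum() == 0 or (d * b).sum() == 0:
                b = np.ones(n)
            res = permutation_pvalue(d, b, exact=True)
            delta_o, p_o = brute_force_exact_p(d, b)
            assert res.delta == pytest.approx(delta_o, abs=1e-12)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_sampled_converges_to_exact(self, rng):
        d = np.abs(rng.normal(size=7))
        b = rng.poisson(1.5, 7).astype(float) + np.array([3, 0, 0, 0, 0, 0, 0.0])
        exact_p = permutation_pvalue(d, b, exact=True).p_value
        for K in (1000, 100_000):
            p = permutation_pvalue(d, b, K=K, seed=7).p_value
            se = math.sqrt(max(exact_p * (1 - exact_p), 1e-6) / K)
            assert abs(p - exact_p) <= 3 * se + 1e-9

    def test_tie_order_invariance_exact(self):
        # reshuffling tied d entries (with their b) leaves the exact p unchanged
        d = np.array([2.0, 2.0, 1.0, 1.0])
        b = np.array([3.0, 0.0, 1.0, 2.0])
        p_ref = permutation_pvalue(d, b, exact=True).p_value
        reorder = [1, 0, 3, 2]
        p_alt = permutation_pvalue(d[reorder], b[reorder], exact=True).p_value
        assert p_alt == pytest.approx(p_ref, abs=1e-12)

    def test_add_one_never_zero(self):
        res = permutation_pvalue(np.array([3.0, 2.0, 1.0]), np.array([1.0, 0.0, 0.0]),
                                 exact=True, add_one=True)
        assert res.p_value == pytest.approx(1.0 / 7.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        c1=st.floats(1e-6, 1e6),
        c2=st.floats(1e-6, 1e6),
    )
    def test_scale_free(self, seed, c1, c2):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        d = np.abs(rng.normal(size=n))
        b = rng.poisson(1.0, n).astype(float)
        if (d * b).sum() == 0:
            b = b + 1
        delta = base_score(*base_cdfs(d, b))
        delta_scaled = base_score(*base_cdfs(c1 * d, c2 * b))
        assert delta_scaled == pytest.approx(delta, abs=1e-12)


class TestRunBase:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        d = rng.normal(size=40)
        counts = rng.poisson(1.0, size=(40, 3))
        profile = DifferentiationProfile(genes, d)
        matrix = BindingCountMatrix(genes, ["mA", "mB", "mC"], counts)
        return profile, matrix

    def test_two_rows_per_motif_sorted_by_p(self):
        profile, counts = self._toy()
        results = run_base(profile, counts, K=200, seed=1)
        assert len(results) == 6
        for direction in ("up", "down"):
            fam = [r for r in results if r.direction == direction]
            assert [r.p_value for r in fam] == sorted(r.p_value for r in fam)
            assert all(r.q_value >= r.p_value for r in fam)

    def test_constant_weights_flagged_both_directions(self):
        genes = [f"g{i}" for i in range(10)]
        profile = DifferentiationProfile(genes, np.linspace(-1, 1, 10))
        counts = BindingCountMatrix(genes, ["m"], np.full((10, 1), 2))
        results = run_base(profile, counts, K=50, seed=0)
        assert all("constant-weights" in r.flags for r in results)

    def test_motif_order_independence(self):
        profile, counts = self._toy()
        ref = {(r.motif_id, r.direction): r.p_value
               for r in run_base(profile, counts, K=300, seed=9)}
        shuffled = BindingCountMatrix(
            counts.gene_ids, ["mC", "mA", "mB"],
            counts.counts[:, [2, 0, 1]],
        )
        alt = {(r.motif_id, r.direction): r.p_value
               for r in run_base(profile, shuffled, K=300, seed=9)}
        assert ref == alt

    def test_inner_join_and_empty_intersection(self):
        profile, counts = self._toy()
        sub = BindingCountMatrix(counts.gene_ids[:20], counts.motif_ids,
                                 counts.counts[:20])
        results = run_base(profile, sub, K=50, seed=0)
        assert all(r.n_genes == 20 for r in results)
        disjoint = BindingCountMatrix(["x1", "x2"], ["m"], np.ones((2, 1), dtype=int))
        with pytest.raises(ValueError):
            run_base(profile, disjoint, K=50, seed=0)

    def test_rank_based_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(60)]
        d = rng.uniform(0.1, 2.0, size=60)  # strictly positive
        counts = BindingCountMatrix(genes, ["m1", "m2"], rng.poisson(1.0, (60, 2)))
        base = run_base(DifferentiationProfile(genes, d), counts,
                        K=400, seed=3, rank_based=True)
        cubed = run_base(DifferentiationProfile(genes, d**3), counts,
                         K=400, seed=3, rank_based=True)
        for r1, r2 in zip(base, cubed):
            assert (r1.motif_id, r1.direction) == (r2.motif_id, r2.direction)
            assert r1.delta == pytest.approx(r2.delta, abs=1e-12)
            assert r1.p_value == r2.p_value


class TestAdjustFdr:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03], "bh"),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2], "bh")[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.all(adjust_fdr(np.ones(5), "bh") == 1.0)
        assert np.all(adjust_fdr(np.ones(5), "storey") == 1.0)

    def test_empty_input(self):
        assert adjust_fdr([], "bh").size == 0

    def test_bh_monotone_and_above_p(self, rng):
        p = rng.uniform(size=50)
        q = adjust_fdr(p, "bh")
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_storey_floored_at_p(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(0.6, 1, 45)])
        q = adjust_fdr(p, "storey")
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
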