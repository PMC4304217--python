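import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lfcseq.counts_io import ConditionDesign, CountMatrix
from lfcseq.core import (
    LFCseqConfig,
    NullPool,
    build_neighborhood,
    enumerate_partitions,
    lfc_statistic,
    null_distribution,
    null_pool_sd,
    prob_nonDE,
    run_lfcseq,
    within_condition_pool,
)
from lfcseq.evaluate import auc
from lfcseq.simulate import SimulationParams, simulate_sim1


def brute_force_neighbors(means, i, k):
    """{i} plus the k-1 genes nearest in mean, ties by input order."""
    order = sorted(
        (j for j in range(len(means)) if j != i),
        key=lambda j: (abs(means[j] - means[i]), j),
    )
    return sorted([i] + order[: k - 1])


class TestLfcStatistic:
    @pytest.mark.parametrize(
        "a,b,expected", [(5, 5, 0.0), (8, 2, 2.0), (0.5, 8, -4.0)]
    )
    def test_closed_form(self, a, b, expected):
        assert lfc_statistic(a, b) == pytest.approx(expected)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            lfc_statistic(0.0, 1.0)


class TestWithinConditionPool:
    def test_constant_gene_pools_zeros(self):
        norm = np.full((3, 4), 7.0)
        ps = enumerate_partitions(range(4))
        pool = within_condition_pool(norm, ps)
        np.testing.assert_allclose(pool, 0.0)

    def test_two_samples_single_value(self):
        norm = np.array([[4.0, 16.0]])
        ps = enumerate_partitions([0, 1])
        pool = within_condition_pool(norm, ps)
        assert abs(pool[0, 0]) == pytest.approx(2.0)

    def test_pool_size_matches_partition_count(self):
        norm = np.random.default_rng(0).uniform(1, 100, size=(6, 5))
        pool = within_condition_pool(norm, enumerate_partitions(range(5)))
        assert pool.shape == (6, 10)


class TestNeighborhood:
    def test_k1_is_self(self):
        nb = build_neighborhood([3.0, 1.0, 2.0], k=1)
        np.testing.assert_array_equal(nb.members[:, 0], [0, 1, 2])
        np.testing.assert_allclose(nb.epsilon, 0.0)

    def test_k_equals_g_takes_all_genes(self):
        nb = build_neighborhood([1.0, 2.0, 10.0], k=3)
        for i in range(3):
            assert sorted(nb.members[i]) == [0, 1, 2]

    def test_k_above_g_warns_and_clamps(self):
        nb = build_neighborhood([1.0, 5.0], k=50)
        assert nb.k == 2

    def test_simple_nearest(self):
        nb = build_neighborhood([1.0, 2.0, 3.0, 10.0], k=2)
        assert set(nb.members[1]) == {1, 0}  # 1 and 3 tie at dist 1; input order

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        g = int(rng.integers(5, 40))
        # duplicated values exercise the tie-break rule
        means = np.round(rng.uniform(0, 10, size=g), 1)
        k = int(rng.integers(1, g + 1))
        nb = build_neighborhood(means, k=k)
        for i in range(g):
            assert sorted(nb.members[i]) == brute_force_neighbors(means, i, k), (
                f"gene {i}, k={k}"
            )

    def test_self_always_member_even_with_mass_ties(self):
        means = np.zeros(10)
        nb = build_neighborhood(means, k=3)
        for i in range(10):
            assert i in nb.members[i]

    def test_epsilon_is_realized_halfwidth(self):
        means = np.array([0.0, 1.0, 4.0, 9.0])
        nb = build_neighborhood(means, k=2)
        assert nb.epsilon[0] == pytest.approx(1.0)
        assert nb.epsilon[3] == pytest.approx(5.0)


class TestNullDistribution:
    def _pools(self, g, ma, mb, seed=0):
        rng = np.random.default_rng(seed)
        return NullPool(pool_A=rng.normal(size=(g, ma)),
                        pool_B=rng.normal(size=(g, mb)))

    def test_size_is_neighbors_times_pools(self):
        pools = self._pools(60, 1, 1)
        nb = build_neighborhood(np.arange(60.0), k=50)
        assert null_distribution(0, pools, nb).size == 50 * 2

    def test_size_with_five_samples_per_condition(self):
        pools = self._pools(60, 10, 10)
        nb = build_neighborhood(np.arange(60.0), k=50)
        assert null_distribution(10, pools, nb).size == 50 * 20

    def test_k1_null_is_own_pools(self):
        pools = self._pools(5, 3, 3)
        nb = build_neighborhood(np.arange(5.0), k=1)
        np.testing.assert_array_equal(
            np.sort(null_distribution(2, pools, nb)),
            np.sort(np.concatenate([pools.pool_A[2], pools.pool_B[2]])),
        )

    def test_duplicates_retained(self):
        pools = NullPool(pool_A=np.ones((2, 3)), pool_B=np.ones((2, 2)))
        nb = build_neighborhood([1.0, 1.0], k=2)
        assert null_distribution(0, pools, nb).size == 10


class TestProbNonDE:
    def test_direct_count(self):
        assert prob_nonDE(1.0, [-3, 2, 0.5, -1]) == pytest.approx(0.5)

    def test_statistic_beyond_null_gives_zero(self):
        assert prob_nonDE(5.0, [-3, 2, 0.5, -1]) == 0.0

    def test_zero_statistic_with_nonzero_null_gives_one(self):
        assert prob_nonDE(0.0, [-3, 2, 0.5, -1]) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            prob_nonDE(1.0, [])

    def test_equal_magnitude_excluded_from_numerator(self):
        # strict inequality: |l| > |L|, so an exact tie does not count
        assert prob_nonDE(2.0, [2.0, -2.0, 3.0]) == pytest.approx(1 / 3)

    @given(
        L=st.floats(-10, 10),
        null=st.lists(st.floats(-10, 10), min_size=1, max_size=50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_count(self, L, null):
        expected = sum(1 for l in null if abs(l) > abs(L)) / len(null)
        assert prob_nonDE(L, null) == pytest.approx(expected)

    @given(null=st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_nonincreasing_in_statistic(self, null):
        probs = [prob_nonDE(L, null) for L in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


class TestRunLfcseq:
    def _dataset(self, g=200, n=5, seed=11, **kw):
        return simulate_sim1(SimulationParams(n_genes=g, n_A=n, n_B=n,
                                              seed=seed, **kw))

    def test_identical_conditions_make_no_calls(self):
        rng = np.random.default_rng(0)
        half = rng.integers(1, 100, size=(100, 3))
        counts = CountMatrix(
            [f"g{i}" for i in range(100)],
            [f"s{j}" for j in range(6)],
            np.hstack([half, half]),  # condition B byte-identical to A
        )
        design = ConditionDesign({f"s{j}": ("A" if j < 3 else "B") for j in range(6)})
        res = run_lfcseq(counts, design, LFCseqConfig(seed=0))
        np.testing.assert_allclose(res["log2FC"], 0.0)
        assert res["de_call"].sum() == 0

    def test_strong_signal_ranks_true_genes_first(self):
        # 16-fold changes: the DE genes must be perfectly separable
        ds = self._dataset(g=200, n=5, seed=3,
                           fold_law=lambda rng, size: np.full(size, 16.0),
                           prop_DE=0.1)
        res = run_lfcseq(ds.counts, ds.design, LFCseqConfig(seed=3))
        truth = ds.truth[np.isin(ds.counts.gene_ids, res["gene_id"])]
        assert auc(1 - res["prob_nonDE"].to_numpy(), truth) == pytest.approx(1.0)

    def test_rerun_same_seed_is_bit_identical(self, tmp_path):
        from lfcseq.counts_io import write_results

        ds = self._dataset(g=150, n=8, seed=5)
        cfg = LFCseqConfig(seed=42)
        for name in ("a.tsv", "b.tsv"):
            write_results(run_lfcseq(ds.counts, ds.design, cfg), tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_requires_two_samples_per_condition(self):
        counts = CountMatrix(["g1", "g2"], ["s1", "s2", "s3"],
                             [[1, 2, 3], [4, 5, 6]])
        design = ConditionDesign({"s1": "A", "s2": "B", "s3": "B"})
        with pytest.raises(ValueError, match="at least 2"):
            run_lfcseq(counts, design)

    def test_common_null_when_k_covers_all_genes(self):
        # with k = G every gene shares one null; permuting gene order
        # leaves each gene's probability unchanged
        ds = self._dataset(g=80, n=4, seed=9)
        cfg = LFCseqConfig(k=10**6, seed=1)
        res = run_lfcseq(ds.counts, ds.design, cfg)

        perm = np.random.default_rng(0).permutation(ds.counts.n_genes)
        counts_p = CountMatrix(ds.counts.gene_ids[perm], ds.counts.sample_ids,
                               ds.counts.counts[perm])
        res_p = run_lfcseq(counts_p, ds.design, cfg).set_index("gene_id")
        orig = res.set_index("gene_id")
        np.testing.assert_allclose(
            res_p.loc[orig.index, "prob_nonDE"], orig["prob_nonDE"], atol=1e-12
        )


class TestNullPoolSd:
    def test_constant_null_sd_zero(self):
        pools = NullPool(pool_A=np.ones((3, 2)), pool_B=np.ones((3, 2)))
        nb = build_neighborhood([1.0, 2.0, 3.0], k=1)
        np.testing.assert_allclose(null_pool_sd(pools, nb), 0.0)

    def test_two_point_null_closed_form(self):
        pools = NullPool(pool_A=np.array([[-1.0]]), pool_B=np.array([[1.0]]))
        nb = build_neighborhood([1.0], k=1)
        assert null_pool_sd(pools, nb)[0] == pytest.approx(np.sqrt(2))

    def test_sd_trend_nonincreasing_on_simulated_data(self):
        # the motivating diagnostic: null spread falls as expression grows
        ds = simulate_sim1(SimulationParams(n_genes=1500, n_A=5, n_B=5, seed=2))
        from lfcseq.counts_io import drop_allzero_genes, replace_zeros
        from lfcseq.core import group_means
        from lfcseq.normalization import estimate_depths, normalize

        m = drop_allzero_genes(ds.counts)
        norm = replace_zeros(normalize(m, estimate_depths(m)), m.counts)
        idx_a = np.arange(5)
        idx_b = np.arange(5, 10)
        _, _, mean_ab = group_means(norm, idx_a, idx_b)
        pools = NullPool(
            pool_A=within_condition_pool(norm, enumerate_partitions(idx_a)),
            pool_B=within_condition_pool(norm, enumerate_partitions(idx_b)),
        )
        nb = build_neighborhood(mean_ab, k=50)
        sd = null_pool_sd(pools, nb)

        order = np.argsort(mean_ab)
        bins = np.array_split(order, 10)
        binned = np.array([sd[b].mean() for b in bins])
        # low-expression bins must be noisier than high-expression bins,
        # and the fitted trend of sd against expression must be decreasing
        assert binned[0] > binned[-1]
        from scipy import stats

        assert stats.spearmanr(mean_ab, sd).statistic < 0
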