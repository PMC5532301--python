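"""MLL calling, consensus genotypes, P_GEN and P_SEX."""

import numpy as np
import pytest

from msatpop import (
    GenotypeTable,
    SimConfig,
    assign_mll,
    consensus_genotypes,
    p_gen,
    p_sex,
    pairwise_locus_differences,
    simulate_genotypes,
)
from msatpop.clonality import ComputationError


def table_from_rows(rows, n_loci=None):
    rows = [np.asarray(r) for r in rows]
    return GenotypeTable(
        [f"s{i}" for i in range(len(rows))],
        [f"L{j}" for j in range(rows[0].shape[0])],
        np.stack(rows),
    )


class TestPairwiseDifferences:
    def test_identical_genotypes(self, rng):
        row = 100 + 4 * rng.integers(0, 5, size=(27, 2))
        t = table_from_rows([row, row])
        d, c = pairwise_locus_differences(t)
        assert (d[0, 1], c[0, 1]) == (0, 27)

    def test_pair_order_is_not_a_difference(self):
        t = table_from_rows([[[100, 104]], [[104, 100]]])
        d, c = pairwise_locus_differences(t)
        assert (d[0, 1], c[0, 1]) == (0, 1)

    def test_differences_and_missing_counted(self, rng):
        """4 differing loci of 27, one extra locus missing in one sample."""
        a = np.sort(100 + 4 * rng.integers(0, 5, size=(27, 2)), axis=1)
        b = a.copy()
        for l in range(4):
            b[l] = [200, 204]
        b[26] = [0, 0]
        t = table_from_rows([a, b])
        d, c = pairwise_locus_differences(t)
        assert (d[0, 1], c[0, 1]) == (4, 26)
        # oracle: direct per-locus count
        n_diff = sum(
            1
            for l in range(27)
            if a[l, 0] != 0 and b[l, 0] != 0 and tuple(a[l]) != tuple(b[l])
        )
        assert d[0, 1] == n_diff

    def test_matrix_symmetric_zero_diagonal(self, rng):
        t = table_from_rows([100 + 4 * rng.integers(0, 3, size=(6, 2)) for _ in range(5)])
        d, c = pairwise_locus_differences(t)
        assert np.array_equal(d, d.T) and np.all(np.diag(d) == 0)
        assert np.array_equal(c, c.T)


class TestAssignMll:
    def make_chain(self):
        """A-B differ at 2 loci, B-C at 2 loci, A-C at 4 loci."""
        base = np.tile([100, 104], (10, 1))
        a = base.copy()
        b = base.copy()
        b[0] = b[1] = [108, 108]
        c = base.copy()
        c[0] = c[1] = [108, 108]
        c[2] = c[3] = [112, 112]
        return table_from_rows([a, b, c])

    def test_single_linkage_chains(self):
        t = self.make_chain()
        res = assign_mll(t, max_diff=3)
        assert res.n_mll == 1
        assert len(set(res.mll_of_sample)) == 1

    def test_all_distinct_when_far_apart(self, rng):
        rows = []
        for i in range(6):
            row = np.tile([100 + 20 * i, 100 + 20 * i], (8, 1))
            rows.append(row)
        res = assign_mll(table_from_rows(rows), max_diff=3)
        assert res.n_mll == 6

    def test_max_diff_zero_equals_exact_matching(self, rng):
        t, _ = simulate_genotypes(
            SimConfig(n_lineages=2, loci=8, genets_per_lineage=8,
                      scoring_error_rate=0.0, missing_rate=0.0, seed=4)
        )
        res = assign_mll(t, max_diff=0)
        assert res.n_mll == res.n_mlg

    def test_max_diff_too_large_rejected(self):
        t = self.make_chain()
        with pytest.raises(ValueError, match="merge"):
            assign_mll(t, max_diff=10)

    def test_order_invariance(self, rng):
        t, _ = simulate_genotypes(
            SimConfig(n_lineages=2, loci=10, genets_per_lineage=10,
                      scoring_error_rate=0.05, seed=6)
        )
        res = assign_mll(t)
        perm = rng.permutation(t.n_samples)
        res_p = assign_mll(t.subset_samples(perm))
        by_sample = dict(zip(res.sample_ids, res.mll_of_sample))
        by_sample_p = dict(zip(res_p.sample_ids, res_p.mll_of_sample))
        # same partition (labels may differ)
        for s1 in t.sample_ids:
            for s2 in t.sample_ids:
                assert (by_sample[s1] == by_sample[s2]) == (
                    by_sample_p[s1] == by_sample_p[s2]
                )

    def test_n_mll_non_increasing_in_max_diff(self, rng):
        t, _ = simulate_genotypes(
            SimConfig(n_lineages=2, loci=12, genets_per_lineage=10,
                      scoring_error_rate=0.1, seed=8)
        )
        counts = [assign_mll(t, max_diff=d).n_mll for d in range(0, 5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_parameter_recovery_on_planted_clones(self):
        """10 genets x 3 ramets with <=3 planted errors each, genets far
        apart: the planted genet partition is recovered exactly."""
        rng = np.random.default_rng(13)
        L = 20
        rows, genet_of = [], []
        for g in range(10):
            base = np.tile([100 + 8 * g, 100 + 8 * g], (L, 1))
            for r, n_err in enumerate([0, 2, 3]):
                row = base.copy()
                for l in rng.choice(L, size=n_err, replace=False):
                    row[l, 0] += 4  # one ladder step off
                    row[l] = np.sort(row[l])
                rows.append(row)
                genet_of.append(g)
        t = table_from_rows(rows)
        res = assign_mll(t, max_diff=3)
        assert res.n_mll == 10
        mll = np.array(res.mll_of_sample)
        genet = np.array(genet_of)
        for g in range(10):
            assert len(set(mll[genet == g])) == 1


class TestConsensus:
    def test_majority_tie_and_singleton(self):
        t2 = table_from_rows(
            [[[100, 104], [100, 100]],
             [[100, 104], [100, 100]],
             [[100, 108], [100, 100]]]
        )
        res = assign_mll(t2, max_diff=1)
        assert res.n_mll == 1
        cons = res.consensus
        assert tuple(cons.genotypes[0, 0]) == (100, 104)  # majority wins
        # two-way tie -> set to missing
        t3 = GenotypeTable(
            ["a", "b"], ["L1", "L2"],
            np.array([[[100, 104], [100, 100]], [[100, 108], [100, 100]]]),
        )
        res3 = assign_mll(t3, max_diff=1)
        assert res3.n_mll == 1
        assert tuple(res3.consensus.genotypes[0, 0]) == (0, 0)
        assert tuple(res3.consensus.genotypes[0, 1]) == (100, 100)

    def test_singleton_passes_through_verbatim(self):
        t = table_from_rows([[[100, 104], [0, 0]]])
        res = assign_mll(t, max_diff=1)
        assert np.array_equal(res.consensus.genotypes[0], t.genotypes[0])

    def test_missing_ramets_ignored(self):
        t = GenotypeTable(
            ["a", "b", "c"], ["L1", "L2", "L3"],
            np.array(
                [[[100, 104], [100, 100], [104, 104]],
                 [[0, 0], [100, 100], [104, 104]],
                 [[100, 104], [100, 100], [104, 104]]]
            ),
        )
        res = assign_mll(t, max_diff=1)
        assert res.n_mll == 1
        assert tuple(res.consensus.genotypes[0, 0]) == (100, 104)


class TestPgen:
    def test_heterozygote_and_product(self):
        freqs = [{100: 0.5, 104: 0.5}]
        assert p_gen(np.array([[100, 104]]), freqs) == pytest.approx(0.5)
        freqs2 = freqs * 2
        g = np.array([[100, 104], [100, 104]])
        assert p_gen(g, freqs2) == pytest.approx(0.25)

    def test_homozygote(self):
        assert p_gen(np.array([[100, 100]]), [{100: 0.3, 104: 0.7}]) == pytest.approx(0.09)

    def test_missing_locus_skipped(self):
        freqs = [{100: 0.5, 104: 0.5}, {100: 1.0}]
        assert p_gen(np.array([[100, 104], [0, 0]]), freqs) == pytest.approx(0.5)

    def test_unknown_allele_raises(self):
        with pytest.raises(ComputationError):
            p_gen(np.array([[100, 112]]), [{100: 0.5, 104: 0.5}])


class TestPsex:
    def test_closed_form_values(self):
        assert p_sex(0.1, 10, 1) == pytest.approx(1 - 0.9**10)  # ~0.6513
        # 1 - P(0) - P(1) by hand
        expected = 1 - 0.9**10 - 10 * 0.1 * 0.9**9
        assert p_sex(0.1, 10, 2) == pytest.approx(expected)  # ~0.2639
        assert p_sex(0.1, 10, 2) == pytest.approx(0.2639, abs=1e-4)

    def test_boundaries(self):
        assert p_sex(0.3, 1, 1) == pytest.approx(0.3)
        assert p_sex(1.0, 7, 5) == pytest.approx(1.0)

    def test_monotonicity(self):
        grid = np.linspace(0.01, 0.9, 8)
        for pg in grid:
            # non-decreasing in N
            vals = [p_sex(pg, n, 2) for n in range(2, 30, 3)]
            assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))
            # non-increasing in n
            vals = [p_sex(pg, 30, n) for n in range(1, 10)]
            assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))
        for pg1, pg2 in zip(grid, grid[1:]):  # non-decreasing in p_gen
            assert p_sex(pg1, 20, 3) <= p_sex(pg2, 20, 3) + 1e-15

    def test_monte_carlo_oracle(self):
        """Empirical frequency of >= n copies of a target genotype under
        HWE draws matches the binomial-tail formula within 3 SE."""
        rng = np.random.default_rng(99)
        p_a = 0.3
        pg = 2 * p_a * (1 - p_a)  # one-locus heterozygote, p_gen = 0.42
        N, n, reps = 20, 2, 10000
        draws = rng.random((reps, N, 2)) < p_a  # True = allele A
        is_het = draws[:, :, 0] != draws[:, :, 1]
        hits = (is_het.sum(axis=1) >= n).mean()
        expected = p_sex(pg, N, n)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(hits - expected) < 3 * se
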