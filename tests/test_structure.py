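"""Admixture-model Gibbs sampler, Ln P(D), run alignment, and delta-K."""

import numpy as np
import pytest

from msatpop import (
    align_runs,
    encode_alleles,
    estimate_lnpd,
    evanno,
    log_likelihood,
    run_structure,
)
from msatpop.structure_model import ConfigError

from conftest import two_cluster_table


def brute_force_loglik(codes, q, p):
    total = 0.0
    n, L, _ = codes.shape
    for i in range(n):
        for l in range(L):
            for c in range(2):
                a = codes[i, l, c]
                if a < 0:
                    continue
                total += np.log(sum(q[i, k] * p[k, l, a] for k in range(q.shape[1])))
    return total


class TestRunStructure:
    def test_invalid_config(self, rng):
        t, _ = two_cluster_table(rng, n_per=5, loci=3)
        with pytest.raises(ConfigError):
            run_structure(t, k=0)
        with pytest.raises(ConfigError):
            run_structure(t, k=2, iterations=0)

    def test_k1_memberships_are_exactly_one(self, rng):
        t, _ = two_cluster_table(rng, n_per=8, loci=4)
        r = run_structure(t, k=1, burnin=20, iterations=50, seed=1)
        assert np.all(r.q_matrix == 1.0)

    def test_rows_normalized(self, rng):
        t, _ = two_cluster_table(rng, n_per=10, loci=5)
        r = run_structure(t, k=3, burnin=50, iterations=150, seed=2)
        assert np.allclose(r.q_matrix.sum(axis=1), 1.0, atol=1e-9)
        psum = r.p_freqs.sum(axis=2)
        assert np.allclose(psum, 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        t, _ = two_cluster_table(rng, n_per=8, loci=4)
        r1 = run_structure(t, k=2, burnin=30, iterations=80, seed=11)
        r2 = run_structure(t, k=2, burnin=30, iterations=80, seed=11)
        assert np.array_equal(r1.q_matrix, r2.q_matrix)
        assert r1.ln_pd == r2.ln_pd

    def test_two_disjoint_lineages_recovered(self, rng):
        t, truth = two_cluster_table(rng, n_per=25, loci=8)
        r = run_structure(t, k=2, burnin=200, iterations=600, seed=5)
        q = r.q_matrix
        truth = np.array(truth)
        acc = max(
            ((q[truth == 0, 0] > 0.5).mean() + (q[truth == 1, 1] > 0.5).mean()) / 2,
            ((q[truth == 0, 1] > 0.5).mean() + (q[truth == 1, 0] > 0.5).mean()) / 2,
        )
        assert acc >= 0.95
        assert q.max(axis=1).mean() >= 0.95

    def test_likelihood_identity(self, rng):
        t, _ = two_cluster_table(rng, n_per=6, loci=4)
        g = t.genotypes.copy()
        g[0, 0] = 0  # include a missing locus
        t = type(t)(t.sample_ids, t.locus_names, g)
        r = run_structure(t, k=2, burnin=20, iterations=60, seed=3)
        codes, _ = encode_alleles(t)
        fast = log_likelihood(codes, r.q_matrix, r.p_freqs)
        slow = brute_force_loglik(codes, r.q_matrix, r.p_freqs)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_planted_frequency_recovery(self, rng):
        """Strong divergence, n=100 per cluster: posterior mean P close to
        the planted per-cluster allele frequencies."""
        t, truth = two_cluster_table(rng, n_per=100, loci=4)
        r = run_structure(t, k=2, burnin=200, iterations=600, seed=7)
        codes, index = encode_alleles(t)
        truth = np.array(truth)
        # empirical per-cluster frequencies as the planted reference
        for k_model in range(2):
            # match model cluster to truth cluster by majority membership
            members = r.q_matrix[:, k_model] > 0.5
            clus = int(np.round(truth[members].mean()))
            for l in range(t.n_loci):
                alleles = t.genotypes[truth == clus, l].ravel()
                emp = np.zeros(len(index[l]))
                for a, j in index[l].items():
                    emp[j] = (alleles == a).mean()
                assert np.abs(r.p_freqs[k_model, l, : len(emp)] - emp).sum() < 0.05


class TestEstimateLnpd:
    def test_constant_trace(self):
        assert estimate_lnpd([-50.0, -50.0, -50.0]) == -50.0

    def test_hand_arithmetic(self):
        # mean -101, population variance 1 -> -101.5
        assert estimate_lnpd([-100.0, -102.0]) == pytest.approx(-101.5)

    def test_noise_lowers_estimate(self, rng):
        base = rng.normal(-1000, 0.5, size=200)
        noisy = base + rng.normal(0, 3.0, size=200)
        assert estimate_lnpd(noisy) < estimate_lnpd(base)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_lnpd([])


class TestAlignRuns:
    def test_label_swap_recovered(self, rng):
        t, _ = two_cluster_table(rng, n_per=10, loci=5)
        r1 = run_structure(t, k=2, burnin=30, iterations=80, seed=1)
        r2 = run_structure(t, k=2, burnin=30, iterations=80, seed=1)
        r2.q_matrix = r2.q_matrix[:, ::-1].copy()
        r2.p_freqs = r2.p_freqs[::-1].copy()
        aligned, mean_q = align_runs([r1, r2])
        assert np.allclose(aligned[1].q_matrix, r1.q_matrix)
        assert np.allclose(mean_q.sum(axis=1), 1.0)

    def test_planted_permutation_recovery(self, rng):
        n, k = 40, 3
        q = rng.dirichlet(np.full(k, 0.3), size=n)
        perm = [2, 0, 1]
        noise = rng.normal(0, 0.01, size=(n, k))
        q2 = np.clip(q[:, perm] + noise, 1e-6, None)
        q2 /= q2.sum(axis=1, keepdims=True)
        r1 = _fake_run(q, k)
        r2 = _fake_run(q2, k)
        aligned, _ = align_runs([r1, r2])
        # inverse of the planted permutation restores column order
        assert np.abs(aligned[1].q_matrix - q).max() < 0.05


def _fake_run(q, k):
    from msatpop import StructureRun

    n = q.shape[0]
    return StructureRun(
        k=k,
        sample_ids=[f"s{i}" for i in range(n)],
        locus_names=["L1"],
        q_matrix=q,
        p_freqs=np.full((k, 1, 2), 0.5),
        allele_index=[{100: 0, 104: 1}],
        ln_pd=-1.0,
        loglik_trace=np.array([-1.0, -1.0]),
        alpha_trace=np.array([1.0]),
        seed=0,
        burnin=0,
        iterations=2,
    )


class TestEvanno:
    def test_hand_arithmetic(self):
        # replicate sets realizing L = (-1000, -900, -880, -875), s(3) = 2
        lnpd = {
            1: [-1000.0, -1000.0],
            2: [-900.0, -900.0],
            3: [-878.0, -882.0],  # mean -880, sd 2 (ddof=1: sqrt(8) != 2)
            4: [-875.0, -875.0],
        }
        # choose replicates with sample sd exactly 2
        lnpd[3] = [-880.0 + 2 / np.sqrt(2) * x for x in (-1.0, 1.0)]
        sd = np.std(lnpd[3], ddof=1)
        ev = evanno(lnpd)
        row = ev.table.set_index("k").loc[3]
        expected = abs(-875 + 2 * 880 - 900) / sd
        assert row["delta_k"] == pytest.approx(expected, abs=1e-12)
        assert row["lsecond"] == pytest.approx(15.0, abs=1e-12)

    def test_linear_lnpd_gives_zero_delta_k(self):
        lnpd = {k: [-1000.0 + 50 * k + e for e in (-1.0, 1.0)] for k in range(1, 6)}
        ev = evanno(lnpd)
        interior = ev.table.dropna(subset=["delta_k"])
        assert np.allclose(interior["delta_k"], 0.0, atol=1e-9)

    def test_boundary_and_zero_sd_undefined(self):
        lnpd = {1: [-10.0, -11.0], 2: [-9.0, -9.0], 3: [-8.0, -8.5]}
        ev = evanno(lnpd)
        tab = ev.table.set_index("k")
        assert np.isnan(tab.loc[1, "delta_k"])  # boundary
        assert np.isnan(tab.loc[2, "delta_k"])  # sd = 0
        assert np.isnan(tab.loc[3, "delta_k"])  # boundary

    def test_matches_independent_recomputation(self, rng):
        """Spreadsheet-style recomputation on random Ln P(D) tables."""
        for _ in range(5):
            lnpd = {
                k: list(rng.normal(-1000 + 20 * k, 5.0, size=4)) for k in range(1, 7)
            }
            ev = evanno(lnpd).table.set_index("k")
            for k in range(2, 6):
                means = {kk: np.mean(lnpd[kk]) for kk in lnpd}
                sd = np.std(lnpd[k], ddof=1)
                expect = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sd
                assert ev.loc[k, "delta_k"] == pytest.approx(expect, abs=1e-12)

    def test_requires_contiguous_range(self):
        with pytest.raises(ValueError):
            evanno({1: [-1.0, -2.0], 3: [-1.0, -2.0], 4: [-1.0, -2.0]})

    def test_tie_broken_toward_smaller_k(self):
        lnpd = {
            1: [-1000.0, -1002.0],
            2: [-900.0, -902.0],
            3: [-850.0, -852.0],
            4: [-825.0, -827.0],
            5: [-812.5, -814.5],
        }
        # second differences at K=2,3,4: 50, 25, 12.5 with equal sd
        ev = evanno(lnpd)
        assert ev.best_k == 2
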