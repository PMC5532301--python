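"""Admixture-model Bayesian clustering, run merging, and Evanno's delta-K.

The model: each individual ``i`` has admixture proportions ``Q[i]`` over K
clusters (symmetric Dirichlet(alpha) prior, alpha sampled by Metropolis);
each cluster ``k`` has independent per-locus allele frequencies ``P[k, l]``
(Dirichlet(lambda) prior); every observed allele copy has a latent cluster
of origin ``Z``. A Gibbs sampler alternates

    Z[i,l,c] ~ Categorical( Q[i,k] * P[k,l,allele] )
    P[k,l]   ~ Dirichlet( lambda + allele counts assigned to k )
    Q[i]     ~ Dirichlet( alpha + per-individual origin counts )

with missing alleles contributing nothing. The per-run model evidence
"Ln P(D)" is approximated from the post-burn-in log-likelihood trace as
``mean - variance/2``. Replicate runs are merged by exhaustive cluster-label
permutation against the first run, and the number of clusters is chosen by
the delta-K statistic: the absolute second difference of mean Ln P(D) over K
divided by the across-replicate standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeTable


class ConfigError(ValueError):
    pass


@dataclass
class StructureRun:
    """One MCMC run: posterior-mean memberships and allele frequencies."""

    k: int
    sample_ids: list[str]
    locus_names: list[str]
    q_matrix: np.ndarray          # (n, k), rows sum to 1
    p_freqs: np.ndarray           # (k, loci, max_alleles), rows sum to 1
    allele_index: list[dict[int, int]]  # per locus: allele size -> column
    ln_pd: float
    loglik_trace: np.ndarray
    alpha_trace: np.ndarray
    seed: int | None
    burnin: int
    iterations: int


@dataclass
class EvannoTable:
    """Per-K Ln P(D) statistics and delta-K; ``best_k`` is argmax delta-K
    (ties broken toward smaller K), None when no interior K is defined."""

    table: pd.DataFrame
    best_k: int | None


def encode_alleles(table: GenotypeTable) -> tuple[np.ndarray, list[dict[int, int]]]:
    """Dense allele codes: (n, loci, 2) int array, -1 = missing, plus the
    per-locus allele-size -> column maps."""
    n, L = table.n_samples, table.n_loci
    codes = np.full((n, L, 2), -1, dtype=np.int64)
    index: list[dict[int, int]] = []
    for l in range(L):
        sizes = sorted(int(a) for a in np.unique(table.genotypes[:, l]) if a != MISSING)
        m = {s: j for j, s in enumerate(sizes)}
        index.append(m)
        for s, j in m.items():
            codes[:, l][table.genotypes[:, l] == s] = j
    return codes, index


def log_likelihood(codes: np.ndarray, q_matrix: np.ndarray, p_freqs: np.ndarray) -> float:
    """ln L = sum over observed allele copies of ln( sum_k Q[i,k] P[k,l,a] )."""
    observed = codes >= 0
    a = np.where(observed, codes, 0)
    L = codes.shape[1]
    # gather P[k, l, a] -> (n, loci, 2, k)
    pal = np.moveaxis(p_freqs, 0, -1)[np.arange(L)[None, :, None], a]
    mix = np.einsum("ilck,ik->ilc", pal, q_matrix)
    return float(np.log(np.clip(mix[observed], 1e-300, None)).sum())


def _alpha_logpost(alpha: float, k: int, n: int, sum_log_q: float) -> float:
    return n * (gammaln(k * alpha) - k * gammaln(alpha)) + (alpha - 1.0) * sum_log_q


def run_structure(
    table: GenotypeTable,
    k: int,
    burnin: int = 5000,
    iterations: int = 20000,
    seed: int | None = 0,
    lambda_: float = 1.0,
    alpha_init: float = 1.0,
    alpha_max: float = 10.0,
    alpha_proposal_sd: float = 0.25,
    fixed_alpha: float | None = None,
) -> StructureRun:
    """One admixture-model Gibbs run at a given K.

    ``iterations`` counts post-burn-in sweeps (the recorded chain);
    ``burnin`` sweeps are discarded first. Intended input is an
    MLL-collapsed table (one row per clonal lineage). ``fixed_alpha``
    disables the Metropolis update of the admixture concentration.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if iterations <= 0 or burnin < 0:
        raise ConfigError("iterations must be > 0 and burnin >= 0")
    rng = np.random.default_rng(seed)
    codes, allele_index = encode_alleles(table)
    n, L = codes.shape[0], codes.shape[1]
    j_max = max(1, max(len(m) for m in allele_index))
    valid = np.zeros((L, j_max), dtype=bool)
    for l, m in enumerate(allele_index):
        valid[l, : len(m)] = True
    observed = codes >= 0
    a_idx = np.where(observed, codes, 0)
    obs_i, obs_l, obs_c = np.nonzero(observed)
    obs_a = codes[obs_i, obs_l, obs_c]
    l_range = np.arange(L)

    # init from the priors
    alpha = float(fixed_alpha if fixed_alpha is not None else alpha_init)
    q = rng.dirichlet(np.full(k, alpha), size=n)
    p = np.zeros((k, L, j_max))
    for l in range(L):
        jl = int(valid[l].sum())
        p[:, l, :jl] = rng.dirichlet(np.full(jl, lambda_), size=k)

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    trace = np.empty(iterations)
    alpha_trace = np.empty(iterations)
    total = burnin + iterations
    for it in range(total):
        # latent origins Z
        pal = np.moveaxis(p, 0, -1)[l_range[None, :, None], a_idx]  # (n, L, 2, k)
        w = q[:, None, None, :] * pal
        tot = w.sum(axis=-1, keepdims=True)
        tot[tot == 0] = 1.0
        u = rng.random((n, L, 2, 1)) * tot
        z = (w.cumsum(axis=-1) < u).sum(axis=-1)
        z = np.minimum(z, k - 1)
        z_obs = z[obs_i, obs_l, obs_c]
        # cluster allele frequencies P
        counts_p = np.zeros((k, L, j_max))
        np.add.at(counts_p, (z_obs, obs_l, obs_a), 1.0)
        gam = rng.gamma(np.where(valid[None, :, :], lambda_ + counts_p, 1.0))
        gam[:, ~valid] = 0.0
        denom = gam.sum(axis=-1, keepdims=True)
        denom[denom == 0] = 1.0  # locus with no scored alleles
        p = gam / denom
        # admixture proportions Q
        counts_q = np.zeros((n, k))
        np.add.at(counts_q, (obs_i, z_obs), 1.0)
        gq = rng.gamma(alpha + counts_q)
        q = gq / gq.sum(axis=-1, keepdims=True)
        # admixture concentration alpha (Metropolis, uniform prior on (0, alpha_max])
        if fixed_alpha is None and k > 1:
            prop = alpha + rng.normal(0.0, alpha_proposal_sd)
            if 0.0 < prop <= alpha_max:
                slq = float(np.log(np.clip(q, 1e-300, None)).sum())
                diff = _alpha_logpost(prop, k, n, slq) - _alpha_logpost(alpha, k, n, slq)
                if np.log(rng.random()) < diff:
                    alpha = prop
        if it >= burnin:
            rec = it - burnin
            pal = np.moveaxis(p, 0, -1)[l_range[None, :, None], a_idx]
            mix = np.einsum("ilck,ik->ilc", pal, q)
            trace[rec] = np.log(np.clip(mix[observed], 1e-300, None)).sum()
            alpha_trace[rec] = alpha
            q_sum += q
            p_sum += p
    q_hat = q_sum / iterations
    p_hat = p_sum / iterations
    p_hat_norm = p_hat.sum(axis=-1, keepdims=True)
    p_hat_norm[p_hat_norm == 0] = 1.0
    p_hat = p_hat / p_hat_norm
    return StructureRun(
        k=k,
        sample_ids=list(table.sample_ids),
        locus_names=list(table.locus_names),
        q_matrix=q_hat / q_hat.sum(axis=-1, keepdims=True),
        p_freqs=p_hat,
        allele_index=allele_index,
        ln_pd=estimate_lnpd(trace),
        loglik_trace=trace,
        alpha_trace=alpha_trace,
        seed=seed,
        burnin=burnin,
        iterations=iterations,
    )


def estimate_lnpd(loglik_trace: Sequence[float]) -> float:
    """Model-evidence approximation mean(trace) - var(trace)/2 (population
    variance), the harmonic-style estimator reported as "Ln P(D)"."""
    t = np.asarray(loglik_trace, dtype=float)
    if t.size == 0:
        raise ValueError("empty log-likelihood trace")
    return float(t.mean() - t.var() / 2.0)


def align_runs(runs: Sequence[StructureRun]) -> tuple[list[StructureRun], np.ndarray]:
    """Permute cluster labels of each run to best match the first run.

    For k <= 8 the k! permutations are searched exhaustively, minimizing the
    summed absolute Q difference; for larger k the optimal assignment is
    found with the Hungarian algorithm on the column-wise L1 cost (the
    objective decomposes per column, so this fallback is also exact).
    Returns the relabeled runs and the element-wise mean Q.
    """
    if not runs:
        raise ValueError("no runs to align")
    k = runs[0].k
    for r in runs:
        if r.k != k or r.sample_ids != runs[0].sample_ids:
            raise ValueError("runs must share k and sample set")
    ref = runs[0].q_matrix
    aligned: list[StructureRun] = []
    for r in runs:
        if k <= 8:
            best, best_cost = None, np.inf
            for perm in permutations(range(k)):
                cost = float(np.abs(ref - r.q_matrix[:, perm]).sum())
                if cost < best_cost:
                    best, best_cost = perm, cost
            perm = list(best)
        else:
            cost = np.abs(ref[:, :, None] - r.q_matrix[:, None, :]).sum(axis=0)
            _, cols = linear_sum_assignment(cost)
            perm = list(cols)
        aligned.append(
            StructureRun(
                k=r.k,
                sample_ids=r.sample_ids,
                locus_names=r.locus_names,
                q_matrix=r.q_matrix[:, perm],
                p_freqs=r.p_freqs[perm],
                allele_index=r.allele_index,
                ln_pd=r.ln_pd,
                loglik_trace=r.loglik_trace,
                alpha_trace=r.alpha_trace,
                seed=r.seed,
                burnin=r.burnin,
                iterations=r.iterations,
            )
        )
    mean_q = np.mean([r.q_matrix for r in aligned], axis=0)
    mean_q = mean_q / mean_q.sum(axis=-1, keepdims=True)
    return aligned, mean_q


def evanno(lnpd_by_k: Mapping[int, Sequence[float]]) -> EvannoTable:
    """Delta-K table from replicate Ln P(D) values per K.

    L(K) is the replicate mean, s(K) the sample standard deviation;
    delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / s(K), defined for interior K
    with at least two replicates and s(K) > 0. ``best_k`` is the argmax,
    ties broken toward smaller K.
    """
    ks = sorted(lnpd_by_k)
    if len(ks) < 3:
        raise ValueError("need a contiguous K range of length >= 3")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    means = {k: float(np.mean(lnpd_by_k[k])) for k in ks}
    sds = {
        k: float(np.std(lnpd_by_k[k], ddof=1)) if len(lnpd_by_k[k]) >= 2 else np.nan
        for k in ks
    }
    rows = []
    for k in ks:
        lprime = means[k] - means[k - 1] if k - 1 in means else np.nan
        if k - 1 in means and k + 1 in means:
            lsecond = abs(means[k + 1] - 2 * means[k] + means[k - 1])
            dk = lsecond / sds[k] if sds[k] and sds[k] > 0 and not np.isnan(sds[k]) else np.nan
        else:
            lsecond, dk = np.nan, np.nan
        rows.append(
            {
                "k": k,
                "n_reps": len(lnpd_by_k[k]),
                "mean_lnpd": means[k],
                "sd_lnpd": sds[k],
                "lprime": lprime,
                "lsecond": lsecond,
                "delta_k": dk,
            }
        )
    df = pd.DataFrame(rows)
    defined = df.dropna(subset=["delta_k"])
    best_k = int(defined.loc[defined["delta_k"].idxmax(), "k"]) if len(defined) else None
    if len(defined) > 1:
        top = defined[defined["delta_k"] == defined["delta_k"].max()]
        best_k = int(top["k"].min())
    return EvannoTable(table=df, best_k=best_k)
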