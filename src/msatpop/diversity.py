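"""Allele frequencies and genetic diversity indices on clone-corrected data.

Per locus and per group (lineage/site): number of alleles N_A, observed and
expected heterozygosity H_O and H_E, inbreeding coefficient
F_IS = 1 - H_O/H_E, and the probability of identity

    P_ID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2 = 2 (sum_i p_i^2)^2 - sum_i p_i^4,

the chance two independent sexually produced individuals share a genotype;
the multilocus P_ID is the product over loci. Indices are meant to be
computed after collapsing clonal replicates to one row per MLL, and are
withheld for groups with too few MLLs to estimate them meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonality import assign_mll, count_mlg
from .io_formats import MISSING, GenotypeTable


@dataclass
class DiversitySummary:
    """Group-level diversity indices; ``None`` marks a withheld index."""

    group: str
    n_samples: int
    n_mlg: int
    n_mll: int
    mean_alleles: float | None
    h_obs: float | None
    h_exp: float | None
    f_is: float | None
    p_id: float | None
    per_locus: pd.DataFrame | None


def allele_frequencies(
    table: GenotypeTable, group: str | None = None
) -> tuple[list[dict[int, float]], np.ndarray]:
    """Per-locus allele frequency dicts and the per-locus scored-sample counts.

    Counts run over non-missing allele copies. A locus with zero scored
    samples gets an empty dict (frequency undefined, flagged by n=0).
    """
    sub = _group_subset(table, group)
    freqs: list[dict[int, float]] = []
    n_scored = np.zeros(sub.n_loci, dtype=int)
    for l in range(sub.n_loci):
        alleles = sub.genotypes[:, l, :].ravel()
        alleles = alleles[alleles != MISSING]
        n_scored[l] = alleles.size // 2
        if alleles.size == 0:
            freqs.append({})
            continue
        vals, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        freqs.append({int(v): float(c) / total for v, c in zip(vals, counts)})
    return freqs, n_scored


def _group_subset(table: GenotypeTable, group: str | None) -> GenotypeTable:
    if group is None:
        return table
    if table.population_labels is None:
        raise ValueError("table has no population labels")
    idx = [i for i, g in enumerate(table.population_labels) if g == group]
    if not idx:
        raise ValueError(f"unknown group label {group!r}")
    return table.subset_samples(idx)


def heterozygosities(
    table: GenotypeTable, group: str | None = None, unbiased: bool = False
) -> pd.DataFrame:
    """Per-locus H_O and H_E (columns: locus, n, n_alleles, h_obs, h_exp).

    H_O is the fraction of scored individuals heterozygous at the locus;
    H_E = 1 - sum p_i^2, optionally with the small-sample correction
    2n/(2n - 1). Loci with no scored samples carry NaN.
    """
    sub = _group_subset(table, group)
    freqs, n_scored = allele_frequencies(sub)
    rows = []
    for l, name in enumerate(sub.locus_names):
        n = int(n_scored[l])
        if n == 0:
            rows.append((name, 0, 0, np.nan, np.nan))
            continue
        g = sub.genotypes[:, l]
        scored = g[:, 0] != MISSING
        het = float((g[scored, 0] != g[scored, 1]).mean())
        p = np.array(list(freqs[l].values()))
        he = 1.0 - float(np.sum(p**2))
        if unbiased and n > 0:
            he *= 2 * n / (2 * n - 1)
        rows.append((name, n, len(p), het, he))
    return pd.DataFrame(rows, columns=["locus", "n", "n_alleles", "h_obs", "h_exp"])


def f_is(h_obs, h_exp):
    """Inbreeding coefficient 1 - H_O/H_E; NaN where H_E = 0 (monomorphic)."""
    h_obs = np.asarray(h_obs, dtype=float)
    h_exp = np.asarray(h_exp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(h_exp > 0, 1.0 - h_obs / h_exp, np.nan)
    return float(out) if out.ndim == 0 else out


def probability_of_identity(
    freqs: list[dict[int, float]],
) -> tuple[np.ndarray, float]:
    """Per-locus P_ID and the multilocus product.

    Per locus P_ID = 2 (sum p^2)^2 - sum p^4, the probability two random
    Hardy-Weinberg genotypes coincide; undefined loci (empty frequency dict)
    get NaN and are excluded from the product.
    """
    per_locus = np.full(len(freqs), np.nan)
    for l, d in enumerate(freqs):
        if not d:
            continue
        p = np.array(list(d.values()))
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        per_locus[l] = 2.0 * s2 * s2 - s4
    defined = per_locus[~np.isnan(per_locus)]
    product = float(np.prod(defined)) if defined.size else float("nan")
    return per_locus, product


def detect_duplicate_loci(table: GenotypeTable) -> list[tuple[str, str]]:
    """Locus pairs with identical unordered genotype vectors across all
    samples scored at both (at least one common scored sample required)."""
    codes = table.pair_codes()
    present = table.present_mask()
    pairs: list[tuple[str, str]] = []
    for i in range(table.n_loci):
        for j in range(i + 1, table.n_loci):
            both = present[:, i] & present[:, j]
            if not both.any():
                continue
            if np.array_equal(codes[both, i], codes[both, j]):
                pairs.append((table.locus_names[i], table.locus_names[j]))
    return pairs


def remove_duplicate_loci(table: GenotypeTable) -> tuple[GenotypeTable, list[tuple[str, str]]]:
    """Drop the later locus of each duplicate pair (input order kept)."""
    pairs = detect_duplicate_loci(table)
    drop = {b for _, b in pairs}
    return table.drop_loci(sorted(drop)), pairs


def summarize(
    table: GenotypeTable,
    groups: list[str] | None = None,
    min_mll: int = 8,
    max_diff: int = 3,
    unbiased: bool = False,
) -> list[DiversitySummary]:
    """Per-group diversity summary on clone-corrected data.

    Duplicate loci are removed first. Within each group, samples are
    collapsed to MLLs (difference threshold ``max_diff``); N, G and N_MLL are
    always reported, while N_A, H_O, H_E, F_IS and P_ID are computed on the
    MLL consensus rows only when N_MLL >= ``min_mll`` (groups with few MLLs
    give unstable index estimates and are withheld).
    """
    table, _ = remove_duplicate_loci(table)
    if groups is None:
        groups = list(table.groups())
    known = table.groups()
    out: list[DiversitySummary] = []
    for g in groups:
        if g not in known:
            raise ValueError(f"unknown group label {g!r}")
        sub = table.subset_samples(known[g]) if table.population_labels is not None else table
        if sub.n_loci > max_diff:
            assignment = assign_mll(sub, max_diff=max_diff)
            n_mll = assignment.n_mll
            collapsed = assignment.consensus
        else:
            n_mll = count_mlg(sub)
            collapsed = sub
        if n_mll < min_mll:
            out.append(
                DiversitySummary(g, sub.n_samples, count_mlg(sub), n_mll,
                                 None, None, None, None, None, None)
            )
            continue
        het = heterozygosities(collapsed, unbiased=unbiased)
        freqs, _ = allele_frequencies(collapsed)
        pid_locus, pid_prod = probability_of_identity(freqs)
        fis_locus = f_is(het["h_obs"].to_numpy(), het["h_exp"].to_numpy())
        per_locus = het.assign(f_is=fis_locus, p_id=pid_locus)
        # monomorphic loci stay in the H_O/H_E means but drop out of F_IS
        out.append(
            DiversitySummary(
                group=g,
                n_samples=sub.n_samples,
                n_mlg=count_mlg(sub),
                n_mll=n_mll,
                mean_alleles=float(het["n_alleles"].mean()),
                h_obs=float(het["h_obs"].mean()),
                h_exp=float(het["h_exp"].mean()),
                f_is=float(np.nanmean(fis_locus)) if np.any(~np.isnan(fis_locus)) else None,
                p_id=pid_prod,
                per_locus=per_locus,
            )
        )
    return out


def summary_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    """Tabular view mirroring the usual N / G / N_MLL / N_A / H_O / H_E /
    F_IS / P_ID column order."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "group": s.group,
                "N": s.n_samples,
                "G": s.n_mlg,
                "N_MLL": s.n_mll,
                "N_A": s.mean_alleles,
                "H_O": s.h_obs,
                "H_E": s.h_exp,
                "F_IS": s.f_is,
                "P_ID": s.p_id,
            }
        )
    return pd.DataFrame(rows)
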