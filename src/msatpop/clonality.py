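"""Clonality analysis: multilocus lineage (MLL) calling, consensus
genotypes, and the probability that repeated genotypes arose sexually.

Distinct colonies (ramets) of one genet can differ at a few loci through
scoring error or somatic mutation, so identical-genotype matching
underestimates clonality. The MLL rule used here links two samples when
their genotypes differ at no more than ``max_diff`` comparable loci
(default 3) and takes connected components (single linkage) as the
lineages. ``P_SEX`` — the probability that ``n`` observed copies of a
genotype arose from independent sexual events in a sample of ``N`` — is the
upper binomial tail at the genotype's Hardy-Weinberg probability ``P_gen``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import MISSING, GenotypeTable


class ComputationError(ValueError):
    pass


@dataclass
class MLLAssignment:
    """Sample-to-MLL mapping with supporting evidence.

    ``n_diff`` / ``n_comparable`` are symmetric sample x sample matrices of
    differing and mutually scored locus counts; ``consensus`` holds one row
    per MLL (modal genotype, ties set to missing).
    """

    sample_ids: list[str]
    mll_of_sample: list[str]
    n_samples: int
    n_mlg: int
    n_mll: int
    n_diff: np.ndarray
    n_comparable: np.ndarray
    consensus: GenotypeTable

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, mll in zip(self.sample_ids, self.mll_of_sample):
            out.setdefault(mll, []).append(sid)
        return out


@dataclass
class PsexResult:
    mll_id: str
    p_gen: float
    n_copies: int
    sample_size: int
    p_sex: float


def pairwise_locus_differences(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per sample pair: (number of differing loci, number of comparable loci).

    A locus is comparable when scored (non-missing) in both samples; it
    differs when the unordered allele pairs are unequal.
    """
    if table.n_loci < 1:
        raise ValueError("need at least one locus")
    present = table.present_mask()  # (n, L)
    codes = table.pair_codes()
    both = present[:, None, :] & present[None, :, :]
    n_comparable = both.sum(axis=2)
    differs = codes[:, None, :] != codes[None, :, :]
    n_diff = (both & differs).sum(axis=2)
    return n_diff, n_comparable


def count_mlg(table: GenotypeTable) -> int:
    """Number of distinct multilocus genotypes (missing pattern included)."""
    codes = table.pair_codes()
    return np.unique(codes, axis=0).shape[0]


def assign_mll(
    table: GenotypeTable,
    max_diff: int = 3,
    min_comparable_fraction: float = 2.0 / 3.0,
) -> MLLAssignment:
    """Collapse samples into multilocus lineages.

    Samples are linked when they differ at <= ``max_diff`` comparable loci
    and share at least ``ceil(min_comparable_fraction * n_loci)`` scored
    loci; MLLs are the connected components of that graph. MLL labels are
    ``MLL_1``, ``MLL_2``, ... in order of first sample appearance.
    """
    if max_diff < 0:
        raise ValueError("max_diff must be >= 0")
    if max_diff >= table.n_loci:
        raise ValueError(
            f"max_diff={max_diff} >= {table.n_loci} loci: every sample pair would merge"
        )
    n_diff, n_comp = pairwise_locus_differences(table)
    min_comp = math.ceil(min_comparable_fraction * table.n_loci)
    adj = (n_diff <= max_diff) & (n_comp >= min_comp)
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    # stable relabeling by first appearance
    order: dict[int, str] = {}
    mll_of_sample: list[str] = []
    for lab in labels:
        if lab not in order:
            order[lab] = f"MLL_{len(order) + 1}"
        mll_of_sample.append(order[lab])
    assignment = MLLAssignment(
        sample_ids=list(table.sample_ids),
        mll_of_sample=mll_of_sample,
        n_samples=table.n_samples,
        n_mlg=count_mlg(table),
        n_mll=len(order),
        n_diff=n_diff,
        n_comparable=n_comp,
        consensus=None,  # filled below
    )
    assignment.consensus = consensus_genotypes(table, assignment)
    return assignment


def consensus_genotypes(table: GenotypeTable, assignment: MLLAssignment) -> GenotypeTable:
    """One consensus row per MLL: the modal unordered allele pair per locus.

    Missing ramet genotypes are ignored; when two or more pairs tie for the
    mode the locus is set to missing (0, 0). Singleton MLLs pass through
    verbatim.
    """
    if assignment.sample_ids != table.sample_ids:
        raise ValueError("assignment does not cover this table")
    members: dict[str, list[int]] = {}
    for i, mll in enumerate(assignment.mll_of_sample):
        members.setdefault(mll, []).append(i)
    mll_ids = list(members)
    geno = np.zeros((len(mll_ids), table.n_loci, 2), dtype=np.int64)
    for r, mll in enumerate(mll_ids):
        idx = members[mll]
        if len(idx) == 1:
            geno[r] = table.genotypes[idx[0]]
            continue
        for l in range(table.n_loci):
            counts: dict[tuple[int, int], int] = {}
            for i in idx:
                a, b = table.genotypes[i, l]
                if a == MISSING:
                    continue
                counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
            if not counts:
                continue  # stays (0, 0)
            best = max(counts.values())
            modal = [p for p, c in counts.items() if c == best]
            if len(modal) == 1:
                geno[r, l] = modal[0]
            # tie -> stays (0, 0)
    return GenotypeTable(mll_ids, list(table.locus_names), geno)


def p_gen(genotype: np.ndarray, allele_freqs: list[dict[int, float]]) -> float:
    """Hardy-Weinberg probability of a multilocus genotype.

    ``genotype`` is an (n_loci, 2) array of allele sizes (0,0 = missing,
    skipped); ``allele_freqs`` is a per-locus dict of allele -> frequency.
    Product over scored loci of ``p_i**2`` (homozygote) or ``2 p_i p_j``
    (heterozygote). An allele absent from the frequency table raises
    :class:`ComputationError` — it signals frequencies computed on the wrong
    sample set.
    """
    genotype = np.asarray(genotype)
    log_p = 0.0
    for l in range(genotype.shape[0]):
        a, b = int(genotype[l, 0]), int(genotype[l, 1])
        if a == MISSING:
            continue
        freqs = allele_freqs[l]
        try:
            pa, pb = freqs[a], freqs[b]
        except KeyError as exc:
            raise ComputationError(
                f"allele {exc.args[0]} at locus index {l} absent from frequency table"
            ) from None
        if pa <= 0 or pb <= 0:
            raise ComputationError(f"non-positive frequency at locus index {l}")
        log_p += math.log(pa * pa) if a == b else math.log(2.0 * pa * pb)
    return math.exp(log_p)


def p_sex(p_gen_value: float, sample_size: int, n_copies: int) -> float:
    """P(X >= n) for X ~ Binomial(N, P_gen): the probability that ``n`` or
    more copies of the genotype arise by independent sexual reproduction."""
    if not 0.0 < p_gen_value <= 1.0:
        raise ValueError("p_gen_value must be in (0, 1]")
    if not 1 <= n_copies <= sample_size:
        raise ValueError("need 1 <= n_copies <= sample_size")
    return float(stats.binom.sf(n_copies - 1, sample_size, p_gen_value))


def psex_for_assignment(
    table: GenotypeTable,
    assignment: MLLAssignment,
    allele_freqs: list[dict[int, float]] | None = None,
) -> list[PsexResult]:
    """P_SEX for every MLL observed more than once (plus singletons).

    Allele frequencies default to plain frequencies computed on the
    MLL-collapsed (clone-corrected) consensus table. Loci whose consensus is
    missing are skipped inside ``p_gen``.
    """
    from .diversity import allele_frequencies  # local import avoids a cycle

    if allele_freqs is None:
        allele_freqs, _ = allele_frequencies(assignment.consensus)
    sizes = {m: len(v) for m, v in assignment.members().items()}
    out: list[PsexResult] = []
    for r, mll in enumerate(assignment.consensus.sample_ids):
        geno = assignment.consensus.genotypes[r]
        if np.all(geno[:, 0] == MISSING):
            continue
        pg = p_gen(geno, allele_freqs)
        out.append(
            PsexResult(
                mll_id=mll,
                p_gen=pg,
                n_copies=sizes[mll],
                sample_size=assignment.n_samples,
                p_sex=p_sex(pg, assignment.n_samples, sizes[mll]),
            )
        )
    return out
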