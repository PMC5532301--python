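"""Synthetic genotype tables and read sets with known ground truth.

Genotype simulation follows the sampling design of a clonal-coral
microsatellite survey: ``K`` discrete genetic lineages, each with its own
per-locus allele frequencies; genets (sexually produced individuals) founded
by Hardy-Weinberg draws with optional inbreeding; ramets (asexually produced
colonies) copying the genet genotype subject to per-locus scoring error or
somatic mutation; and missing data. Read simulation plants perfect tandem
repeats (4-5 bp motifs) into background reads for two lineages, with
controlled flank divergence at shared loci, emulating the input to SSR marker
discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import MISSING, GenotypeTable

# allele sizes live on a 4-bp fragment-length ladder starting here
ALLELE_BASE = 100
ALLELE_STEP = 4

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the genotype simulation.

    ``ramets_per_genet`` is either a fixed int (that many sampled colonies
    per genet) or a tuple ``("geometric", p, max)`` drawing a truncated
    geometric count on 1..max — many singleton genets, few large clones.
    """

    n_lineages: int = 3
    loci: int = 10
    alleles_per_locus: int = 6
    dirichlet_concentration: float = 1.0
    genets_per_lineage: int = 20
    ramets_per_genet: int | tuple = ("geometric", 0.5, 8)
    scoring_error_rate: float = 0.01
    max_errors_per_ramet: int = 3
    inbreeding_f: float = 0.0
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lineages", "loci", "alleles_per_locus", "genets_per_lineage"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be > 0")
        for name in ("scoring_error_rate", "missing_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ConfigError("inbreeding_f must be in [0, 1)")
        if self.max_errors_per_ramet < 0:
            raise ConfigError("max_errors_per_ramet must be >= 0")
        if isinstance(self.ramets_per_genet, int):
            if self.ramets_per_genet < 0:
                raise ConfigError("ramets_per_genet must be >= 0")
        else:
            kind, p, mx = self.ramets_per_genet
            if kind != "geometric" or not 0 < p <= 1 or mx < 1:
                raise ConfigError(f"bad ramets_per_genet spec {self.ramets_per_genet!r}")


@dataclass
class SimTruth:
    """Ground truth recorded alongside simulated data."""

    lineage_of_sample: list[str] = field(default_factory=list)
    genet_of_sample: list[str] = field(default_factory=list)
    allele_freqs_true: np.ndarray | None = None  # (K, loci, alleles)
    allele_sizes: np.ndarray | None = None
    planted_ssrs: list[tuple[str, str, int, int]] = field(default_factory=list)
    planted_ssrs_b: list[tuple[str, str, int, int]] = field(default_factory=list)
    shared_pairs: list[tuple[str, str]] = field(default_factory=list)


def _draw_ramet_counts(spec: int | tuple, n_genets: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, int):
        return np.full(n_genets, spec, dtype=int)
    _, p, mx = spec
    support = np.arange(1, mx + 1)
    w = (1.0 - p) ** (support - 1)
    w /= w.sum()
    return rng.choice(support, size=n_genets, p=w)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeTable, SimTruth]:
    """Simulate a multi-lineage clonal genotype table.

    Per genet and locus the founding genotype is drawn from the lineage's
    allele frequencies: with probability ``inbreeding_f`` a single allele is
    drawn and duplicated (identical by descent), else two independent draws.
    Ramets copy the genet genotype; each locus is then independently replaced
    by a +-1-ladder-step perturbation of one allele with probability
    ``scoring_error_rate`` (total perturbed loci per ramet capped at
    ``max_errors_per_ramet``); finally whole loci are zeroed with probability
    ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    K, L, A = config.n_lineages, config.loci, config.alleles_per_locus
    sizes = ALLELE_BASE + ALLELE_STEP * np.arange(A)
    freqs = rng.dirichlet(np.full(A, config.dirichlet_concentration), size=(K, L))

    sample_ids: list[str] = []
    lineages: list[str] = []
    genets: list[str] = []
    rows: list[np.ndarray] = []
    for k in range(K):
        lin = f"L{k + 1}"
        counts = _draw_ramet_counts(config.ramets_per_genet, config.genets_per_lineage, rng)
        for g in range(config.genets_per_lineage):
            genet_id = f"{lin}_G{g + 1}"
            geno = np.empty((L, 2), dtype=np.int64)
            for l in range(L):
                if rng.random() < config.inbreeding_f:
                    a = rng.choice(A, p=freqs[k, l])
                    geno[l] = sizes[a], sizes[a]
                else:
                    pair = rng.choice(A, size=2, p=freqs[k, l])
                    geno[l] = np.sort(sizes[pair])
            for r in range(counts[g]):
                ramet = geno.copy()
                if config.scoring_error_rate > 0:
                    hit = np.flatnonzero(rng.random(L) < config.scoring_error_rate)
                    if hit.size > config.max_errors_per_ramet:
                        hit = rng.choice(hit, size=config.max_errors_per_ramet, replace=False)
                    for l in hit:
                        which = rng.integers(2)
                        step = ALLELE_STEP if rng.random() < 0.5 else -ALLELE_STEP
                        ramet[l, which] = max(ALLELE_STEP, ramet[l, which] + step)
                        ramet[l] = np.sort(ramet[l])
                if config.missing_rate > 0:
                    miss = rng.random(L) < config.missing_rate
                    ramet[miss] = MISSING
                sample_ids.append(f"{genet_id}_R{r + 1}")
                lineages.append(lin)
                genets.append(genet_id)
                rows.append(ramet)
    if not rows:
        raise ConfigError("simulation produced no samples (all ramet counts zero)")
    table = GenotypeTable(
        sample_ids,
        [f"Loc{l + 1}" for l in range(L)],
        np.stack(rows),
        lineages,
    )
    truth = SimTruth(
        lineage_of_sample=lineages,
        genet_of_sample=genets,
        allele_freqs_true=freqs,
        allele_sizes=sizes,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Read simulation for SSR discovery
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    """Parameters of the two-lineage read-set simulation.

    ``n_shared`` loci appear in both sets with homologous flanks diverged at
    per-base substitution rate ``flank_divergence``; ``n_private_a`` /
    ``n_private_b`` loci appear in only one set. Copy counts are drawn from
    ``copies_range`` per motif length.
    """

    n_shared: int = 50
    n_private_a: int = 50
    n_private_b: int = 0
    read_length: int = 300
    motif_lengths: tuple[int, ...] = (4, 5)
    copies_range: dict | None = None  # {motif_len: (lo, hi)}
    flank_divergence: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_range is None:
            self.copies_range = {4: (10, 15), 5: (8, 12)}
        if self.read_length <= 0:
            raise ConfigError("read_length must be positive")
        if not 0.0 <= self.flank_divergence <= 1.0:
            raise ConfigError("flank_divergence must be in [0, 1]")
        for m, (lo, hi) in self.copies_range.items():
            if lo < 2:
                raise ConfigError("copy counts must be >= 2")
            if m * hi + 2 > self.read_length:
                raise ConfigError(f"planted repeat ({m}-mer x {hi}) longer than read")


def _random_primitive_motif(m: int, rng: np.random.Generator) -> str:
    while True:
        motif = "".join(rng.choice(list("ACGT"), size=m))
        if len(set(motif)) == 1:
            continue
        if m == 4 and motif[:2] * 2 == motif:
            continue
        return motif


def _mutate(seq: str, d: float, rng: np.random.Generator) -> str:
    """Substitute each base with a *different* random base with probability d."""
    if d == 0:
        return seq
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < d):
        alt = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alt[rng.integers(3)]
    return "".join(chars)


def _plant(read_len: int, motif: str, copies: int, rng: np.random.Generator) -> tuple[str, int]:
    """One background read with a perfect repeat planted at a random start."""
    rep = motif * copies
    if len(rep) >= read_len:
        raise ConfigError("planted repeat longer than read")
    margin = read_len - len(rep)
    # keep reasonable flanks on both sides when there is room
    lo = min(margin, max(1, margin // 4))
    start = int(rng.integers(lo, margin - lo + 1)) if margin > 2 * lo else margin // 2
    bg = rng.choice(list("ACGT"), size=read_len)
    seq = "".join(bg[:start]) + rep + "".join(bg[start + len(rep):])
    return seq, start


def simulate_reads(config: ReadSimConfig) -> tuple[list, list, SimTruth]:
    """Simulate two FASTA-ready read sets with planted tandem repeats.

    Returns ``(reads_a, reads_b, truth)`` where each read set is a list of
    ``(id, sequence)`` and the truth records every planted repeat as
    ``(read_id, motif, copies, start)`` plus the A/B pairing of shared loci.
    """
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    reads_a: list[tuple[str, str]] = []
    reads_b: list[tuple[str, str]] = []

    def draw_copies(m: int) -> int:
        lo, hi = config.copies_range[m]
        return int(rng.integers(lo, hi + 1))

    for i in range(config.n_shared):
        m = int(rng.choice(config.motif_lengths))
        motif = _random_primitive_motif(m, rng)
        ca, cb = draw_copies(m), draw_copies(m)
        seq_a, start_a = _plant(config.read_length, motif, ca, rng)
        rid_a, rid_b = f"A_shared_{i + 1}", f"B_shared_{i + 1}"
        left = _mutate(seq_a[:start_a], config.flank_divergence, rng)
        right = _mutate(seq_a[start_a + m * ca:], config.flank_divergence, rng)
        seq_b = left + motif * cb + right
        # pad/trim on the right so both sets have uniform read length
        if len(seq_b) < config.read_length:
            seq_b += "".join(rng.choice(list("ACGT"), size=config.read_length - len(seq_b)))
        else:
            seq_b = seq_b[: max(config.read_length, len(left) + m * cb)]
        reads_a.append((rid_a, seq_a))
        reads_b.append((rid_b, seq_b))
        truth.planted_ssrs.append((rid_a, motif, ca, start_a))
        truth.planted_ssrs_b.append((rid_b, motif, cb, len(left)))
        truth.shared_pairs.append((rid_a, rid_b))
    for i in range(config.n_private_a):
        m = int(rng.choice(config.motif_lengths))
        motif = _random_primitive_motif(m, rng)
        c = draw_copies(m)
        seq, start = _plant(config.read_length, motif, c, rng)
        rid = f"A_priv_{i + 1}"
        reads_a.append((rid, seq))
        truth.planted_ssrs.append((rid, motif, c, start))
    for i in range(config.n_private_b):
        m = int(rng.choice(config.motif_lengths))
        motif = _random_primitive_motif(m, rng)
        c = draw_copies(m)
        seq, start = _plant(config.read_length, motif, c, rng)
        rid = f"B_priv_{i + 1}"
        reads_b.append((rid, seq))
        truth.planted_ssrs_b.append((rid, motif, c, start))
    return reads_a, reads_b, truth


def plant_repeat(read_length: int, motif: str, copies: int, start: int,
                 seed: int = 0) -> str:
    """Deterministic single-read helper: background read with ``motif`` x
    ``copies`` planted at ``start`` (used by examples and tests)."""
    if start + len(motif) * copies > read_length:
        raise ConfigError("planted repeat longer than read")
    rng = np.random.default_rng(seed)
    bg = rng.choice(list("ACGT"), size=read_length)
    rep = motif * copies
    return "".join(bg[:start]) + rep + "".join(bg[start + len(rep):])
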