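"""Perfect tandem-repeat (SSR) detection, retention filtering, and
cross-lineage locus matching between two read sets.

The scanner reports maximal perfect runs of primitive 4/5-bp motifs meeting a
per-motif-length copy threshold. The retention filter applies the copy-count
windows used for fragment-analysis-friendly markers (tetramers 10-15 copies,
pentamers 8-12 by default), a minimum read length, minimum flank lengths, and
drops reads carrying more than one passing repeat. The cross-lineage matcher
replaces a BLAST screen with exact k-mer seeding plus ungapped flank
extension anchored at the repeat boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_MIN_COPIES = {4: 10, 5: 8}
DEFAULT_COPY_RANGES = {4: (10, 15), 5: (8, 12)}


@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem repeat on a read.

    ``read[start:end]`` is exactly ``motif * copies``; the motif is primitive
    (not a power of a shorter string). Flanks are the full read segments
    outside the repeat; ``read_length`` is the length of the carrying read.
    """

    read_id: str
    motif: str
    copies: int
    start: int
    end: int
    left_flank: str
    right_flank: str
    read_length: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.copies * len(self.motif):
            raise ValueError("interval length inconsistent with copies x motif")


@dataclass(frozen=True)
class CrossLineageMatch:
    """A locus shared between read sets A and B with conserved flanks."""

    locus_a: SSRLocus
    locus_b: SSRLocus
    left_identity: float
    right_identity: float
    same_motif: bool


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif[:d] * (m // d) == motif:
            return False
    return True


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation (forward strand only)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _periodic_segments(seq_arr: np.ndarray, valid: np.ndarray, m: int) -> list[tuple[int, int]]:
    """Maximal intervals [s, e) on which the sequence has exact period m
    (restricted to valid bases), with e - s >= 2 m."""
    n = seq_arr.size
    if n < 2 * m:
        return []
    match = (seq_arr[:-m] == seq_arr[m:]) & valid[:-m] & valid[m:]
    if not match.any():
        return []
    padded = np.concatenate(([False], match, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive ends of match runs
    out = []
    for s, e in zip(starts, ends):
        if e - s >= m:  # at least 2 full copies in the periodic segment
            out.append((int(s), int(e) + m))
    return out


def find_ssrs(
    sequence: str,
    min_copies_by_motif_length: Mapping[int, int] | None = None,
    read_id: str = "",
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the copy thresholds.

    Non-ACGT characters break repeat runs. Non-primitive motifs are skipped
    (an ``(ACAC)xk`` run is a dinucleotide repeat, not a tetramer). When a
    maximal periodic segment contains a fractional copy, the reported window
    is anchored at the segment's right edge (the leading remainder is
    dropped). Overlapping reports of different motif lengths are suppressed
    in favor of the longer run. Output is sorted by start position.
    """
    thresholds = dict(min_copies_by_motif_length or DEFAULT_MIN_COPIES)
    seq = sequence.upper()
    if not seq:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    candidates: list[tuple[int, int, str]] = []  # (start, end, motif)
    for m, min_copies in sorted(thresholds.items()):
        for s, e in _periodic_segments(arr, valid, m):
            copies = (e - s) // m
            if copies < min_copies:
                continue
            start = s + (e - s) % m  # right-anchored placement
            motif = seq[start : start + m]
            if not _is_primitive(motif):
                continue
            candidates.append((start, start + copies * m, motif))
    # suppress overlapping reports, longer run wins; ties to smaller start
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    kept: list[tuple[int, int, str]] = []
    for c in candidates:
        if all(c[1] <= k[0] or c[0] >= k[1] for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c[0])
    return [
        SSRLocus(
            read_id=read_id,
            motif=mo,
            copies=(e - s) // len(mo),
            start=s,
            end=e,
            left_flank=seq[:s],
            right_flank=seq[e:],
            read_length=len(seq),
        )
        for s, e, mo in kept
    ]


def scan_reads(
    reads: Iterable[tuple[str, str]],
    min_copies_by_motif_length: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """Run :func:`find_ssrs` over a read set; sorted by (read id, start)."""
    loci: list[SSRLocus] = []
    for rid, seq in reads:
        loci.extend(find_ssrs(seq, min_copies_by_motif_length, read_id=rid))
    loci.sort(key=lambda x: (x.read_id, x.start))
    return loci


def filter_ssrs(
    loci: Sequence[SSRLocus],
    copy_ranges: Mapping[int, tuple[int, int]] | None = None,
    min_read_length: int = 100,
    min_flank: int = 20,
) -> list[SSRLocus]:
    """Retention filter for fragment-analysis-friendly loci.

    Keeps loci whose copy count lies in the closed range for their motif
    length, on reads of at least ``min_read_length`` with at least
    ``min_flank`` bases on both sides of the repeat; reads carrying more than
    one passing locus are dropped entirely (compound-repeat exclusion).
    """
    ranges = dict(copy_ranges or DEFAULT_COPY_RANGES)
    passing: list[SSRLocus] = []
    for loc in loci:
        rng = ranges.get(len(loc.motif))
        if rng is None:
            continue
        lo, hi = rng
        if not lo <= loc.copies <= hi:
            continue
        if loc.read_length < min_read_length:
            continue
        if len(loc.left_flank) < min_flank or len(loc.right_flank) < min_flank:
            continue
        passing.append(loc)
    per_read: dict[str, int] = {}
    for loc in passing:
        per_read[loc.read_id] = per_read.get(loc.read_id, 0) + 1
    return [loc for loc in passing if per_read[loc.read_id] == 1]


def _identity_suffix(a: str, b: str) -> tuple[float, int]:
    span = min(len(a), len(b))
    if span == 0:
        return 0.0, 0
    x = np.frombuffer(a[-span:].encode(), dtype=np.uint8)
    y = np.frombuffer(b[-span:].encode(), dtype=np.uint8)
    return float((x == y).mean()), span


def _identity_prefix(a: str, b: str) -> tuple[float, int]:
    span = min(len(a), len(b))
    if span == 0:
        return 0.0, 0
    x = np.frombuffer(a[:span].encode(), dtype=np.uint8)
    y = np.frombuffer(b[:span].encode(), dtype=np.uint8)
    return float((x == y).mean()), span


def _has_shared_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def match_cross_lineage(
    loci_a: Sequence[SSRLocus],
    reads_b: Iterable[tuple[str, str]],
    k: int = 15,
    min_identity: float = 0.9,
    min_flank_span: int = 30,
) -> list[CrossLineageMatch]:
    """Nominate loci conserved between lineages A and B.

    For each retained A locus, reads of B are scanned for perfect repeats of
    the same primitive motif (canonical rotation, any copy count >= 2); the
    flanks of candidate pairs are aligned without gaps, anchored at the
    repeat boundaries. A match requires an exact shared ``k``-mer seed in
    either flank pair and identity >= ``min_identity`` over at least
    ``min_flank_span`` aligned bases on both sides.
    """
    b_loci = scan_reads(reads_b, {4: 2, 5: 2})
    by_motif: dict[str, list[SSRLocus]] = {}
    for loc in b_loci:
        by_motif.setdefault(canonical_rotation(loc.motif), []).append(loc)
    matches: list[CrossLineageMatch] = []
    for la in sorted(loci_a, key=lambda x: (x.read_id, x.start)):
        for lb in by_motif.get(canonical_rotation(la.motif), []):
            li, lspan = _identity_suffix(la.left_flank, lb.left_flank)
            ri, rspan = _identity_prefix(la.right_flank, lb.right_flank)
            if lspan < min_flank_span or rspan < min_flank_span:
                continue
            if li < min_identity or ri < min_identity:
                continue
            seed = _has_shared_kmer(
                la.left_flank[-lspan:], lb.left_flank[-lspan:], k
            ) or _has_shared_kmer(la.right_flank[:rspan], lb.right_flank[:rspan], k)
            if not seed:
                continue
            matches.append(
                CrossLineageMatch(
                    locus_a=la,
                    locus_b=lb,
                    left_identity=li,
                    right_identity=ri,
                    same_motif=True,
                )
            )
    return matches
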