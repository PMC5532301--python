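"""Text formats for co-dominant microsatellite data.

The central container is :class:`GenotypeTable`: a samples x loci matrix of
unordered diploid allele-size pairs, with ``(0, 0)`` coding a missing locus.
Readers and writers are provided for a GenAlEx-style CSV layout, the Genepop
dialect, STRUCTURE raw input, and FASTA (via Biopython). All round-trip
losslessly on valid tables; see the individual functions for the dialect
details and their limitations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = 0

# population-column header names recognised in CSV input (case-insensitive)
_POP_HEADERS = {"pop", "population", "site", "lineage", "group"}

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Malformed input file; message carries the row/column location."""


@dataclass
class GenotypeTable:
    """Samples x loci matrix of unordered diploid allele pairs.

    ``genotypes`` has shape ``(n_samples, n_loci, 2)``; each pair is stored
    sorted ascending so that pair order is non-semantic. Allele code 0 occurs
    only as the missing pair ``(0, 0)``.
    """

    sample_ids: list[str]
    locus_names: list[str]
    genotypes: np.ndarray
    population_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_names = list(self.locus_names)
        g = np.asarray(self.genotypes, dtype=np.int64)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError(f"genotypes must have shape (n, loci, 2), got {g.shape}")
        if g.shape[0] != len(self.sample_ids) or g.shape[1] != len(self.locus_names):
            raise ValueError("genotype array shape does not match sample/locus names")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicate locus names")
        if np.any(g < 0):
            raise ValueError("negative allele code")
        half_missing = (g == MISSING).sum(axis=2) == 1
        if np.any(half_missing):
            raise ValueError("allele code 0 may only appear as the pair (0, 0)")
        self.genotypes = np.sort(g, axis=2)
        if self.population_labels is not None:
            self.population_labels = list(self.population_labels)
            if len(self.population_labels) != len(self.sample_ids):
                raise ValueError("population_labels length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) mask, True where the locus is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def present_mask(self) -> np.ndarray:
        return ~self.missing_mask()

    def pair_codes(self) -> np.ndarray:
        """Integer (n, loci) codes unique per unordered pair; 0 = missing."""
        g = self.genotypes
        base = int(g.max()) + 1
        return g[:, :, 0] * base + g[:, :, 1]

    def subset_samples(self, index: Sequence[int]) -> "GenotypeTable":
        idx = list(index)
        pops = None
        if self.population_labels is not None:
            pops = [self.population_labels[i] for i in idx]
        return GenotypeTable(
            [self.sample_ids[i] for i in idx],
            list(self.locus_names),
            self.genotypes[idx].copy(),
            pops,
        )

    def subset_loci(self, index: Sequence[int]) -> "GenotypeTable":
        idx = list(index)
        return GenotypeTable(
            list(self.sample_ids),
            [self.locus_names[i] for i in idx],
            self.genotypes[:, idx].copy(),
            None if self.population_labels is None else list(self.population_labels),
        )

    def drop_loci(self, names: Sequence[str]) -> "GenotypeTable":
        drop = set(names)
        keep = [i for i, n in enumerate(self.locus_names) if n not in drop]
        return self.subset_loci(keep)

    def groups(self) -> dict[str, list[int]]:
        """Sample indices per population label (single group if unlabeled)."""
        if self.population_labels is None:
            return {"all": list(range(self.n_samples))}
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(self.population_labels):
            out.setdefault(lab, []).append(i)
        return out

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.genotypes, other.genotypes)
            and self.population_labels == other.population_labels
        )


# ---------------------------------------------------------------------------
# GenAlEx-style CSV: one row per sample, two columns per locus
# ---------------------------------------------------------------------------

def write_genotype_csv(table: GenotypeTable, path: str | Path) -> None:
    """Write the two-columns-per-locus CSV layout (locus name repeated)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["sample_id"]
        if table.population_labels is not None:
            header.append("population")
        for name in table.locus_names:
            header += [name, name]
        w.writerow(header)
        for i, sid in enumerate(table.sample_ids):
            row: list[str] = [sid]
            if table.population_labels is not None:
                row.append(table.population_labels[i])
            for l in range(table.n_loci):
                a, b = table.genotypes[i, l]
                row += [str(int(a)), str(int(b))]
            w.writerow(row)


def read_genotype_csv(path: str | Path) -> GenotypeTable:
    """Read the CSV layout written by :func:`write_genotype_csv`.

    The population column is detected by header name (pop/population/site/
    lineage/group, case-insensitive). Raises :class:`FormatError` with the
    offending row and column for odd allele-column counts, duplicate sample
    ids, or non-integer alleles.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    has_pop = len(header) > 1 and header[1].lower() in _POP_HEADERS
    first_allele_col = 2 if has_pop else 1
    allele_headers = header[first_allele_col:]
    if len(allele_headers) == 0 or len(allele_headers) % 2 != 0:
        raise FormatError(
            f"{path}: header row has {len(allele_headers)} allele columns "
            "(two per locus required)"
        )
    locus_names = allele_headers[0::2]
    if len(set(locus_names)) != len(locus_names):
        raise FormatError(f"{path}: duplicate locus names in header")
    sample_ids: list[str] = []
    pops: list[str] = []
    geno = np.zeros((len(rows) - 1, len(locus_names), 2), dtype=np.int64)
    for r, row in enumerate(rows[1:], start=2):
        cells = [c.strip() for c in row]
        if len(cells) != len(header):
            raise FormatError(f"{path}: row {r} has {len(cells)} fields, expected {len(header)}")
        sid = cells[0]
        if sid in sample_ids:
            raise FormatError(f"{path}: row {r}: duplicate sample id {sid!r}")
        sample_ids.append(sid)
        if has_pop:
            pops.append(cells[1])
        for l in range(len(locus_names)):
            for k in range(2):
                c = first_allele_col + 2 * l + k
                try:
                    geno[r - 2, l, k] = int(cells[c])
                except ValueError:
                    raise FormatError(
                        f"{path}: row {r}, column {c + 1}: non-integer allele {cells[c]!r}"
                    ) from None
    try:
        return GenotypeTable(sample_ids, locus_names, geno, pops if has_pop else None)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def write_genepop(table: GenotypeTable, path: str | Path, title: str = "msatpop export") -> None:
    """Write the Genepop dialect (3 digits per allele, 000000 = missing).

    Population names are not part of the dialect; consecutive samples sharing
    a population label form one ``Pop`` block.
    """
    if int(table.genotypes.max(initial=0)) > 999:
        raise FormatError("Genepop 3-digit encoding requires allele codes <= 999")
    lines = [title]
    lines += table.locus_names
    labels = table.population_labels or ["all"] * table.n_samples
    prev = None
    for i, sid in enumerate(table.sample_ids):
        if labels[i] != prev:
            lines.append("Pop")
            prev = labels[i]
        toks = [f"{int(a):03d}{int(b):03d}" for a, b in table.genotypes[i]]
        lines.append(f"{sid} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read Genepop; blocks become labels ``pop_1``, ``pop_2``, ... in order."""
    raw = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    raw = [ln for ln in raw if ln.strip()]
    if len(raw) < 3:
        raise FormatError(f"{path}: not a Genepop file (too short)")
    locus_names: list[str] = []
    i = 1  # skip title
    while i < len(raw) and raw[i].strip().lower() != "pop":
        # a single comma-separated locus line is also legal in the dialect
        locus_names += [t.strip() for t in raw[i].split(",") if t.strip()]
        i += 1
    if not locus_names or i == len(raw):
        raise FormatError(f"{path}: no locus names / no Pop line")
    sample_ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_idx = 0
    for ln in raw[i:]:
        if ln.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in ln:
            raise FormatError(f"{path}: sample line without comma: {ln!r}")
        sid, geno_part = ln.split(",", 1)
        toks = geno_part.split()
        if len(toks) != len(locus_names):
            raise FormatError(
                f"{path}: sample {sid.strip()!r} has {len(toks)} genotypes, "
                f"expected {len(locus_names)}"
            )
        pair_row: list[int] = []
        for t in toks:
            if len(t) != 6 or not t.isdigit():
                raise FormatError(f"{path}: bad genotype token {t!r}")
            pair_row += [int(t[:3]), int(t[3:])]
        sample_ids.append(sid.strip())
        pops.append(f"pop_{pop_idx}")
        rows.append(pair_row)
    geno = np.asarray(rows, dtype=np.int64).reshape(len(rows), len(locus_names), 2)
    return GenotypeTable(sample_ids, locus_names, geno, pops)


# ---------------------------------------------------------------------------
# STRUCTURE raw input
# ---------------------------------------------------------------------------

def write_structure_input(
    table: GenotypeTable,
    path: str | Path,
    layout: str = "two-row",
    recode: bool = True,
) -> dict:
    """Write STRUCTURE raw text: locus-name header, then per-sample rows.

    ``two-row`` puts one allele per row (two rows per sample); ``one-row``
    puts two adjacent columns per locus. Missing is coded -9. Populations are
    written as integer codes. With ``recode=True`` allele sizes are recoded to
    1..n per locus; the allele and population maps are written to a sidecar
    ``<path>.map.json`` and returned.
    """
    if layout not in ("two-row", "one-row"):
        raise ValueError(f"unknown layout {layout!r}")
    pops = table.population_labels or ["all"] * table.n_samples
    pop_code = {lab: i + 1 for i, lab in enumerate(dict.fromkeys(pops))}
    allele_map: dict[str, dict[str, int]] = {}
    coded = table.genotypes.copy()
    if recode:
        for l, name in enumerate(table.locus_names):
            sizes = sorted(int(a) for a in np.unique(table.genotypes[:, :, :][:, l]) if a != MISSING)
            m = {s: j + 1 for j, s in enumerate(sizes)}
            allele_map[name] = {str(s): c for s, c in m.items()}
            for s, c in m.items():
                coded[:, l][table.genotypes[:, l] == s] = c
    out = coded.astype(object)
    out[table.genotypes == MISSING] = -9
    lines = ["\t".join(table.locus_names)]
    for i, sid in enumerate(table.sample_ids):
        if layout == "two-row":
            for k in range(2):
                cells = [sid, str(pop_code[pops[i]])] + [str(out[i, l, k]) for l in range(table.n_loci)]
                lines.append("\t".join(cells))
        else:
            cells = [sid, str(pop_code[pops[i]])]
            for l in range(table.n_loci):
                cells += [str(out[i, l, 0]), str(out[i, l, 1])]
            lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
    sidecar = {
        "layout": layout,
        "recode": recode,
        "populations": {str(c): lab for lab, c in pop_code.items()},
        "alleles": allele_map,
        "has_labels": table.population_labels is not None,
    }
    Path(str(path) + ".map.json").write_text(json.dumps(sidecar, indent=1))
    return sidecar


def read_structure_input(path: str | Path, sidecar: dict | None = None) -> GenotypeTable:
    """Read the STRUCTURE text written by :func:`write_structure_input`."""
    if sidecar is None:
        sc_path = Path(str(path) + ".map.json")
        sidecar = json.loads(sc_path.read_text()) if sc_path.exists() else {
            "layout": "two-row", "recode": False, "populations": {}, "alleles": {},
            "has_labels": True,
        }
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    locus_names = lines[0].split("\t")
    L = len(locus_names)
    sample_ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    body = lines[1:]
    if sidecar["layout"] == "two-row":
        if len(body) % 2:
            raise FormatError(f"{path}: odd number of data rows in two-row layout")
        for j in range(0, len(body), 2):
            r1, r2 = body[j].split("\t"), body[j + 1].split("\t")
            if r1[0] != r2[0]:
                raise FormatError(f"{path}: row pair for {r1[0]!r}/{r2[0]!r} mismatched")
            sample_ids.append(r1[0])
            pops.append(r1[1])
            pair = np.stack(
                [np.array(r1[2 : 2 + L], dtype=np.int64), np.array(r2[2 : 2 + L], dtype=np.int64)],
                axis=1,
            )
            rows.append(pair)
    else:
        for ln in body:
            cells = ln.split("\t")
            sample_ids.append(cells[0])
            pops.append(cells[1])
            vals = np.array(cells[2 : 2 + 2 * L], dtype=np.int64)
            rows.append(vals.reshape(L, 2))
    geno = np.stack(rows)
    geno[geno == -9] = MISSING
    if sidecar.get("recode"):
        decoded = geno.copy()
        for l, name in enumerate(locus_names):
            inv = {c: int(s) for s, c in sidecar["alleles"].get(name, {}).items()}
            for c, s in inv.items():
                decoded[:, l][geno[:, l] == c] = s
        geno = decoded
    pop_names = sidecar.get("populations", {})
    labels = [pop_names.get(p, p) for p in pops]
    if not sidecar.get("has_labels", True):
        labels = None
    return GenotypeTable(sample_ids, locus_names, geno, labels)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, uppercase sequence) pairs.

    Rejects empty files, duplicate ids, and non-IUPAC characters.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise FormatError(f"{path}: {rec.id}: non-IUPAC characters {sorted(bad)}")
        out.append((rec.id, seq))
    return out


def write_fasta(sequences: Sequence[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.upper()), id=i, description="") for i, s in sequences]
    SeqIO.write(records, str(path), "fasta")
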