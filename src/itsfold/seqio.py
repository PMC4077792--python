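"""Sequence and structure I/O.

Core domain types (:class:`SequenceRecord`, :class:`SecondaryStructure`) plus
readers/writers for FASTA, Vienna dot-bracket, and CT connectivity tables.

Coordinate conventions: pair indices are 0-based internally; serialized CT
files use the conventional 1-based indexing.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC nucleotide one-letter codes accepted in a record (RNA alphabet).
IUPAC_RNA = frozenset("ACGURYSWKMBDHVN")

GAP_CHARS = frozenset("-.")


class Region(str, enum.Enum):
    """Which class a sequence belongs to in the analysis design."""

    ITS1 = "ITS1"
    ITS2 = "ITS2"
    RANDOM = "RANDOM"
    SYNTH = "SYNTH"


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped nucleotide sequence with identity and class labels.

    ``residues`` is an upper-case RNA string; DNA input is converted on read
    (T -> U). IUPAC ambiguity codes are retained but never allowed to pair
    during folding.
    """

    id: str
    residues: str
    region: Region = Region.ITS1
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_RNA
        if bad & GAP_CHARS:
            raise ValueError(
                f"record {self.id!r}: gap characters present; read with degap=True"
            )
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def gc_count(self) -> int:
        return sum(self.residues.count(b) for b in "GCS")

    @property
    def gc_fraction(self) -> float:
        return self.gc_count / len(self.residues)


def pooled_gc(records: Iterable[SequenceRecord]) -> float:
    """GC fraction over all bases of all records pooled together."""
    records = list(records)
    if not records:
        raise ValueError("pooled_gc of an empty record set")
    total = sum(len(r) for r in records)
    return sum(r.gc_count for r in records) / total


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing of one sequence plus its free energy.

    ``pairs`` holds 0-based ``(i, j)`` tuples with ``i < j``; ``energy`` is in
    kcal/mol (0.0 for the open chain).
    """

    seq_id: str
    pairs: tuple[tuple[int, int], ...]
    energy: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(sorted(tuple(p) for p in self.pairs)))
        seen: set[int] = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i},{j}): need i < j")
            if j - i - 1 < 3:
                raise ValueError(f"pair ({i},{j}): hairpin loop shorter than 3")
            if i in seen or j in seen:
                raise ValueError(f"index {i if i in seen else j} paired twice")
            seen.update((i, j))
        plist = self.pairs
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                i, j = plist[a]
                k, l = plist[b]
                if i < k < j < l:
                    raise ValueError(f"pairs ({i},{j}) and ({k},{l}) cross")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_table(self, n: int) -> list[int]:
        """Partner index per position (-1 = unpaired), validating bounds."""
        table = [-1] * n
        for i, j in self.pairs:
            if j >= n:
                raise ValueError(f"pair ({i},{j}) outside sequence of length {n}")
            table[i], table[j] = j, i
        return table


# ---------------------------------------------------------------------------
# FASTA


def _normalize(raw: str, rec_id: str, degap: bool) -> str:
    s = raw.upper().replace("T", "U")
    if degap:
        s = "".join(c for c in s if c not in GAP_CHARS)
    return s


def read_fasta(
    path: str | Path,
    degap: bool = True,
    region: Region = Region.ITS1,
) -> list[SequenceRecord]:
    """Read a (possibly gapped/aligned) FASTA file into records.

    With ``degap`` on, '-' and '.' are removed; T is mapped to U and case is
    folded to upper. Malformed residues raise with the offending record id.
    """
    out: list[SequenceRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        residues = _normalize(str(rec.seq), rec.id, degap)
        out.append(SequenceRecord(id=rec.id, residues=residues, region=region))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.region.value)
        for r in records
    ]
    with open(path, "w") as fh:
        _BioSeqIO.write(bio, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Dot-bracket


def pairs_to_dotbracket(pairs: Sequence[tuple[int, int]], n: int) -> str:
    chars = ["."] * n
    for i, j in pairs:
        if j >= n:
            raise ValueError(f"pair ({i},{j}) outside sequence of length {n}")
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def dotbracket_to_pairs(db: str) -> tuple[tuple[int, int], ...]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} in dot-bracket")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return tuple(sorted(pairs))


def write_dotbracket(structure: SecondaryStructure, seq: SequenceRecord) -> str:
    """Serialize to three-line Vienna format: header, sequence, annotation."""
    db = pairs_to_dotbracket(structure.pairs, len(seq))
    return f">{seq.id}\n{seq.residues}\n{db} ({structure.energy:.1f})\n"


def read_dotbracket(text: str) -> tuple[SequenceRecord, SecondaryStructure]:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) != 3 or not lines[0].startswith(">"):
        raise ValueError("expected 3 lines: >header, sequence, dot-bracket")
    seq_id = lines[0][1:].split()[0]
    residues = lines[1].strip()
    parts = lines[2].rsplit(None, 1)
    if len(parts) == 2 and parts[1].startswith("(") and parts[1].endswith(")"):
        db, energy = parts[0], float(parts[1][1:-1])
    else:
        db, energy = lines[2].strip(), 0.0
    if len(db) != len(residues):
        raise ValueError("dot-bracket length differs from sequence length")
    rec = SequenceRecord(id=seq_id, residues=residues)
    struct = SecondaryStructure(seq_id=seq_id, pairs=dotbracket_to_pairs(db), energy=energy)
    return rec, struct


# ---------------------------------------------------------------------------
# CT (connectivity table) — the exchange format for external cross-checks.


def write_ct(structure: SecondaryStructure, seq: SequenceRecord) -> str:
    n = len(seq)
    table = structure.pair_table(n)
    buf = io.StringIO()
    buf.write(f"{n}\tdG = {structure.energy:.1f}\t{seq.id}\n")
    for i in range(n):
        buf.write(
            f"{i + 1}\t{seq.residues[i]}\t{i}\t{(i + 2) if i + 1 < n else 0}"
            f"\t{table[i] + 1}\t{i + 1}\n"
        )
    return buf.getvalue()


def read_ct(text: str) -> tuple[SequenceRecord, SecondaryStructure]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    head = lines[0].split()
    n = int(head[0])
    energy = 0.0
    for tok_i, tok in enumerate(head):
        if tok == "=":
            energy = float(head[tok_i + 1])
    seq_id = head[-1]
    residues = []
    pairs = []
    for ln in lines[1 : n + 1]:
        toks = ln.split()
        idx, base, partner = int(toks[0]) - 1, toks[1], int(toks[4]) - 1
        residues.append(base)
        if partner > idx:
            pairs.append((idx, partner))
    rec = SequenceRecord(id=seq_id, residues="".join(residues))
    return rec, SecondaryStructure(seq_id=seq_id, pairs=tuple(pairs), energy=energy)
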