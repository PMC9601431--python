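"""FASTA reading, alphabet detection, and sanitization.

Sequences are held fully in memory as uppercase residue strings. Each record
carries a declared alphabet (DNA, RNA, or protein) and an optional class
label; labels are normally assigned per file (one FASTA per class), mirroring
how two-class sequence benchmarks are usually distributed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger("seqentropy")

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "detect_alphabet",
    "sanitize",
    "sanitize_all",
]


class Alphabet(str, Enum):
    DNA = "dna"
    RNA = "rna"
    PROTEIN = "protein"


#: Canonical residue sets. Ambiguity codes are NOT canonical; after masking,
#: every out-of-alphabet symbol becomes the alphabet's ambiguity character.
CANONICAL = {
    Alphabet.DNA: frozenset("ACGT"),
    Alphabet.RNA: frozenset("ACGU"),
    Alphabet.PROTEIN: frozenset("ACDEFGHIKLMNPQRSTVWY"),
}

#: Symbol used to mark an ambiguous position after masking.
AMBIGUITY = {
    Alphabet.DNA: "N",
    Alphabet.RNA: "N",
    Alphabet.PROTEIN: "X",
}

#: Fixed lexicographic symbol order per alphabet; pins feature-vector layout.
SYMBOL_ORDER = {
    Alphabet.DNA: "ACGT",
    Alphabet.RNA: "ACGU",
    Alphabet.PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
}


@dataclass(frozen=True)
class SequenceRecord:
    """One named residue string with a declared alphabet.

    ``length`` (the N in the k-mer denominator N-k+1) is always the number
    of residue symbols, including any masked/ambiguous positions.
    """

    id: str
    residues: str
    alphabet: Alphabet | None = None
    label: str | None = None

    @property
    def length(self) -> int:
        return len(self.residues)

    def ambiguity_symbol(self) -> str:
        if self.alphabet is None:
            raise ValueError(f"record {self.id!r} has no alphabet assigned")
        return AMBIGUITY[self.alphabet]


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path,
    label: str | None = None,
    alphabet: Alphabet | str | None = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Residues are uppercased; the record id is the first whitespace-delimited
    token after ``>``. ``label`` is attached to every record. If ``alphabet``
    is None, each record's alphabet is detected with :func:`detect_alphabet`.

    Raises
    ------
    ValueError
        On an empty file ("no sequences"), a header with an empty body, or
        non-FASTA content before the first ``>``.
    """
    path = Path(path)
    if alphabet is not None:
        alphabet = Alphabet(alphabet)
    with _open_text(path) as handle:
        # Bio.SeqIO tolerates some malformed inputs; check the leading
        # character ourselves so the error contract is explicit.
        head = handle.read(1)
        while head and head.isspace():
            head = handle.read(1)
        if not head:
            raise ValueError(f"{path}: no sequences")
        if head != ">":
            raise ValueError(f"{path}: not FASTA — content before first '>'")
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            residues = str(entry.seq).upper()
            if not residues:
                raise ValueError(f"{path}: entry {entry.id!r} has an empty body")
            rec = SequenceRecord(id=entry.id, residues=residues, label=label)
            rec = replace(rec, alphabet=alphabet or detect_alphabet(rec))
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with open(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def detect_alphabet(record: SequenceRecord, override: Alphabet | str | None = None) -> Alphabet:
    """Classify residues as DNA, RNA, or protein.

    DNA if all residues are in {A,C,G,T,N}; RNA if in {A,C,G,U,N}; otherwise
    protein. Ambiguous cases (e.g. an all-A sequence) resolve to DNA unless
    ``override`` is given.
    """
    if override is not None:
        return Alphabet(override)
    if not record.residues:
        raise ValueError(f"record {record.id!r} is empty")
    symbols = set(record.residues)
    if symbols <= CANONICAL[Alphabet.DNA] | {"N"}:
        return Alphabet.DNA
    if symbols <= CANONICAL[Alphabet.RNA] | {"N"}:
        return Alphabet.RNA
    return Alphabet.PROTEIN


def sanitize(record: SequenceRecord, policy: str = "mask") -> SequenceRecord | None:
    """Resolve out-of-alphabet symbols.

    policy="mask"
        Replace every symbol outside the canonical alphabet with the
        ambiguity character (N for nucleotides, X for protein). Windows
        containing a masked position are later excluded from k-mer counting.
    policy="drop_sequence"
        Return None (record removed) if any out-of-alphabet symbol occurs; a
        warning is logged. Clean records are returned unchanged.
    """
    if record.alphabet is None:
        raise ValueError(f"record {record.id!r}: assign an alphabet before sanitizing")
    canonical = CANONICAL[record.alphabet]
    amb = AMBIGUITY[record.alphabet]
    dirty = [c for c in record.residues if c not in canonical and c != amb]
    if policy == "mask":
        if not dirty:
            return record
        cleaned = "".join(c if c in canonical else amb for c in record.residues)
        return replace(record, residues=cleaned)
    if policy == "drop_sequence":
        if dirty:
            logger.warning(
                "dropping sequence %r: %d out-of-alphabet symbol(s) e.g. %r",
                record.id, len(dirty), dirty[0],
            )
            return None
        return record
    raise ValueError(f"unknown sanitize policy {policy!r}")


def sanitize_all(records: Iterable[SequenceRecord], policy: str = "mask") -> list[SequenceRecord]:
    """Apply :func:`sanitize` to every record, removing dropped ones."""
    out = []
    for rec in records:
        clean = sanitize(rec, policy=policy)
        if clean is not None:
            out.append(clean)
    return out


def map_u_to_t(record: SequenceRecord) -> SequenceRecord:
    """Recode RNA U as DNA T (opt-in; U is never silently converted)."""
    return replace(record, residues=record.residues.replace("U", "T"), alphabet=Alphabet.DNA)
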