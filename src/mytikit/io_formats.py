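"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (plain and aligned), Stockholm 1.0, Newick and TSV reports. Parsing is
delegated to Biopython / dendropy / pandas; this module adds the strict
validation the rest of the pipeline relies on (unique ids, a closed residue
alphabet, 1-based coordinates in reports).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 IUPAC one-letter amino acids plus the ambiguity code X.
PEPTIDE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

PROVENANCES = ("fixture", "synthetic", "screened")


class DuplicateIdError(ValueError):
    """Two records in one file share an id."""


class AlphabetError(ValueError):
    """A sequence contains a character outside its declared alphabet."""


def _validate_sequence(record_id: str, seq: str, alphabet: frozenset[str], what: str) -> str:
    if not seq:
        raise AlphabetError(f"record {record_id!r}: empty {what} sequence")
    if seq != seq.upper():
        warnings.warn(f"record {record_id!r}: lowercase letters uppercased", stacklevel=3)
        seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise AlphabetError(
                f"record {record_id!r}: illegal character {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class Peptide:
    """An amino-acid sequence with an id and a provenance tag."""

    id: str
    residues: str
    description: str = ""
    provenance: str = "fixture"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("peptide id must be non-empty")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(
            self, "residues", _validate_sequence(self.id, self.residues, PEPTIDE_ALPHABET, "peptide")
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled transcript; both strands are searched downstream."""

    id: str
    nucleotides: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        object.__setattr__(
            self,
            "nucleotides",
            _validate_sequence(self.id, self.nucleotides, NUCLEOTIDE_ALPHABET, "nucleotide"),
        )

    def __len__(self) -> int:
        return len(self.nucleotides)


def _open_maybe_gzip(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_unique(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise DuplicateIdError(f"duplicate record id {rid!r}")
        seen.add(rid)


def read_fasta(path, kind: str = "peptide", provenance: str = "fixture"):
    """Read a FASTA file into a list of :class:`Peptide` or :class:`TranscriptRecord`.

    Parameters
    ----------
    kind:
        ``"peptide"`` or ``"transcript"``; selects the record type and alphabet.
    provenance:
        Provenance tag stamped on peptides (ignored for transcripts).
    """
    if kind not in ("peptide", "transcript"):
        raise ValueError(f"unknown kind {kind!r}")
    records = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if kind == "peptide":
                records.append(
                    Peptide(rec.id, seq, description=rec.description, provenance=provenance)
                )
            else:
                records.append(TranscriptRecord(rec.id, seq, description=rec.description))
    _check_unique([r.id for r in records])
    return records


def _to_seqrecords(objects) -> list[SeqRecord]:
    out = []
    for obj in objects:
        seq = getattr(obj, "residues", None) or getattr(obj, "nucleotides", None)
        if seq is None:
            raise TypeError(f"cannot write object of type {type(obj).__name__} as FASTA")
        out.append(SeqRecord(Seq(seq), id=obj.id, description=getattr(obj, "description", "") or ""))
    return out


def write_fasta(objects, path, width: int = 60) -> None:
    """Write peptides or transcripts as wrapped FASTA."""
    records = _to_seqrecords(objects)
    _check_unique([r.id for r in records])
    with _open_maybe_gzip(path, "wt") as handle:
        for rec in records:
            desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
            handle.write(f">{rec.id}{desc}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_aligned_fasta(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file as ``(id, gapped_row)`` pairs (gaps allowed)."""
    rows = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rows.append((rec.id, str(rec.seq).upper()))
    _check_unique([rid for rid, _ in rows])
    lengths = {len(r) for _, r in rows}
    if len(lengths) > 1:
        raise ValueError("aligned FASTA rows have unequal lengths")
    return rows


def write_aligned_fasta(rows: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    rows = list(rows)
    _check_unique([rid for rid, _ in rows])
    with _open_maybe_gzip(path, "wt") as handle:
        for rid, row in rows:
            handle.write(f">{rid}\n")
            for i in range(0, len(row), width):
                handle.write(row[i : i + width] + "\n")


def write_stockholm(rows: Iterable[tuple[str, str]], path) -> None:
    """Write ``(id, gapped_row)`` pairs as a Stockholm 1.0 alignment."""
    rows = list(rows)
    _check_unique([rid for rid, _ in rows])
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=rid, description="") for rid, row in rows]
    )
    with _open_maybe_gzip(path, "wt") as handle:
        AlignIO.write(msa, handle, "stockholm")


def read_stockholm(path) -> list[tuple[str, str]]:
    with _open_maybe_gzip(path) as handle:
        msa = AlignIO.read(handle, "stockholm")
    return [(rec.id, str(rec.seq).upper()) for rec in msa]


def write_newick(tree: dendropy.Tree, path) -> None:
    with _open_maybe_gzip(path, "wt") as handle:
        handle.write(tree.as_string(schema="newick", suppress_rooting=True))


def read_newick(path) -> dendropy.Tree:
    with _open_maybe_gzip(path) as handle:
        return dendropy.Tree.get(data=handle.read(), schema="newick")


def write_tsv_report(frame: pd.DataFrame, path) -> None:
    """Write a report table as TSV with a header row (coordinates 1-based inclusive)."""
    frame.to_csv(path, sep="\t", index=False)


def read_tsv_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
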