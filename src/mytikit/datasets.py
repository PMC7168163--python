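"""Bundled reference data: 30 mytilin-like mature peptides.

The table covers six species (Mytilus californianus, M. coruscus,
M. galloprovincialis, Perna canaliculus, P. viridis, Trichomya hirsuta) and
records, next to each published mature-peptide sequence, the length and net
charge reported alongside it. Two rows carry internally inconsistent
reported values; they are kept verbatim so that :func:`validate_reference_table`
can surface them rather than silently "fixing" the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import Peptide

_TABLE_FILE = "table1.tsv"

#: Name prefixes of the two Perna species in the reference table.
PERNA_PREFIXES = ("Pcan", "Pvir")


def load_reference_frame() -> pd.DataFrame:
    """The raw reference table as a DataFrame.

    Columns: ``name``, ``mature_sequence``, ``reported_length``,
    ``reported_net_charge`` and ``reported_length_alt`` (a second, conflicting
    published length where one exists).
    """
    with resources.files("mytikit.data").joinpath(_TABLE_FILE).open() as handle:
        frame = pd.read_csv(handle, sep="\t", dtype={"name": str, "mature_sequence": str})
    return frame


def load_reference_peptides() -> list[Peptide]:
    """The 30 reference mature peptides as :class:`Peptide` objects."""
    frame = load_reference_frame()
    return [
        # ids are FASTA-safe (no whitespace); the display name keeps spaces
        Peptide(row["name"].replace(" ", "_"), row["mature_sequence"],
                description=row["name"], provenance="fixture")
        for _, row in frame.iterrows()
    ]


def perna_peptides() -> list[Peptide]:
    """The 15 Perna spp. rows of the reference table."""
    return [p for p in load_reference_peptides() if p.id.startswith(PERNA_PREFIXES)]


@dataclass(frozen=True)
class LengthFlag:
    """A reference row whose reported length disagrees with itself or its sequence."""

    name: str
    sequence_length: int
    reported_length: int
    reported_length_alt: int | None
    reason: str


def validate_reference_table(frame: pd.DataFrame | None = None) -> list[LengthFlag]:
    """Check each row's sequence length against its reported length(s).

    Returns one flag per inconsistent row: either the sequence does not have
    the reported number of residues, or two different lengths were reported
    for the same peptide. Consistent rows produce no flag.
    """
    if frame is None:
        frame = load_reference_frame()
    flags: list[LengthFlag] = []
    for _, row in frame.iterrows():
        seq_len = len(row["mature_sequence"])
        reported = int(row["reported_length"])
        alt = row.get("reported_length_alt")
        alt = None if pd.isna(alt) else int(alt)
        if seq_len != reported:
            flags.append(
                LengthFlag(row["name"], seq_len, reported, alt,
                           "sequence length differs from reported length")
            )
        elif alt is not None and alt != reported:
            flags.append(
                LengthFlag(row["name"], seq_len, reported, alt,
                           "two conflicting lengths reported")
            )
    return flags
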