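"""Tripartite segmentation of mytilin precursors.

A precursor splits into a ~20 aa signal peptide (SP), a 32-38 aa cysteine-rich
cationic mature peptide, and an anionic C-terminal extension. The SP cleavage
site is predicted by a von Heijne-style heuristic (hydrophobic-core window
plus small-residue bonuses at the -3/-1 positions); the mature/C-tail boundary
is always mapped through a global alignment with a reference precursor of
known segmentation — there is no ab initio C-tail caller. All coordinates are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import global_align
from .io_formats import Peptide

HYDROPHOBIC = frozenset("AILVFMW")
SMALL_MINUS1 = frozenset("AGSC")
SMALL_MINUS3 = frozenset("AGSVC")
CLEAVAGE_RANGE = (15, 30)  # candidate positions for the last SP residue
PREFERRED_SP_LENGTH = 20  # typical mytilin signal peptide length
MATURE_LENGTH_BOUNDS = (30, 45)  # sanity bound for called mature peptides


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class PrecursorAnnotation:
    """1-based inclusive intervals; ctail may be empty for truncated precursors."""

    peptide_id: str
    sp: tuple[int, int]
    mature: tuple[int, int]
    ctail: tuple[int, int] | None
    method: str  # given | heuristic | by_alignment

    def __post_init__(self) -> None:
        if self.sp[0] != 1 or self.sp[1] + 1 != self.mature[0]:
            raise ValueError("sp and mature intervals must be contiguous from position 1")
        if self.ctail is not None and self.mature[1] + 1 != self.ctail[0]:
            raise ValueError("mature and ctail intervals must be contiguous")
        if self.method != "given":
            mlen = self.mature[1] - self.mature[0] + 1
            lo, hi = MATURE_LENGTH_BOUNDS
            if not lo <= mlen <= hi:
                raise SegmentationError(
                    f"{self.peptide_id}: called mature length {mlen} outside [{lo}, {hi}]"
                )

    @property
    def sp_end(self) -> int:
        return self.sp[1]

    @property
    def mature_interval(self) -> tuple[int, int]:
        return self.mature


def _cleavage_score(seq: str, pos: int) -> float:
    """Heuristic score for cleaving after 1-based position ``pos``."""
    window = seq[max(0, pos - 12) : pos - 1]  # the 11 residues preceding the candidate
    s = float(sum(aa in HYDROPHOBIC for aa in window))
    if seq[pos - 1] in SMALL_MINUS1:
        s += 2.0
    if pos >= 3 and seq[pos - 3] in SMALL_MINUS3:
        s += 1.0
    return s


def predict_signal_cleavage(precursor: Peptide | str) -> int:
    """Position of the last signal-peptide residue, scanned over positions 15-30.

    Ties are broken toward position 20 (the typical mytilin SP length), then
    toward the shorter peptide. Raises if no candidate has a hydrophobic core.
    """
    seq = precursor.residues if isinstance(precursor, Peptide) else precursor
    if len(seq) < 40:
        raise SegmentationError("precursor too short for signal-peptide prediction")
    lo, hi = CLEAVAGE_RANGE
    hi = min(hi, len(seq) - 1)
    best_pos, best_score = None, -1.0
    for pos in range(lo, hi + 1):
        s = _cleavage_score(seq, pos)
        if s > best_score or (
            s == best_score
            and (abs(pos - PREFERRED_SP_LENGTH), pos)
            < (abs(best_pos - PREFERRED_SP_LENGTH), best_pos)
        ):
            best_pos, best_score = pos, s
    # require at least a minimal hydrophobic core to call a signal peptide
    if best_score < 5.0:
        raise SegmentationError("no plausible signal peptide")
    return best_pos


def _map_position(aln_query: str, aln_ref: str, ref_pos: int, snap_toward: str) -> int:
    """Map a 1-based reference position through an alignment onto the query.

    If the query has a gap in the reference position's column, snap to the
    nearest query residue toward the mature region (``snap_toward`` is
    ``"right"`` for the SP end / mature start side and ``"left"`` for the
    mature end side).
    """
    ref_count = 0
    col_of_ref = None
    for col, ch in enumerate(aln_ref):
        if ch != "-":
            ref_count += 1
            if ref_count == ref_pos:
                col_of_ref = col
                break
    if col_of_ref is None:
        raise ValueError("reference position beyond alignment")

    def query_pos_at(col: int) -> int | None:
        if aln_query[col] == "-":
            return None
        return sum(1 for c in range(col + 1) if aln_query[c] != "-")

    qp = query_pos_at(col_of_ref)
    if qp is not None:
        return qp
    cols = range(col_of_ref + 1, len(aln_query)) if snap_toward == "right" else range(col_of_ref - 1, -1, -1)
    for col in cols:
        qp = query_pos_at(col)
        if qp is not None:
            return qp
    raise ValueError("no query residue on the mature side of the boundary")


def segment_by_alignment(precursor: Peptide, reference: Peptide,
                         reference_annotation: PrecursorAnnotation,
                         min_identity: float = 25.0) -> PrecursorAnnotation:
    """Transfer a reference segmentation onto a precursor through global alignment.

    Boundary columns falling in query-gap columns snap to the nearest query
    residue toward the mature region. Alignments below ``min_identity``
    percent identity are refused.
    """
    aln = global_align(precursor, reference)
    if aln.percent_identity < min_identity:
        raise SegmentationError(
            f"reference too distant ({aln.percent_identity:.1f}% identity)"
        )
    ref_sp_end = reference_annotation.sp[1]
    ref_mature_end = reference_annotation.mature[1]
    # the mature start maps rightward (into the mature), the mature end leftward
    mature_start = _map_position(aln.aligned_query, aln.aligned_target, ref_sp_end + 1, "right")
    mature_end = _map_position(aln.aligned_query, aln.aligned_target, ref_mature_end, "left")
    n = len(precursor.residues)
    ctail = (mature_end + 1, n) if mature_end < n else None
    return PrecursorAnnotation(
        precursor.id, (1, mature_start - 1), (mature_start, mature_end), ctail, "by_alignment"
    )


def annotate_precursor(precursor: Peptide, reference: Peptide,
                       reference_annotation: PrecursorAnnotation,
                       sp_method: str = "heuristic") -> PrecursorAnnotation:
    """Full tripartite annotation: heuristic SP call + alignment-mapped C-tail boundary.

    With ``sp_method="by_alignment"`` the SP boundary is also taken from the
    reference alignment.
    """
    by_aln = segment_by_alignment(precursor, reference, reference_annotation)
    if sp_method == "by_alignment":
        return by_aln
    sp_end = predict_signal_cleavage(precursor)
    mature_end = by_aln.mature[1]
    n = len(precursor.residues)
    ctail = (mature_end + 1, n) if mature_end < n else None
    return PrecursorAnnotation(
        precursor.id, (1, sp_end), (sp_end + 1, mature_end), ctail, "heuristic"
    )


def mature_sequence(precursor: Peptide, annotation: PrecursorAnnotation) -> str:
    lo, hi = annotation.mature
    return precursor.residues[lo - 1 : hi]


def annotation_frame(annotations):
    """TSV-ready DataFrame (peptide_id, sp_end, mature_start, mature_end, ctail_start, method)."""
    import pandas as pd

    rows = [
        {
            "peptide_id": a.peptide_id,
            "sp_end": a.sp[1],
            "mature_start": a.mature[0],
            "mature_end": a.mature[1],
            "ctail_start": a.ctail[0] if a.ctail else "",
            "method": a.method,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)
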