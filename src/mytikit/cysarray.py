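"""Cysteine-array detection, classification and disulfide-topology assignment.

Mytilin mature peptides carry eight structural cysteines forming four
disulfide bonds in a C1-C5, C2-C6, C3-C7, C4-C8 pattern. The *canonical*
array has the spacing C1-x3-C2-x3-C3-x(2-5)-C4-x11-C5-x-C6-x(0-2)-C7-x2-C8
(an "x" may itself be a cysteine: several peptides carry extra, non-structural
cysteines inside the array). The *alternative* array keeps the C1-C4 block
and the C6-C8 terminal block but displaces C5 away from its canonical slot,
re-routing the C1-C5 bond; the loop between C1 and C2 may also be longer.
Perna mytilins frequently insert an extra cysteine between C6 and C7,
creating a CCC triplet whose central residue is left without an
intra-molecular partner.

Classification is purely sequence-based: a backtracking search selects the
leftmost 8-cysteine subset compatible with each spacing template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Peptide

# (min_gap, max_gap) of residues strictly between consecutive structural cysteines.
CANONICAL_GAPS = ((3, 3), (3, 3), (2, 5), (11, 11), (1, 1), (0, 2), (2, 2))
# C4->C5 gap deliberately excludes 11-with-C5-x-C6: a subset matching the canonical
# template is always claimed by the canonical search, which runs first.
ALTERNATIVE_GAPS = ((2, 8), (3, 3), (2, 5), (1, 10), (1, 15), (0, 2), (2, 2))

#: Disulfide connectivity over the eight structural cysteines (1-based C-numbering).
DISULFIDE_TOPOLOGY = ((1, 5), (2, 6), (3, 7), (4, 8))


@dataclass(frozen=True)
class CysteineArrayReport:
    peptide_id: str
    cys_positions: tuple[int, ...]  # 1-based residue positions of every cysteine
    n_cys: int
    array_class: str  # canonical | alternative | noncanonical
    has_ccc: bool
    structural_eight: tuple[int, ...]  # indices into cys_positions (0-based), len 8 or 0
    pairs: tuple[tuple[int, int], ...]  # index pairs into cys_positions
    unpaired: tuple[int, ...]  # indices into cys_positions
    c1_c2_loop_len: int
    missing_c8: bool = False


@dataclass(frozen=True)
class DisulfideAssignment:
    """One or more sterically plausible pairings over the structural cysteines."""

    pairings: tuple[tuple[tuple[int, int], ...], ...]
    unpaired: tuple[int, ...]


def _find_subset(positions: tuple[int, ...], gaps, size: int):
    """Leftmost increasing subset of cysteine indices matching the gap template."""
    n = len(positions)

    def extend(chosen: list[int]):
        depth = len(chosen)
        if depth == size:
            return tuple(chosen)
        lo, hi = gaps[depth - 1] if depth > 0 else (None, None)
        start = chosen[-1] + 1 if chosen else 0
        for idx in range(start, n):
            if chosen:
                gap = positions[idx] - positions[chosen[-1]] - 1
                if gap < lo:
                    continue
                if gap > hi:
                    break
            chosen.append(idx)
            hit = extend(chosen)
            if hit is not None:
                return hit
            chosen.pop()
        return None

    return extend([])


def _canonical_pairs(positions, subset, sequence):
    pairs = tuple((subset[a - 1], subset[b - 1]) for a, b in DISULFIDE_TOPOLOGY)
    unpaired = tuple(i for i in range(len(positions)) if i not in subset)
    return pairs, unpaired


def detect_array(mature: Peptide | str, peptide_id: str | None = None) -> CysteineArrayReport:
    """Locate cysteines, classify the array and assign the default topology."""
    if isinstance(mature, Peptide):
        seq, pid = mature.residues, mature.id
    else:
        seq, pid = mature, peptide_id or "peptide"
    if not seq:
        raise ValueError("empty mature sequence")
    positions = tuple(i + 1 for i, aa in enumerate(seq) if aa == "C")
    n_cys = len(positions)
    has_ccc = "CCC" in seq

    if n_cys < 2:
        return CysteineArrayReport(pid, positions, n_cys, "noncanonical", has_ccc,
                                   (), (), tuple(range(n_cys)), 0)

    loop_first_two = positions[1] - positions[0] - 1

    for klass, gaps in (("canonical", CANONICAL_GAPS), ("alternative", ALTERNATIVE_GAPS)):
        subset = _find_subset(positions, gaps, 8)
        if subset is not None:
            pairs, unpaired = _canonical_pairs(positions, subset, seq)
            loop = positions[subset[1]] - positions[subset[0]] - 1
            return CysteineArrayReport(pid, positions, n_cys, klass, has_ccc,
                                       subset, pairs, unpaired, loop)

    # A truncated array missing only the final structural cysteine (seen in one
    # P. viridis peptide) is reported as noncanonical with an explicit flag.
    missing_c8 = _find_subset(positions, CANONICAL_GAPS[:6], 7) is not None
    return CysteineArrayReport(pid, positions, n_cys, "noncanonical", has_ccc,
                               (), (), tuple(range(n_cys)), loop_first_two,
                               missing_c8=missing_c8)


def assign_disulfides(report: CysteineArrayReport) -> DisulfideAssignment:
    """C1-C5 / C2-C6 / C3-C7 / C4-C8 pairing over the structural cysteines.

    Extra cysteines (e.g. the central residue of a CCC triplet) stay unpaired.
    For nine-cysteine alternative arrays where a second free cysteine sits in
    the C4..C6 span, both sterically plausible C5 choices are returned as
    alternative pairings.
    """
    if report.array_class not in ("canonical", "alternative"):
        raise ValueError(f"topology undefined for {report.array_class} array "
                         f"({report.peptide_id})")
    pairings = [report.pairs]
    if report.array_class == "alternative":
        subset = report.structural_eight
        c4_pos = report.cys_positions[subset[3]]
        c6_pos = report.cys_positions[subset[5]]
        for idx in report.unpaired:
            pos = report.cys_positions[idx]
            in_ccc = (pos - 1) in report.cys_positions and (pos + 1) in report.cys_positions
            if c4_pos < pos < c6_pos and idx != subset[4] and not in_ccc:
                alt = tuple(
                    (idx if a == subset[4] else a, idx if b == subset[4] else b)
                    for a, b in report.pairs
                )
                pairings.append(alt)
    return DisulfideAssignment(tuple(pairings), report.unpaired)


def count_ccc(peptides) -> int:
    """Number of peptides whose sequence contains at least one CCC triplet."""
    count = 0
    for pep in peptides:
        seq = pep.residues if isinstance(pep, Peptide) else pep
        if "CCC" in seq:
            count += 1
    return count


def array_report_frame(reports):
    """TSV-ready DataFrame of array reports."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append({
            "peptide_id": r.peptide_id,
            "n_cys": r.n_cys,
            "array_class": r.array_class,
            "has_ccc": r.has_ccc,
            "missing_c8": r.missing_c8,
            "c1_c2_loop_len": r.c1_c2_loop_len,
            "cys_positions": ",".join(map(str, r.cys_positions)),
            "pairs": ";".join(f"{r.cys_positions[a]}-{r.cys_positions[b]}" for a, b in r.pairs),
            "unpaired": ",".join(str(r.cys_positions[i]) for i in r.unpaired),
        })
    return pd.DataFrame(rows)
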