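"""Pairwise and progressive multiple alignment.

Pairwise global (Needleman-Wunsch) and local (Smith-Waterman) alignment with
affine gaps uses BLOSUM62 with gap open 11 / extend 1 — the usual protein
BLAST parameters — via Biopython's PairwiseAligner. The multiple aligner is a
classic progressive scheme: UPGMA guide tree over pairwise global-alignment
distances, then profile-profile merging from the leaves to the root. No
iterative refinement is attempted; at the scale of a few dozen short
peptides the progressive result is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import Peptide

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11  # cost of a length-k gap is GAP_OPEN + k * GAP_EXTEND
GAP_EXTEND = 1

_MATRIX_ALPHABET = str(BLOSUM62.alphabet)


def _seq(x) -> str:
    return x.residues if isinstance(x, Peptide) else str(x)


def _sid(x, default: str) -> str:
    return x.id if isinstance(x, Peptide) else default


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    mode: str  # global | local

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("aligned strings differ in length")

    @property
    def percent_identity(self) -> float:
        """100 * identical columns / aligned columns (gap columns included)."""
        cols = len(self.aligned_query)
        if cols == 0:
            return 0.0
        matches = sum(
            a == b and a != "-"
            for a, b in zip(self.aligned_query, self.aligned_target)
        )
        return 100.0 * matches / cols


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    aligner.mode = mode
    return aligner


def global_align(a, b, query_id: str | None = None, target_id: str | None = None) -> PairwiseAlignment:
    """Optimal affine-gap global alignment (BLOSUM62, open 11 / extend 1)."""
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner("global")
    aln = aligner.align(sa, sb)[0]
    return PairwiseAlignment(
        query_id or _sid(a, "query"),
        target_id or _sid(b, "target"),
        str(aln[0]),
        str(aln[1]),
        float(aln.score),
        "global",
    )


def local_align(a, b, query_id: str | None = None, target_id: str | None = None) -> PairwiseAlignment:
    """Smith-Waterman local alignment; score >= 0, empty alignment if nothing scores positive."""
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner("local")
    qid = query_id or _sid(a, "query")
    tid = target_id or _sid(b, "target")
    score = float(aligner.score(sa, sb))
    if score <= 0:
        return PairwiseAlignment(qid, tid, "", "", 0.0, "local")
    aln = aligner.align(sa, sb)[0]
    return PairwiseAlignment(qid, tid, str(aln[0]), str(aln[1]), float(aln.score), "local")


def local_score(a, b) -> float:
    """Smith-Waterman score only (no traceback); faster inside the screen loop."""
    sa, sb = _seq(a), _seq(b)
    aligner = _make_aligner("local")
    return max(0.0, float(aligner.score(sa, sb)))


def percent_identity(aln: PairwiseAlignment) -> float:
    return aln.percent_identity


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSA:
    """Ordered rows of equal-length gapped sequences."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def as_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.rows))


def _blosum(a: str, b: str) -> float:
    return float(BLOSUM62[a, b])


# Residue-vs-gap pairs inside already-built profiles score as a mild extension
# penalty; gap-gap pairs score zero. New gaps introduced while merging two
# profiles pay the full affine cost.
_PROFILE_GAP_SCORE = -1.0


def _column_score(col_a: Sequence[str], col_b: Sequence[str]) -> float:
    total = 0.0
    n = 0
    for x in col_a:
        for y in col_b:
            n += 1
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                total += _PROFILE_GAP_SCORE
            else:
                total += _blosum(x, y)
    return total / n


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles over column scores."""
    la, lb = len(rows_a[0]), len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(la)]
    cols_b = ["".join(r[j] for r in rows_b) for j in range(lb)]
    score = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            score[i, j] = _column_score(cols_a[i], cols_b[j])

    neg = -np.inf
    open_cost = GAP_OPEN + GAP_EXTEND
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in profile B (consume A column)
    Y = np.full((la + 1, lb + 1), neg)  # gap in profile A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -open_cost - GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -open_cost - GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = score[i - 1, j - 1] + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - GAP_EXTEND)

    # traceback, deterministic preference M > X > Y
    i, j = la, lb
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i, j])
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            prev = {"M": M, "X": X, "Y": Y}
            best = max(("M", "X", "Y"), key=lambda s: prev[s][i - 1, j - 1])
            i, j = i - 1, j - 1
            state = best
        elif state == "X":
            ops.append("X")
            if M[i - 1, j] - open_cost >= X[i - 1, j] - GAP_EXTEND:
                state = "M"
            i -= 1
        else:
            ops.append("Y")
            if M[i, j - 1] - open_cost >= Y[i, j - 1] - GAP_EXTEND:
                state = "M"
            j -= 1
        if i == 0 and j > 0:
            while j > 0:
                ops.append("Y")
                j -= 1
            break
        if j == 0 and i > 0:
            while i > 0:
                ops.append("X")
                i -= 1
            break
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
    return out_a, out_b


def pairwise_distance(a, b) -> float:
    """1 - fractional identity of the global alignment; in [0, 1]."""
    return 1.0 - global_align(a, b).percent_identity / 100.0


def _upgma(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA join order over a distance matrix; ties broken by smallest index pair.

    Returns the merge list; node k >= n is the cluster created by merge k - n.
    """
    n = dist.shape[0]
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int]] = []
    next_id = n
    while len(active) > 1:
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), _ = best
        members = active[i] + active[j]
        sizes = (len(active[i]), len(active[j]))
        del active[i], active[j]
        new_d = {}
        for k in list(active):
            a = d.pop((min(i, k), max(i, k)))
            b = d.pop((min(j, k), max(j, k)))
            new_d[(k, next_id)] = (a * sizes[0] + b * sizes[1]) / sum(sizes)
        d.pop((i, j), None)
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        d.update(new_d)
        active[next_id] = members
        merges.append((i, j))
        next_id += 1
    return merges


def progressive_msa(peptides: Sequence[Peptide]) -> MSA:
    """Progressive multiple alignment over a UPGMA guide tree.

    Deterministic for a fixed input order. A single peptide yields a
    degenerate one-row alignment.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no sequences to align")
    if len(peptides) == 1:
        return MSA((peptides[0].id,), (peptides[0].residues,))

    n = len(peptides)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pairwise_distance(peptides[i], peptides[j])

    merges = _upgma(dist)
    # cluster id -> (member indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [peptides[i].residues]) for i in range(n)
    }
    next_id = n
    for i, j in merges:
        mem_a, rows_a = clusters.pop(i)
        mem_b, rows_b = clusters.pop(j)
        out_a, out_b = _align_profiles(rows_a, rows_b)
        clusters[next_id] = (mem_a + mem_b, out_a + out_b)
        next_id += 1

    members, rows = clusters.popitem()[1]
    order = np.argsort(members, kind="stable")
    ids = tuple(peptides[members[k]].id for k in order)
    out_rows = tuple(rows[k] for k in order)
    return MSA(ids, out_rows)
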