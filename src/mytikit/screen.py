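"""Iterative seed-based mining of mytilin-like precursors from transcripts.

The screen replaces a heuristic translated BLAST search with exhaustive
six-frame translation plus Smith-Waterman. Every complete ATG..stop ORF of at
least ``min_orf_len`` codons is aligned against the current seed list; ORFs
whose best e-value-like statistic clears the threshold AND whose post-signal
region carries a mytilin-classifiable cysteine array join the seed list, and
the search repeats until a pass adds nothing. Accepted hits are finally
compared against the known set: a hit is *novel* when its best percent
identity against every known peptide is strictly below the cutoff (default
95%).

The e-value-like statistic is Karlin-Altschul shaped, ``K * m * n *
exp(-lambda * S)`` with fixed BLOSUM62-flavoured constants (K = 0.041,
lambda = 0.267); it is approximate but monotone in the score, which is all
the acceptance rule needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio.Seq import Seq

from .align import global_align, local_score
from .cysarray import detect_array
from .io_formats import Peptide, TranscriptRecord
from .precursor_model import SegmentationError, predict_signal_cleavage

logger = logging.getLogger(__name__)

KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267
DEFAULT_EVALUE = 1e-3
DEFAULT_NOVELTY_CUTOFF = 95.0
DEFAULT_MIN_ORF_LEN = 60  # amino acids
DEFAULT_MAX_ITER = 20


def evalue_like(score: float, m: int, n: int) -> float:
    """Karlin-Altschul style expectation for a local score S on an m x n search."""
    return KARLIN_K * m * n * math.exp(-KARLIN_LAMBDA * score)


@dataclass(frozen=True)
class OrfCandidate:
    transcript_id: str
    frame: int  # 1..3 forward, -1..-3 reverse
    start: int  # 1-based forward-strand coordinates, stop codon included
    end: int
    protein: str  # translation without the stop


@dataclass(frozen=True)
class ScreenHit:
    transcript_id: str
    frame: int
    orf_start: int
    orf_end: int
    precursor: Peptide
    best_seed_id: str
    local_score: float
    evalue_like: float
    iteration_found: int
    novel: bool | None = None


def six_frame_orfs(transcript: TranscriptRecord, min_len: int = DEFAULT_MIN_ORF_LEN) -> list[OrfCandidate]:
    """All complete ATG..stop ORFs of >= min_len aa on all six frames.

    Reverse-strand ORFs are reported in forward coordinates with a negative
    frame. Nested same-frame ORFs (internal ATGs) are collapsed to the
    longest one.
    """
    seq = transcript.nucleotides
    length = len(seq)
    out: list[OrfCandidate] = []
    for strand in (1, -1):
        s = seq if strand == 1 else str(Seq(seq).reverse_complement())
        for offset in range(3):
            frame = (offset + 1) * strand
            codons = [s[i : i + 3] for i in range(offset, length - 2, 3)]
            i = 0
            while i < len(codons):
                if codons[i] == "ATG":
                    for j in range(i, len(codons)):
                        if codons[j] in ("TAA", "TAG", "TGA"):
                            n_aa = j - i
                            if n_aa >= min_len:
                                prot = str(Seq("".join(codons[i:j])).translate())
                                lo = offset + 3 * i  # 0-based on strand s
                                hi = offset + 3 * (j + 1)  # stop included
                                if strand == 1:
                                    start, end = lo + 1, hi
                                else:
                                    start, end = length - hi + 1, length - lo
                                out.append(OrfCandidate(transcript.id, frame, start, end, prot))
                            i = j  # skip past this stop; collapses nested ATGs
                            break
                    else:
                        break  # no stop downstream: incomplete ORF, drop
                i += 1
    return out


def _mytilin_gate(protein: str) -> bool:
    """Check that the ORF looks like a mytilin precursor at sequence level."""
    try:
        sp_end = predict_signal_cleavage(protein)
    except SegmentationError:
        return False
    report = detect_array(protein[sp_end:], "candidate")
    return report.array_class in ("canonical", "alternative")


def iterative_screen(seeds, transcripts, e_threshold: float = DEFAULT_EVALUE,
                     min_orf_len: int = DEFAULT_MIN_ORF_LEN,
                     max_iter: int = DEFAULT_MAX_ITER,
                     apply_gate: bool = True) -> list[ScreenHit]:
    """Iterate Smith-Waterman screening until no new hit is found.

    Accepted hits are added to the seed list, so remote homologs become
    reachable through intermediates. The accepted set only ever grows;
    termination is guaranteed by ``max_iter`` (a warning is logged if the
    cap is hit).
    """
    seed_list: list[Peptide] = list(seeds)
    if not seed_list:
        raise ValueError("at least one seed is required")
    candidates: list[OrfCandidate] = []
    for tx in transcripts:
        candidates.extend(six_frame_orfs(tx, min_len=min_orf_len))

    hits: list[ScreenHit] = []
    accepted: set[tuple[str, int, int]] = set()
    # best (score, seed id) seen so far per candidate; updated as seeds grow
    best: dict[int, tuple[float, str, int]] = {i: (-1.0, "", 1) for i in range(len(candidates))}
    fresh_seeds = list(seed_list)
    iteration = 0
    while fresh_seeds and iteration < max_iter:
        iteration += 1
        for idx, cand in enumerate(candidates):
            for seed in fresh_seeds:
                s = local_score(seed, cand.protein)
                if s > best[idx][0]:
                    best[idx] = (s, seed.id, len(seed.residues))
        fresh_seeds = []
        for idx, cand in enumerate(candidates):
            key = (cand.transcript_id, cand.start, cand.end)
            if key in accepted:
                continue
            score, seed_id, seed_len = best[idx]
            e = evalue_like(score, seed_len, len(cand.protein))
            if e >= e_threshold:
                continue
            if apply_gate and not _mytilin_gate(cand.protein):
                continue
            pep = Peptide(f"{cand.transcript_id}|{cand.frame}|{cand.start}-{cand.end}",
                          cand.protein, provenance="screened")
            hits.append(ScreenHit(cand.transcript_id, cand.frame, cand.start, cand.end,
                                  pep, seed_id, score, e, iteration))
            accepted.add(key)
            fresh_seeds.append(pep)
    if iteration >= max_iter and fresh_seeds:
        logger.warning("iterative screen stopped at max_iter=%d with hits pending", max_iter)
    return hits


def novelty_filter(hits, known, cutoff: float = DEFAULT_NOVELTY_CUTOFF) -> list[ScreenHit]:
    """Flag hits sharing < cutoff percent identity with every known peptide as novel."""
    known = list(known)
    out = []
    for hit in hits:
        best_pid = 0.0
        for ref in known:
            pid = global_align(hit.precursor, ref).percent_identity
            best_pid = max(best_pid, pid)
        out.append(ScreenHit(hit.transcript_id, hit.frame, hit.orf_start, hit.orf_end,
                             hit.precursor, hit.best_seed_id, hit.local_score,
                             hit.evalue_like, hit.iteration_found,
                             novel=best_pid < cutoff))
    return out


def hits_frame(hits):
    import pandas as pd

    rows = [
        {
            "transcript_id": h.transcript_id,
            "frame": h.frame,
            "orf_start": h.orf_start,
            "orf_end": h.orf_end,
            "best_seed": h.best_seed_id,
            "score": h.local_score,
            "evalue_like": h.evalue_like,
            "novel": h.novel,
            "iteration": h.iteration_found,
        }
        for h in hits
    ]
    return pd.DataFrame(rows)
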