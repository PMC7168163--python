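"""Profile hidden Markov models built from a reduced multiple alignment.

A family-specific profile HMM summarizes a multiple alignment as a chain of
match states (position-specific emission distributions) with insert and
delete states, and scores candidate peptides by their log-odds against an
i.i.d. background. The machinery here is the classic architecture: match
columns are alignment columns with gap fraction below 0.5, sequences get
Henikoff position-based weights, emissions and transitions are count-based
with background-weighted (emissions) and Laplace (transitions) pseudocounts,
and scoring runs the standard Viterbi / forward recursions in log space.

Statistical calibration fits a Gumbel (EVD) to Viterbi scores of random
background sequences by moment matching, giving approximate E-values. Family
screens should be run pairwise (e.g. a mytilin model against a myticin
model) so that hits from a structurally similar sister family are claimed by
the better-fitting model rather than mis-assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import MSA
from .io_formats import Peptide

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Robinson & Robinson amino-acid background frequencies (as used by HMMER).
BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
BACKGROUND /= BACKGROUND.sum()

MATCH_GAP_FRACTION = 0.5
EMISSION_PSEUDOCOUNT = 1.0  # background-weighted strength
TRANSITION_PSEUDOCOUNT = 1.0  # Laplace

_STATES = ("M", "I", "D")
_EULER_GAMMA = 0.5772156649015329


def henikoff_weights(rows: Sequence[str]) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, normalized to sum 1."""
    n = len(rows)
    weights = np.zeros(n)
    ncol = len(rows[0])
    for c in range(ncol):
        col = [row[c] for row in rows]
        symbols = [s for s in col if s != "-"]
        if not symbols:
            continue
        distinct = set(symbols)
        r = len(distinct)
        counts = {s: symbols.count(s) for s in distinct}
        for i, s in enumerate(col):
            if s != "-":
                weights[i] += 1.0 / (r * counts[s])
    if weights.sum() == 0:
        return np.full(n, 1.0 / n)
    return weights / weights.sum()


@dataclass(frozen=True)
class ProfileHMM:
    length: int  # number of match states M
    match_emissions: np.ndarray  # (M, 20) rows summing to 1
    insert_emissions: np.ndarray  # (20,) background row
    transitions: np.ndarray  # (M+1, 3, 3) t[j, from, to] over states (M, I, D)
    background: np.ndarray  # (20,)
    n_training: int
    training_lengths: tuple[int, ...]
    calibration: tuple[float, float] | None = None  # (mu, lambda) of the null Gumbel

    def __post_init__(self) -> None:
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise AssertionError("match emission rows must sum to 1")
        if not np.allclose(self.transitions.sum(axis=2), 1.0, atol=1e-9):
            raise AssertionError("outgoing transition triplets must sum to 1")


def _state_path(row: str, is_match: Sequence[bool]) -> list[str]:
    """Per-row state path through the model (M/D for match columns, I otherwise)."""
    path = []
    for c, symbol in enumerate(row):
        if is_match[c]:
            path.append("M" if symbol != "-" else "D")
        elif symbol != "-":
            path.append("I")
    return path


def build_hmm(msa: MSA, gap_fraction: float = MATCH_GAP_FRACTION,
              emission_pseudocount: float = EMISSION_PSEUDOCOUNT,
              transition_pseudocount: float = TRANSITION_PSEUDOCOUNT) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Match columns are those with gap fraction strictly below ``gap_fraction``;
    an alignment with no such column is rejected.
    """
    rows = list(msa.rows)
    if not rows:
        raise ValueError("empty alignment")
    ncol = msa.n_columns
    nrow = len(rows)
    is_match = [sum(r[c] == "-" for r in rows) / nrow < gap_fraction for c in range(ncol)]
    M = sum(is_match)
    if M == 0:
        raise ValueError("alignment has no match column below the gap-fraction threshold")

    weights = henikoff_weights(rows) if nrow > 1 else np.array([1.0])

    emissions = np.zeros((M, 20))
    match_cols = [c for c in range(ncol) if is_match[c]]
    for m, c in enumerate(match_cols):
        for i, row in enumerate(rows):
            aa = row[c]
            if aa == "-":
                continue
            if aa == "X":  # ambiguity spreads over the background
                emissions[m] += weights[i] * BACKGROUND
            else:
                emissions[m, _AA_INDEX[aa]] += weights[i]
        emissions[m] += emission_pseudocount * BACKGROUND
        emissions[m] /= emissions[m].sum()

    # transition counts over nodes 0..M (node 0 = begin)
    trans = np.zeros((M + 1, 3, 3))
    for i, row in enumerate(rows):
        path = ["M"] + _state_path(row, is_match) + ["M"]  # begin and end act as match
        node = 0
        prev = 0  # index into _STATES
        for step in path[1:]:
            cur = _STATES.index(step)
            trans[node, prev, cur] += weights[i]
            if step != "I":
                node += 1
            prev = cur
    trans += transition_pseudocount / 3.0
    trans /= trans.sum(axis=2, keepdims=True)

    return ProfileHMM(
        length=M,
        match_emissions=emissions,
        insert_emissions=BACKGROUND.copy(),
        transitions=trans,
        background=BACKGROUND.copy(),
        n_training=nrow,
        training_lengths=tuple(len(r.replace("-", "")) for r in rows),
    )


def _log_odds_tables(hmm: ProfileHMM):
    with np.errstate(divide="ignore"):
        em = np.log2(hmm.match_emissions / hmm.background)
        tr = np.log2(hmm.transitions)
    return em, tr


def _score_dp(hmm: ProfileHMM, sequence: str, forward: bool) -> float:
    """Global log-odds DP (bits). ``forward=False`` gives the Viterbi score."""
    seq_idx = []
    for aa in sequence:
        seq_idx.append(_AA_INDEX.get(aa, -1))  # X and unknowns: log-odds 0 emission
    n = len(seq_idx)
    M = hmm.length
    em, tr = _log_odds_tables(hmm)
    neg = -np.inf

    def combine(values):
        if forward:
            m = max(values)
            if m == neg:
                return neg
            return m + math.log2(sum(2.0 ** (v - m) for v in values if v > neg))
        return max(values)

    # V[state][j][i]: best/total log-odds ending at node j having consumed i residues
    VM = np.full((M + 1, n + 1), neg)
    VI = np.full((M + 1, n + 1), neg)
    VD = np.full((M + 1, n + 1), neg)
    VM[0, 0] = 0.0  # begin state

    iM, iI, iD = 0, 1, 2
    for j in range(0, M + 1):
        for i in range(0, n + 1):
            if j > 0:
                if i > 0:
                    e = em[j - 1, seq_idx[i - 1]] if seq_idx[i - 1] >= 0 else 0.0
                    VM[j, i] = e + combine((
                        VM[j - 1, i - 1] + tr[j - 1, iM, iM],
                        VI[j - 1, i - 1] + tr[j - 1, iI, iM],
                        VD[j - 1, i - 1] + tr[j - 1, iD, iM],
                    ))
                VD[j, i] = combine((
                    VM[j - 1, i] + tr[j - 1, iM, iD],
                    VI[j - 1, i] + tr[j - 1, iI, iD],
                    VD[j - 1, i] + tr[j - 1, iD, iD],
                ))
            if i > 0 and j <= M:
                VI[j, i] = combine((  # insert emissions at background: log-odds 0
                    VM[j, i - 1] + tr[j, iM, iI],
                    VI[j, i - 1] + tr[j, iI, iI],
                    VD[j, i - 1] + tr[j, iD, iI],
                ))
    # exit into the end state (modelled as the M-transition out of node M)
    final = combine((
        VM[M, n] + tr[M, iM, iM],
        VI[M, n] + tr[M, iI, iM],
        VD[M, n] + tr[M, iD, iM],
    ))
    return float(final)


def score(hmm: ProfileHMM, peptide: Peptide | str, algorithm: str = "viterbi") -> float:
    """Log-odds bit score of a sequence under the model (global alignment mode)."""
    seq = peptide.residues if isinstance(peptide, Peptide) else peptide
    if algorithm == "viterbi":
        return _score_dp(hmm, seq, forward=False)
    if algorithm == "forward":
        return _score_dp(hmm, seq, forward=True)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def calibrate(hmm: ProfileHMM, n_null: int = 1000, seed: int = 0) -> ProfileHMM:
    """Fit a Gumbel to Viterbi scores of random background sequences.

    Null sequences are drawn i.i.d. from the background composition with
    lengths resampled from the training lengths. The scale comes from moment
    matching, ``lambda = pi / (sqrt(6) * sd)``; the location is anchored at
    the empirical null median (``mu = median + ln(ln 2) / lambda``) so that
    the fitted survival function is exactly centred: the median null score
    maps to P = 0.5 by construction, which keeps E-values honest near the
    decision region even though the true null is only approximately Gumbel.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.choice(hmm.training_lengths, size=n_null)
    scores = np.empty(n_null)
    aa = np.array(list(AMINO_ACIDS))
    for k in range(n_null):
        seq = "".join(rng.choice(aa, size=int(lengths[k]), p=hmm.background))
        scores[k] = _score_dp(hmm, seq, forward=False)
    sd = scores.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate null score variance")
    lam = math.pi / (math.sqrt(6.0) * sd)
    mu = float(np.median(scores)) + math.log(math.log(2.0)) / lam
    return ProfileHMM(
        length=hmm.length,
        match_emissions=hmm.match_emissions,
        insert_emissions=hmm.insert_emissions,
        transitions=hmm.transitions,
        background=hmm.background,
        n_training=hmm.n_training,
        training_lengths=hmm.training_lengths,
        calibration=(float(mu), float(lam)),
    )


def e_value(hmm: ProfileHMM, bit_score: float, n_db: int = 1) -> float:
    """Expected number of >= bit_score null hits in a database of n_db sequences."""
    if hmm.calibration is None:
        raise ValueError("model is not calibrated")
    mu, lam = hmm.calibration
    p = 1.0 - math.exp(-math.exp(-lam * (bit_score - mu)))
    return n_db * p


@dataclass(frozen=True)
class HmmHit:
    peptide_id: str
    bit_score: float
    e_value: float
    best_model: str  # mytilin | myticin | none


def dual_screen(peptides: Iterable[Peptide], mytilin_hmm: ProfileHMM,
                myticin_hmm: ProfileHMM, e_threshold: float = 0.05,
                model_names: tuple[str, str] = ("mytilin", "myticin")) -> list[HmmHit]:
    """Score every peptide against two family models and keep the better claim.

    A peptide is labelled by the model giving the lower E-value among those
    below the threshold, and ``none`` if neither model is significant.
    """
    peptides = list(peptides)
    n_db = max(len(peptides), 1)
    hits = []
    for pep in peptides:
        s_a = score(mytilin_hmm, pep)
        s_b = score(myticin_hmm, pep)
        e_a = e_value(mytilin_hmm, s_a, n_db)
        e_b = e_value(myticin_hmm, s_b, n_db)
        if e_a >= e_threshold and e_b >= e_threshold:
            best, s, e = "none", s_a, e_a
        elif e_a <= e_b:
            best, s, e = model_names[0], s_a, e_a
        else:
            best, s, e = model_names[1], s_b, e_b
        hits.append(HmmHit(pep.id, float(s), float(e), best))
    return hits


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------


def save_hmm(hmm: ProfileHMM, path) -> None:
    """Write the model as a simple line-oriented text format."""
    with open(path, "w") as fh:
        fh.write(f"MYTIKIT-HMM 1\nM {hmm.length}\nALPHABET {AMINO_ACIDS}\n")
        fh.write(f"NTRAIN {hmm.n_training}\n")
        fh.write("TRAINLEN " + " ".join(map(str, hmm.training_lengths)) + "\n")
        if hmm.calibration:
            fh.write(f"CALIBRATION {hmm.calibration[0]:.10g} {hmm.calibration[1]:.10g}\n")
        fh.write("BACKGROUND " + " ".join(f"{x:.10g}" for x in hmm.background) + "\n")
        for m in range(hmm.length):
            fh.write(f"MATCH {m + 1} " + " ".join(f"{x:.10g}" for x in hmm.match_emissions[m]) + "\n")
        for j in range(hmm.length + 1):
            flat = hmm.transitions[j].reshape(-1)
            fh.write(f"TRANS {j} " + " ".join(f"{x:.10g}" for x in flat) + "\n")


def load_hmm(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("MYTIKIT-HMM"):
        raise ValueError("not a mytikit HMM file")
    meta: dict[str, str] = {}
    match_rows: dict[int, np.ndarray] = {}
    trans_rows: dict[int, np.ndarray] = {}
    for ln in lines[1:]:
        key, _, rest = ln.partition(" ")
        if key == "MATCH":
            idx, _, vals = rest.partition(" ")
            match_rows[int(idx) - 1] = np.array(vals.split(), dtype=float)
        elif key == "TRANS":
            idx, _, vals = rest.partition(" ")
            trans_rows[int(idx)] = np.array(vals.split(), dtype=float).reshape(3, 3)
        else:
            meta[key] = rest
    M = int(meta["M"])
    emissions = np.vstack([match_rows[m] for m in range(M)])
    transitions = np.stack([trans_rows[j] for j in range(M + 1)])
    calibration = None
    if "CALIBRATION" in meta:
        mu, lam = map(float, meta["CALIBRATION"].split())
        calibration = (mu, lam)
    return ProfileHMM(
        length=M,
        match_emissions=emissions,
        insert_emissions=np.array(meta["BACKGROUND"].split(), dtype=float),
        transitions=transitions,
        background=np.array(meta["BACKGROUND"].split(), dtype=float),
        n_training=int(meta["NTRAIN"]),
        training_lengths=tuple(int(x) for x in meta["TRAINLEN"].split()),
        calibration=calibration,
    )
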