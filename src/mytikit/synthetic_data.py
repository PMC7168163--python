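"""Synthetic precursors, decoys and transcript corpora.

The generator emulates the tripartite mytilin precursor: a ~20 aa signal
peptide with a hydrophobic core and small residues at the -3/-1 cleavage
positions, a 33-38 aa cysteine-rich cationic mature region built on an exact
cysteine-array template (canonical, alternative or CCC-bearing), and an
anionic C-terminal extension. Mature net charges default to the +4..+10
range and C-tail charges to -8..-3, mirroring the published family
statistics. Decoys are residue shuffles or peptides built on distinct
(myticin-like / defensin-like) cysteine spacings; transcripts embed
back-translated precursors between UTRs on either strand.

Everything is driven by a single integer seed: the same seed yields
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import Peptide, TranscriptRecord
from .physchem import net_charge
from .precursor_model import PrecursorAnnotation

# Residues strictly between consecutive structural cysteines, per array kind.
ARRAY_TEMPLATES = {
    "canonical": (3, 3, 4, 11, 1, 1, 2),
    "alternative": (2, 3, 4, 4, 8, 1, 2),
    "ccc": (3, 3, 4, 11, 1, 0, 0, 2),  # extra cysteine between C6 and C7
    # decoy families: the C2-C3 spacing differs from the mytilin value (3),
    # so neither mytilin template can ever match
    "myticin_like": (4, 2, 6, 9, 2, 2, 3),
    "defensin_like": (5, 2, 4, 6, 1, 3, 2),
}

MYTILIN_KINDS = ("canonical", "alternative", "ccc")

# A and V are omitted from the signal-peptide interior: they also belong to the
# small-residue cleavage sets, and scattering them through the core would create
# spurious cleavage candidates.
_SP_HYDROPHOBIC = "ILFMW"
_MATURE_FILLER = "RKYSGNTHVAFW"  # cationic-leaning background for the mature region
_MATURE_FILLER_P = np.array([0.16, 0.14, 0.12, 0.10, 0.08, 0.08, 0.06, 0.06, 0.06, 0.06, 0.04, 0.04])
_CTAIL_FILLER = "DESGNTAQ"  # anionic-leaning background for the C-terminal extension
_CTAIL_FILLER_P = np.array([0.24, 0.20, 0.14, 0.12, 0.10, 0.08, 0.06, 0.06])
_NEUTRAL = "SGNTQ"

#: Fixed most-frequent-codon back-translation table (standard genetic code).
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
STOP_CODON = "TAA"


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_mytilins: int = 30
    n_decoys: int = 60
    sp_length: int = 20
    mature_length: tuple[int, int] = (33, 38)
    target_mature_charge: tuple[int, int] = (4, 10)
    target_ctail_charge: tuple[int, int] = (-8, -3)
    ctail_length: int = 25
    n_transcripts: int = 20
    utr_length: int = 100
    reverse_fraction: float = 0.3
    array_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # canonical, alternative, ccc


def _skeleton_length(array_kind: str) -> int:
    gaps = ARRAY_TEMPLATES[array_kind]
    return (len(gaps) + 1) + sum(gaps)


def _adjust_charge(residues: list[str], mutable: list[int], target: int,
                   rng: np.random.Generator) -> None:
    """Deterministically retune filler residues until the net charge matches."""
    order = list(rng.permutation(mutable))
    for _ in range(2 * len(residues)):
        current = net_charge("".join(residues))
        if current == target:
            return
        if current < target:
            for idx in order:  # promote a non-basic filler to K/R
                if residues[idx] not in "KRC":
                    residues[idx] = "K" if rng.random() < 0.5 else "R"
                    break
            else:
                raise ValueError("charge target infeasible: no promotable position")
        else:
            demotable = [i for i in order if residues[i] in "KR"]
            if demotable:  # neutralize a basic filler before adding acidics
                residues[demotable[0]] = str(rng.choice(list(_NEUTRAL)))
            else:
                for idx in order:
                    if residues[idx] not in "DEC":
                        residues[idx] = "D" if rng.random() < 0.5 else "E"
                        break
                else:
                    raise ValueError("charge target infeasible")
    if net_charge("".join(residues)) != target:
        raise ValueError("charge target infeasible for this length")


def make_mature(rng: np.random.Generator, array_kind: str, length: int, charge: int) -> str:
    """A mature peptide matching the requested cysteine-array template exactly."""
    if array_kind not in ARRAY_TEMPLATES:
        raise ValueError(f"unknown array kind {array_kind!r}")
    skeleton = _skeleton_length(array_kind)
    lead = length - skeleton
    if lead < 0:
        raise ValueError(f"mature length {length} too short for the {array_kind} template")
    residues: list[str] = []
    mutable: list[int] = []

    def filler() -> str:
        return str(rng.choice(list(_MATURE_FILLER), p=_MATURE_FILLER_P))

    for _ in range(lead):
        mutable.append(len(residues))
        residues.append(filler())
    gaps = ARRAY_TEMPLATES[array_kind]
    residues.append("C")
    for gap in gaps:
        for _ in range(gap):
            mutable.append(len(residues))
            residues.append(filler())
        residues.append("C")
    _adjust_charge(residues, mutable, charge, rng)
    return "".join(residues)


def make_signal_peptide(rng: np.random.Generator, sp_length: int = 20) -> str:
    """Hydrophobic-core signal peptide with small residues at the -3/-1 positions."""
    if sp_length < 12:
        raise ValueError("signal peptide too short")
    sp = ["M", "K", "N"]
    while len(sp) < sp_length - 3:
        sp.append(str(rng.choice(list(_SP_HYDROPHOBIC))))
    # V sits in the -3 small-residue set but not the -1 set, so it anchors the
    # cleavage site without creating a decoy site two positions upstream
    sp.append("V")  # -3 position
    sp.append(str(rng.choice(list(_SP_HYDROPHOBIC))))
    sp.append("A")  # -1 position
    return "".join(sp)


def make_ctail(rng: np.random.Generator, length: int, charge: int) -> str:
    residues = [str(rng.choice(list(_CTAIL_FILLER), p=_CTAIL_FILLER_P)) for _ in range(length)]
    _adjust_charge(residues, list(range(length)), charge, rng)
    return "".join(residues)


def make_precursor(config: SyntheticConfig, array_kind: str,
                   mature_charge: int, ctail_charge: int,
                   rng: np.random.Generator, peptide_id: str,
                   mature_length: int | None = None) -> tuple[Peptide, PrecursorAnnotation]:
    """A full tripartite precursor plus its true segmentation."""
    if mature_length is None:
        lo, hi = config.mature_length
        mature_length = int(rng.integers(lo, hi + 1))
    sp = make_signal_peptide(rng, config.sp_length)
    mature = make_mature(rng, array_kind, mature_length, mature_charge)
    ctail = make_ctail(rng, config.ctail_length, ctail_charge)
    residues = sp + mature + ctail
    annotation = PrecursorAnnotation(
        peptide_id,
        (1, len(sp)),
        (len(sp) + 1, len(sp) + len(mature)),
        (len(sp) + len(mature) + 1, len(residues)),
        "given",
    )
    return Peptide(peptide_id, residues, provenance="synthetic"), annotation


def make_decoy(config: SyntheticConfig, kind: str, rng: np.random.Generator,
               peptide_id: str, source: Peptide | None = None) -> Peptide:
    """A non-mytilin peptide: a residue shuffle or a distinct cysteine spacing."""
    if kind == "shuffled":
        if source is None:
            raise ValueError("shuffled decoys need a source peptide")
        residues = list(source.residues)
        rng.shuffle(residues)
        return Peptide(peptide_id, "".join(residues), provenance="synthetic")
    if kind in ("myticin_like", "defensin_like"):
        length = _skeleton_length(kind) + int(rng.integers(1, 4))
        charge = int(rng.integers(3, 8))
        return Peptide(peptide_id, make_mature(rng, kind, length, charge),
                       provenance="synthetic")
    raise ValueError(f"unknown decoy kind {kind!r}")


def make_mytilin_cohort(config: SyntheticConfig, prefix: str = "syn_mytilin"):
    """n_mytilins precursors with the configured array mix; returns (peptides, annotations)."""
    rng = np.random.default_rng(config.seed)
    kinds = rng.choice(len(MYTILIN_KINDS), size=config.n_mytilins, p=np.array(config.array_mix))
    peptides, annotations = [], []
    for i in range(config.n_mytilins):
        mc = int(rng.integers(config.target_mature_charge[0], config.target_mature_charge[1] + 1))
        cc = int(rng.integers(config.target_ctail_charge[0], config.target_ctail_charge[1] + 1))
        pep, ann = make_precursor(config, MYTILIN_KINDS[kinds[i]], mc, cc, rng, f"{prefix}_{i:03d}")
        peptides.append(pep)
        annotations.append(ann)
    return peptides, annotations


def make_decoy_set(config: SyntheticConfig, sources, prefix: str = "syn_decoy"):
    """n_decoys decoys: equal thirds shuffled / myticin-like / defensin-like."""
    rng = np.random.default_rng(config.seed + 1)
    sources = list(sources)
    decoys = []
    kinds = ["shuffled", "myticin_like", "defensin_like"]
    for i in range(config.n_decoys):
        kind = kinds[i % 3]
        source = sources[i % len(sources)] if kind == "shuffled" else None
        decoys.append(make_decoy(config, kind, rng, f"{prefix}_{kind}_{i:03d}", source))
    return decoys


def make_mature_family(seed: int, kind: str, n: int, length: int | None = None,
                       charge: int = 7, mutation_rate: float = 0.2,
                       prefix: str | None = None) -> list[Peptide]:
    """A homologous family of mature peptides on one cysteine-array template.

    An ancestor is drawn and members mutate its non-cysteine positions at
    ``mutation_rate`` within the mature filler alphabet; used to train and
    test family-specific profile models (including decoy families).
    """
    rng = np.random.default_rng(seed)
    if length is None:
        length = _skeleton_length(kind) + 1
    ancestor = make_mature(rng, kind, length, charge)
    prefix = prefix or f"{kind}_fam"
    members = []
    for i in range(n):
        residues = list(ancestor)
        for idx in range(len(residues)):
            if residues[idx] != "C" and rng.random() < mutation_rate:
                pool = [aa for aa in _MATURE_FILLER if aa != residues[idx]]
                residues[idx] = str(rng.choice(pool))
        members.append(Peptide(f"{prefix}_{i:03d}", "".join(residues), provenance="synthetic"))
    return members


def make_family_cohort(config: SyntheticConfig, prefix: str = "fam",
                       mutation_rate: float = 0.2):
    """An ancestor precursor plus n_mytilins derived members (one family).

    Members mutate non-structural positions at ``mutation_rate`` within the
    region-appropriate alphabets (hydrophobic core, mature filler, C-tail
    filler), so the family stays alignable (~80% identity) the way real
    mytilin paralogs are. Returns (ancestor, ancestor_annotation, members,
    member_annotations); member segmentations equal the ancestor's since
    lengths are preserved.
    """
    rng = np.random.default_rng(config.seed)
    ancestor, anc_ann = make_precursor(config, "canonical", 8, -6, rng, f"{prefix}_ancestor")
    sp_end = anc_ann.sp[1]
    mature_lo, mature_hi = anc_ann.mature
    protected = {0, 1, 2, sp_end - 3, sp_end - 1, mature_lo - 1}
    members, annotations = [], []
    for i in range(config.n_mytilins):
        residues = list(ancestor.residues)
        for idx in range(len(residues)):
            if idx in protected or residues[idx] == "C":
                continue
            if rng.random() >= mutation_rate:
                continue
            if idx < sp_end:
                pool = [aa for aa in _SP_HYDROPHOBIC if aa != residues[idx]]
            elif idx < mature_hi:
                pool = [aa for aa in _MATURE_FILLER if aa != residues[idx]]
            else:
                pool = [aa for aa in _CTAIL_FILLER if aa != residues[idx]]
            residues[idx] = str(rng.choice(pool))
        pep = Peptide(f"{prefix}_{i:03d}", "".join(residues), provenance="synthetic")
        members.append(pep)
        annotations.append(replace(anc_ann, peptide_id=pep.id))
    return ancestor, anc_ann, members, annotations


# ---------------------------------------------------------------------------
# Transcript corpora
# ---------------------------------------------------------------------------


def back_translate(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein) + STOP_CODON


def _random_utr(rng: np.random.Generator, length: int) -> str:
    utr = "".join(rng.choice(list("ACGT"), size=length))
    # remove start codons so no upstream ORF can engulf the embedded one
    while "ATG" in utr:
        utr = utr.replace("ATG", "ACG")
    return utr


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def make_transcripts(config: SyntheticConfig, precursors,
                     rng: np.random.Generator | None = None,
                     prefix: str = "syn_tx") -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Embed back-translated precursors in UTR-flanked transcripts.

    A ``reverse_fraction`` of the precursors goes in on the reverse strand.
    Returns the transcripts plus a truth table (transcript_id, peptide_id,
    strand, frame, orf_start, orf_end; coordinates 1-based on the forward
    strand, stop codon included).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    precursors = list(precursors)
    if config.n_transcripts < len(precursors):
        raise ValueError("need at least one transcript per embedded precursor")
    transcripts: list[TranscriptRecord] = []
    truth_rows = []
    for i in range(config.n_transcripts):
        tx_id = f"{prefix}_{i:03d}"
        if i < len(precursors):
            pep = precursors[i]
            orf = back_translate(pep.residues)
            utr5 = _random_utr(rng, config.utr_length)
            utr3 = _random_utr(rng, config.utr_length)
            cassette = utr5 + orf + utr3
            reverse = bool(rng.random() < config.reverse_fraction)
            seq = _revcomp(cassette) if reverse else cassette
            if reverse:
                start = len(seq) - (len(utr5) + len(orf)) + 1
                end = len(seq) - len(utr5)
                frame = -(((len(seq) - end) % 3) + 1)
            else:
                start = len(utr5) + 1
                end = len(utr5) + len(orf)
                frame = ((start - 1) % 3) + 1
            truth_rows.append({
                "transcript_id": tx_id, "peptide_id": pep.id,
                "strand": "-" if reverse else "+", "frame": frame,
                "orf_start": start, "orf_end": end,
            })
            transcripts.append(TranscriptRecord(tx_id, seq))
        else:
            length = 2 * config.utr_length + 300
            transcripts.append(TranscriptRecord(tx_id, "".join(rng.choice(list("ACGT"), size=length))))
    truth = pd.DataFrame(truth_rows,
                         columns=["transcript_id", "peptide_id", "strand", "frame",
                                  "orf_start", "orf_end"])
    return transcripts, truth


# ---------------------------------------------------------------------------
# Chained-divergence corpus for the iterative screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainedCorpus:
    """A corpus where remote homologs are reachable only through intermediates.

    ``e_threshold`` is part of the construction: link divergence is chosen so
    that each parent-child pair is significant at this threshold while the
    seed-to-remote pairs are not.
    """

    seed_peptides: list[Peptide]
    seed_annotations: list[PrecursorAnnotation]
    transcripts: list[TranscriptRecord]
    truth: pd.DataFrame
    embedded_ids: tuple[str, ...]  # all mytilin precursors hidden in the corpus
    close_ids: tuple[str, ...]
    remote_ids: tuple[str, ...]
    e_threshold: float


_SP_LINK_MUTATION_RATE = 0.6


def _dissimilar_residue(original: str, rng: np.random.Generator) -> str:
    """A non-cysteine residue scoring <= -2 (fallback -1) against the original."""
    from .align import BLOSUM62

    for cutoff in (-2.0, -1.0):
        pool = [aa for aa in "ADEFGHIKLMNPQRSTVWY"
                if aa != original and float(BLOSUM62[original, aa]) <= cutoff]
        if pool:
            return str(rng.choice(pool))
    raise AssertionError("no dissimilar residue found")  # unreachable for BLOSUM62


def _chain_child(pep: Peptide, annotation: PrecursorAnnotation,
                 rng: np.random.Generator, new_id: str, half: str) -> Peptide:
    """Derive a homolog sharing one intact contiguous filler block with its parent.

    ``half="first"`` scrambles the first half of the mature filler positions
    (keeping the second mature half and the whole C-tail intact);
    ``half="second"`` scrambles the complement. Scrambled positions take
    BLOSUM62-dissimilar residues so they align as noise. The signal-peptide
    core is remixed within the hydrophobic alphabet; cysteines, the mature
    lead residue and the cleavage anchors are preserved, so the child still
    passes the signal-peptide and cysteine-array gates.
    """
    residues = list(pep.residues)
    sp_end = annotation.sp[1]
    mature_lo, mature_hi = annotation.mature  # 1-based inclusive
    mature_fillers = [
        idx for idx in range(mature_lo, mature_hi)  # 0-based: skips the lead residue
        if residues[idx] != "C"
    ]
    tail = list(range(mature_hi, len(residues)))
    mid = len(mature_fillers) // 2
    if half == "first":
        selected = mature_fillers[:mid]
    else:
        selected = mature_fillers[mid:] + tail
    for idx in selected:
        residues[idx] = _dissimilar_residue(residues[idx], rng)
    protected_sp = {0, 1, 2, sp_end - 3, sp_end - 1}
    for idx in range(3, sp_end):
        if idx in protected_sp:
            continue
        if rng.random() < _SP_LINK_MUTATION_RATE:
            choices = [aa for aa in _SP_HYDROPHOBIC if aa != residues[idx]]
            residues[idx] = str(rng.choice(choices))
    return Peptide(new_id, "".join(residues), provenance="synthetic")


def make_chained_corpus(seed: int = 0, n_close: int = 5, n_remote: int = 3,
                        n_decoy_orfs: int = 4, n_empty: int = 5) -> ChainedCorpus:
    """Seed + close homologs + remotes derived from the close ones.

    Seed -> close scrambles the first filler half; close -> remote scrambles
    the second. Parent and child therefore always share one intact half (a
    strongly significant local alignment), while seed and remote share
    neither, leaving only the conserved cysteine/anchor floor — far above the
    bundled e-value threshold (1e-12). Remotes are thus reachable only once
    the close homologs have joined the seed list.
    """
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(seed=seed, sp_length=20, ctail_length=25)
    seed_pep, seed_ann = make_precursor(config, "canonical", 9, -6, rng, "chain_seed")

    embedded: list[Peptide] = []
    annotations: dict[str, PrecursorAnnotation] = {}
    close_ids, remote_ids = [], []
    closes = []
    for i in range(n_close):
        close = _chain_child(seed_pep, seed_ann, rng, f"chain_close_{i}", "first")
        closes.append(close)
        embedded.append(close)
        annotations[close.id] = replace(seed_ann, peptide_id=close.id)
        close_ids.append(close.id)
    for i in range(n_remote):
        parent = closes[i % len(closes)]
        remote = _chain_child(parent, seed_ann, rng, f"chain_remote_{i}", "second")
        embedded.append(remote)
        annotations[remote.id] = replace(seed_ann, peptide_id=remote.id)
        remote_ids.append(remote.id)

    decoys = []
    for i in range(n_decoy_orfs):
        kind = ("myticin_like", "defensin_like")[i % 2]
        mature = make_decoy(config, kind, rng, f"chain_decoy_{i}")
        sp = make_signal_peptide(rng, config.sp_length)
        tail = make_ctail(rng, config.ctail_length, -4)
        decoys.append(Peptide(f"chain_decoy_{i}", sp + mature.residues + tail,
                              provenance="synthetic"))

    all_embedded = embedded + decoys
    tx_config = replace(config, n_transcripts=len(all_embedded) + n_empty)
    transcripts, truth = make_transcripts(tx_config, all_embedded, rng=rng, prefix="chain_tx")
    return ChainedCorpus(
        seed_peptides=[seed_pep],
        seed_annotations=[seed_ann],
        transcripts=transcripts,
        truth=truth,
        embedded_ids=tuple(p.id for p in embedded),
        close_ids=tuple(close_ids),
        remote_ids=tuple(remote_ids),
        e_threshold=1e-12,
    )


def make_two_family_cohort(seed: int = 0, n_per_family: int = 6):
    """Two diverged mature-peptide families (for clade-separation checks).

    One family uses the canonical template, the other the CCC template; family
    members are light (15%) mutations of a family ancestor, so within-family
    distances are far below between-family distances.
    """
    rng = np.random.default_rng(seed)
    families = {}
    for name, kind in (("famA", "canonical"), ("famB", "ccc")):
        ancestor = make_mature(rng, kind, 34, 7)
        members = []
        for i in range(n_per_family):
            residues = list(ancestor)
            for idx in range(len(residues)):
                if residues[idx] != "C" and rng.random() < 0.15:
                    choices = [aa for aa in _MATURE_FILLER if aa != residues[idx]]
                    residues[idx] = str(rng.choice(choices))
            members.append(Peptide(f"{name}_{i}", "".join(residues), provenance="synthetic"))
        families[name] = members
    return families
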