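"""End-to-end workflow: screen, annotate, profile, reduce, model, tree.

``run_pipeline`` wires the stages together in the order a discovery study
runs them: mine transcripts with the iterative screen, segment accepted
precursors, profile their charge structure, classify cysteine arrays, reduce
redundancy, build and calibrate the family HMM, and emit an NJ tree. With no
input paths it generates a self-contained synthetic corpus from the run seed,
which makes the demo run fully reproducible offline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .align import progressive_msa
from .cysarray import array_report_frame, detect_array
from .io_formats import Peptide, read_fasta, write_fasta, write_newick, write_tsv_report
from .physchem import profile_frame, sliding_pi_profile
from .phylo import msa_distance_matrix, neighbor_joining
from .precursor_model import annotate_precursor, annotation_frame, mature_sequence
from .profile_hmm import build_hmm, calibrate, save_hmm
from .redundancy import reduce_peptides, reduction_frame
from .screen import iterative_screen, novelty_filter
from .synthetic_data import SyntheticConfig, make_family_cohort, make_transcripts

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    seeds_path: str | None = None  # protein FASTA of seed precursors
    transcripts_path: str | None = None  # nucleotide FASTA search space
    out_dir: str = "mytikit_run"
    redundancy_threshold: float = 0.1
    screen_evalue: float = 1e-3
    hmm_evalue: float = 0.05
    novelty_cutoff: float = 95.0
    pi_window: int = 15
    n_null: int = 300  # HMM calibration sample size

    def validate(self) -> None:
        for name in ("redundancy_threshold", "screen_evalue", "hmm_evalue", "novelty_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pi_window < 1:
            raise ValueError("pi_window must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _demo_inputs(config: RunConfig):
    """Synthetic seed + corpus when no input files are given."""
    syn = SyntheticConfig(seed=config.seed, n_mytilins=8, n_transcripts=12)
    ancestor, anc_ann, members, _ = make_family_cohort(syn, prefix="demo")
    transcripts, _ = make_transcripts(syn, members)
    return [ancestor], [anc_ann], transcripts


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the artifact set; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.seeds_path and config.transcripts_path:
        seeds = read_fasta(config.seeds_path, kind="peptide", provenance="fixture")
        transcripts = read_fasta(config.transcripts_path, kind="transcript")
        seed_annotations = None
    else:
        seeds, seed_annotations, transcripts = _demo_inputs(config)

    stage = "screen"
    try:
        hits = iterative_screen(seeds, transcripts, e_threshold=config.screen_evalue)
        hits = novelty_filter(hits, seeds, cutoff=config.novelty_cutoff)
        precursors = [h.precursor for h in hits]
        write_fasta(precursors, out / "hits.fasta")
        from .screen import hits_frame

        write_tsv_report(hits_frame(hits), out / "hits.tsv")

        stage = "annotate"
        if seed_annotations is None:
            from .precursor_model import PrecursorAnnotation, predict_signal_cleavage

            sp_end = predict_signal_cleavage(seeds[0])
            n = len(seeds[0].residues)
            mature_end = min(sp_end + 34, n - 1)
            seed_annotations = [PrecursorAnnotation(
                seeds[0].id, (1, sp_end), (sp_end + 1, mature_end), (mature_end + 1, n), "given"
            )]
        reference, reference_ann = seeds[0], seed_annotations[0]
        annotations = [
            annotate_precursor(p, reference, reference_ann) for p in precursors
        ]
        write_tsv_report(annotation_frame(annotations), out / "annotations.tsv")

        stage = "physchem"
        profiles = [sliding_pi_profile(p, window=config.pi_window) for p in precursors]
        write_tsv_report(profile_frame(profiles), out / "physchem.tsv")

        stage = "cysarray"
        matures = [
            Peptide(p.id, mature_sequence(p, a), provenance=p.provenance)
            for p, a in zip(precursors, annotations)
        ]
        reports = [detect_array(m) for m in matures]
        write_tsv_report(array_report_frame(reports), out / "cysarray.tsv")

        stage = "reduce"
        retained, removals = reduce_peptides(matures, threshold=config.redundancy_threshold)
        write_tsv_report(
            reduction_frame(matures, [p.id for p in retained], removals), out / "reduced.tsv"
        )

        stage = "hmm"
        model_peptides = retained if len(retained) >= 2 else matures
        msa = progressive_msa(model_peptides)
        hmm = calibrate(build_hmm(msa), n_null=config.n_null, seed=config.seed)
        save_hmm(hmm, out / "mytilin.hmm")

        stage = "tree"
        if len(matures) >= 3:
            full_msa = progressive_msa(matures)
            ids, dist = msa_distance_matrix(full_msa)
            tree = neighbor_joining(ids, dist)
            write_newick(tree, out / "tree.nwk")
        else:
            (out / "tree.nwk").write_text(";\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "mytikit_version": __version__,
        "config": asdict(config),
        "n_seeds": len(seeds),
        "n_transcripts": len(transcripts),
        "n_hits": len(hits),
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d hits, artifacts in %s", len(hits), out)
    return out
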