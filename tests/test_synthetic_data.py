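import collections
import re

import numpy as np
import pytest
from Bio.Seq import Seq

from mytikit.cysarray import detect_array
from mytikit.io_formats import write_fasta
from mytikit.physchem import net_charge
from mytikit.synthetic_data import (
    ARRAY_TEMPLATES,
    SyntheticConfig,
    make_chained_corpus,
    make_decoy,
    make_decoy_set,
    make_family_cohort,
    make_mature,
    make_mytilin_cohort,
    make_precursor,
    make_transcripts,
)

CANONICAL_RE = re.compile(r"C.{3}C.{3}C.{4}C.{11}C.C.C.{2}C")


class TestMature:
    def test_canonical_matches_motif(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = make_mature(rng, "canonical", 34, 9)
            assert CANONICAL_RE.search(m)
            assert net_charge(m) == 9

    def test_ccc_template_has_triplet_and_nine_cysteines(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = make_mature(rng, "ccc", 34, 5)
            assert "CCC" in m
            assert m.count("C") == 9

    def test_charge_hit_by_construction(self):
        rng = np.random.default_rng(2)
        for target in (-3, 0, 4, 9):
            assert net_charge(make_mature(rng, "canonical", 36, target)) == target

    def test_too_short_for_template_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="too short"):
            make_mature(rng, "canonical", 30, 5)

    def test_infeasible_charge_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="infeasible"):
            make_mature(rng, "canonical", 33, 30)  # more charge than filler slots


class TestDecoys:
    def test_shuffle_preserves_composition(self):
        config = SyntheticConfig(seed=5)
        rng = np.random.default_rng(5)
        source, _ = make_precursor(config, "canonical", 8, -6, rng, "src")
        decoy = make_decoy(config, "shuffled", rng, "shuf", source=source)
        assert decoy.residues != source.residues
        assert collections.Counter(decoy.residues) == collections.Counter(source.residues)

    @pytest.mark.parametrize("kind", ["myticin_like", "defensin_like"])
    def test_structured_decoys_are_not_mytilins(self, kind):
        config = SyntheticConfig(seed=6)
        rng = np.random.default_rng(6)
        for i in range(10):
            decoy = make_decoy(config, kind, rng, f"{kind}_{i}")
            assert not CANONICAL_RE.search(decoy.residues)
            assert detect_array(decoy).array_class == "noncanonical"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_decoy(SyntheticConfig(), "random", np.random.default_rng(0), "x")


class TestCohorts:
    def test_determinism_is_byte_identical(self, tmp_path):
        paths = []
        for run in (1, 2):
            cfg = SyntheticConfig(seed=99)
            peps, _ = make_mytilin_cohort(cfg)
            decoys = make_decoy_set(cfg, peps)
            txs, _ = make_transcripts(cfg, peps[:5])
            path = tmp_path / f"run{run}.fasta"
            write_fasta(peps + decoys, path)
            write_fasta(txs, tmp_path / f"tx{run}.fasta")
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "tx1.fasta").read_bytes() == (tmp_path / "tx2.fasta").read_bytes()

    def test_requested_arrays_exactly_generated(self):
        cfg = SyntheticConfig(seed=7, n_mytilins=30)
        peps, anns = make_mytilin_cohort(cfg)
        for pep, ann in zip(peps, anns):
            mature = pep.residues[ann.mature[0] - 1 : ann.mature[1]]
            assert detect_array(mature).array_class in ("canonical", "alternative")

    def test_charge_separation_between_mature_and_tail(self):
        cfg = SyntheticConfig(seed=8, n_mytilins=30)
        peps, anns = make_mytilin_cohort(cfg)
        mature_charges = [
            net_charge(p.residues[a.mature[0] - 1 : a.mature[1]]) for p, a in zip(peps, anns)
        ]
        tail_charges = [net_charge(p.residues[a.ctail[0] - 1 :]) for p, a in zip(peps, anns)]
        assert np.mean(mature_charges) > 0 > np.mean(tail_charges)

    def test_family_cohort_is_alignable(self, family_cohort):
        from mytikit.align import global_align

        ancestor, _, members, _ = family_cohort
        for pep in members[:6]:
            assert global_align(pep, ancestor).percent_identity > 60


@pytest.fixture(scope="module")
def tx_corpus():
    cfg = SyntheticConfig(seed=9, n_transcripts=10)
    peps, anns = make_mytilin_cohort(cfg)
    txs, truth = make_transcripts(cfg, peps[:3])
    return peps, txs, truth


class TestTranscripts:

    def test_truth_table_has_one_row_per_embedding(self, tx_corpus):
        _, _, truth = tx_corpus
        assert len(truth) == 3

    def test_recorded_coordinates_translate_back_exactly(self, tx_corpus):
        peps, txs, truth = tx_corpus
        txmap = {t.id: t for t in txs}
        pepmap = {p.id: p for p in peps}
        for _, row in truth.iterrows():
            sub = txmap[row.transcript_id].nucleotides[row.orf_start - 1 : row.orf_end]
            if row.strand == "-":
                sub = str(Seq(sub).reverse_complement())
            assert str(Seq(sub).translate()) == pepmap[row.peptide_id].residues + "*"

    def test_reverse_strand_embeddings_present(self):
        cfg = SyntheticConfig(seed=10, n_transcripts=20, reverse_fraction=0.5)
        peps, _ = make_mytilin_cohort(cfg)
        _, truth = make_transcripts(cfg, peps[:20])
        assert (truth.strand == "-").any()
        assert (truth.strand == "+").any()

    def test_too_few_transcripts_rejected(self):
        cfg = SyntheticConfig(seed=11, n_transcripts=2)
        peps, _ = make_mytilin_cohort(cfg)
        with pytest.raises(ValueError):
            make_transcripts(cfg, peps[:5])


def test_chained_corpus_structure():
    corpus = make_chained_corpus(seed=1)
    assert len(corpus.close_ids) == 5
    assert len(corpus.remote_ids) == 3
    assert set(corpus.embedded_ids) == set(corpus.close_ids) | set(corpus.remote_ids)
    assert corpus.e_threshold < 1e-6
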