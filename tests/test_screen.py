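import numpy as np
import pytest

from mytikit.io_formats import Peptide, TranscriptRecord
from mytikit.screen import (
    evalue_like,
    iterative_screen,
    novelty_filter,
    six_frame_orfs,
)
from mytikit.synthetic_data import (
    SyntheticConfig,
    make_chained_corpus,
    make_decoy,
    make_ctail,
    make_mytilin_cohort,
    make_signal_peptide,
    make_transcripts,
)


class TestSixFrameOrfs:
    def test_embedded_orf_found_at_truth_coordinates(self):
        cfg = SyntheticConfig(seed=1, n_transcripts=5)
        peps, _ = make_mytilin_cohort(cfg)
        txs, truth = make_transcripts(cfg, peps[:5])
        txmap = {t.id: t for t in txs}
        for _, row in truth.iterrows():
            orfs = six_frame_orfs(txmap[row.transcript_id])
            match = [
                o for o in orfs
                if (o.start, o.end, o.frame) == (row.orf_start, row.orf_end, row.frame)
            ]
            assert len(match) == 1, row.transcript_id
            pep = next(p for p in peps if p.id == row.peptide_id)
            assert match[0].protein == pep.residues

    def test_all_n_transcript_has_no_orfs(self):
        assert six_frame_orfs(TranscriptRecord("n", "N" * 500)) == []

    def test_reverse_strand_orf_has_negative_frame(self):
        cfg = SyntheticConfig(seed=3, n_transcripts=30, reverse_fraction=1.0)
        peps, _ = make_mytilin_cohort(cfg)
        txs, truth = make_transcripts(cfg, peps[:5])
        assert (truth.frame < 0).all()
        txmap = {t.id: t for t in txs}
        for _, row in truth.iterrows():
            orfs = six_frame_orfs(txmap[row.transcript_id])
            assert any(o.frame == row.frame and o.start == row.orf_start for o in orfs)

    def test_short_orfs_filtered_by_min_len(self):
        # ATG + 10 codons + stop: complete but short
        seq = "ATG" + "GCT" * 10 + "TAA"
        assert six_frame_orfs(TranscriptRecord("t", seq), min_len=60) == []
        assert len(six_frame_orfs(TranscriptRecord("t", seq), min_len=5)) >= 1


def test_evalue_monotone_in_score():
    evs = [evalue_like(s, 90, 90) for s in range(0, 300, 10)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


@pytest.fixture(scope="module")
def corpus():
    return make_chained_corpus(seed=0)


class TestIterativeScreen:

    def test_full_recall_no_false_positives(self, corpus):
        hits = iterative_screen(corpus.seed_peptides, corpus.transcripts,
                                e_threshold=corpus.e_threshold)
        tx_to_pep = dict(zip(corpus.truth.transcript_id, corpus.truth.peptide_id))
        found = {tx_to_pep.get(h.transcript_id) for h in hits}
        assert found == set(corpus.embedded_ids)

    def test_remotes_require_iteration(self, corpus):
        hits = iterative_screen(corpus.seed_peptides, corpus.transcripts,
                                e_threshold=corpus.e_threshold)
        tx_to_pep = dict(zip(corpus.truth.transcript_id, corpus.truth.peptide_id))
        by_pep = {tx_to_pep.get(h.transcript_id): h.iteration_found for h in hits}
        assert all(by_pep[c] == 1 for c in corpus.close_ids)
        assert all(by_pep[r] >= 2 for r in corpus.remote_ids)

    def test_single_pass_finds_only_close_homologs(self, corpus):
        hits = iterative_screen(corpus.seed_peptides, corpus.transcripts,
                                e_threshold=corpus.e_threshold, max_iter=1)
        tx_to_pep = dict(zip(corpus.truth.transcript_id, corpus.truth.peptide_id))
        found = {tx_to_pep.get(h.transcript_id) for h in hits}
        assert found == set(corpus.close_ids)

    def test_mytilin_free_corpus_is_empty(self):
        rng = np.random.default_rng(12)
        txs = [
            TranscriptRecord(f"bg_{i}", "".join(rng.choice(list("ACGT"), size=600)))
            for i in range(10)
        ]
        seed = make_mytilin_cohort(SyntheticConfig(seed=13, n_mytilins=1))[0][0]
        hits = iterative_screen([seed], txs)
        assert hits == []

    def test_decoy_only_corpus_rejected_by_array_gate(self):
        cfg = SyntheticConfig(seed=14, n_transcripts=6)
        rng = np.random.default_rng(14)
        decoy_precursors = []
        for i in range(4):
            kind = ("myticin_like", "defensin_like")[i % 2]
            mature = make_decoy(cfg, kind, rng, f"d{i}")
            sp = make_signal_peptide(rng, 20)
            tail = make_ctail(rng, 25, -4)
            decoy_precursors.append(Peptide(f"d{i}", sp + mature.residues + tail))
        txs, _ = make_transcripts(cfg, decoy_precursors, rng=rng)
        seed = make_mytilin_cohort(SyntheticConfig(seed=15, n_mytilins=1))[0][0]
        # generous threshold: only the cysteine-array gate separates these
        hits = iterative_screen([seed], txs, e_threshold=1.0)
        assert hits == []

    def test_accepted_set_grows_monotonically(self, corpus):
        sizes = []
        for cap in (1, 2, 3):
            hits = iterative_screen(corpus.seed_peptides, corpus.transcripts,
                                    e_threshold=corpus.e_threshold, max_iter=cap)
            sizes.append(len(hits))
        assert sizes == sorted(sizes)

    def test_requires_a_seed(self):
        with pytest.raises(ValueError):
            iterative_screen([], [])


class TestNoveltyFilter:
    def _hit_for(self, pep, corpus):
        hits = iterative_screen(corpus.seed_peptides, corpus.transcripts,
                                e_threshold=corpus.e_threshold, max_iter=1)
        return hits

    def test_identical_hit_is_not_novel(self):
        corpus = make_chained_corpus(seed=2)
        hits = iterative_screen(corpus.seed_peptides, corpus.transcripts,
                                e_threshold=corpus.e_threshold, max_iter=1)
        flagged = novelty_filter(hits, [hits[0].precursor])
        assert flagged[0].novel is False

    def test_exact_cutoff_is_not_novel(self):
        pep = Peptide("hit", "A" * 19 + "C")  # 95% identical to the known below
        known = Peptide("known", "A" * 20)
        hit = _fake_hit(pep)
        (flagged,) = novelty_filter([hit], [known], cutoff=95.0)
        assert flagged.novel is False

    def test_ten_percent_divergence_is_novel(self):
        pep = Peptide("hit", "A" * 18 + "CC")
        known = Peptide("known", "A" * 20)
        (flagged,) = novelty_filter([_fake_hit(pep)], [known], cutoff=95.0)
        assert flagged.novel is True


def _fake_hit(pep):
    from mytikit.screen import ScreenHit

    return ScreenHit("tx", 1, 1, 3 * len(pep.residues) + 3, pep, "seed", 100.0, 1e-20, 1)
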