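import math
import random

import numpy as np
import pytest

from oracles import enumerate_hmm_paths, hmm_log_odds, random_peptide

from conftest import mature_peptides
from mytikit.align import MSA, progressive_msa
from mytikit.io_formats import Peptide
from mytikit.profile_hmm import (
    BACKGROUND,
    _AA_INDEX,
    build_hmm,
    calibrate,
    dual_screen,
    e_value,
    henikoff_weights,
    load_hmm,
    save_hmm,
    score,
)
from mytikit.synthetic_data import make_mature_family


def toy_hmm():
    return build_hmm(MSA(("a", "b"), ("AC", "AG")))


class TestBuild:
    def test_two_row_toy_matches_hand_computation(self):
        hmm = toy_hmm()
        assert hmm.length == 2
        # both rows weigh 0.5 (identical Henikoff contribution), so column 1
        # counts A=1.0; with background pseudocount of strength 1 the row is
        # (counts + bg) / 2
        assert hmm.match_emissions[0, _AA_INDEX["A"]] == pytest.approx((1 + BACKGROUND[_AA_INDEX["A"]]) / 2)
        assert hmm.match_emissions[1, _AA_INDEX["C"]] == pytest.approx((0.5 + BACKGROUND[_AA_INDEX["C"]]) / 2)
        assert hmm.match_emissions[1, _AA_INDEX["G"]] == pytest.approx((0.5 + BACKGROUND[_AA_INDEX["G"]]) / 2)
        # every observed transition is M->M (count 1 per node); Laplace 1/3
        assert hmm.transitions[0, 0, 0] == pytest.approx((1 + 1 / 3) / 2)
        assert hmm.transitions[0, 0, 1] == pytest.approx((1 / 3) / 2)

    def test_single_row_degenerate(self):
        hmm = build_hmm(MSA(("only",), ("SCAR",)))
        assert hmm.length == 4
        for m, aa in enumerate("SCAR"):
            assert hmm.match_emissions[m].argmax() == _AA_INDEX[aa]

    def test_gap_heavy_columns_excluded(self):
        msa = MSA(("a", "b", "c"), ("A-C", "A-C", "AGC"))
        hmm = build_hmm(msa)
        assert hmm.length == 2  # middle column is 2/3 gapped

    def test_duplicating_every_row_leaves_weighted_emissions_unchanged(self):
        # Henikoff weights halve uniformly when the whole alignment is doubled
        rows = ("SCAR", "SCTR", "WCAR")
        base = build_hmm(MSA(("a", "b", "c"), rows))
        doubled = build_hmm(MSA(("a", "b", "c", "a2", "b2", "c2"), rows + rows))
        assert np.allclose(base.match_emissions, doubled.match_emissions, atol=1e-12)

    def test_single_row_duplication_damped_by_weighting(self):
        # duplicating one row shifts weighted emissions far less than it
        # shifts unweighted counts: the copies share their original weight
        rows = ("SCAR", "SCTR", "WCAR")
        base = build_hmm(MSA(("a", "b", "c"), rows))
        dup = build_hmm(MSA(("a", "b", "c", "c2"), rows + ("WCAR",)))
        weighted_shift = np.abs(dup.match_emissions - base.match_emissions).max()

        flat = [1.0, 1.0, 1.0]
        def unweighted(rows_, w):
            em = np.zeros((4, 20))
            for row, wi in zip(rows_, w):
                for m, aa in enumerate(row):
                    em[m, _AA_INDEX[aa]] += wi
            em += BACKGROUND
            return em / em.sum(axis=1, keepdims=True)

        unweighted_shift = np.abs(
            unweighted(rows + ("WCAR",), flat + [1.0]) - unweighted(rows, flat)
        ).max()
        assert weighted_shift < 0.5 * unweighted_shift

    def test_no_match_columns_rejected(self):
        with pytest.raises(ValueError, match="match column"):
            build_hmm(MSA(("a", "b"), ("A-", "-A")))

    def test_henikoff_weights_downweight_duplicates(self):
        w = henikoff_weights(["SCAR", "SCAR", "WCTR"])
        assert w[2] > w[0] == pytest.approx(w[1])
        assert w.sum() == pytest.approx(1.0)


class TestScoring:
    @pytest.mark.parametrize("seq", ["AC", "AG", "C", "ACG", "WW", "A"])
    def test_forward_and_viterbi_match_path_enumeration(self, seq):
        hmm = toy_hmm()
        total, best = enumerate_hmm_paths(hmm, seq)
        assert score(hmm, seq, "forward") == pytest.approx(hmm_log_odds(hmm, seq, total), abs=1e-9)
        assert score(hmm, seq, "viterbi") == pytest.approx(hmm_log_odds(hmm, seq, best), abs=1e-9)

    def test_three_state_model_against_enumeration(self):
        hmm = build_hmm(MSA(("a", "b", "c"), ("ACD", "AKD", "AC-")))
        rng = random.Random(0)
        for _ in range(12):
            seq = random_peptide(rng, rng.randint(1, 4), "ACDKW")
            total, best = enumerate_hmm_paths(hmm, seq)
            assert score(hmm, seq, "forward") == pytest.approx(hmm_log_odds(hmm, seq, total), abs=1e-9)
            assert score(hmm, seq, "viterbi") == pytest.approx(hmm_log_odds(hmm, seq, best), abs=1e-9)

    def test_forward_dominates_viterbi(self):
        members = make_mature_family(seed=21, kind="canonical", n=5)
        hmm = build_hmm(progressive_msa(members))
        rng = random.Random(1)
        for _ in range(100):
            seq = random_peptide(rng, rng.randint(5, 45))
            assert score(hmm, seq, "forward") >= score(hmm, seq, "viterbi") - 1e-9

    def test_training_sequence_outscores_its_shuffle(self):
        members = make_mature_family(seed=22, kind="canonical", n=8)
        hmm = build_hmm(progressive_msa(members))
        rng = random.Random(2)
        for pep in members[:4]:
            shuffled = list(pep.residues)
            rng.shuffle(shuffled)
            assert score(hmm, pep) > score(hmm, "".join(shuffled))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            score(toy_hmm(), "AC", "posterior")


@pytest.fixture(scope="module")
def calibrated():
    members = make_mature_family(seed=23, kind="canonical", n=10)
    hmm = build_hmm(progressive_msa(members))
    return calibrate(hmm, n_null=400, seed=3)


class TestCalibration:

    def test_deterministic_under_seed(self, calibrated):
        members = make_mature_family(seed=23, kind="canonical", n=10)
        again = calibrate(build_hmm(progressive_msa(members)), n_null=400, seed=3)
        assert again.calibration == calibrated.calibration

    def test_e_value_monotone_decreasing_in_score(self, calibrated):
        scores = np.linspace(-50, 80, 40)
        evs = [e_value(calibrated, s, n_db=100) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_median_null_score_has_half_database_e_value(self, calibrated):
        rng = np.random.default_rng(5)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        nulls = []
        for _ in range(300):
            L = int(rng.choice(calibrated.training_lengths))
            nulls.append(score(calibrated, "".join(rng.choice(aa, L, p=calibrated.background))))
        med = float(np.median(nulls))
        assert e_value(calibrated, med, n_db=100) == pytest.approx(50.0, rel=0.10)

    def test_uncalibrated_model_rejects_e_value(self):
        with pytest.raises(ValueError, match="not calibrated"):
            e_value(toy_hmm(), 10.0)


@pytest.fixture(scope="module")
def models():
    # train on the first half of each family; the second halves are the
    # held-out test sets, disjoint from training but of the same lineage
    mytilin_family = make_mature_family(seed=31, kind="canonical", n=60, prefix="myt")
    myticin_family = make_mature_family(seed=32, kind="myticin_like", n=60, prefix="mtc")
    mytilin = calibrate(build_hmm(progressive_msa(mytilin_family[:30])), n_null=300, seed=31)
    myticin = calibrate(build_hmm(progressive_msa(myticin_family[:30])), n_null=300, seed=32)
    return mytilin, myticin, mytilin_family[30:], myticin_family[30:]


class TestDualScreen:

    def test_held_out_mytilins_all_claimed_by_mytilin_model(self, models):
        mytilin, myticin, held_mytilins, _ = models
        hits = dual_screen(held_mytilins, mytilin, myticin)
        assert all(h.best_model == "mytilin" for h in hits)

    def test_myticin_decoys_never_labelled_mytilin(self, models):
        mytilin, myticin, _, held_myticins = models
        hits = dual_screen(held_myticins, mytilin, myticin)
        assert all(h.best_model != "mytilin" for h in hits)

    def test_empty_input(self, models):
        assert dual_screen([], models[0], models[1]) == []


def test_save_load_roundtrip(tmp_path):
    members = make_mature_family(seed=41, kind="canonical", n=6)
    hmm = calibrate(build_hmm(progressive_msa(members)), n_null=100, seed=4)
    path = tmp_path / "model.hmm"
    save_hmm(hmm, path)
    back = load_hmm(path)
    assert back.length == hmm.length
    assert np.allclose(back.match_emissions, hmm.match_emissions)
    assert np.allclose(back.transitions, hmm.transitions)
    assert back.calibration == pytest.approx(hmm.calibration)
    assert score(back, members[0]) == pytest.approx(score(hmm, members[0]))
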