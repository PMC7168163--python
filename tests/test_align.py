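import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_global_score, brute_local_score, random_peptide

from mytikit.align import (
    MSA,
    global_align,
    local_align,
    local_score,
    pairwise_distance,
    percent_identity,
    progressive_msa,
)
from mytikit.datasets import load_reference_peptides
from mytikit.io_formats import Peptide


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACDE", "ACDE")
        assert aln.percent_identity == 100.0
        assert "-" not in aln.aligned_query + aln.aligned_target

    def test_matches_bruteforce_on_short_pairs(self):
        rng = random.Random(0)
        for _ in range(60):
            a = random_peptide(rng, rng.randint(1, 6), "ACDEFGHKRWY")
            b = random_peptide(rng, rng.randint(1, 6), "ACDEFGHKRWY")
            assert global_align(a, b).score == pytest.approx(brute_global_score(a, b)), (a, b)

    def test_score_symmetry(self):
        rng = random.Random(1)
        for _ in range(20):
            a = random_peptide(rng, rng.randint(2, 12))
            b = random_peptide(rng, rng.randint(2, 12))
            assert global_align(a, b).score == global_align(b, a).score

    def test_degapping_recovers_inputs(self):
        aln = global_align("ACDEFG", "ACFG")
        assert aln.aligned_query.replace("-", "") == "ACDEFG"
        assert aln.aligned_target.replace("-", "") == "ACFG"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACDE")

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.text(alphabet="ACDEFGHKR", min_size=1, max_size=5),
        st.text(alphabet="ACDEFGHKR", min_size=1, max_size=5),
    )
    def test_bruteforce_property(self, a, b):
        assert global_align(a, b).score == pytest.approx(brute_global_score(a, b))


class TestLocalAlign:
    def test_all_negative_pairs_give_empty_alignment(self):
        aln = local_align("GGGG", "PPPP")
        assert aln.score == 0.0
        assert aln.aligned_query == "" and aln.aligned_target == ""

    def test_embedded_exact_match_recovered(self):
        core = "WCKYRCRARRCRYYVSVRYG"
        aln = local_align("AAAA" + core + "SSSS", core)
        assert aln.aligned_query == core
        assert aln.aligned_target == core

    def test_matches_bruteforce_on_short_pairs(self):
        rng = random.Random(2)
        for _ in range(12):
            a = random_peptide(rng, rng.randint(1, 5), "ACDEFGHKRWY")
            b = random_peptide(rng, rng.randint(1, 5), "ACDEFGHKRWY")
            assert local_align(a, b).score == pytest.approx(brute_local_score(a, b)), (a, b)

    def test_score_shortcut_agrees_with_alignment(self):
        rng = random.Random(3)
        for _ in range(10):
            a = random_peptide(rng, 20)
            b = random_peptide(rng, 25)
            assert local_score(a, b) == local_align(a, b).score


class TestPercentIdentity:
    def test_single_mismatch(self):
        aln = global_align("AAAA", "AAAT")
        assert percent_identity(aln) == 75.0

    def test_hand_worked_gapped_pair(self):
        # ACDEF vs ACF aligns as ACDEF / AC--F: 3 matches over 5 columns
        aln = global_align("ACDEF", "ACF")
        assert aln.aligned_query == "ACDEF"
        assert aln.aligned_target.count("-") == 2
        assert percent_identity(aln) == pytest.approx(60.0)


class TestProgressiveMSA:
    def test_identical_sequences_align_gapless(self):
        peps = [Peptide(f"s{i}", "SCASRCKYRCRARRC") for i in range(3)]
        msa = progressive_msa(peps)
        assert all("-" not in row for row in msa.rows)

    def test_degap_roundtrip_and_column_bound(self, family_cohort):
        _, _, members, _ = family_cohort
        msa = progressive_msa(members[:8])
        for pep, row_id in zip(members[:8], msa.ids):
            idx = msa.ids.index(pep.id)
            assert msa.degapped(idx) == pep.residues
        assert msa.n_columns >= max(len(p) for p in members[:8])

    def test_reference_mytilins_share_conserved_cysteine_columns(self):
        mcal = [p for p in load_reference_peptides() if p.id.startswith("Mcal_mytilin_") and p.id[-1] in "1234"]
        msa = progressive_msa(mcal)
        conserved_c = sum(
            1 for c in range(msa.n_columns) if all(row[c] == "C" for row in msa.rows)
        )
        assert conserved_c == 8

    def test_duplicate_row_does_not_change_gap_pattern(self):
        peps = [
            Peptide("a", "SCASRCKYRCRARRCRYYVSVRYGWFCYCRCLHC"),
            Peptide("b", "SCASRCKSRCRARRCKYYVSVRYGWFCYCRCLRC"),
            Peptide("c", "SCALLCKAHCRARRCGYYVSVFYHGRCYCRCLRC"),
        ]
        base = progressive_msa(peps)
        dup = progressive_msa(peps + [Peptide("a2", peps[0].residues)])
        gaps = lambda msa, rid: msa.rows[msa.ids.index(rid)]
        for rid in ("a", "b", "c"):
            assert gaps(base, rid) == gaps(dup, rid)

    def test_single_peptide_degenerate(self):
        msa = progressive_msa([Peptide("only", "SCASRC")])
        assert msa.rows == ("SCASRC",)

    def test_distance_of_identical_is_zero(self):
        assert pairwise_distance("SCASRC", "SCASRC") == 0.0
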