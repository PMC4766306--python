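"""Local alignment, E-values, motif scanning, ORF prediction."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from cypscreen.homology import (
    DNA_KA,
    PROTEIN_KA,
    classify_p450,
    dna_scoring,
    evalue_of,
    find_homologs,
    local_align,
    longest_orf_peptide,
    protein_scoring,
    scan_p450_motifs,
)
from cypscreen.io import SequenceRecord
from cypscreen.synthetic import mutate_homolog, reverse_translate
from cypscreen import _templates

from oracle_utils import brute_force_local_score, brute_force_longest_orf


def prot(seq, id="q"):
    return SequenceRecord(id=id, seq=seq, alphabet="protein")


def dna(seq, id="q"):
    return SequenceRecord(id=id, seq=seq, alphabet="dna")


class TestLocalAlign:
    def test_self_alignment_blosum62_diagonal(self):
        hit = local_align(prot("ACDEFG"), prot("ACDEFG", id="s"))
        # BLOSUM62 diagonal: A4 + C9 + D6 + E5 + F6 + G6
        assert hit.raw_score == 36
        assert hit.query_span == (0, 6) and hit.subject_span == (0, 6)

    def test_no_positive_pair_scores_zero(self):
        hit = local_align(dna("AAAA"), dna("CCCC", id="s"))
        assert hit.raw_score == 0
        assert hit.query_span == (0, 0) and hit.subject_span == (0, 0)

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            local_align(dna("ACGT"), prot("MKL", id="s"))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration_dna(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=10))
        b = "".join(rng.choice(list("ACGT"), size=10))
        sc = dna_scoring()
        oracle = brute_force_local_score(
            a, b,
            lambda x, y: sc.match if x == y else sc.mismatch,
            sc.gap_open, sc.gap_extend,
        )
        hit = local_align(dna(a), dna(b, id="s"), sc)
        assert hit.raw_score == oracle

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_exhaustive_enumeration_protein_12mers(self, seed):
        rng = np.random.default_rng(seed)
        mat = substitution_matrices.load("BLOSUM62")
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
        b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
        sc = protein_scoring()
        oracle = brute_force_local_score(
            a, b, lambda x, y: mat[x, y], sc.gap_open, sc.gap_extend
        )
        assert local_align(prot(a), prot(b, id="s"), sc).raw_score == oracle

    def test_score_symmetric_under_swap(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=60))
        b = "".join(rng.choice(list("ACGT"), size=60))
        assert (
            local_align(dna(a), dna(b, id="s")).raw_score
            == local_align(dna(b), dna(a, id="s")).raw_score
        )

    def test_lengthening_homologous_block_never_decreases_score(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=30))
        flank_a = "".join(rng.choice(list("ACGT"), size=20))
        flank_b = "".join(rng.choice(list("ACGT"), size=20))
        prev = 0
        for k in range(10, 31, 5):
            block = core[:k]
            score = local_align(
                dna(flank_a + block), dna(block + flank_b, id="s")
            ).raw_score
            assert score >= prev
            prev = score


class TestEvalue:
    def test_unit_expectation_identity(self):
        ka = PROTEIN_KA
        s = math.log(ka.k * 200 * 300) / ka.lam
        assert evalue_of(s, 200, 300, ka) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert evalue_of(40, 100, 100, PROTEIN_KA) == pytest.approx(9.4e-3, rel=0.01)

    def test_strictly_decreasing_in_score_and_positive(self):
        evals = [evalue_of(s, 500, 500, DNA_KA) for s in range(0, 401, 20)]
        assert all(e > 0 for e in evals)
        assert all(a > b for a, b in zip(evals, evals[1:]))

    def test_extreme_scores_stay_positive(self):
        # scores past the exp() underflow point clamp to the float floor
        assert evalue_of(2000, 500, 500, DNA_KA) > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            evalue_of(10, 0, 100, PROTEIN_KA)


class TestFindHomologs:
    def test_exact_copy_found_among_decoys(self, rng):
        target = "".join(rng.choice(list("ACGT"), size=300))
        subjects = [dna(target, id="target")] + [
            dna("".join(rng.choice(list("ACGT"), size=300)), id=f"decoy{i}")
            for i in range(5)
        ]
        hits = find_homologs([dna(target, id="q")], subjects, e_cutoff=1e-4)
        assert hits["q"].subject_id == "target"

    def test_stringent_cutoff_drops_distant_homolog(self, rng):
        # a diverged nucleotide homolog passes the permissive protein-stage
        # style cutoff but not the stringent cross-assembly one
        base = dna("".join(rng.choice(list("ACGT"), size=300)), id="base")
        distant = mutate_homolog(base, 0.65, 123)
        subjects = [SequenceRecord("s", distant.seq, alphabet="dna")]
        loose = find_homologs([base], subjects, e_cutoff=1e-4)
        strict = find_homologs([base], subjects, e_cutoff=1e-50)
        assert "base" in loose
        assert "base" not in strict

    def test_no_positive_pair_gives_no_hit(self):
        hits = find_homologs([dna("AAAAAA")], [dna("CCCCCC", id="s")], e_cutoff=10.0)
        assert hits == {}

    def test_empty_subjects_empty_result(self):
        assert find_homologs([dna("ACGT")], [], e_cutoff=1.0) == {}

    def test_result_invariant_to_subject_order(self, rng):
        q = dna("".join(rng.choice(list("ACGT"), size=200)), id="q")
        subjects = [mutate_homolog(q, ident, seed) for ident, seed in
                    [(0.95, 1), (0.9, 2), (0.85, 3)]]
        subjects = [
            SequenceRecord(f"s{i}", s.seq, alphabet="dna") for i, s in enumerate(subjects)
        ]
        fwd = find_homologs([q], subjects, e_cutoff=1e-4)
        rev = find_homologs([q], subjects[::-1], e_cutoff=1e-4)
        assert fwd == rev

    def test_prefilter_preserves_strong_hits(self, rng):
        q = dna("".join(rng.choice(list("ACGT"), size=200)), id="q")
        s = SequenceRecord("s", mutate_homolog(q, 0.95, 5).seq, alphabet="dna")
        plain = find_homologs([q], [s], e_cutoff=1e-10)
        filtered = find_homologs([q], [s], e_cutoff=1e-10, prefilter_k=8)
        assert plain == filtered


class TestMotifs:
    def test_exxr_position(self):
        hits = scan_p450_motifs(prot("AAEKLRAA"))
        assert [(h.motif_name, h.position) for h in hits] == [("EXXR", 2)]

    def test_heme_motif(self):
        hits = scan_p450_motifs(prot("FGAGRRACPG"))
        assert any(h.motif_name == "heme_FXXGXRXCXG" and h.position == 0 for h in hits)

    def test_negative_sequence(self):
        assert scan_p450_motifs(prot("AAEKLA")) == []

    def test_template_contains_all_four(self):
        names = {h.motif_name for h in scan_p450_motifs(_templates.p450_template())}
        assert names == {"EXXR", "PXRX", "heme_FXXGXRXCXG", "oxygen_binding"}

    def test_one_based_reporting(self):
        (hit,) = scan_p450_motifs(prot("AAEKLRAA"))
        assert hit.position_1based == hit.position + 1 == 3

    def test_nucleotide_input_rejected(self):
        with pytest.raises(ValueError):
            scan_p450_motifs(dna("ACGT"))


class TestClassifyP450:
    def test_template_is_positive_with_motifs(self):
        call = classify_p450(_templates.p450_template(), _templates.reference_p450_set())
        assert call.is_p450
        assert {m.motif_name for m in call.motifs} == set(
            ["EXXR", "PXRX", "heme_FXXGXRXCXG", "oxygen_binding"]
        )

    def test_random_peptides_are_negative(self):
        refs = _templates.reference_p450_set()
        n_positive = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pep = prot(_templates.random_peptide(500, rng), id=f"r{seed}")
            if classify_p450(pep, refs).is_p450:
                n_positive += 1
        assert n_positive <= 2

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            classify_p450(prot("MKLV"), [])


class TestLongestOrf:
    def test_minimal_orf(self):
        pep = longest_orf_peptide(dna("ATGAAATAA"), min_aa=1)
        assert pep.seq == "MK"

    def test_reverse_strand(self):
        from oracle_utils import revcomp

        pep = longest_orf_peptide(dna(revcomp("ATGAAATAA")), min_aa=1)
        assert pep.seq == "MK"

    def test_below_min_aa_returns_none(self):
        assert longest_orf_peptide(dna("ATGAAATAA"), min_aa=50) is None

    def test_non_acgtn_rejected(self):
        # non-ACGTN characters are already rejected at record construction
        with pytest.raises(ValueError):
            dna("ACGR" * 50)
        pep = longest_orf_peptide(dna("ATG" + "AAN" * 60 + "TAA"), min_aa=10)
        assert set(pep.seq[1:]) == {"X"}  # ambiguous codons translate to X

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_six_frame_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        oracle = brute_force_longest_orf(seq)
        pep = longest_orf_peptide(dna(seq), min_aa=1)
        if oracle is None:
            assert pep is None
        else:
            assert pep.seq == oracle

    def test_round_trips_generated_coding_sequence(self, rng):
        peptide = _templates.random_peptide(120, rng)
        cds = "ATG" + reverse_translate(peptide[1:], rng) + "TAA"
        pep = longest_orf_peptide(dna("GGCC" + cds + "TTGG"), min_aa=50)
        assert pep.seq == peptide
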