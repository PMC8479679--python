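"""Disambiguation: trimming, simplification, 3' rolling, dup detection."""

import random

import pytest

from hgvscanon import ReferenceModel, format_description
from hgvscanon.apply_engine import InternalVariant, apply_variants
from hgvscanon.coordinates import TranscriptLayout
from hgvscanon.grammar import parse_description
from hgvscanon.normalizer import (detect_dup, normalize, normalize_text,
                                  roll_3prime, simplify, trim_delins,
                                  trim_inversion)
from hgvscanon.reference_model import AnnotatedTranscript
from hgvscanon.semantics import check_description
from hgvscanon.sequences import reverse_complement

from conftest import random_sequence, random_valid_allele


# ---------------------------------------------------------------------------
# elementary steps


def test_trim_delins_removes_longest_common_prefix_then_suffix():
    assert trim_delins("ACGTA", "ATTTA", (1, 6)) == ((2, 4), "TT")


def test_trim_delins_of_identical_sequences_is_empty():
    assert trim_delins("ACGT", "ACGT", (3, 7)) == ((7, 7), "")


def test_trim_delins_matches_exhaustive_minimum():
    """The trimmed delins is the shortest equivalent one (brute force)."""
    rng = random.Random(5)
    for _ in range(400):
        n = rng.randrange(1, 12)
        deleted = random_sequence(rng, n)
        inserted = random_sequence(rng, rng.randrange(0, 12))
        (s, e), ins2 = trim_delins(deleted, inserted, (0, n))
        # equivalence on the concrete segment
        assert deleted[:s] + ins2 + deleted[e:] == inserted
        # brute force: all (i, j) trims that keep equivalence
        best = None
        for i in range(n + 1):
            for j in range(n - i + 1):
                k = len(inserted) - i - j
                if k < 0:
                    continue
                if deleted[:i] == inserted[:i] and \
                        (j == 0 or deleted[n - j:] == inserted[len(inserted) - j:]):
                    width = (n - i - j) + k
                    if best is None or width < best:
                        best = width
        assert (e - s) + len(ins2) == best


def test_trim_inversion_partial_palindrome():
    # AACGT: leading A pairs with the trailing T under reverse complement
    assert trim_inversion("AACGT", (0, 5)) == (1, 4)


def test_trim_inversion_full_palindrome_empties():
    assert trim_inversion("AATT", (0, 4)) == (2, 2)


def test_trim_inversion_preserves_the_observed_sequence():
    rng = random.Random(6)
    for _ in range(400):
        ref = random_sequence(rng, rng.randrange(6, 30))
        a = rng.randrange(0, len(ref) - 2)
        b = rng.randrange(a + 2, min(len(ref), a + 10) + 1)
        s, e = trim_inversion(ref[a:b], (a, b))
        full = apply_variants(ref, [InternalVariant(a, b,
                                                    reverse_complement(ref[a:b]))])
        if e > s:
            trimmed = apply_variants(
                ref, [InternalVariant(s, e, reverse_complement(ref[s:e]))])
        else:
            trimmed = ref
        assert trimmed == full


@pytest.mark.parametrize("start, end, alt, label", [
    (1, 3, "", "del"),
    (3, 3, "GG", "ins"),
    (2, 3, "T", "substitution"),
    (1, 5, "GT", "delins"),
    (2, 4, "", "del"),
])
def test_simplify_labels(start, end, alt, label):
    _, got = simplify(InternalVariant(start, end, alt), "AACGTAA")
    assert got == label


def test_simplify_detects_inversion_and_complement_substitution():
    ref = "AAACGTAA"
    seg = ref[3:6]
    _, label = simplify(InternalVariant(3, 6, reverse_complement(seg)), ref)
    assert label == "inv"
    _, label = simplify(InternalVariant(3, 4, reverse_complement(ref[3])), ref)
    assert label == "substitution"


def test_roll_insertion_with_circular_permutation():
    iv = roll_3prime(InternalVariant(2, 2, "CGTC"), "AACGTAA")
    assert iv == InternalVariant(5, 5, "CCGT")


def test_roll_deletion_in_repeat():
    ref = "AACGTTGATATGGCCTACGA"  # C at 1-based 14 and 15
    assert roll_3prime(InternalVariant(13, 14), ref) == InternalVariant(14, 15)


def test_roll_without_equal_context_is_identity():
    assert roll_3prime(InternalVariant(2, 4), "ACGTACGT") == InternalVariant(2, 4)


def test_roll_respects_barrier():
    ref = "AATTTTTA"
    assert roll_3prime(InternalVariant(2, 3), ref) == InternalVariant(6, 7)
    assert roll_3prime(InternalVariant(2, 3), ref,
                       barrier=(0, 5)) == InternalVariant(4, 5)


def test_roll_reverse_direction():
    ref = "AATTTTTA"
    assert roll_3prime(InternalVariant(6, 7), ref,
                       direction="reverse") == InternalVariant(2, 3)


def test_detect_dup():
    iv, seg = detect_dup(InternalVariant(5, 5, "T"), "AACGTAA")
    assert seg == (4, 5)
    iv, seg = detect_dup(InternalVariant(5, 5, "G"), "AACGTAA")
    assert seg is None


def test_rolled_3prime_matches_exhaustive_oracle():
    """Single del/ins <= 6 nt: the canonical position equals the maximum of
    the brute-force equivalence class."""
    rng = random.Random(77)
    for _ in range(60):
        n = 40
        ref = random_sequence(rng, n)
        for L in range(1, 7):
            for s in range(0, n - L + 1):
                obs = ref[:s] + ref[s + L:]
                best = max(s2 for s2 in range(0, n - L + 1)
                           if ref[:s2] + ref[s2 + L:] == obs)
                assert roll_3prime(InternalVariant(s, s + L), ref).start == best
            for s in range(1, n):
                alt = random_sequence(rng, L)
                obs = ref[:s] + alt + ref[s:]
                best = max(s2 for s2 in range(0, n + 1)
                           if ref[:s2] + obs[s2:s2 + L] + ref[s2:] == obs)
                got = roll_3prime(InternalVariant(s, s, alt), ref)
                assert got.start == min(best, n), (ref, s, alt)
                # equivalence always preserved
                assert ref[:got.start] + got.alt + ref[got.start:] == obs


# ---------------------------------------------------------------------------
# full pipeline


def test_allele_example_applies_the_3prime_rule(demo_model):
    report = normalize_text("DEMOREF.1:g.[7G>T;14del]", demo_model)
    assert format_description(report.canonical) == "DEMOREF.1:g.[7G>T;15del]"
    assert [c.code for c in report.diagnostics.corrections] == ["C3PRIME"]


def test_minimization_example(aacgtaa):
    report = normalize_text("R1.1:g.2_6delinsATTTA", aacgtaa)
    assert format_description(report.canonical) == "R1.1:g.3_4delinsTT"
    assert [c.code for c in report.diagnostics.corrections] == ["CMINIMIZED"]


def test_simplification_examples(aacgtaa):
    report = normalize_text("R1.1:g.2_5delinsGT", aacgtaa)
    assert format_description(report.canonical) == "R1.1:g.2_3del"
    report = normalize_text("R1.1:g.3delinsT", aacgtaa)
    assert format_description(report.canonical) == "R1.1:g.3C>T"
    assert any(c.code == "CVARTYPE" for c in report.diagnostics.corrections)


def test_rolling_example(aacgtaa):
    report = normalize_text("R1.1:g.2_3insCGTC", aacgtaa)
    assert format_description(report.canonical) == "R1.1:g.5_6insCCGT"


def test_insertion_simplified_to_dup(aacgtaa):
    report = normalize_text("R1.1:g.5_6insT", aacgtaa)
    assert format_description(report.canonical) == "R1.1:g.5dup"
    # apply-oracle equality of the two spellings
    i1, _ = check_description(parse_description("R1.1:g.5_6insT"), aacgtaa)
    i2, _ = check_description(parse_description("R1.1:g.5dup"), aacgtaa)
    assert apply_variants("AACGTAA", i1) == apply_variants("AACGTAA", i2)


def test_adjacent_substitutions_are_not_merged():
    m = ReferenceModel(id="R.1", sequence="AATCGG")
    report = normalize_text("R.1:g.[2A>G;3T>C]", m)
    assert format_description(report.canonical) == "R.1:g.[2A>G;3T>C]"
    assert not report.diagnostics.corrections


def test_already_canonical_input_is_a_fixpoint(aacgtaa):
    report = normalize_text("R1.1:g.3_4delinsTT", aacgtaa)
    assert format_description(report.canonical) == "R1.1:g.3_4delinsTT"
    assert not report.diagnostics.corrections


def test_degenerate_delins_becomes_identity(aacgtaa):
    report = normalize_text("R1.1:g.3delinsC", aacgtaa)
    assert format_description(report.canonical) == "R1.1:g.="
    assert [c.code for c in report.diagnostics.corrections] == ["CIDENTITY"]


def test_errors_block_canonical_output(aacgtaa):
    report = normalize_text("R1.1:g.99del", aacgtaa)
    assert report.canonical is None
    assert not report.ok


def test_equivalent_g_description_is_emitted_for_transcript_systems(
        coding_model):
    report = normalize_text("GEN1.1(T1.1):c.5del", coding_model,
                            predict_proteins=False)
    assert report.equivalent_g is not None
    g = format_description(report.equivalent_g)
    ivs, diags = check_description(parse_description(g), coding_model)
    assert diags.ok
    assert ivs == report.internal_variants


def test_splice_site_barrier_blocks_rolling_into_the_intron():
    #       exon1 ends with TT, intron starts with TTT -> g. rolls on,
    #       c. must stop at the boundary
    seq = "GGATGCCTTTTTGGAGGCCTAAGG"
    layout = TranscriptLayout(exons=((2, 9), (15, 23)), strand="+",
                              cds=(2, 23))
    m = ReferenceModel(id="B.1", sequence=seq,
                       transcripts=[AnnotatedTranscript("T.1", layout)])
    g_rep = normalize_text("B.1:g.8del", m, predict_proteins=False)
    assert format_description(g_rep.canonical) == "B.1:g.12del"
    c_rep = normalize_text("B.1(T.1):c.7del", m, predict_proteins=False)
    assert format_description(c_rep.canonical) == "B.1(T.1):c.7del"


def test_reverse_strand_transcripts_roll_opposite_to_genomic():
    ref = "ACGCAGTTTTGACCGGA"
    layout = TranscriptLayout(exons=((0, len(ref)),), strand="-",
                              cds=(2, 14))
    m = ReferenceModel(id="R.1", sequence=ref,
                       transcripts=[AnnotatedTranscript("T.1", layout)])
    g_rep = normalize_text("R.1:g.7del", m, predict_proteins=False)
    assert format_description(g_rep.canonical) == "R.1:g.10del"
    c_rep = normalize_text("R.1(T.1):c.5del", m, predict_proteins=False)
    assert format_description(c_rep.canonical) == "R.1(T.1):c.8del"
    assert format_description(c_rep.equivalent_g) == "R.1:g.7del"


def test_strand_symmetry_of_normalization():
    """Normalizing c. on the - strand equals + strand normalization on the
    reverse complement sequence."""
    rng = random.Random(13)
    for _ in range(50):
        n = 60
        fwd = random_sequence(rng, n)
        rev = reverse_complement(fwd)
        lay_plus = TranscriptLayout(exons=((0, n),), strand="+", cds=(6, 54))
        lay_minus = TranscriptLayout(exons=((0, n),), strand="-",
                                     cds=(6, 54))
        m_plus = ReferenceModel(id="P.1", sequence=rev,
                                transcripts=[AnnotatedTranscript("T.1",
                                                                 lay_plus)])
        m_minus = ReferenceModel(id="M.1", sequence=fwd,
                                 transcripts=[AnnotatedTranscript("T.1",
                                                                  lay_minus)])
        a = rng.randrange(1, 45)
        b = a + rng.randrange(0, 4)
        op = rng.choice(["del", "dup"])
        text = f"c.{a}_{b}{op}" if b > a else f"c.{a}{op}"
        rep_p = normalize_text(f"P.1(T.1):{text}", m_plus,
                               predict_proteins=False)
        rep_m = normalize_text(f"M.1(T.1):{text}", m_minus,
                               predict_proteins=False)
        assert rep_p.ok and rep_m.ok
        vp = format_description(rep_p.canonical).split(":")[1]
        vm = format_description(rep_m.canonical).split(":")[1]
        assert vp == vm, (fwd, text, vp, vm)


def test_observed_sequence_preservation_and_idempotence_randomized():
    rng = random.Random(2024)
    for _ in range(800):
        ref = random_sequence(rng, rng.randrange(20, 60))
        m = ReferenceModel(id="R.1", sequence=ref)
        d = random_valid_allele(rng, ref)
        ivs, diags = check_description(d, m)
        if not diags.ok:
            continue
        want = apply_variants(ref, ivs)
        report = normalize(d, m, predict_proteins=False)
        assert report.ok
        ivs2, diags2 = check_description(report.canonical, m)
        assert diags2.ok, (ref, format_description(d),
                           format_description(report.canonical))
        assert apply_variants(ref, ivs2) == want
        again = normalize(report.canonical, m, predict_proteins=False)
        assert format_description(again.canonical) == \
            format_description(report.canonical)
        assert not again.diagnostics.corrections
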