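"""Protein consequence prediction and restriction-site change tables."""

import random

import pytest
from Bio.Seq import Seq

from hgvscanon import ReferenceModel
from hgvscanon.apply_engine import InternalVariant, apply_variants
from hgvscanon.coordinates import TranscriptLayout
from hgvscanon.grammar import parse_description
from hgvscanon.normalizer import normalize, normalize_text
from hgvscanon.protein_effects import (build_cds, build_mrna,
                                       describe_protein_change,
                                       load_enzyme_table, predict_protein,
                                       restriction_changes, translate)
from hgvscanon.reference_model import AnnotatedTranscript
from hgvscanon.semantics import check_description

from conftest import build_coding_model, random_sequence, random_valid_allele


# ---------------------------------------------------------------------------
# mRNA assembly and translation


def test_build_mrna_concatenates_exons():
    genome = "AAAATGCCGGGGTTTACCCC"
    t = AnnotatedTranscript("T.1", TranscriptLayout(
        exons=((2, 8), (12, 18)), strand="+", cds=(3, 16)))
    assert build_mrna(t, genome) == genome[2:8] + genome[12:18]
    assert build_cds(t, genome) == genome[3:8] + genome[12:16]


def test_single_exon_transcript_mrna_is_a_substring():
    genome = "AAAATGCCGGGGTTTACCCC"
    t = AnnotatedTranscript("T.1", TranscriptLayout(exons=((2, 18),),
                                                    strand="+"))
    assert build_mrna(t, genome) == genome[2:18]


def test_minus_strand_mrna_is_reverse_complement_of_concatenation():
    genome = "AAAATGCCGGGGTTTACCCC"
    t = AnnotatedTranscript("T.1", TranscriptLayout(
        exons=((2, 8), (12, 18)), strand="-"))
    assert build_mrna(t, genome) == str(
        Seq(genome[2:8] + genome[12:18]).reverse_complement())


def test_translate_simple_cases():
    assert translate("ATGTGA") == "M"
    assert translate("ATGAAATAG") == "MK"
    assert translate("ATGAA") == "M"  # trailing partial codon ignored


def test_translate_matches_biopython_on_random_cds():
    rng = random.Random(123)
    for _ in range(200):
        cds = random_sequence(rng, 3 * rng.randrange(1, 40))
        assert translate(cds) == str(Seq(cds).translate(to_stop=True))


# ---------------------------------------------------------------------------
# geometry cases


def run(model, text):
    report = normalize_text(text, model)
    assert report.ok, report.diagnostics.to_list()
    assert len(report.proteins) == 1
    return report.proteins[0]


def test_deletion_ending_in_an_intron_omits_prediction(coding_model):
    # geometry of an exonic start with the end a few bases into the intron
    p = run(coding_model, "GEN1.1(T1.1):c.10_15+5del")
    assert p.p_description == "p.?"
    assert "splice_omitted" in p.flags
    assert p.observed_protein is None
    assert [w.code for w in p.warnings] == ["WSPLICE"]


def test_deletion_spanning_an_intron_forms_a_fusion_exon(coding_model):
    # both ends exonic, one complete intron inside, in frame (6 exonic nt)
    p = run(coding_model, "GEN1.1(T1.1):c.13_18del")
    assert "fusion_exon" in p.flags
    assert p.observed_protein is not None
    assert p.p_description == "p.(Phe5_Cys6del)"


def test_deletion_with_intronic_ends_removes_whole_exons(coding_model):
    # intron1 into intron2: the whole (in-frame, 18 nt) middle exon goes
    p = run(coding_model, "GEN1.1(T1.1):c.15+3_33+4del")
    assert "exons_removed" in p.flags
    obs = p.observed_protein
    assert obs is not None and len(obs) == len(p.reference_protein) - 6
    assert p.p_description.endswith("del)")


def test_variant_outside_the_transcript_is_silent(coding_model):
    p = run(coding_model, "GEN1.1:g.3del")
    assert p.p_description == "p.(=)"
    assert p.observed_protein == p.reference_protein


def test_silent_exonic_substitution_gives_protein_identity(coding_model):
    # find a synonymous third-base change
    from hgvscanon.protein_effects import _CODON_TABLE
    g = coding_model.sequence
    tx = g[13:28] + g[40:58] + g[70:85]
    for ci in range(1, len(tx) // 3 - 1):
        codon = tx[3 * ci:3 * ci + 3]
        for b in "ACGT":
            if b != codon[2] and _CODON_TABLE[codon[:2] + b] == \
                    _CODON_TABLE[codon]:
                p = run(coding_model,
                        f"GEN1.1(T1.1):c.{3 * ci + 3}{codon[2]}>{b}")
                assert p.p_description == "p.(=)"
                return
    pytest.fail("fixture offers no synonymous substitution")


def test_frameshift_reports_distance_to_new_stop(coding_model):
    p = run(coding_model, "GEN1.1(T1.1):c.5del")
    assert "fsTer" in p.p_description
    # verify the printed stop distance against a direct translation
    obs = p.observed_protein
    ref = p.reference_protein
    i = next(k for k, (x, y) in enumerate(zip(ref + "$", obs + "$"))
             if x != y)
    suffix = p.p_description.split("fsTer")[1].rstrip(")")
    if suffix != "?":
        assert int(suffix) == len(obs) - i + 1


def test_variant_covering_the_start_codon_is_unknown_effect(coding_model):
    p = run(coding_model, "GEN1.1(T1.1):c.1_2del")
    assert p.p_description == "p.?"
    assert [w.code for w in p.warnings] == ["WSTART"]


def test_other_transcripts_get_the_other_splice_code(coding_model):
    ivs, diags = check_description(
        parse_description("GEN1.1(T1.1):c.10_15+5del"), coding_model)
    assert diags.ok
    t = coding_model.transcripts[0]
    p_own = predict_protein(ivs, t, coding_model, is_selector=True)
    p_other = predict_protein(ivs, t, coding_model, is_selector=False)
    assert [w.code for w in p_own.warnings] == ["WSPLICE"]
    assert [w.code for w in p_other.warnings] == ["WSPLICE_OTHER"]


def test_minus_strand_prediction_uses_transcript_orientation():
    minus = build_coding_model(seed=9, strand="-",
                               exons=((12, 30), (42, 60), (72, 90)),
                               cds=(15, 87))
    cds = build_cds(minus.transcripts[0], minus.sequence)
    assert cds.startswith("ATG")
    # substitute the second base of codon 2 (c.5), stated in transcript
    # orientation; the predicted change must land on residue 2
    old = cds[4]
    new = "A" if old != "A" else "C"
    p = run(minus, f"GEN1.1(T1.1):c.5{old}>{new}")
    assert p.p_description.startswith("p.(") and "2" in p.p_description


def test_prediction_is_total_over_admitted_variants():
    """No admitted variant may crash prediction (random stress)."""
    rng = random.Random(31)
    model = build_coding_model()
    for _ in range(400):
        d = random_valid_allele(rng, model.sequence)
        d = d.__class__(model.id, "g", d.variants, is_allele=d.is_allele)
        report = normalize(d, model)
        if not report.ok:
            continue
        for p in report.proteins:
            assert p.p_description
            if "splice_omitted" in p.flags or "start_codon" in p.flags:
                assert p.observed_protein is None
                assert p.p_description == "p.?"


def test_whole_intron_deletion_frame_rule(coding_model):
    """Fusion deletions keep the frame iff the exonic loss is 0 mod 3."""
    # c.13_18del removes 6 exonic nt -> in frame
    p = run(coding_model, "GEN1.1(T1.1):c.13_18del")
    assert "fsTer" not in p.p_description
    # c.13_17del removes 5 exonic nt -> frameshift
    p = run(coding_model, "GEN1.1(T1.1):c.13_17del")
    assert "fsTer" in p.p_description or p.p_description.endswith("Ter)")


# ---------------------------------------------------------------------------
# protein change descriptions


@pytest.mark.parametrize("ref, obs, want", [
    ("MAYG*", "MAYG*", "p.(=)"),
    ("MAYG*", "MACG*", "p.(Tyr3Cys)"),
    ("MAYG*", "MAG*", "p.(Tyr3del)"),
    ("MAYG*", "MAYTG*", "p.(Tyr3_Gly4insThr)"),
    ("MAYG*", "MA*", "p.(Tyr3Ter)"),
    ("MAYGKL*", "MAYHHH", "p.(Gly4HisfsTer?)"),
])
def test_describe_protein_change_forms(ref, obs, want):
    assert describe_protein_change(ref, obs) == want


def test_describe_frameshift_counts_to_the_observed_stop():
    assert describe_protein_change("MAYGKL*", "MAYHH*",
                                   frameshift=True) == "p.(Gly4HisfsTer3)"


# ---------------------------------------------------------------------------
# restriction sites


def test_substitution_creating_ecori_site():
    #       GAATTA -> GAATTC
    ref = "TTTGAATTATTT"
    changes = restriction_changes(ref, [InternalVariant(8, 9, "C")])
    assert "EcoRI" in changes[0].added
    assert "EcoRI" not in changes[0].removed


def test_deletion_destroying_bamhi_site():
    ref = "AAAGGATCCTTT"
    changes = restriction_changes(ref, [InternalVariant(5, 6)])
    assert "BamHI" in changes[0].removed


def test_variant_in_pattern_free_context_reports_nothing():
    changes = restriction_changes("TTTTTTTTTT", [InternalVariant(4, 5, "A")])
    assert changes[0].added == () and changes[0].removed == ()


def test_removed_and_added_are_disjoint_under_fuzzing():
    rng = random.Random(17)
    table = load_enzyme_table()
    assert table, "built-in enzyme table must not be empty"
    for _ in range(200):
        ref = random_sequence(rng, 60)
        s = rng.randrange(1, 50)
        e = min(60, s + rng.randrange(0, 6))
        alt = random_sequence(rng, rng.randrange(0, 6))
        if s == e and not alt:
            continue
        (change,) = restriction_changes(ref, [InternalVariant(s, e, alt)])
        assert not set(change.removed) & set(change.added)
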