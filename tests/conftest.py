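"""Shared fixtures: hand-built reference models and random generators."""

import random

import pytest

from hgvscanon import ReferenceModel
from hgvscanon.coordinates import TranscriptLayout
from hgvscanon.grammar import (Description, ElementaryVariant, HgvsLocation,
                               HgvsPoint)
from hgvscanon.reference_model import AnnotatedTranscript, demo_reference


@pytest.fixture
def aacgtaa():
    """The 7 nt reference the disambiguation examples run on."""
    return ReferenceModel(id="R1.1", sequence="AACGTAA")


@pytest.fixture
def demo_model():
    return demo_reference()


def build_coding_model(seed=3, n=100,
                       exons=((10, 28), (40, 58), (70, 88)),
                       cds=(13, 85), strand="+"):
    """Deterministic single-transcript genomic model with a clean ORF:
    ATG start, one terminal stop, no internal in-frame stop."""
    rng = random.Random(seed)
    seq = [rng.choice("ACGT") for _ in range(n)]
    layout = TranscriptLayout(exons=exons, strand=strand, cds=cds)
    tx_pos = []
    for s, e in layout.exons_tx():
        r = range(s, e) if strand == "+" else range(e - 1, s - 1, -1)
        tx_pos.extend(r)
    cds_lo = min(p for p in tx_pos if cds[0] <= p < cds[1])
    cds_pos = [p for p in tx_pos if cds[0] <= p < cds[1]]
    assert len(cds_pos) % 3 == 0, "fixture CDS must be in frame"
    comp = str.maketrans("ACGT", "TGCA")

    def write(codon_positions, codon):
        if strand == "-":
            codon = codon.translate(comp)[::-1]
            for p, b in zip(sorted(codon_positions), codon):
                seq[p] = b
        else:
            for p, b in zip(codon_positions, codon):
                seq[p] = b

    def read(codon_positions):
        if strand == "-":
            return "".join(seq[p] for p in sorted(codon_positions)
                           ).translate(comp)[::-1]
        return "".join(seq[p] for p in codon_positions)

    write(cds_pos[:3], "ATG")
    write(cds_pos[-3:], "TAA")
    for c in range(3, len(cds_pos) - 3, 3):
        while read(cds_pos[c:c + 3]) in ("TAA", "TAG", "TGA"):
            write(cds_pos[c:c + 3],
                  "".join(rng.choice("ACGT") for _ in range(3)))
    t = AnnotatedTranscript("T1.1", layout, protein_id="P1.1")
    return ReferenceModel(id="GEN1.1", sequence="".join(seq), transcripts=[t])


@pytest.fixture
def coding_model():
    return build_coding_model()


@pytest.fixture
def coding_model_minus():
    return build_coding_model(seed=5, strand="-")


# ---------------------------------------------------------------------------
# random structural Description generator (grammar round trips)


def random_point(rng, system):
    if system in "gm":
        return HgvsPoint(rng.randrange(1, 500))
    anchors = ["plain"] * 3 + (["upstream", "downstream"] if system == "c"
                               else ["upstream"])
    anchor = rng.choice(anchors)
    offset = fuzzy = None
    r = rng.random()
    if r < 0.25:
        offset = rng.choice([-1, 1]) * rng.randrange(1, 50)
    elif r < 0.32:
        fuzzy = rng.choice("+-")
    return HgvsPoint(rng.randrange(1, 500), anchor, offset, fuzzy)


def random_structural_variant(rng, system):
    op = rng.choice(["substitution", "del", "dup", "ins", "inv", "delins"])
    p1 = random_point(rng, system)
    if op == "substitution":
        return ElementaryVariant(HgvsLocation.point(p1), op,
                                 ref_stated=rng.choice("ACGT"),
                                 alt=rng.choice("ACGT"))
    if op == "ins" or rng.random() > 0.4:
        loc = HgvsLocation(p1, random_point(rng, system))
    else:
        loc = HgvsLocation.point(p1)
    seq = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 8)))
    kwargs = {}
    if op in ("del", "dup", "inv", "delins"):
        r = rng.random()
        if r < 0.2:
            kwargs["ref_stated"] = "".join(
                rng.choice("ACGTN") for _ in range(rng.randrange(1, 5)))
        elif r < 0.4:
            kwargs["ref_stated_length"] = rng.randrange(1, 20)
    if op in ("ins", "delins"):
        kwargs["alt"] = seq
    return ElementaryVariant(loc, op, **kwargs)


def random_description(rng):
    system = rng.choice("gcnm")
    nv = rng.choice([0, 1, 1, 1, 2, 3])
    vs = tuple(random_structural_variant(rng, system) for _ in range(nv))
    return Description(
        reference_id=rng.choice(["NG_012337.1", "NM_000059", "R1",
                                 "LRG_199t1"]),
        system=system, variants=vs,
        selector_id=rng.choice([None, "NM_000059.3"]),
        is_allele=len(vs) > 1)


# ---------------------------------------------------------------------------
# random semantically valid g. alleles on a given reference


def random_valid_allele(rng, ref, max_variants=3):
    """(Description, spans) with pairwise well-separated variants."""
    n = len(ref)
    vs, spans = [], []
    for _ in range(rng.randrange(1, max_variants + 1)):
        op = rng.choice(["substitution", "del", "dup", "ins", "inv",
                         "delins"])
        if op == "ins":
            a = rng.randrange(1, n)
            span = (a, a + 1)
            v = ElementaryVariant(
                HgvsLocation(HgvsPoint(a), HgvsPoint(a + 1)), op,
                alt="".join(rng.choice("ACGT")
                            for _ in range(rng.randrange(1, 5))))
        else:
            a = rng.randrange(1, n + 1)
            b = min(n, a + rng.randrange(0, 5))
            span = (a, b)
            loc = HgvsLocation.point(HgvsPoint(a)) if a == b \
                else HgvsLocation(HgvsPoint(a), HgvsPoint(b))
            if op == "substitution":
                if a != b:
                    continue
                v = ElementaryVariant(loc, op, ref_stated=ref[a - 1],
                                      alt=rng.choice("ACGT"))
            elif op == "delins":
                v = ElementaryVariant(loc, op, alt="".join(
                    rng.choice("ACGT") for _ in range(rng.randrange(1, 6))))
            else:
                v = ElementaryVariant(loc, op)
        if any(not (span[1] < s0 - 1 or span[0] > s1 + 1)
               for s0, s1 in spans):
            continue
        spans.append(span)
        vs.append(v)
    if not vs:
        vs = [ElementaryVariant(HgvsLocation.point(HgvsPoint(1)),
                                "substitution", ref_stated=ref[0], alt="T")]
    return Description("R.1", "g", tuple(vs), is_allele=len(vs) > 1)


def random_sequence(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))
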