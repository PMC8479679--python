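"""Protein-level consequence prediction and restriction-site change tables.

Prediction takes the safe road around splice sites: if any variant endpoint
falls inside an intron without the variant spanning that intron completely,
translation is omitted and ``p.?`` is reported with a splice warning
(``WSPLICE`` for the transcript the description used, ``WSPLICE_OTHER`` for
any other annotated transcript).  Two deletion geometries are still
predicted: a deletion with both breakpoints in exons that spans one or more
introns is interpreted as forming a fusion exon, and a deletion with
intronic breakpoints that covers complete exons removes those exons from
the transcript before translation.  Variants covering the translation start
site yield ``p.?`` with a warning.

Predicted descriptions are always parenthesized (``p.(...)``) with
three-letter amino-acid codes, since they are predictions rather than
experimentally observed changes.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

from .apply_engine import InternalVariant, apply_variants
from .coordinates import TranscriptLayout
from .diagnostics import Diagnostic
from .reference_model import AnnotatedTranscript, ReferenceModel
from .sequences import reverse_complement

# standard genetic code
_CODON_TABLE: Dict[str, str] = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter", "X": "Xaa",
}


def aa3(seq: str) -> str:
    """One-letter amino acids -> three-letter codes."""
    return "".join(_AA3.get(a, "Xaa") for a in seq)


def translate(cds: str, include_stop: bool = False) -> str:
    """Translate with the standard genetic code, stopping at the first stop
    codon; a trailing partial codon is ignored."""
    out = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3].upper()
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*":
            if include_stop:
                out.append("*")
            break
        out.append(aa)
    return "".join(out)


def build_mrna(t: AnnotatedTranscript, genome: str) -> str:
    """Concatenate the exons; reverse-complemented for - strand."""
    mrna = "".join(genome[s:e] for s, e in t.layout.exons)
    return reverse_complement(mrna) if t.layout.strand == "-" else mrna


def build_cds(t: AnnotatedTranscript, genome: str) -> str:
    """Exonic CDS sequence in transcript orientation."""
    if t.layout.cds is None:
        raise ValueError(f"transcript {t.id} has no CDS")
    cs, ce = t.layout.cds
    parts = [genome[max(s, cs):min(e, ce)]
             for s, e in t.layout.exons if min(e, ce) > max(s, cs)]
    seq = "".join(parts)
    return reverse_complement(seq) if t.layout.strand == "-" else seq


@dataclass
class ProteinPrediction:
    transcript_id: str
    reference_protein: str
    observed_protein: Optional[str]
    p_description: str
    flags: frozenset = frozenset()
    warnings: List[Diagnostic] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "transcript": self.transcript_id,
            "p": self.p_description,
            "reference_protein": self.reference_protein,
            "observed_protein": self.observed_protein,
            "flags": sorted(self.flags),
        }


@dataclass(frozen=True)
class RestrictionChange:
    variant_index: int
    removed: Tuple[str, ...]
    added: Tuple[str, ...]


# ---------------------------------------------------------------------------
# geometry classification


def _regions(layout: TranscriptLayout, seq_len: int):
    lo, hi = layout.span
    out = []
    if lo > 0:
        out.append(("flank", (0, lo)))
    prev_end = None
    for s, e in layout.exons:
        if prev_end is not None:
            out.append(("intron", (prev_end, s)))
        out.append(("exon", (s, e)))
        prev_end = e
    if hi < seq_len:
        out.append(("flank", (hi, seq_len)))
    return out


def _region_of(regions, pos: int) -> Tuple[str, Tuple[int, int]]:
    for kind, (s, e) in regions:
        if s <= pos < e:
            return kind, (s, e)
    return "flank", (pos, pos + 1)


def _start_codon_interval(layout: TranscriptLayout) -> Tuple[int, int]:
    cs, ce = layout.cds
    if layout.strand == "+":
        return cs, min(cs + 3, ce)
    return max(ce - 3, cs), ce


def classify_variant(iv: InternalVariant, layout: TranscriptLayout,
                     seq_len: int) -> str:
    """Geometry class of one variant against a transcript layout:
    ``start`` | ``splice`` | ``fusion`` | ``exons_removed`` | ``normal``."""
    if layout.cds is not None:
        ss, se = _start_codon_interval(layout)
        if iv.start < se and iv.end > ss:
            return "start"
        if iv.is_insertion and ss < iv.start < se:
            return "start"
    regions = _regions(layout, seq_len)
    if iv.is_insertion:
        left = _region_of(regions, iv.start - 1)[0] if iv.start > 0 else "flank"
        right = _region_of(regions, iv.start)[0] if iv.start < seq_len \
            else "flank"
        if "intron" in (left, right):
            return "splice"
        return "normal"
    k1, r1 = _region_of(regions, iv.start)
    k2, r2 = _region_of(regions, iv.end - 1)
    if k1 != "intron" and k2 != "intron":
        if r1 == r2:
            return "normal"
        if k1 == "exon" and k2 == "exon" and iv.alt == "":
            return "fusion"  # deletion joining two exon remainders
        return "splice"
    if k1 == "intron" and k2 == "intron" and r1 != r2 and iv.alt == "":
        # complete exons lie between the two intronic breakpoints
        return "exons_removed"
    return "splice"


# ---------------------------------------------------------------------------
# observed transcript construction


def _observed_mrna(variants: Sequence[InternalVariant],
                   layout: TranscriptLayout, genome: str,
                   ) -> Tuple[str, Optional[int]]:
    """Observed mRNA plus the index of the CDS start base within it.

    Works by classifying every observed base (kept reference bases and
    inserted bases) as exonic or not; exon boundaries thereby adjust to
    length changes, fused exons join seamlessly and removed exons vanish.
    """
    ordered = sorted(variants, key=lambda v: (v.start, v.end))
    regions = _regions(layout, len(genome))
    cs, ce = layout.cds if layout.cds else (None, None)
    start_base = None
    if layout.cds:
        start_base = cs if layout.strand == "+" else ce - 1

    def exonic(pos: int) -> bool:
        return _region_of(regions, pos)[0] == "exon"

    chunks: List[Tuple[str, bool]] = []  # (text, is_exonic)
    pos = 0
    for v in ordered:
        if pos < v.start:
            _emit_ref(chunks, genome, pos, v.start, exonic)
        if v.alt:
            # inserted bases inherit the exonic status of their surroundings
            if v.is_insertion:
                ins_exonic = v.start > 0 and exonic(v.start - 1) and \
                    (v.start >= len(genome) or exonic(v.start))
            else:
                ins_exonic = exonic(v.start) and exonic(v.end - 1)
            chunks.append((v.alt, ins_exonic))
        pos = v.end
    if pos < len(genome):
        _emit_ref(chunks, genome, pos, len(genome), exonic)
    mrna = "".join(text for text, is_ex in chunks if is_ex)

    start_idx = None
    if start_base is not None:
        start_idx = _index_of_base(ordered, regions, genome, start_base)
    if layout.strand == "-":
        mrna = reverse_complement(mrna)
        if start_idx is not None:
            start_idx = len(mrna) - 1 - start_idx
    return mrna, start_idx


def _emit_ref(chunks, genome, start, end, exonic):
    i = start
    while i < end:
        j = i
        flag = exonic(i)
        while j < end and exonic(j) == flag:
            j += 1
        chunks.append((genome[i:j], flag))
        i = j


def _index_of_base(ordered, regions, genome, target: int) -> Optional[int]:
    """Index of reference base ``target`` among observed exonic bases
    (genomic order), or None if it was deleted."""
    def exonic(pos: int) -> bool:
        return _region_of(regions, pos)[0] == "exon"

    idx = 0
    pos = 0
    for v in ordered:
        for p in range(pos, v.start):
            if exonic(p):
                if p == target:
                    return idx
                idx += 1
        if v.start <= target < v.end:
            return None  # deleted
        if v.alt:
            if v.is_insertion:
                ins_exonic = v.start > 0 and exonic(v.start - 1) and \
                    (v.start >= len(genome) or exonic(v.start))
            else:
                ins_exonic = exonic(v.start) and exonic(v.end - 1)
            if ins_exonic:
                idx += len(v.alt)
        pos = v.end
    for p in range(pos, len(genome)):
        if exonic(p):
            if p == target:
                return idx
            idx += 1
    return None


# ---------------------------------------------------------------------------
# prediction


def predict_protein(variants: Sequence[InternalVariant],
                    t: AnnotatedTranscript, model: ReferenceModel,
                    is_selector: bool = True) -> ProteinPrediction:
    """Predict the protein consequence of canonical variants on transcript
    ``t``; total over everything the semantic check admits."""
    layout = t.layout
    genome = model.sequence
    splice_code = "WSPLICE" if is_selector else "WSPLICE_OTHER"
    warnings: List[Diagnostic] = []
    flags = set()

    ref_cds = build_cds(t, genome)
    if len(ref_cds) % 3:
        warnings.append(Diagnostic(
            "warning", "WCDSLENGTH",
            f"CDS of {t.id} is not a multiple of 3; translation truncated"))
    ref_protein = translate(ref_cds, include_stop=True)

    classes = [classify_variant(v, layout, len(genome)) for v in variants]
    if "start" in classes:
        warnings.append(Diagnostic(
            "warning", "WSTART",
            f"variant covers the translation start site of {t.id}"))
        return ProteinPrediction(t.id, ref_protein.rstrip("*"), None, "p.?",
                                 frozenset({"start_codon"}), warnings)
    if "splice" in classes:
        warnings.append(Diagnostic(
            "warning", splice_code,
            f"variant hits a splice site of {t.id}; protein prediction "
            f"omitted"))
        return ProteinPrediction(t.id, ref_protein.rstrip("*"), None, "p.?",
                                 frozenset({"splice_omitted"}), warnings)
    if "fusion" in classes:
        flags.add("fusion_exon")
        warnings.append(Diagnostic(
            "warning", splice_code,
            f"deletion spans an intron of {t.id}; interpreted as a fusion "
            f"exon"))
    if "exons_removed" in classes:
        flags.add("exons_removed")
        warnings.append(Diagnostic(
            "warning", splice_code,
            f"deletion removes complete exons of {t.id}"))

    # observed translation: from the CDS start through the rest of the mRNA,
    # so frameshifts run on into the 3' region until a stop is found
    mrna, start_idx = _observed_mrna(variants, layout, genome)
    ref_mrna, ref_start_idx = _observed_mrna([], layout, genome)
    if start_idx is None or ref_start_idx is None:
        return ProteinPrediction(t.id, ref_protein.rstrip("*"), None, "p.?",
                                 frozenset(flags | {"start_codon"}), warnings)
    obs_protein = translate(mrna[start_idx:], include_stop=True)
    ref_protein_full = translate(ref_mrna[ref_start_idx:], include_stop=True)
    frameshift = _cds_length_delta(variants, layout) % 3 != 0
    p_desc = describe_protein_change(ref_protein_full, obs_protein,
                                     frameshift=frameshift)
    return ProteinPrediction(t.id, ref_protein_full.rstrip("*"),
                             obs_protein.rstrip("*"), p_desc,
                             frozenset(flags), warnings)


def _cds_length_delta(variants: Sequence[InternalVariant],
                      layout: TranscriptLayout) -> int:
    """Net change in exonic CDS length; non-zero mod 3 means a frameshift."""
    cs, ce = layout.cds
    delta = 0
    for v in variants:
        removed = 0
        for es, ee in layout.exons:
            lo, hi = max(v.start, es, cs), min(v.end, ee, ce)
            if hi > lo:
                removed += hi - lo
        added = 0
        if v.alt:
            if v.is_insertion:
                if cs < v.start < ce and any(
                        es < v.start < ee for es, ee in layout.exons):
                    added = len(v.alt)
            elif removed:
                added = len(v.alt)
        delta += added - removed
    return delta


def describe_protein_change(ref_protein: str, obs_protein: str,
                            frameshift: Optional[bool] = None) -> str:
    """First-difference p. description between two (possibly ``*``-terminated)
    proteins: ``p.(=)``, substitution, in-frame del/ins/delins, or the
    frameshift form with the distance to the next stop.

    ``frameshift`` marks whether the underlying DNA change shifted the
    reading frame; when unknown it is inferred from the protein shapes.
    """
    if ref_protein == obs_protein:
        return "p.(=)"
    i = 0
    while i < min(len(ref_protein), len(obs_protein)) and \
            ref_protein[i] == obs_protein[i]:
        i += 1
    # first changed residue is a stop: Ter form, whatever follows
    if i < len(obs_protein) and obs_protein[i] == "*":
        return f"p.({aa3(ref_protein[i])}{i + 1}Ter)"
    a, b = ref_protein[i:], obs_protein[i:]
    j = 0
    while j < min(len(a), len(b)) and a[len(a) - 1 - j] == b[len(b) - 1 - j]:
        j += 1
    ref_seg = a[:len(a) - j]
    obs_seg = b[:len(b) - j]

    if frameshift is None:
        frameshift = j == 0 and len(ref_protein) != len(obs_protein)
    if not frameshift:
        if len(ref_seg) == 1 and len(obs_seg) == 1:
            return f"p.({aa3(ref_seg)}{i + 1}{aa3(obs_seg)})"
        if obs_seg == "":
            first = f"{aa3(ref_seg[0])}{i + 1}"
            if len(ref_seg) == 1:
                return f"p.({first}del)"
            last = f"{aa3(ref_seg[-1])}{i + len(ref_seg)}"
            return f"p.({first}_{last}del)"
        if ref_seg == "" and i >= 1:
            left = f"{aa3(ref_protein[i - 1])}{i}"
            right = f"{aa3(ref_protein[i])}{i + 1}"
            return f"p.({left}_{right}ins{aa3(obs_seg)})"
        first = f"{aa3(ref_seg[0])}{i + 1}"
        if len(ref_seg) == 1:
            return f"p.({first}delins{aa3(obs_seg)})"
        last = f"{aa3(ref_seg[-1])}{i + len(ref_seg)}"
        return f"p.({first}_{last}delins{aa3(obs_seg)})"

    # frameshift: new reading frame from the first changed residue
    ref_aa = aa3(ref_protein[i]) if i < len(ref_protein) else "Ter"
    if i >= len(obs_protein):
        return f"p.({ref_aa}{i + 1}Ter)"
    obs_aa = aa3(obs_protein[i])
    if obs_protein.endswith("*"):
        ter = len(obs_protein) - i
        return f"p.({ref_aa}{i + 1}{obs_aa}fsTer{ter})"
    return f"p.({ref_aa}{i + 1}{obs_aa}fsTer?)"


# ---------------------------------------------------------------------------
# restriction sites

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
    "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
    "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(_IUPAC[b] for b in pattern) + "))")


def load_enzyme_table() -> Dict[str, str]:
    """Built-in table of common restriction enzymes (name -> IUPAC site)."""
    table = {}
    with resources.files("hgvscanon.data").joinpath(
            "restriction_enzymes.tsv").open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0]] = row[1].upper()
    return table


def _count_sites(seq: str, regexes: Dict[str, re.Pattern]) -> Dict[str, int]:
    return {name: len(rx.findall(seq)) for name, rx in regexes.items()}


def restriction_changes(reference: str,
                        variants: Sequence[InternalVariant],
                        enzymes: Optional[Dict[str, str]] = None,
                        ) -> List[RestrictionChange]:
    """Per-variant removed/added restriction sites.

    Sites are counted in a window of the variant span extended by
    (longest pattern - 1) on both sides, in the reference and in the
    observed sequence of that single variant.
    """
    table = enzymes if enzymes is not None else load_enzyme_table()
    if not table:
        raise ValueError("enzyme table is empty")
    regexes = {name: _pattern_regex(p) for name, p in table.items()}
    margin = max(len(p) for p in table.values()) - 1
    out = []
    for idx, v in enumerate(variants):
        lo = max(0, v.start - margin)
        hi = min(len(reference), v.end + margin)
        ref_win = reference[lo:hi]
        obs_win = (reference[lo:v.start] + v.alt + reference[v.end:hi])
        before = _count_sites(ref_win, regexes)
        after = _count_sites(obs_win, regexes)
        removed = tuple(sorted(n for n in table if before[n] > after[n]))
        added = tuple(sorted(n for n in table if after[n] > before[n]))
        out.append(RestrictionChange(idx, removed, added))
    return out
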