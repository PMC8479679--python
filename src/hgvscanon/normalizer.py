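"""Disambiguation of validated variants into the canonical HGVS description.

The pipeline per elementary variant is

    trim -> simplify -> 3' roll -> dup detection -> relabel

* **trim** narrows a delins by removing the longest common prefix and then
  the longest common suffix of the deleted and inserted sequences; an
  inversion is narrowed symmetrically where its leading bases equal the
  complement of its trailing bases (partial palindrome).
* **simplify** relabels to the simplest equivalent type (delins -> del /
  ins / substitution / inv / dup; inv of length 1 -> substitution).
* **3' roll** shifts deletions and insertions to the most 3' equivalent
  position by walking circular permutations of the deleted/inserted
  sequence.  On reverse-strand transcripts the transcript 3' direction is
  the genomic 5' direction.  For c./n. descriptions the shift never crosses
  a splice site: the rolling window is the single exon or intron containing
  the variant; g. descriptions roll unbounded.
* **dup detection** turns an insertion equal to the immediately preceding
  (transcript 5') reference segment into a duplication.

Adjacent variants are never merged: elementary variants are treated
independently.  Each applied rule is recorded as a correction entry, and the
canonical output applied to the reference always reproduces the same
observed sequence as the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

from . import coordinates as coords
from .apply_engine import InternalVariant
from .diagnostics import Diagnostics
from .grammar import (Description, ElementaryVariant, format_description,
                      format_variant)
from .reference_model import ReferenceModel
from .semantics import CheckedVariant, analyze
from .sequences import reverse_complement


# ---------------------------------------------------------------------------
# elementary steps


def trim_delins(deleted: str, inserted: str,
                interval: Tuple[int, int]) -> Tuple[Tuple[int, int], str]:
    """Remove the longest common prefix, then the longest common suffix, of
    the deleted and inserted sequences; returns the narrowed interval and
    the residual insert."""
    start, end = interval
    if end - start != len(deleted):
        raise ValueError("interval length must equal the deleted sequence")
    i = 0
    while i < min(len(deleted), len(inserted)) and deleted[i] == inserted[i]:
        i += 1
    a, b = deleted[i:], inserted[i:]
    j = 0
    while j < min(len(a), len(b)) and a[len(a) - 1 - j] == b[len(b) - 1 - j]:
        j += 1
    return (start + i, end - j), inserted[i:len(inserted) - j]


def trim_inversion(segment: str, interval: Tuple[int, int]) -> Tuple[int, int]:
    """Symmetrically trim a partial palindrome off an inversion.

    The trim k is the number of leading positions i with
    ``segment[i] == complement(segment[-1 - i])``, capped at half the
    length; inverting the trimmed core yields the same observed sequence.
    """
    start, end = interval
    if end - start != len(segment):
        raise ValueError("interval length must equal the segment")
    rc = reverse_complement(segment)
    k = 0
    while k < len(segment) // 2 and segment[k] == rc[k]:
        k += 1
    return start + k, end - k


def simplify(variant: InternalVariant,
             reference: str) -> Tuple[InternalVariant, str]:
    """Relabel an already-trimmed variant with the simplest equivalent type."""
    deleted = reference[variant.start:variant.end]
    alt = variant.alt
    if deleted == alt:
        return variant, "identity"
    if alt == "":
        return variant, "del"
    if deleted == "":
        return variant, "ins"
    if len(deleted) == 1 and len(alt) == 1:
        return variant, "substitution"
    if len(deleted) >= 2 and alt == reverse_complement(deleted):
        return variant, "inv"
    return variant, "delins"


def roll_3prime(variant: InternalVariant, reference: str,
                direction: str = "forward",
                barrier: Optional[Tuple[int, int]] = None) -> InternalVariant:
    """Shift a deletion or insertion to the most 3' equivalent position.

    ``direction`` is the transcript 3' direction in genomic terms: "forward"
    shifts right, "reverse" shifts left (reverse-strand transcripts).  The
    variant never leaves ``barrier`` (a half-open interval; defaults to the
    whole sequence).  Insertions come back with their circularly permuted
    insert.
    """
    lo, hi = barrier if barrier is not None else (0, len(reference))
    s, e, alt = variant.start, variant.end, variant.alt
    if s == e and alt:  # insertion
        L = len(alt)
        if direction == "forward":
            k = 0
            while s + k < hi and reference[s + k] == alt[k % L]:
                k += 1
            r = k % L
            return InternalVariant(s + k, s + k, alt[r:] + alt[:r])
        k = 0
        while s - 1 - k >= lo and reference[s - 1 - k] == alt[-1 - (k % L)]:
            k += 1
        r = k % L
        new = alt[-r:] + alt[:-r] if r else alt
        return InternalVariant(s - k, s - k, new)
    if alt == "" and e > s:  # deletion
        if direction == "forward":
            k = 0
            while e + k < hi and reference[e + k] == reference[s + k]:
                k += 1
            return InternalVariant(s + k, e + k)
        k = 0
        while s - 1 - k >= lo and reference[s - 1 - k] == reference[e - 1 - k]:
            k += 1
        return InternalVariant(s - k, e - k)
    return variant


def detect_dup(variant: InternalVariant, reference: str,
               direction: str = "forward",
               ) -> Tuple[InternalVariant, Optional[Tuple[int, int]]]:
    """If an (already rolled) insertion equals the reference segment on its
    transcript-5' side, relabel it as a duplication of that segment.

    Returns the variant unchanged plus the duplicated interval, or
    ``(variant, None)`` when it stays an insertion.
    """
    if not variant.is_insertion:
        return variant, None
    s, alt = variant.start, variant.alt
    L = len(alt)
    if direction == "forward":
        if s - L >= 0 and reference[s - L:s] == alt:
            return variant, (s - L, s)
    else:
        if s + L <= len(reference) and reference[s:s + L] == alt:
            return variant, (s, s + L)
    return variant, None


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class NormalizationReport:
    input: Description
    canonical: Optional[Description]
    diagnostics: Diagnostics
    equivalent_g: Optional[Description] = None
    internal_variants: List[InternalVariant] = field(default_factory=list)
    proteins: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.diagnostics.ok

    def to_dict(self) -> dict:
        return {
            "input": format_description(self.input),
            "canonical": (format_description(self.canonical)
                          if self.canonical else None),
            "equivalent_g": (format_description(self.equivalent_g)
                             if self.equivalent_g else None),
            "diagnostics": self.diagnostics.to_list(),
            "proteins": [p.to_dict() for p in self.proteins],
        }


def _rolling_barrier(iv: InternalVariant, layout, system: str,
                     seq_len: int, direction: str) -> Tuple[int, int]:
    """Splice-site barrier for c./n. descriptions: the window between the
    splice sites around the variant.  Transcript ends are not splice sites,
    so the terminal windows include the flanks; g. descriptions roll over
    the whole sequence."""
    if system in ("g", "m") or layout is None or layout.is_intronless:
        return 0, seq_len
    cuts = sorted({e for _, e in layout.exons[:-1]}
                  | {s for s, _ in layout.exons[1:]})
    edges = [0] + cuts + [seq_len]
    regions = list(zip(edges, edges[1:]))
    if iv.start == iv.end:  # insertion
        p = iv.start
        if p in cuts:
            return p, p  # sits on a splice site: shifting would cross it
        probe = min(max(p, 0), seq_len - 1)
        for r in regions:
            if r[0] <= probe < r[1]:
                return r
        return iv.start, iv.end
    for r in regions:
        if r[0] <= iv.start and iv.end <= r[1]:
            return r
    return iv.start, iv.end  # spans a splice site: no rolling


def fix_edge_insertion(iv: InternalVariant, label: str,
                       reference: str) -> Tuple[InternalVariant, str]:
    """An insertion flush against a sequence end has no flanking position on
    one side and cannot be written as ``a_b ins``; anchor it on the terminal
    base as a one-base delins instead."""
    if label != "ins":
        return iv, label
    if iv.start == 0:
        return InternalVariant(0, 1, iv.alt + reference[0]), "delins"
    if iv.start == len(reference):
        n = len(reference)
        return InternalVariant(n - 1, n, reference[n - 1] + iv.alt), "delins"
    return iv, label


def trim_and_simplify(checked: CheckedVariant,
                      reference: str) -> Tuple[InternalVariant, str]:
    """Stage 1 of the pipeline: minimize and relabel, no position shift."""
    iv = checked.internal
    op = checked.elementary.op
    if op in ("delins", "substitution"):
        (s, e), alt = trim_delins(reference[iv.start:iv.end], iv.alt,
                                  iv.interval)
        iv = InternalVariant(s, e, alt)
    elif op == "inv":
        s, e = trim_inversion(reference[iv.start:iv.end], iv.interval)
        iv = InternalVariant(s, e, reverse_complement(reference[s:e]))
    return simplify(iv, reference)


def roll_and_label(iv: InternalVariant, label: str, reference: str,
                   direction: str, barrier: Tuple[int, int],
                   ) -> Tuple[InternalVariant, str,
                              Optional[Tuple[int, int]]]:
    """Stage 2: 3' roll, dup detection and edge anchoring of one variant."""
    if label in ("del", "ins"):
        iv = roll_3prime(iv, reference, direction, barrier)
    dup_seg = None
    if label == "ins":
        iv, dup_seg = detect_dup(iv, reference, direction)
        if dup_seg is not None:
            label = "dup"
    iv, label = fix_edge_insertion(iv, label, reference)
    return iv, label, dup_seg


def canonicalize_variant(checked: CheckedVariant, reference: str,
                         direction: str, barrier: Tuple[int, int],
                         ) -> Tuple[InternalVariant, str,
                                    Optional[Tuple[int, int]]]:
    """Run trim -> simplify -> roll -> dup detection on one variant.

    Returns (internal variant, final op label, dup segment or None).
    """
    iv, label = trim_and_simplify(checked, reference)
    if label == "identity":
        return InternalVariant(iv.start, iv.start), "identity", None
    return roll_and_label(iv, label, reference, direction, barrier)


def serialize_variant(iv: InternalVariant, label: str,
                      dup_seg: Optional[Tuple[int, int]], reference: str,
                      system: str, layout) -> ElementaryVariant:
    """Render a canonical internal variant back into HGVS spelling."""
    minus = system in ("c", "n") and layout is not None and \
        layout.strand == "-"

    def orient(seq: str) -> str:
        return reverse_complement(seq) if minus else seq

    use_layout = layout if system in ("c", "n") else None
    if label == "substitution":
        loc = coords.interval_to_location(iv.start, iv.end, system, use_layout)
        return ElementaryVariant(loc, "substitution",
                                 ref_stated=orient(
                                     reference[iv.start:iv.end]),
                                 alt=orient(iv.alt))
    if label == "ins":
        loc = coords.interval_to_location(iv.start, iv.end, system,
                                          use_layout, insertion=True)
        return ElementaryVariant(loc, "ins", alt=orient(iv.alt))
    if label == "dup":
        s, e = dup_seg
        loc = coords.interval_to_location(s, e, system, use_layout)
        return ElementaryVariant(loc, "dup")
    if label in ("del", "inv"):
        loc = coords.interval_to_location(iv.start, iv.end, system, use_layout)
        return ElementaryVariant(loc, label)
    if label == "delins":
        loc = coords.interval_to_location(iv.start, iv.end, system, use_layout)
        return ElementaryVariant(loc, "delins", alt=orient(iv.alt))
    raise ValueError(f"cannot serialize {label!r}")


def normalize(d: Description, model: ReferenceModel,
              predict_proteins: bool = True) -> NormalizationReport:
    """Validate and disambiguate a description; never merges variants.

    On semantic errors the report carries the diagnostics and no canonical
    output.  For c./n. inputs the equivalent g. description on the same
    reference is also emitted.  Protein predictions (one per annotated
    transcript) are attached unless disabled.
    """
    result = analyze(d, model)
    diags = result.diagnostics
    if not result.ok:
        return NormalizationReport(input=d, canonical=None, diagnostics=diags)

    reference = model.sequence
    layout = result.layout
    system = result.description.system
    minus = system in ("c", "n") and layout is not None and \
        layout.strand == "-"
    direction = "reverse" if minus else "forward"
    dirsign = -1 if minus else 1

    # stage 1: trim + simplify; drop no-op variants before anyone uses them
    # as a rolling barrier
    staged = []
    for c in result.checked:
        iv, label = trim_and_simplify(c, reference)
        if label == "identity":
            diags.correction(
                "CIDENTITY",
                f"variant {format_variant(c.elementary)} does not change the "
                f"reference and was removed", c.index)
            continue
        staged.append([c, iv, label, None])

    # stage 2: roll in 3' -> 5' order so each variant is capped by the
    # *final* position of its already-rolled 3' neighbour; shifting one
    # variant across another would change the combined observed sequence
    order = sorted(range(len(staged)),
                   key=lambda k: staged[k][1].interval,
                   reverse=(direction == "forward"))
    for rank, k in enumerate(order):
        c, iv, label, _ = staged[k]
        lo, hi = _rolling_barrier(iv, layout, system, len(reference),
                                  direction)
        if rank > 0:
            neighbour = staged[order[rank - 1]][1]
            if direction == "forward":
                cap = neighbour.start
                if neighbour.start == neighbour.end:
                    cap -= 1  # never roll onto another insertion point
                hi = min(hi, cap)
            else:
                cap = neighbour.end
                if neighbour.start == neighbour.end:
                    cap += 1
                lo = max(lo, cap)
        iv, label, dup_seg = roll_and_label(iv, label, reference, direction,
                                            (lo, hi))
        staged[k] = [c, iv, label, dup_seg]

    finals: List[Tuple[InternalVariant, str, Optional[Tuple[int, int]]]] = []
    for c, iv, label, dup_seg in staged:
        elem = serialize_variant(iv, label, dup_seg, reference, system,
                                 layout)
        _record_corrections(c, iv, label, dup_seg, elem, diags)
        finals.append((iv, label, dup_seg))

    finals.sort(key=lambda f: (dirsign * _sort_pos(f)[0],
                               dirsign * _sort_pos(f)[1]))
    variants = tuple(serialize_variant(iv, label, dup_seg, reference, system,
                                       layout)
                     for iv, label, dup_seg in finals)
    canonical = Description(reference_id=result.description.reference_id,
                            system=system, variants=variants,
                            selector_id=result.description.selector_id,
                            is_allele=len(variants) > 1)
    equivalent_g = None
    if system in ("c", "n"):
        g_vars = tuple(serialize_variant(iv, label, dup_seg, reference,
                                         "g", None)
                       for iv, label, dup_seg in sorted(finals,
                                                        key=_sort_pos))
        equivalent_g = Description(
            reference_id=result.description.reference_id, system="g",
            variants=g_vars, is_allele=len(g_vars) > 1)

    report = NormalizationReport(
        input=d, canonical=canonical, diagnostics=diags,
        equivalent_g=equivalent_g,
        internal_variants=[iv for iv, _, _ in finals])

    if predict_proteins and model.transcripts:
        from .protein_effects import predict_protein
        selected = result.transcript
        for t in model.transcripts:
            if t.layout.cds is None:
                continue
            pred = predict_protein(report.internal_variants, t, model,
                                   is_selector=(selected is not None
                                                and t.id == selected.id))
            report.proteins.append(pred)
            for w in pred.warnings:
                diags.add(w)
    return report


def _sort_pos(final) -> Tuple[int, int]:
    iv, label, dup_seg = final
    if label == "dup" and dup_seg is not None:
        return dup_seg
    return iv.start, iv.end


def _record_corrections(c: CheckedVariant, iv: InternalVariant, label: str,
                        dup_seg, elem: ElementaryVariant,
                        diags: Diagnostics) -> None:
    orig = c.elementary
    orig_op = orig.op
    if orig_op == "delins" or orig_op == "inv":
        orig_iv = c.internal
        final_span = dup_seg if label == "dup" else iv.interval
        if (orig_iv.end - orig_iv.start) > (final_span[1] - final_span[0]) \
                and label in ("delins", "inv"):
            diags.correction(
                "CMINIMIZED",
                f"{format_variant(orig)} narrowed to its minimal form "
                f"{format_variant(elem)}", c.index)
    if label != orig_op:
        diags.correction(
            "CVARTYPE",
            f"variant type updated from {orig_op} to {label} "
            f"({format_variant(elem)})", c.index)
    moved = False
    if orig_op in ("del", "ins", "dup") and label in ("del", "ins", "dup"):
        if orig_op == "dup" and label == "dup":
            moved = dup_seg != c.dup_source
        else:
            moved = iv.interval != c.internal.interval
    if moved:
        diags.correction(
            "C3PRIME",
            f"{format_variant(orig)} shifted 3' to {format_variant(elem)}",
            c.index)


def normalize_text(text: str, model: ReferenceModel,
                   predict_proteins: bool = True) -> NormalizationReport:
    """Parse + normalize in one call (convenience wrapper)."""
    from .grammar import parse_description
    return normalize(parse_description(text), model,
                     predict_proteins=predict_proteins)
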