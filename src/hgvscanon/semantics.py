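"""Semantic validation of parsed descriptions against a reference model.

The check runs per variant, in a fixed order: position conversion, sequence
bounds, range order, insertion adjacency, intronic-offset validity (all via
the coordinates module), stated-length equality (``3_9del7``) and
stated-deleted-sequence equality (``10_12delAAT`` -> EREF on mismatch).
Deprecated IVS intron positions are rewritten with a correction entry, fuzzy
intronic offsets are placed at the intron center.  Stated inverted sequences
are deliberately not checked.

Variants within one allele must be sorted 5'->3' in the description's own
system; unsorted input is re-sorted with a correction entry, overlapping
variants are an error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

from . import coordinates as coords
from .apply_engine import InternalVariant, OverlapError, check_disjoint
from .coordinates import CoordinateError, TranscriptLayout
from .diagnostics import Diagnostics
from .grammar import (Description, ElementaryVariant, HgvsLocation, HgvsPoint,
                      IvsPoint)
from .reference_model import AnnotatedTranscript, ReferenceModel
from .sequences import complement, reverse_complement


@dataclass
class CheckedVariant:
    """One elementary variant after rewriting and conversion."""

    index: int                      # position in the (rewritten) description
    elementary: ElementaryVariant   # with IVS/fuzzy points made concrete
    internal: Optional[InternalVariant] = None
    dup_source: Optional[Tuple[int, int]] = None  # duplicated segment, for dup


@dataclass
class CheckResult:
    description: Description        # rewritten (concrete points, upcased)
    checked: List[CheckedVariant]
    diagnostics: Diagnostics
    layout: Optional[TranscriptLayout]
    transcript: Optional[AnnotatedTranscript]

    @property
    def ok(self) -> bool:
        return self.diagnostics.ok

    @property
    def internal_variants(self) -> List[InternalVariant]:
        return [c.internal for c in self.checked if c.internal is not None]


def _select_transcript(d: Description, model: ReferenceModel,
                       diags: Diagnostics):
    if d.selector_id is not None:
        t = model.get_transcript(d.selector_id)
        if t is None:
            diags.error("ENOSELECTOR",
                        f"transcript {d.selector_id} is not annotated on "
                        f"{model.id}")
        return t
    if d.system in ("c", "n"):
        if len(model.transcripts) == 1:
            return model.transcripts[0]
        diags.error("ENOSELECTOR",
                    f"the {d.system}. system needs a transcript selector; "
                    f"{model.id} annotates {len(model.transcripts)} transcripts")
        return None
    return model.transcripts[0] if model.transcripts else None


def _rewrite_ivs(p: IvsPoint, system: str, layout: TranscriptLayout,
                 ) -> HgvsPoint:
    """IVS<k>+m -> offset form anchored on the boundary of intron k."""
    n_introns = len(layout.exons) - 1
    if layout.is_intronless or p.intron > n_introns:
        raise coords.NoIntronError(
            f"reference has no intron {p.intron}")
    cum = coords._cum_lengths(layout)
    if p.offset > 0:  # anchored on the last base of exon k
        t = cum[p.intron] - 1
    else:             # anchored on the first base of exon k+1
        t = cum[p.intron]
    anchor = coords.point_from_axis(t, 0, system, layout)
    return replace(anchor, offset=p.offset)


def _rewrite_points(v: ElementaryVariant, system: str,
                    layout: Optional[TranscriptLayout], index: int,
                    diags: Diagnostics) -> Optional[ElementaryVariant]:
    def fix(p):
        if isinstance(p, IvsPoint):
            if layout is None:
                raise coords.NoIntronError("IVS position without a transcript")
            new = _rewrite_ivs(p, system, layout)
            diags.correction(
                "CIVS", f"deprecated intron position IVS{p.intron}"
                f"{p.offset:+d} rewritten to "
                f"{_fmt_point(new)}", index)
            return new
        if p.fuzzy is not None:
            if layout is None:
                raise coords.NoIntronError("fuzzy offset without a transcript")
            new = coords.resolve_fuzzy_offset(p, layout, system)
            diags.correction(
                "CFUZZY", f"fuzzy offset {_fmt_point(p)} interpreted at the "
                f"intron center as {_fmt_point(new)}", index)
            return new
        return p

    try:
        start = fix(v.location.start)
        end = start if v.location.is_point else fix(v.location.end)
        loc = HgvsLocation(start, end)
    except CoordinateError as exc:
        diags.error(exc.code, str(exc), index)
        return None
    return replace(v, location=loc)


def _fmt_point(p) -> str:
    from .grammar import format_point
    return format_point(p)


def analyze(d: Description, model: ReferenceModel) -> CheckResult:
    """Full semantic check; returns per-variant internal intervals plus
    ordered diagnostics.  Side-effect free and deterministic."""
    diags = Diagnostics()
    sequence = model.sequence
    transcript = _select_transcript(d, model, diags)
    layout = transcript.layout if transcript else None
    if d.system == "c" and layout is not None and layout.cds is None:
        diags.error("ENOCDS",
                    f"transcript {transcript.id} has no annotated CDS")
        layout = None
    if diags.errors:
        return CheckResult(d, [], diags, layout, transcript)

    if d.had_lowercase:
        diags.warning("WLOWERCASE", "lowercase sequence letters were upcased")

    minus = d.system in ("c", "n") and layout is not None and \
        layout.strand == "-"
    dirsign = -1 if minus else 1

    def orient(seq: str) -> str:
        return reverse_complement(seq) if minus else seq

    checked: List[CheckedVariant] = []
    rewritten: List[ElementaryVariant] = []
    for i, v0 in enumerate(d.variants):
        v = _rewrite_points(v0, d.system, layout, i, diags)
        if v is None:
            rewritten.append(v0)
            continue
        rewritten.append(v)
        if v.op == "identity":
            continue
        use_layout = layout if d.system in ("c", "n") else None
        try:
            g1 = coords.to_internal(v.location.start, d.system, use_layout)
            g2 = coords.to_internal(v.location.end, d.system, use_layout)
        except CoordinateError as exc:
            diags.error(exc.code, str(exc), i)
            continue
        out_of_bounds = False
        for g in (g1, g2):
            if not 0 <= g < len(sequence):
                diags.error("EOUTOFBOUNDS",
                            f"position maps outside the sequence "
                            f"(1..{len(sequence)})", i)
                out_of_bounds = True
                break
        if out_of_bounds:
            continue
        lo, hi = (g1, g2) if g1 <= g2 else (g2, g1)
        if not v.location.is_point and (g2 - g1) * dirsign <= 0:
            diags.error("ERANGEORDER",
                        "range end must be after the range start", i)
            continue

        if v.op == "ins":
            if (g2 - g1) * dirsign != 1:
                diags.error("EINSRANGE",
                            "insertion positions must be consecutive", i)
                continue
            iv = InternalVariant(lo + 1, lo + 1, orient(v.alt))
            checked.append(CheckedVariant(i, v, iv))
            continue

        span = hi - lo + 1
        segment = sequence[lo:hi + 1]
        if v.ref_stated_length is not None and v.ref_stated_length != span:
            diags.error("ELENGTHMISMATCH",
                        f"stated length {v.ref_stated_length} differs from "
                        f"the positional span {span}", i)
            continue
        if v.ref_stated is not None and v.op != "inv":
            # stated sequences are written in the description's orientation
            if orient(v.ref_stated) != segment:
                stated = v.ref_stated
                diags.error("EREF",
                            f"stated sequence {stated} does not match the "
                            f"reference ({orient(segment)})", i)
                continue

        if v.op == "substitution":
            if not v.location.is_point:
                diags.error("ERANGEORDER",
                            "substitution requires a single position", i)
                continue
            iv = InternalVariant(lo, hi + 1, orient(v.alt))
        elif v.op == "del":
            iv = InternalVariant(lo, hi + 1, "")
        elif v.op == "delins":
            iv = InternalVariant(lo, hi + 1, orient(v.alt))
        elif v.op == "inv":
            iv = InternalVariant(lo, hi + 1, reverse_complement(segment))
        elif v.op == "dup":
            # the copy sits transcript-3' of the duplicated segment, which
            # is the genomic-left side on reverse-strand transcripts
            point = lo if minus else hi + 1
            iv = InternalVariant(point, point, segment)
            checked.append(CheckedVariant(i, v, iv, dup_source=(lo, hi + 1)))
            continue
        else:  # pragma: no cover - parser guarantees the op set
            raise AssertionError(v.op)
        checked.append(CheckedVariant(i, v, iv))

    # 5'->3' ordering in the description's own system; duplications order by
    # their stated (duplicated) segment, not the internal insertion point
    def stated_interval(c: CheckedVariant) -> Tuple[int, int]:
        return c.dup_source if c.dup_source is not None \
            else c.internal.interval

    order = sorted(range(len(checked)),
                   key=lambda k: (dirsign * stated_interval(checked[k])[0],
                                  dirsign * stated_interval(checked[k])[1]))
    if order != list(range(len(checked))):
        diags.correction("CSORTED",
                         "variants re-sorted 5'->3' within the allele")
        checked = [checked[k] for k in order]

    try:
        check_disjoint([c.internal for c in checked])
    except OverlapError as exc:
        diags.error("EOVERLAP", str(exc))

    d2 = replace(d, variants=tuple(rewritten))
    return CheckResult(d2, checked, diags, layout, transcript)


def check_description(d: Description, model: ReferenceModel,
                      ) -> Tuple[List[InternalVariant], Diagnostics]:
    """Validate ``d`` against ``model``.

    Returns the internal variants for every variant that passed all checks
    (none for failing variants) and the full diagnostics.
    """
    result = analyze(d, model)
    return result.internal_variants, result.diagnostics
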