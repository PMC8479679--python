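"""Generate an HGVS description from a (reference, observed) sequence pair.

The decomposition anchors on the maximal equal prefix and suffix, then runs
a longest-common-subsequence alignment (difflib) over the middle.  Change
blocks separated by fewer than two matching bases are merged into a single
deletion-insertion — so, unlike the name checker proper, the extractor does
merge adjacent substitutions into a delins.  A changed block whose observed
side equals the reverse complement of its reference span is emitted as an
inversion.  Every variant then goes through the canonical per-variant
pipeline (trim, simplify, 3' roll, dup detection); when the 3' roll of one
variant is stopped only by the next variant, the two are merged and the
block is reprocessed, so the output is always already canonical.

The defining contract: applying the extracted variants to the reference
reproduces the observed sequence exactly.
"""

from __future__ import annotations

from difflib import SequenceMatcher
from typing import List, Tuple

from .apply_engine import InternalVariant
from .grammar import Description, ElementaryVariant, HgvsLocation, HgvsPoint
from .normalizer import (detect_dup, fix_edge_insertion, roll_3prime,
                         serialize_variant, simplify, trim_delins)
from .sequences import reverse_complement

#: change blocks separated by fewer than this many matching bases merge
MERGE_GAP = 2


def _raw_blocks(reference: str, observed: str) -> List[InternalVariant]:
    """Anchored LCS decomposition into disjoint change blocks."""
    # maximal equal prefix/suffix anchoring
    n = min(len(reference), len(observed))
    p = 0
    while p < n and reference[p] == observed[p]:
        p += 1
    s = 0
    while s < n - p and reference[-1 - s] == observed[-1 - s]:
        s += 1
    mid_ref = reference[p:len(reference) - s]
    mid_obs = observed[p:len(observed) - s]
    if not mid_ref and not mid_obs:
        return []
    blocks = []
    sm = SequenceMatcher(a=mid_ref, b=mid_obs, autojunk=False)
    for tag, i1, i2, j1, j2 in sm.get_opcodes():
        if tag == "equal":
            continue
        blocks.append(InternalVariant(p + i1, p + i2, mid_obs[j1:j2]))
    return blocks


def _merge(a: InternalVariant, b: InternalVariant,
           reference: str) -> InternalVariant:
    gap = reference[a.end:b.start]
    return InternalVariant(a.start, b.end, a.alt + gap + b.alt)


def _merge_close(blocks: List[InternalVariant],
                 reference: str) -> List[InternalVariant]:
    out: List[InternalVariant] = []
    for b in blocks:
        if out and b.start - out[-1].end < MERGE_GAP:
            out[-1] = _merge(out[-1], b, reference)
        else:
            out.append(b)
    return out


def extract_variants(reference: str,
                     observed: str) -> List[Tuple[InternalVariant, str,
                                                  Tuple[int, int] | None]]:
    """Canonical internal variants turning reference into observed.

    Returns (variant, op label, dup segment) triples, sorted, disjoint, and
    stable under re-normalization.
    """
    blocks = _merge_close(_raw_blocks(reference, observed), reference)
    finals = []
    i = 0
    while i < len(blocks):
        iv = blocks[i]
        (s, e), alt = trim_delins(reference[iv.start:iv.end], iv.alt,
                                  iv.interval)
        iv = InternalVariant(s, e, alt)
        iv, label = simplify(iv, reference)
        if label == "identity":
            i += 1
            continue
        if label in ("del", "ins"):
            limit = blocks[i + 1].start if i + 1 < len(blocks) \
                else len(reference)
            rolled = roll_3prime(iv, reference, "forward", (0, limit))
            unbounded = roll_3prime(iv, reference, "forward",
                                    (0, len(reference)))
            if i + 1 < len(blocks) and unbounded.end > rolled.end:
                # the roll is capped only by the next block: merge and redo
                blocks[i] = _merge(iv, blocks[i + 1], reference)
                del blocks[i + 1]
                continue
            iv = rolled
        dup_seg = None
        if label == "ins":
            iv, dup_seg = detect_dup(iv, reference, "forward")
            if dup_seg is not None:
                label = "dup"
        iv, label = fix_edge_insertion(iv, label, reference)
        finals.append((iv, label, dup_seg))
        i += 1
    return finals


def extract(reference: str, observed: str,
            reference_id: str = "REF") -> Description:
    """HGVS g. description (local frame) of observed relative to reference."""
    if not reference or not observed:
        raise ValueError("both sequences must be non-empty")
    reference = reference.upper()
    observed = observed.upper()
    finals = extract_variants(reference, observed)
    variants = tuple(serialize_variant(iv, label, dup_seg, reference, "g",
                                       None)
                     for iv, label, dup_seg in finals)
    return Description(reference_id=reference_id, system="g",
                       variants=variants, is_allele=len(variants) > 1)
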