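"""Apply internal-coordinate variants to a reference sequence.

This is the ground truth for the rest of the package: two variant lists are
equivalent exactly when :func:`apply_variants` maps the reference to the
same observed sequence under both.  Variants are applied simultaneously, so
the list describes the difference together, not as sequential edits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple


class OverlapError(ValueError):
    """Two variants in one list touch the same reference bases."""

    code = "EOVERLAP"

    def __init__(self, a: "InternalVariant", b: "InternalVariant"):
        super().__init__(f"overlapping variants {a} and {b}")
        self.pair = (a, b)


@dataclass(frozen=True)
class InternalVariant:
    """One transformation: replace reference ``[start, end)`` with ``alt``.

    Zero-length interval + non-empty alt = insertion at that point;
    non-empty interval + empty alt = deletion.
    """

    start: int
    end: int
    alt: str = ""

    def __post_init__(self):
        if not 0 <= self.start <= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def interval(self) -> Tuple[int, int]:
        return self.start, self.end

    @property
    def is_insertion(self) -> bool:
        return self.start == self.end and bool(self.alt)

    @property
    def length_delta(self) -> int:
        return len(self.alt) - (self.end - self.start)


def check_disjoint(variants: Iterable[InternalVariant]) -> List[InternalVariant]:
    """Sort by position and raise :class:`OverlapError` on any conflict.

    Two insertions at the same point are rejected: their relative order is
    undefined.  A zero-length variant on the boundary of another interval is
    allowed.
    """
    ordered = sorted(variants, key=lambda v: (v.start, v.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise OverlapError(prev, cur)
        if cur.start == prev.start == cur.end == prev.end:
            raise OverlapError(prev, cur)
    return ordered


def apply_variants(reference: str, variants: Iterable[InternalVariant]) -> str:
    """Simultaneously replace each interval by its alt, left to right."""
    ordered = check_disjoint(variants)
    out = []
    pos = 0
    for v in ordered:
        if v.end > len(reference):
            raise ValueError(f"variant {v} outside the reference "
                             f"(length {len(reference)})")
        out.append(reference[pos:v.start])
        out.append(v.alt)
        pos = v.end
    out.append(reference[pos:])
    return "".join(out)
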