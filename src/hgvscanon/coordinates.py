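"""Strand-aware conversion between HGVS positioning systems and internal
zero-based half-open coordinates.

HGVS positioning systems have no position zero and contain several
discontinuities: in ``c.`` the positions -1 and 1 are adjacent, the first
position after the CDS is ``*1``, and intronic offsets make ``c.12``
adjacent to ``c.12+1`` rather than to ``c.13``.  On reverse-strand
transcripts the ``c.``/``n.`` axes run opposite to the genomic one (if c.1
is g.10, then c.2 is g.9).  All arithmetic in this package therefore happens
in a single canonical frame: zero-based, half-open, genomic forward
orientation.  This module is the only place where the two frames meet.

The conversion works through a *transcript axis*: an integer ``t`` that
counts exonic bases in transcript direction (0-based), extended linearly
into the 5'/3' flanks, plus an intronic offset counted in transcript
direction from an exon boundary.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Tuple

from .grammar import HgvsLocation, HgvsPoint, IvsPoint, Point


class CoordinateError(ValueError):
    """Base for coordinate conversion failures; carries a diagnostic code."""

    code = "EOUTOFBOUNDS"


class NoIntronError(CoordinateError):
    code = "ENOINTRON"


class OffsetFromBoundaryError(CoordinateError):
    code = "EOFFSETFROMBOUNDARY"


class OutOfBoundsError(CoordinateError):
    code = "EOUTOFBOUNDS"


@dataclass(frozen=True)
class TranscriptLayout:
    """Exon/CDS structure of one transcript in internal genomic coordinates.

    Exons are sorted, non-overlapping, zero-based half-open intervals in
    genomic forward orientation regardless of strand; strand is consulted
    only during conversion and rolling.
    """

    exons: Tuple[Tuple[int, int], ...]
    strand: str = "+"
    cds: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("layout needs at least one exon")
        prev = None
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval ({s}, {e})")
            if prev is not None and s < prev:
                raise ValueError("exons must be sorted and non-overlapping")
            prev = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise ValueError("CDS must lie within the exon span")

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_intronless(self) -> bool:
        return len(self.exons) == 1

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exons_tx(self) -> Tuple[Tuple[int, int], ...]:
        """Exons in transcript order (reversed for the - strand)."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Gaps between exons, genomic order."""
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))


# ---------------------------------------------------------------------------
# transcript axis <-> genomic


def _cum_lengths(layout: TranscriptLayout):
    cum = [0]
    for s, e in layout.exons_tx():
        cum.append(cum[-1] + (e - s))
    return cum


def genomic_from_axis(layout: TranscriptLayout, t: int, offset: int = 0) -> int:
    """Map transcript-axis position (``t``, ``offset``) to a genomic coordinate.

    Offsets are validated: they must anchor on the correct exon boundary in
    transcript direction and stay within the flanking intron.
    """
    exons = layout.exons_tx()
    cum = _cum_lengths(layout)
    L = cum[-1]
    fwd = layout.strand == "+"

    if offset:
        if layout.is_intronless:
            raise NoIntronError("reference has no intronic sequence")
        if not 0 <= t < L:
            raise NoIntronError("no intron beyond the transcript ends")
        i = bisect_right(cum, t) - 1
        if offset > 0:
            if t != cum[i + 1] - 1:
                raise OffsetFromBoundaryError(
                    "+offset must anchor on the last base of an exon")
            if i == len(exons) - 1:
                raise NoIntronError("no intron downstream of the last exon")
            nxt = exons[i + 1]
            ilen = (nxt[0] - exons[i][1]) if fwd else (exons[i][0] - nxt[1])
            if offset > ilen:
                raise OutOfBoundsError("offset runs past the intron")
            boundary = exons[i][1] - 1 if fwd else exons[i][0]
            return boundary + offset if fwd else boundary - offset
        else:
            if t != cum[i]:
                raise OffsetFromBoundaryError(
                    "-offset must anchor on the first base of an exon")
            if i == 0:
                raise NoIntronError("no intron upstream of the first exon")
            prv = exons[i - 1]
            ilen = (exons[i][0] - prv[1]) if fwd else (prv[0] - exons[i][1])
            if -offset > ilen:
                raise OutOfBoundsError("offset runs past the intron")
            boundary = exons[i][0] if fwd else exons[i][1] - 1
            return boundary + offset if fwd else boundary - offset

    if t < 0:  # 5' flank, transcript direction
        return exons[0][0] + t if fwd else exons[0][1] - 1 - t
    if t >= L:  # 3' flank
        d = t - (L - 1)
        return exons[-1][1] - 1 + d if fwd else exons[-1][0] - d
    i = bisect_right(cum, t) - 1
    within = t - cum[i]
    s, e = exons[i]
    return s + within if fwd else e - 1 - within


def axis_from_genomic(layout: TranscriptLayout, pos: int) -> Tuple[int, int]:
    """Map a genomic coordinate to (transcript axis, intronic offset).

    Intronic positions anchor on the nearer exon boundary; ties go to the
    5' boundary in transcript direction.
    """
    exons = layout.exons_tx()
    cum = _cum_lengths(layout)
    L = cum[-1]
    fwd = layout.strand == "+"

    for i, (s, e) in enumerate(exons):
        if s <= pos < e:
            within = (pos - s) if fwd else (e - 1 - pos)
            return cum[i] + within, 0

    lo, hi = layout.span
    if pos < lo or pos >= hi:  # flank
        if fwd:
            t = pos - exons[0][0] if pos < lo else (L - 1) + (pos - (hi - 1))
        else:
            t = exons[0][1] - 1 - pos if pos >= hi else (L - 1) + (lo - pos)
        return t, 0

    # intronic: find the flanking exons in transcript order
    for i in range(len(exons) - 1):
        a, b = exons[i], exons[i + 1]
        if fwd:
            inside = a[1] <= pos < b[0]
            d_plus, d_minus = pos - (a[1] - 1), b[0] - pos
        else:
            inside = b[1] <= pos < a[0]
            d_plus, d_minus = a[0] - pos, pos - (b[1] - 1)
        if inside:
            if d_plus <= d_minus:
                return cum[i + 1] - 1, d_plus
            return cum[i + 1], -d_minus
    raise OutOfBoundsError(f"position {pos} not mappable on this layout")


# ---------------------------------------------------------------------------
# HGVS points <-> internal


def _cds_axis_bounds(layout: TranscriptLayout) -> Tuple[int, int]:
    if layout.cds is None:
        raise CoordinateError("the c. system requires an annotated CDS")
    cs, ce = layout.cds
    first = cs if layout.strand == "+" else ce - 1
    last = ce - 1 if layout.strand == "+" else cs
    t_first, off1 = axis_from_genomic(layout, first)
    t_last, off2 = axis_from_genomic(layout, last)
    if off1 or off2:
        raise CoordinateError("CDS boundaries must be exonic")
    return t_first, t_last


def point_to_axis(p: HgvsPoint, system: str,
                  layout: Optional[TranscriptLayout]) -> int:
    """Transcript-axis index of a point's anchor (offset not applied)."""
    if system == "n":
        if p.anchor == "plain":
            return p.base - 1
        if p.anchor == "upstream":
            return -p.base
        return (layout.transcript_length - 1) + p.base  # downstream
    # system == "c"
    cds_start_t, cds_end_t = _cds_axis_bounds(layout)
    if p.anchor == "plain":
        return cds_start_t + p.base - 1
    if p.anchor == "upstream":
        return cds_start_t - p.base
    return cds_end_t + p.base  # downstream


def to_internal(p: Point, system: str,
                layout: Optional[TranscriptLayout] = None) -> int:
    """Convert an HGVS point to the zero-based forward-strand coordinate of
    the addressed nucleotide."""
    if isinstance(p, IvsPoint):
        raise CoordinateError("deprecated IVS positions must be rewritten first")
    if p.fuzzy is not None:
        raise CoordinateError("fuzzy offsets must be resolved first")
    if system in ("g", "m"):
        return p.base - 1
    if layout is None:
        raise CoordinateError(f"the {system}. system requires a transcript layout")
    t = point_to_axis(p, system, layout)
    return genomic_from_axis(layout, t, p.offset or 0)


def from_internal(pos: int, system: str,
                  layout: Optional[TranscriptLayout] = None) -> HgvsPoint:
    """Exact inverse of :func:`to_internal` for every in-bounds coordinate."""
    if system in ("g", "m"):
        if pos < 0:
            raise OutOfBoundsError("negative genomic position")
        return HgvsPoint(base=pos + 1)
    if layout is None:
        raise CoordinateError(f"the {system}. system requires a transcript layout")
    t, offset = axis_from_genomic(layout, pos)
    return point_from_axis(t, offset, system, layout)


def point_from_axis(t: int, offset: int, system: str,
                    layout: TranscriptLayout) -> HgvsPoint:
    if system == "n":
        if t >= 0:
            return HgvsPoint(base=t + 1, offset=offset or None)
        return HgvsPoint(base=-t, anchor="upstream", offset=offset or None)
    cds_start_t, cds_end_t = _cds_axis_bounds(layout)
    if t < cds_start_t:
        return HgvsPoint(base=cds_start_t - t, anchor="upstream",
                         offset=offset or None)
    if t <= cds_end_t:
        return HgvsPoint(base=t - cds_start_t + 1, offset=offset or None)
    return HgvsPoint(base=t - cds_end_t, anchor="downstream",
                     offset=offset or None)


def resolve_fuzzy_offset(p: HgvsPoint, layout: TranscriptLayout,
                         system: str) -> HgvsPoint:
    """Replace a fuzzy intronic offset (``+?``/``-?``) with the intron midpoint.

    The concrete offset is floor(intron length / 2) from the anchoring exon
    boundary, with a minimum of 1; deterministic by construction.
    """
    if p.fuzzy is None:
        return p
    if layout.is_intronless:
        raise NoIntronError("reference has no intronic sequence")
    t = point_to_axis(p, system, layout)
    cum = _cum_lengths(layout)
    L = cum[-1]
    if not 0 <= t < L:
        raise NoIntronError("no intron beyond the transcript ends")
    exons = layout.exons_tx()
    i = bisect_right(cum, t) - 1
    fwd = layout.strand == "+"
    if p.fuzzy == "+":
        if t != cum[i + 1] - 1:
            raise OffsetFromBoundaryError(
                "+? must anchor on the last base of an exon")
        if i == len(exons) - 1:
            raise NoIntronError("no intron downstream of the last exon")
        nxt = exons[i + 1]
        ilen = (nxt[0] - exons[i][1]) if fwd else (exons[i][0] - nxt[1])
        off = max(1, ilen // 2)
    else:
        if t != cum[i]:
            raise OffsetFromBoundaryError(
                "-? must anchor on the first base of an exon")
        if i == 0:
            raise NoIntronError("no intron upstream of the first exon")
        prv = exons[i - 1]
        ilen = (exons[i][0] - prv[1]) if fwd else (prv[0] - exons[i][1])
        off = -max(1, ilen // 2)
    return HgvsPoint(base=p.base, anchor=p.anchor, offset=off)


# ---------------------------------------------------------------------------
# locations <-> internal intervals


def location_to_interval(loc: HgvsLocation, system: str,
                         layout: Optional[TranscriptLayout],
                         insertion: bool = False) -> Tuple[int, int]:
    """HGVS closed range -> internal half-open interval (genomic forward).

    Insertion locations ``a_b`` with adjacent a, b convert to the zero-length
    interval at the junction.
    """
    g1 = to_internal(loc.start, system, layout)
    g2 = to_internal(loc.end, system, layout)
    lo, hi = (g1, g2) if g1 <= g2 else (g2, g1)
    if insertion:
        return lo + 1, lo + 1
    return lo, hi + 1


def interval_to_location(start: int, end: int, system: str,
                         layout: Optional[TranscriptLayout],
                         insertion: bool = False) -> HgvsLocation:
    """Internal half-open interval -> HGVS closed range in transcript order."""
    if insertion or start == end:
        g1, g2 = start - 1, start
    else:
        g1, g2 = start, end - 1
    p1 = from_internal(g1, system, layout)
    p2 = from_internal(g2, system, layout)
    if system in ("c", "n") and layout is not None and layout.strand == "-":
        p1, p2 = p2, p1
    if p1 == p2:
        return HgvsLocation.point(p1)
    return HgvsLocation(p1, p2)
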