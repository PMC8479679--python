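"""Parsing and deterministic serialization of HGVS DNA variant descriptions.

A description names a reference sequence, a positioning system and a list of
elementary variants, e.g. ``NG_012337.1:g.[7G>T;14del]``.  The supported
positioning systems are ``g.`` (linear genomic), ``c.`` (coding DNA), ``n.``
(non-coding transcript) and ``m.`` (mitochondrial, handled like ``g.``
downstream).  Supported elementary operations are substitution, del, dup,
ins, inv, delins and identity (``=``).

Constructs outside this subset — repeats (``[2]``), mosaic/chimeric alleles
(``/``, ``//``), uncertainty ranges (``(100_200)``) and insertions that name
another reference — raise :class:`UnsupportedConstructError`, a distinct
subclass of the generic :class:`HgvsSyntaxError`.

Two deprecated/fuzzy constructs are parsed into dedicated forms so that the
semantic layer can rewrite them: legacy intron positions (``IVS4+1``) and
fuzzy intronic offsets (``+?``/``-?``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

SYSTEMS = frozenset("gcnm")

#: elementary variant operation labels
OPS = frozenset({"substitution", "del", "dup", "ins", "inv", "delins", "identity"})

_ACCESSION_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*(?:\.\d+)?")
_NUM_RE = re.compile(r"\d+")
_SEQ_RE = re.compile(r"[ACGTNacgtn]+")


class HgvsSyntaxError(ValueError):
    """Raised on unparsable input; carries the 0-based character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.reason = message
        self.offset = offset


class UnsupportedConstructError(HgvsSyntaxError):
    """Syntactically recognizable HGVS that is outside the supported subset."""


@dataclass(frozen=True)
class HgvsPoint:
    """One position in an HGVS positioning system.

    ``base`` is always a positive integer (HGVS has no position zero); the
    anchor distinguishes plain positions from CDS-upstream (``-base``) and
    CDS-downstream (``*base``) positions.  ``offset`` is a signed intronic
    offset; ``fuzzy`` is ``'+'`` or ``'-'`` for the fuzzy offsets ``+?``/``-?``.
    """

    base: int
    anchor: str = "plain"  # plain | upstream | downstream
    offset: Optional[int] = None
    fuzzy: Optional[str] = None

    def __post_init__(self):
        if self.base < 1:
            raise ValueError("HGVS positions are 1-based; zero/negative base")
        if self.anchor not in ("plain", "upstream", "downstream"):
            raise ValueError(f"bad anchor {self.anchor!r}")
        if self.offset is not None and self.fuzzy is not None:
            raise ValueError("point cannot have both a concrete and fuzzy offset")
        if self.offset == 0:
            raise ValueError("intronic offset zero does not exist")
        if self.fuzzy not in (None, "+", "-"):
            raise ValueError(f"bad fuzzy marker {self.fuzzy!r}")


@dataclass(frozen=True)
class IvsPoint:
    """Deprecated ``IVS<n><+/-><k>`` intronic position (1-based intron index).

    Kept distinct so the semantic layer can rewrite it to the modern offset
    form with a correction entry.
    """

    intron: int
    offset: int

    def __post_init__(self):
        if self.intron < 1 or self.offset == 0:
            raise ValueError("IVS needs a positive intron number and non-zero offset")


Point = Union[HgvsPoint, IvsPoint]


@dataclass(frozen=True)
class HgvsLocation:
    start: Point
    end: Point

    @property
    def is_point(self) -> bool:
        return self.start == self.end

    @classmethod
    def point(cls, p: Point) -> "HgvsLocation":
        return cls(p, p)


@dataclass(frozen=True)
class ElementaryVariant:
    location: HgvsLocation
    op: str
    ref_stated: Optional[str] = None
    ref_stated_length: Optional[int] = None
    alt: Optional[str] = None

    def __post_init__(self):
        if self.op not in OPS:
            raise ValueError(f"unknown operation {self.op!r}")
        if self.op == "substitution":
            if not (self.ref_stated and len(self.ref_stated) == 1
                    and self.alt and len(self.alt) == 1):
                raise ValueError("substitution needs one stated base and one alt base")
        if self.op == "ins" and not self.alt:
            raise ValueError("insertion needs a non-empty inserted sequence")
        if self.op == "identity" and (self.ref_stated or self.alt):
            raise ValueError("identity carries no sequences")
        if self.ref_stated is not None and self.ref_stated_length is not None:
            raise ValueError("stated sequence and stated length are exclusive")


@dataclass(frozen=True)
class Description:
    reference_id: str
    system: str
    variants: Tuple[ElementaryVariant, ...]
    selector_id: Optional[str] = None
    is_allele: bool = False
    had_lowercase: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown positioning system {self.system!r}")


# ---------------------------------------------------------------------------
# parsing


class _Cursor:
    __slots__ = ("text", "pos")

    def __init__(self, text: str, pos: int = 0):
        self.text = text
        self.pos = pos

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, token: str) -> bool:
        if self.text.startswith(token, self.pos):
            self.pos += len(token)
            return True
        return False

    def expect(self, token: str, what: str) -> None:
        if not self.take(token):
            raise HgvsSyntaxError(f"expected {what}", self.pos)

    def match(self, regex: re.Pattern) -> Optional[str]:
        m = regex.match(self.text, self.pos)
        if m:
            self.pos = m.end()
            return m.group(0)
        return None

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.text)


def _parse_point(cur: _Cursor, system: str) -> Point:
    start = cur.pos
    if cur.take("IVS") or cur.take("ivs"):
        if system not in ("c", "n"):
            raise HgvsSyntaxError("IVS positions require the c. or n. system", start)
        num = cur.match(_NUM_RE)
        if num is None:
            raise HgvsSyntaxError("expected intron number after IVS", cur.pos)
        sign = cur.peek()
        if sign not in "+-":
            raise HgvsSyntaxError("IVS position needs a signed offset", cur.pos)
        cur.pos += 1
        off = cur.match(_NUM_RE)
        if off is None:
            raise HgvsSyntaxError("expected offset after IVS sign", cur.pos)
        return IvsPoint(intron=int(num), offset=int(off) * (1 if sign == "+" else -1))

    if cur.peek() == "(":
        raise UnsupportedConstructError("uncertainty ranges are not supported", cur.pos)

    anchor = "plain"
    if cur.take("-"):
        anchor = "upstream"
    elif cur.take("*"):
        anchor = "downstream"
    if anchor != "plain" and system in ("g", "m"):
        raise HgvsSyntaxError(f"{'-' if anchor == 'upstream' else '*'} positions "
                              "are not valid in the g./m. systems", start)
    num = cur.match(_NUM_RE)
    if num is None:
        raise HgvsSyntaxError("expected a position", cur.pos)
    base = int(num)
    if base == 0:
        raise HgvsSyntaxError("position zero does not exist in HGVS", start)

    offset = None
    fuzzy = None
    if cur.peek() in "+-":
        sign = cur.peek()
        nxt = cur.text[cur.pos + 1: cur.pos + 2]
        if nxt == "?" or nxt.isdigit():
            cur.pos += 1
            if system in ("g", "m"):
                raise HgvsSyntaxError("intronic offsets are not valid in g./m.", cur.pos - 1)
            if cur.take("?"):
                fuzzy = sign
            else:
                off = cur.match(_NUM_RE)
                val = int(off)
                if val == 0:
                    raise HgvsSyntaxError("offset zero does not exist", cur.pos)
                offset = val if sign == "+" else -val
        # a bare +/- not followed by digits/? belongs to the next token
    return HgvsPoint(base=base, anchor=anchor, offset=offset, fuzzy=fuzzy)


def _parse_location(cur: _Cursor, system: str) -> HgvsLocation:
    start = _parse_point(cur, system)
    if cur.take("_"):
        end = _parse_point(cur, system)
        return HgvsLocation(start, end)
    return HgvsLocation.point(start)


def _valid_seq(text: str) -> Optional[str]:
    """Validate a nucleotide string; returns the upcased sequence or None."""
    if text and _SEQ_RE.fullmatch(text):
        return text.upper()
    return None


def _parse_variant(cur: _Cursor, system: str, stop: str) -> Tuple[ElementaryVariant, bool]:
    """Parse one elementary variant up to (not including) any char in `stop`.

    Returns the variant and whether any lowercase sequence letters were seen.
    """
    vstart = cur.pos
    if "/" in cur.text[cur.pos:]:
        slash = cur.text.index("/", cur.pos)
        if slash < _find_stop(cur.text, cur.pos, stop):
            raise UnsupportedConstructError(
                "mosaic/chimeric descriptions are not supported", slash)
    loc = _parse_location(cur, system)
    rest_end = _find_stop(cur.text, cur.pos, stop)
    rest = cur.text[cur.pos:rest_end]
    seen_lower = []

    def _seq(text: str) -> Optional[str]:
        s = _valid_seq(text)
        if s is not None and s != text:
            seen_lower.append(True)
        return s

    def done(v: ElementaryVariant) -> Tuple[ElementaryVariant, bool]:
        cur.pos = rest_end
        return v, bool(seen_lower)

    # substitution: one stated base, '>', one alt base
    m = re.match(r"([ACGTNacgtn])>([ACGTNacgtn])$", rest)
    if m:
        if not loc.is_point:
            raise HgvsSyntaxError("substitution requires a single position", vstart)
        if not (m.group(1) + m.group(2)).isupper():
            seen_lower.append(True)
        return done(ElementaryVariant(loc, "substitution",
                                      ref_stated=m.group(1).upper(),
                                      alt=m.group(2).upper()))

    if rest.startswith("delins"):
        tail = rest[6:]
        alt = _seq(tail)
        if alt is None:
            if ":" in tail:
                raise UnsupportedConstructError(
                    "insertions naming another reference are not supported",
                    cur.pos + 6)
            raise HgvsSyntaxError("expected inserted sequence after delins", cur.pos + 6)
        return done(ElementaryVariant(loc, "delins", alt=alt))

    if rest.startswith("del"):
        tail = rest[3:]
        # an embedded 'ins' splits a stated-deletion delins: del<seq|len>ins<seq>
        idx = tail.find("ins")
        while idx != -1:
            before, after = tail[:idx], tail[idx + 3:]
            alt = _seq(after)
            if alt is not None and (before == "" or before.isdigit() or _seq(before)):
                kw = {}
                if before.isdigit():
                    kw["ref_stated_length"] = int(before)
                elif before:
                    kw["ref_stated"] = before.upper()
                return done(ElementaryVariant(loc, "delins", alt=alt, **kw))
            idx = tail.find("ins", idx + 1)
        if tail == "":
            return done(ElementaryVariant(loc, "del"))
        if tail.isdigit():
            return done(ElementaryVariant(loc, "del", ref_stated_length=int(tail)))
        st = _seq(tail)
        if st is not None:
            return done(ElementaryVariant(loc, "del", ref_stated=st))
        if tail.startswith("["):
            raise UnsupportedConstructError("repeat counts are not supported",
                                            cur.pos + 3)
        raise HgvsSyntaxError("malformed deletion", cur.pos + 3)

    for kw in ("dup", "inv"):
        if rest.startswith(kw):
            tail = rest[3:]
            if tail == "":
                return done(ElementaryVariant(loc, kw))
            if tail.isdigit():
                return done(ElementaryVariant(loc, kw, ref_stated_length=int(tail)))
            st = _seq(tail)
            if st is not None:
                return done(ElementaryVariant(loc, kw, ref_stated=st))
            if tail.startswith("["):
                raise UnsupportedConstructError("repeat counts are not supported",
                                                cur.pos + 3)
            raise HgvsSyntaxError(f"malformed {kw}", cur.pos + 3)

    if rest.startswith("ins"):
        tail = rest[3:]
        if ":" in tail:
            raise UnsupportedConstructError(
                "insertions naming another reference are not supported", cur.pos + 3)
        if tail.startswith("["):
            raise UnsupportedConstructError("compound insertions are not supported",
                                            cur.pos + 3)
        alt = _seq(tail)
        if alt is None:
            raise HgvsSyntaxError("expected inserted sequence after ins", cur.pos + 3)
        return done(ElementaryVariant(loc, "ins", alt=alt))

    if rest == "=":
        return done(ElementaryVariant(loc, "identity"))

    if re.match(r"\[\d", rest):
        raise UnsupportedConstructError("repeat counts are not supported", cur.pos)
    raise HgvsSyntaxError("expected a variant operation", cur.pos)


def _find_stop(text: str, pos: int, stop: str) -> int:
    for i in range(pos, len(text)):
        if text[i] in stop:
            return i
    return len(text)


def parse_description(text: str) -> Description:
    """Parse a single HGVS DNA description into a :class:`Description`.

    Leading/trailing whitespace is tolerated, as is whitespace after the
    ``;`` separators inside an allele.  Lowercase sequence letters are
    accepted and upcased; this is recorded on ``Description.had_lowercase``
    so the semantic layer can warn.
    """
    stripped = text.strip()
    lead = len(text) - len(text.lstrip())
    cur = _Cursor(stripped)
    try:
        return _parse(cur)
    except HgvsSyntaxError as exc:
        if lead:  # report offsets relative to the original string
            raise type(exc)(exc.reason, exc.offset + lead) from None
        raise


def _parse(cur: _Cursor) -> Description:
    acc = cur.match(_ACCESSION_RE)
    if acc is None:
        raise HgvsSyntaxError("expected a reference accession", cur.pos)
    selector = None
    if cur.take("("):
        selector = cur.match(_ACCESSION_RE)
        if selector is None:
            raise HgvsSyntaxError("expected a selector accession", cur.pos)
        cur.expect(")", "')' closing the selector")
    cur.expect(":", "':' after the reference identifier")
    system = cur.peek()
    if system not in SYSTEMS:
        if system == "o":
            raise UnsupportedConstructError(
                "the circular o. positioning system is not supported", cur.pos)
        if system in ("p", "r"):
            raise UnsupportedConstructError(
                f"{system}. descriptions are not accepted as input", cur.pos)
        raise HgvsSyntaxError("expected a positioning system (g/c/n/m)", cur.pos)
    cur.pos += 1
    cur.expect(".", "'.' after the positioning system")

    lowercase = False
    variants = []
    is_allele = False
    if cur.take("="):
        if not cur.exhausted:
            raise HgvsSyntaxError("unexpected trailing characters", cur.pos)
    elif cur.take("["):
        is_allele = True
        while True:
            while cur.peek() == " ":
                cur.pos += 1
            v, lc = _parse_variant(cur, system, ";]")
            lowercase |= lc
            variants.append(v)
            if cur.take(";"):
                continue
            cur.expect("]", "';' or ']' in the allele")
            break
        if not cur.exhausted:
            raise HgvsSyntaxError("unexpected trailing characters", cur.pos)
    else:
        v, lowercase = _parse_variant(cur, system, "")
        variants.append(v)
        if not cur.exhausted:
            raise HgvsSyntaxError("unexpected trailing characters", cur.pos)

    variants = tuple(v for v in variants if v.op != "identity" or len(variants) > 1)
    return Description(reference_id=acc, system=system, variants=variants,
                       selector_id=selector, is_allele=is_allele,
                       had_lowercase=lowercase)


# ---------------------------------------------------------------------------
# serialization


def format_point(p: Point) -> str:
    if isinstance(p, IvsPoint):
        return f"IVS{p.intron}{p.offset:+d}"
    prefix = {"plain": "", "upstream": "-", "downstream": "*"}[p.anchor]
    s = f"{prefix}{p.base}"
    if p.fuzzy is not None:
        s += f"{p.fuzzy}?"
    elif p.offset is not None:
        s += f"{p.offset:+d}"
    return s


def format_location(loc: HgvsLocation) -> str:
    if loc.is_point:
        return format_point(loc.start)
    return f"{format_point(loc.start)}_{format_point(loc.end)}"


def format_variant(v: ElementaryVariant) -> str:
    loc = format_location(v.location)
    stated = ""
    if v.ref_stated is not None:
        stated = v.ref_stated
    elif v.ref_stated_length is not None:
        stated = str(v.ref_stated_length)
    if v.op == "substitution":
        return f"{loc}{v.ref_stated}>{v.alt}"
    if v.op == "delins":
        return f"{loc}del{stated}ins{v.alt}"
    if v.op in ("del", "dup", "inv"):
        return f"{loc}{v.op}{stated}"
    if v.op == "ins":
        return f"{loc}ins{v.alt}"
    if v.op == "identity":
        return f"{loc}="
    raise ValueError(f"unknown operation {v.op!r}")


def format_description(d: Description) -> str:
    """Serialize canonically: no spaces, allele brackets when >= 2 variants."""
    ref = d.reference_id
    if d.selector_id:
        ref += f"({d.selector_id})"
    head = f"{ref}:{d.system}."
    if not d.variants:
        return head + "="
    if len(d.variants) == 1 and not d.is_allele:
        return head + format_variant(d.variants[0])
    return head + "[" + ";".join(format_variant(v) for v in d.variants) + "]"
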