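"""Coded diagnostics: errors, warnings and corrections.

Codes are a closed, stable registry (part of the public API).  Severities:

* ``error`` — the description cannot be interpreted against the reference;
  no canonical output is produced.
* ``warning`` — the description is interpretable but deserves attention
  (e.g. a variant near a splice site).
* ``correction`` — the description was interpretable but not canonical; the
  entry records which rewrite rule was applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional

SEVERITIES = ("error", "warning", "correction")

#: the closed code registry
CODES = frozenset({
    # errors
    "ESYNTAX",              # unparsable input
    "EUNSUPPORTED",         # recognizable HGVS outside the supported subset
    "EREF",                 # stated sequence does not match the reference
    "ENOINTRON",            # intronic position on an intron-less reference
    "EOFFSETFROMBOUNDARY",  # intronic offset not anchored on an exon boundary
    "EOUTOFBOUNDS",         # position outside the sequence
    "ERANGEORDER",          # range end not after range start
    "EINSRANGE",            # insertion positions not consecutive
    "ELENGTHMISMATCH",      # stated length differs from the positional span
    "ENOSELECTOR",          # transcript selector missing or ambiguous
    "ENOCDS",               # c. used on a transcript without a CDS
    "EOVERLAP",             # variants in one allele overlap
    # warnings
    "WSPLICE",              # variant hits a splice site of the used transcript
    "WSPLICE_OTHER",        # variant hits a splice site of another transcript
    "WNOMRNA_OTHER",        # transcript model reconstructed from a CDS
    "WSTART",               # variant covers the translation start site
    "WCDSLENGTH",           # CDS length not a multiple of three
    "WLOWERCASE",           # lowercase sequence letters were upcased
    # corrections
    "CIVS",                 # deprecated IVS position rewritten
    "CFUZZY",               # fuzzy intronic offset placed at the intron center
    "CSORTED",              # allele variants re-sorted 5'->3'
    "C3PRIME",              # variant shifted to the most 3' position
    "CVARTYPE",             # variant type updated (e.g. ins -> dup)
    "CMINIMIZED",           # delins/inv narrowed to its minimal form
    "CIDENTITY",            # variant is a no-op and was removed
})


@dataclass(frozen=True)
class Diagnostic:
    severity: str
    code: str
    message: str
    variant_index: Optional[int] = None

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.code not in CODES:
            raise ValueError(f"code {self.code!r} not in the registry")

    def to_dict(self) -> dict:
        d = {"severity": self.severity, "code": self.code,
             "message": self.message}
        if self.variant_index is not None:
            d["variant_index"] = self.variant_index
        return d


class Diagnostics:
    """Ordered collection of diagnostics attached to one run."""

    def __init__(self, items: Optional[List[Diagnostic]] = None):
        self.items: List[Diagnostic] = list(items or [])

    def add(self, item: Diagnostic) -> None:
        self.items.append(item)

    def error(self, code: str, message: str, index: Optional[int] = None) -> None:
        self.add(Diagnostic("error", code, message, index))

    def warning(self, code: str, message: str, index: Optional[int] = None) -> None:
        self.add(Diagnostic("warning", code, message, index))

    def correction(self, code: str, message: str,
                   index: Optional[int] = None) -> None:
        self.add(Diagnostic("correction", code, message, index))

    def extend(self, other: "Diagnostics") -> None:
        self.items.extend(other.items)

    @property
    def errors(self) -> List[Diagnostic]:
        return [d for d in self.items if d.severity == "error"]

    @property
    def warnings(self) -> List[Diagnostic]:
        return [d for d in self.items if d.severity == "warning"]

    @property
    def corrections(self) -> List[Diagnostic]:
        return [d for d in self.items if d.severity == "correction"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def codes(self) -> List[str]:
        return [d.code for d in self.items]

    def __iter__(self) -> Iterator[Diagnostic]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __repr__(self) -> str:
        return f"Diagnostics({self.items!r})"

    def to_list(self) -> List[dict]:
        return [d.to_dict() for d in self.items]
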