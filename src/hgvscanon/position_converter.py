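"""Position conversion between chromosomal g. and transcript c./n. frames.

Works purely on mapping records (exon structure, CDS, strand of a transcript
on a chromosome); it performs **no semantic checks and no disambiguation**
and never reads sequence content — variant operations and inserted
sequences pass through untouched.  The output should therefore always be
re-checked against an actual reference sequence before dissemination;
chromosomal and standalone transcript references for the same transcript
may even differ in sequence content, which position mapping alone cannot
detect.

Mapping records are read from a refFlat-like tab-delimited file:

    transcript  chromosome  strand  exonStarts  exonEnds  cdsStart  cdsEnd

with 0-based half-open coordinates and comma-separated exon lists; an empty
or ``.`` CDS marks a non-coding transcript.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

from . import coordinates as coords
from .coordinates import TranscriptLayout
from .grammar import (Description, ElementaryVariant, HgvsLocation, HgvsPoint,
                      IvsPoint)

CAVEAT = ("position conversion performs no semantic checks; verify the "
          "result with the name checker against a real reference sequence")


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptMapping:
    transcript_id: str
    chromosome_id: str
    layout: TranscriptLayout


def read_mappings(path) -> List[TranscriptMapping]:
    """Load TranscriptMapping records from a refFlat-like TSV file."""
    out = []
    with open(Path(path), newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 7:
                raise MappingError(f"line {lineno}: expected 7 columns")
            tx, chrom, strand, starts, ends, cds_s, cds_e = row[:7]
            exon_starts = [int(x) for x in starts.rstrip(",").split(",")]
            exon_ends = [int(x) for x in ends.rstrip(",").split(",")]
            if len(exon_starts) != len(exon_ends):
                raise MappingError(f"line {lineno}: exon list mismatch")
            exons = tuple(sorted(zip(exon_starts, exon_ends)))
            cds = None
            if cds_s not in ("", ".") and cds_e not in ("", "."):
                cds = (int(cds_s), int(cds_e))
            layout = TranscriptLayout(exons=exons, strand=strand, cds=cds)
            out.append(TranscriptMapping(tx, chrom, layout))
    return out


def _find(mappings: Sequence[TranscriptMapping],
          transcript_id: str) -> TranscriptMapping:
    for m in mappings:
        if m.transcript_id == transcript_id:
            return m
    base = transcript_id.split(".")[0]
    hits = [m for m in mappings if m.transcript_id.split(".")[0] == base]
    if len(hits) == 1:
        return hits[0]
    raise MappingError(f"no mapping for transcript {transcript_id}")


def _convert_point(p, src: str, dst: str,
                   layout: Optional[TranscriptLayout]) -> HgvsPoint:
    if isinstance(p, IvsPoint) or (isinstance(p, HgvsPoint) and p.fuzzy):
        raise MappingError("IVS/fuzzy positions must be checked, not converted")
    g = coords.to_internal(p, src, layout if src in ("c", "n") else None)
    if g < 0:
        raise MappingError("position lies outside the mapped span")
    return coords.from_internal(g, dst, layout if dst in ("c", "n") else None)


def convert(d: Description, mappings: Sequence[TranscriptMapping],
            target: str) -> Description:
    """Convert a description between the g. frame of a chromosome and the
    c./n. frame of a mapped transcript.

    ``target`` is ``"g"`` or a transcript id.  Point-by-point conversion:
    intronic g. positions become offset form; operations and inserted
    sequences are copied verbatim.
    """
    if target == "g":
        if d.system not in ("c", "n"):
            raise MappingError("description is already genomic")
        tx_id = d.selector_id or d.reference_id
        m = _find(mappings, tx_id)
        src, dst, layout = d.system, "g", m.layout
        ref_id, selector = m.chromosome_id, None
    else:
        m = _find(mappings, target)
        if d.system in ("c", "n"):
            # transcript-to-transcript lift through the shared g. frame
            g_desc = convert(d, mappings, "g")
            return convert(g_desc, mappings, target)
        if d.reference_id.split(".")[0] != m.chromosome_id.split(".")[0]:
            raise MappingError(
                f"description names {d.reference_id}, mapping is on "
                f"{m.chromosome_id}")
        src, dst, layout = d.system, "c" if m.layout.cds else "n", m.layout
        ref_id, selector = m.chromosome_id, m.transcript_id

    variants = []
    for v in d.variants:
        loc = HgvsLocation(_convert_point(v.location.start, src, dst, layout),
                           _convert_point(v.location.end, src, dst, layout))
        variants.append(replace(v, location=loc))
    return Description(reference_id=ref_id, system=dst,
                       variants=tuple(variants), selector_id=selector,
                       is_allele=d.is_allele)
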