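"""Uniform reference model over locally supplied annotated sequences.

A :class:`ReferenceModel` holds one nucleotide sequence plus the annotated
transcripts (exons, CDS, strand) needed for semantic checking and protein
prediction.  Dedicated readers cover FASTA + GFF3 (the primary dialect,
parsed with gffutils) and GenBank flat files (Biopython; join/complement
locations only — fuzzy ``<``/``>`` locations are a load error).

Everything is strictly offline: an on-disk directory maps accession to
files, and an unversioned accession resolves only when exactly one version
is present.

The module also ships a deterministic synthetic-reference generator used for
fixtures and property tests: multi-exon transcripts on either strand with an
ATG-initiated, stop-terminated, internally stop-free CDS.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import gffutils
from Bio import SeqIO
from Bio.SeqFeature import AfterPosition, BeforePosition

from .coordinates import TranscriptLayout
from .diagnostics import Diagnostic, Diagnostics

_STOPS = ("TAA", "TAG", "TGA")


class ReferenceLoadError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatedTranscript:
    id: str
    layout: TranscriptLayout
    protein_id: Optional[str] = None
    reconstructed: bool = False


@dataclass
class _OrphanCds:
    id: str
    parts: Tuple[Tuple[int, int], ...]
    strand: str
    parent: Optional[str] = None
    protein_id: Optional[str] = None


@dataclass
class ReferenceModel:
    id: str
    sequence: str
    transcripts: List[AnnotatedTranscript] = field(default_factory=list)
    kind: str = "genomic"  # genomic | transcript
    orphan_cds: List[_OrphanCds] = field(default_factory=list)

    def get_transcript(self, selector: str) -> Optional[AnnotatedTranscript]:
        """Resolve a transcript id; an unversioned selector matches a unique
        versioned transcript, but a wrong version never silently resolves."""
        for t in self.transcripts:
            if t.id == selector:
                return t
        if "." in selector:
            return None
        hits = [t for t in self.transcripts
                if t.id.split(".")[0] == selector]
        return hits[0] if len(hits) == 1 else None


def _infer_kind(sequence: str, transcripts: List[AnnotatedTranscript]) -> str:
    if len(transcripts) == 1:
        layout = transcripts[0].layout
        if layout.is_intronless and layout.exons[0] == (0, len(sequence)):
            return "transcript"
    return "genomic"


# ---------------------------------------------------------------------------
# loading


def load_reference(sequence_file, annotation_file) -> ReferenceModel:
    """Load FASTA + (GFF3 | GenBank) into a ReferenceModel.

    GFF3 features use 1-based closed coordinates and are converted to the
    internal zero-based half-open convention.  A sequence/annotation length
    mismatch is a load error.
    """
    sequence_file = Path(sequence_file)
    annotation_file = Path(annotation_file)
    record = SeqIO.read(str(sequence_file), "fasta")
    sequence = str(record.seq).upper()
    suffix = annotation_file.suffix.lower()
    if suffix in (".gff", ".gff3"):
        model = _load_gff3(record.id, sequence, annotation_file)
    elif suffix in (".gb", ".gbk", ".genbank"):
        model = _load_genbank(annotation_file)
        if len(model.sequence) != len(sequence):
            raise ReferenceLoadError(
                f"FASTA length {len(sequence)} != GenBank length "
                f"{len(model.sequence)}")
        model.sequence = sequence
    else:
        raise ReferenceLoadError(f"unrecognized annotation format: {annotation_file}")
    model.kind = _infer_kind(model.sequence, model.transcripts)
    return model


def _feature_interval(f) -> Tuple[int, int]:
    return f.start - 1, f.end  # GFF3 1-based closed -> 0-based half-open


def _load_gff3(seq_id: str, sequence: str, path: Path) -> ReferenceModel:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    transcripts: List[AnnotatedTranscript] = []
    orphans: List[_OrphanCds] = []
    claimed_cds = set()

    tx_features = list(db.features_of_type(("mRNA", "transcript")))
    for tx in tx_features:
        exons = sorted(_feature_interval(f)
                       for f in db.children(tx, featuretype="exon"))
        if not exons:
            exons = [_feature_interval(tx)]
        cds_parts = sorted(_feature_interval(f)
                           for f in db.children(tx, featuretype="CDS"))
        cds = (cds_parts[0][0], cds_parts[-1][1]) if cds_parts else None
        protein = None
        for f in db.children(tx, featuretype="CDS"):
            claimed_cds.add(f.id)
            protein = (f.attributes.get("protein_id") or [None])[0]
        _check_bounds(exons, len(sequence), path)
        layout = TranscriptLayout(exons=tuple(exons), strand=tx.strand or "+",
                                  cds=cds)
        transcripts.append(AnnotatedTranscript(id=_gff_name(tx), layout=layout,
                                               protein_id=protein))

    # CDS features whose Parent is not a transcript (or absent) become orphans
    seen = set()
    for f in db.features_of_type("CDS"):
        if f.id in claimed_cds:
            continue
        parent = (f.attributes.get("Parent") or [None])[0]
        key = f.id or parent or f"CDS@{f.start}"
        if key in seen:
            continue
        seen.add(key)
        parts = []
        for g in db.features_of_type("CDS"):
            if (g.id or (g.attributes.get("Parent") or [None])[0]
                    or f"CDS@{g.start}") == key:
                parts.append(_feature_interval(g))
        parts.sort()
        _check_bounds(parts, len(sequence), path)
        orphans.append(_OrphanCds(id=key, parts=tuple(parts),
                                  strand=f.strand or "+", parent=parent))
    return ReferenceModel(id=seq_id, sequence=sequence, transcripts=transcripts,
                          orphan_cds=orphans)


def _gff_name(feature) -> str:
    for k in ("transcript_id", "Name", "ID"):
        v = feature.attributes.get(k)
        if v:
            return v[0]
    return feature.id


def _check_bounds(intervals, length: int, path) -> None:
    for s, e in intervals:
        if not (0 <= s < e <= length):
            raise ReferenceLoadError(
                f"annotation interval ({s}, {e}) outside sequence of length "
                f"{length} in {path}")


def _gb_parts(location) -> Tuple[Tuple[int, int], ...]:
    parts = []
    for part in location.parts:
        if isinstance(part.start, (BeforePosition, AfterPosition)) or \
           isinstance(part.end, (BeforePosition, AfterPosition)):
            raise ReferenceLoadError("fuzzy GenBank locations are not supported")
        parts.append((int(part.start), int(part.end)))
    return tuple(sorted(parts))


def _load_genbank(path: Path) -> ReferenceModel:
    record = SeqIO.read(str(path), "genbank")
    sequence = str(record.seq).upper()
    transcripts: List[AnnotatedTranscript] = []
    orphans: List[_OrphanCds] = []
    mrnas = []
    for f in record.features:
        if f.type == "mRNA":
            mrnas.append(f)
    for f in record.features:
        if f.type != "CDS":
            continue
        parts = _gb_parts(f.location)
        strand = "-" if f.location.strand == -1 else "+"
        name = (f.qualifiers.get("transcript_id") or
                f.qualifiers.get("gene") or f.qualifiers.get("locus_tag") or
                ["CDS"])[0]
        protein = (f.qualifiers.get("protein_id") or [None])[0]
        parent = None
        for m in mrnas:
            mparts = _gb_parts(m.location)
            span = (mparts[0][0], mparts[-1][1])
            mstrand = "-" if m.location.strand == -1 else "+"
            if mstrand == strand and span[0] <= parts[0][0] and \
                    parts[-1][1] <= span[1]:
                parent = (m.qualifiers.get("transcript_id") or
                          m.qualifiers.get("gene") or [None])[0]
                break
        orphans.append(_OrphanCds(id=name, parts=parts, strand=strand,
                                  parent=parent, protein_id=protein))
    for m in mrnas:
        parts = _gb_parts(m.location)
        strand = "-" if m.location.strand == -1 else "+"
        name = (m.qualifiers.get("transcript_id") or
                m.qualifiers.get("gene") or ["mRNA"])[0]
        layout = TranscriptLayout(exons=parts, strand=strand)
        transcripts.append(AnnotatedTranscript(id=name, layout=layout))
    model = ReferenceModel(id=record.id, sequence=sequence,
                           transcripts=transcripts, orphan_cds=orphans)
    return model


# ---------------------------------------------------------------------------
# enrichment


def enrich(model: ReferenceModel) -> Tuple[ReferenceModel, Diagnostics]:
    """Link every CDS to a parent transcript; reconstruct missing transcripts.

    A CDS that cannot be matched to any annotated transcript becomes a
    reconstructed transcript built from the CDS extent (warning
    ``WNOMRNA_OTHER``).  Enrichment is idempotent and never errors.
    """
    diags = Diagnostics()
    transcripts = list(model.transcripts)
    known_ids = {t.id for t in transcripts}
    for cds in model.orphan_cds:
        span = (cds.parts[0][0], cds.parts[-1][1])
        # a Parent only constrains linking when it names a real transcript;
        # otherwise containment on the same strand decides
        parent = cds.parent if cds.parent in known_ids else None
        host = None
        for i, t in enumerate(transcripts):
            if t.layout.cds is not None or t.layout.strand != cds.strand:
                continue
            if parent and t.id != parent:
                continue
            lo, hi = t.layout.span
            if lo <= span[0] and span[1] <= hi:
                host = i
                break
        if host is not None:
            t = transcripts[host]
            transcripts[host] = replace(
                t, layout=replace(t.layout, cds=span),
                protein_id=t.protein_id or cds.protein_id)
        else:
            layout = TranscriptLayout(exons=cds.parts, strand=cds.strand,
                                      cds=span)
            transcripts.append(AnnotatedTranscript(
                id=cds.id, layout=layout, protein_id=cds.protein_id,
                reconstructed=True))
            diags.add(Diagnostic(
                "warning", "WNOMRNA_OTHER",
                f"no transcript annotated for CDS {cds.id}; transcript model "
                f"reconstructed from the CDS"))
    enriched = ReferenceModel(id=model.id, sequence=model.sequence,
                              transcripts=transcripts,
                              kind=_infer_kind(model.sequence, transcripts))
    return enriched, diags


# ---------------------------------------------------------------------------
# offline reference store


def resolve_reference(directory, accession) -> Tuple[Path, Path]:
    """Find (sequence_file, annotation_file) for an accession in a directory.

    ``<acc>.fasta`` (or ``.fa``) plus ``<acc>.gff3``/``.gff``/``.gb``.
    An unversioned accession resolves only if exactly one versioned file set
    is present.
    """
    directory = Path(directory)
    candidates = [accession]
    if "." not in accession:
        versions = sorted({p.stem for p in directory.glob(f"{accession}.*.fasta")}
                          | {p.stem for p in directory.glob(f"{accession}.*.fa")})
        versions = [v for v in versions
                    if re.fullmatch(re.escape(accession) + r"\.\d+", v)]
        if len(versions) > 1:
            raise ReferenceLoadError(
                f"accession {accession} is ambiguous offline: versions "
                f"{versions}; supply an explicit version")
        candidates = versions or [accession]
    acc = candidates[0]
    seq = None
    for ext in (".fasta", ".fa"):
        p = directory / f"{acc}{ext}"
        if p.exists():
            seq = p
            break
    if seq is None:
        raise ReferenceLoadError(f"no sequence file for {accession} in {directory}")
    for ext in (".gff3", ".gff", ".gb", ".gbk"):
        p = directory / f"{acc}{ext}"
        if p.exists():
            return seq, p
    raise ReferenceLoadError(f"no annotation file for {accession} in {directory}")


def load_from_directory(directory, accession) -> Tuple[ReferenceModel, Diagnostics]:
    seq, ann = resolve_reference(directory, accession)
    model = load_reference(seq, ann)
    acc = seq.stem
    model.id = acc
    return enrich(model)


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_synthetic_model(seed: int, n_transcripts: int = 2, n_exons: int = 3,
                         strand_mix: bool = True,
                         length: int = 1000) -> ReferenceModel:
    """Deterministic synthetic genomic reference with annotated transcripts.

    Each transcript gets ``n_exons`` exons, a CDS whose exonic length is a
    multiple of three, an ATG start, a stop codon at its end and no internal
    in-frame stop.  When ``n_transcripts >= 2`` and ``strand_mix`` is set, at
    least one multi-exon transcript lies on the reverse strand.
    """
    if min(n_transcripts, n_exons, length) < 1:
        raise ValueError("fixture parameters must be positive")
    rng = random.Random(seed)
    per = length // n_transcripts
    if per < n_exons * 18 + 20:
        raise ValueError("sequence too short for the requested structure")
    seq = [rng.choice("ACGT") for _ in range(length)]
    transcripts = []
    for k in range(n_transcripts):
        lo, hi = k * per + 5, (k + 1) * per - 5
        strand = "-" if (strand_mix and k % 2 == 1) else \
            ("+" if not strand_mix or k % 2 == 0 else "-")
        # split [lo, hi) into n_exons exons separated by introns of >= 4 nt
        cuts = sorted(rng.sample(range(lo + 9, hi - 9), 2 * (n_exons - 1))) \
            if n_exons > 1 else []
        # enforce minimum segment sizes by spreading evenly on collision
        bounds = [lo] + cuts + [hi]
        exons = []
        ok = True
        for i in range(n_exons):
            s, e = bounds[2 * i], bounds[2 * i + 1]
            if e - s < 9:
                ok = False
            exons.append((s, e))
        for i in range(n_exons - 1):
            if bounds[2 * i + 2] - bounds[2 * i + 1] < 4:
                ok = False
        if not ok:
            # evenly spaced fallback keeps determinism without rejection loops
            exon_len = (hi - lo - 4 * (n_exons - 1)) // n_exons
            exons = []
            pos = lo
            for i in range(n_exons):
                exons.append((pos, pos + exon_len))
                pos += exon_len + 4
        exonic = sum(e - s for s, e in exons)
        # CDS: trim a few bases of UTR at both transcript ends, length % 3 == 0
        utr5 = rng.randrange(1, 4)
        utr3 = rng.randrange(1, 4)
        cds_len = exonic - utr5 - utr3
        cds_len -= cds_len % 3
        utr3 = exonic - utr5 - cds_len
        layout0 = TranscriptLayout(exons=tuple(exons), strand=strand)
        tx_positions = _exonic_positions_tx(layout0)
        cds_positions = tx_positions[utr5:utr5 + cds_len]
        cds = (min(cds_positions), max(cds_positions) + 1)
        _write_codon(seq, cds_positions[0:3], "ATG", strand)
        _write_codon(seq, cds_positions[-3:], rng.choice(_STOPS), strand)
        for c in range(3, cds_len - 3, 3):
            codon_pos = cds_positions[c:c + 3]
            codon = _read_codon(seq, codon_pos, strand)
            while codon in _STOPS:
                _write_codon(seq, codon_pos,
                             "".join(rng.choice("ACGT") for _ in range(3)),
                             strand)
                codon = _read_codon(seq, codon_pos, strand)
        layout = TranscriptLayout(exons=tuple(exons), strand=strand, cds=cds)
        transcripts.append(AnnotatedTranscript(
            id=f"TX{k + 1:03d}.1", layout=layout,
            protein_id=f"PR{k + 1:03d}.1"))
    model = ReferenceModel(id=f"SYN{seed:08d}.1", sequence="".join(seq),
                           transcripts=transcripts)
    model.kind = _infer_kind(model.sequence, transcripts)
    return model


def _exonic_positions_tx(layout: TranscriptLayout) -> List[int]:
    positions: List[int] = []
    for s, e in layout.exons_tx():
        r = range(s, e) if layout.strand == "+" else range(e - 1, s - 1, -1)
        positions.extend(r)
    return positions


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _write_codon(seq: List[str], positions: List[int], codon: str,
                 strand: str) -> None:
    if strand == "-":
        codon = codon.translate(_COMPLEMENT)[::-1]
        for p, b in zip(sorted(positions), codon):
            seq[p] = b
    else:
        for p, b in zip(positions, codon):
            seq[p] = b


def _read_codon(seq: List[str], positions: List[int], strand: str) -> str:
    if strand == "-":
        return "".join(seq[p] for p in sorted(positions)).translate(
            _COMPLEMENT)[::-1]
    return "".join(seq[p] for p in positions)


def write_model(model: ReferenceModel, directory) -> Tuple[Path, Path]:
    """Write a model as <id>.fasta + <id>.gff3 (byte-deterministic)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / f"{model.id}.fasta"
    gff = directory / f"{model.id}.gff3"
    with open(fasta, "w") as fh:
        fh.write(f">{model.id}\n")
        for i in range(0, len(model.sequence), 70):
            fh.write(model.sequence[i:i + 70] + "\n")
    lines = ["##gff-version 3",
             f"##sequence-region {model.id} 1 {len(model.sequence)}"]
    for t in model.transcripts:
        lo, hi = t.layout.span
        lines.append("\t".join([
            model.id, "hgvscanon", "mRNA", str(lo + 1), str(hi),
            ".", t.layout.strand, ".", f"ID={t.id};transcript_id={t.id}"]))
        for i, (s, e) in enumerate(t.layout.exons, 1):
            lines.append("\t".join([
                model.id, "hgvscanon", "exon", str(s + 1), str(e),
                ".", t.layout.strand, ".", f"ID={t.id}:exon{i};Parent={t.id}"]))
        if t.layout.cds is not None:
            cs, ce = t.layout.cds
            for i, (s, e) in enumerate(t.layout.exons, 1):
                s2, e2 = max(s, cs), min(e, ce)
                if s2 < e2:
                    attrs = f"ID={t.id}:cds;Parent={t.id}"
                    if t.protein_id:
                        attrs += f";protein_id={t.protein_id}"
                    lines.append("\t".join([
                        model.id, "hgvscanon", "CDS", str(s2 + 1), str(e2),
                        ".", t.layout.strand, "0", attrs]))
    with open(gff, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return fasta, gff


def make_fixture(seed: int, directory, n_transcripts: int = 2,
                 n_exons: int = 3, strand_mix: bool = True,
                 length: int = 1000) -> Tuple[Path, Path]:
    """Generate a synthetic annotated reference on disk (FASTA + GFF3).

    Byte-identical output for a fixed seed and parameters.
    """
    model = make_synthetic_model(seed, n_transcripts=n_transcripts,
                                 n_exons=n_exons, strand_mix=strand_mix,
                                 length=length)
    return write_model(model, directory)


def demo_reference() -> ReferenceModel:
    """Small named preset used throughout the documentation and tests.

    The sequence has a G at 1-based position 7, a C at positions 14 and 15
    and a T at 16, so that ``g.[7G>T;14del]`` normalizes to ``[7G>T;15del]``
    under the 3' rule.  One forward two-exon coding transcript is annotated
    (CDS codons ATG GCC TAC | GGA TAA, protein MAYG).
    """
    #          1234567890123456789012345678901234567890
    sequence = "AACGTTGATATGGCCTACGATCGATTGGATAATTCAGGCA"
    layout = TranscriptLayout(exons=((2, 18), (26, 38)), strand="+",
                              cds=(9, 32))
    tx = AnnotatedTranscript(id="DTX1.1", layout=layout, protein_id="DPR1.1")
    return ReferenceModel(id="DEMOREF.1", sequence=sequence, transcripts=[tx])
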