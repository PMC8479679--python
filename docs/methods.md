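# Methods

## Scope and data model

The package checks and canonicalizes HGVS DNA descriptions against locally
supplied annotated references.  A parsed `Description` holds a reference
accession, an optional transcript selector, a positioning system (`g.`,
`c.`, `n.`, with `m.` treated exactly like `g.`) and an ordered list of
elementary variants (substitution, del, dup, ins, inv, delins, identity).
A `ReferenceModel` holds one nucleotide sequence and its annotated
transcripts; each transcript is a `TranscriptLayout` of sorted, zero-based,
half-open exon intervals in genomic forward orientation plus an optional CDS
interval and a strand.  Strand is consulted only at coordinate conversion
and rolling time, so the spatial frame is unique.

Two variant lists are considered equivalent exactly when applying them to
the reference yields the same observed sequence.  `apply_variants` is the
ground-truth oracle for this equivalence throughout the test suite:
variants are applied simultaneously (never sequentially), intervals must be
pairwise disjoint, and two insertions at the same point are rejected
because their relative order would be undefined.

## Coordinate arithmetic

HGVS positioning systems contain no zero and several discontinuities
(`-1`/`1` adjacency, `*1` after the CDS, intronic offsets, reverse-strand
transcripts numbering opposite to the genome).  All conversions pass
through a *transcript axis*: an integer counting exonic bases in transcript
direction, extended linearly into the 5′/3′ flanks, plus an intronic offset
counted from an exon boundary in transcript direction.  Converting back
from an internal coordinate anchors intronic positions on the nearer exon
boundary, ties going to the 5′ boundary in transcript direction.  Offsets
are validated: they must anchor on the correct boundary
(`EOFFSETFROMBOUNDARY` otherwise), require an intron (`ENOINTRON` on
intron-less, transcript-style references) and may not run past the intron.

Fuzzy intronic offsets (`+?`/`-?`), used for imprecise large-deletion
breakpoints, resolve to the intron center.  For an intron of length L the
concrete offset is `max(1, floor(L/2))` from the anchoring boundary; the
floor convention is a deterministic choice — for odd-length introns the
"center" is ambiguous by one base and nothing downstream depends on which
side is picked.

HGVS ranges are closed; internally they become half-open by adding one to
the end.  Insertion locations `a_b` with adjacent flanking positions become
the zero-length interval at the junction.

## Semantic checking

Checks run per variant in a fixed order: position conversion, sequence
bounds, range order (end after start in the description's own direction),
insertion adjacency, intronic-offset validity, stated-length equality
(`3_9del7`), stated-sequence equality (`10_12delAAT`, compared in the
description's orientation — reverse-complemented on minus-strand
transcripts — with `EREF` on mismatch; the same code covers substitution
reference bases).  Stated inverted sequences are deliberately not checked.
Deprecated `IVS<n>±k` intron positions are rewritten to the modern offset
form with a `CIVS` correction.  Variants inside one allele must be listed
5′→3′ in the description's system; unsorted input is re-sorted with a
`CSORTED` correction, overlap is an error.  A failing variant produces no
internal interval; the remaining variants are still checked so one run
reports everything.

The diagnostic registry is closed and stable.  `EREF`, `ENOINTRON`,
`EOFFSETFROMBOUNDARY`, `WSPLICE`, `WSPLICE_OTHER` and `WNOMRNA_OTHER` carry
their conventional meanings; all other codes (`EOUTOFBOUNDS`, `ERANGEORDER`,
`EINSRANGE`, `ELENGTHMISMATCH`, `ENOSELECTOR`, `ENOCDS`, `EOVERLAP`,
`ESYNTAX`, `WSTART`, `WCDSLENGTH`, `WLOWERCASE` and the `C*` correction
codes) are this package's own vocabulary.

## Canonicalization

Per variant the pipeline is **trim → simplify → 3′ roll → dup detection**,
each stage's precondition being the previous stage's postcondition:

* *trim*: a delins loses the longest common prefix, then the longest common
  suffix, of its deleted and inserted sequences.  An inversion is trimmed
  symmetrically by k, the number of leading positions whose base equals the
  complement of the mirrored trailing base (a partial palindrome); a full
  palindrome trims to the empty variant.
* *simplify*: relabel to the simplest type — empty insert → del, empty
  deletion → ins, 1↔1 → substitution, insert equal to the reverse
  complement of the deletion (length ≥ 2) → inv, inversion of length 1 →
  substitution by the complement.  A variant that trims to nothing becomes
  an explicit identity and is dropped with a `CIDENTITY` correction.
* *3′ roll*: deletions and insertions shift to the maximal equivalent
  position by walking circular permutations of the deleted/inserted
  sequence; the insert comes back rotated (`2_3insCGTC` → `5_6insCCGT`).
  Substitutions and inversions never roll.  On reverse-strand transcripts
  the transcript 3′ direction is genomically leftward, so `c.` descriptions
  on the minus strand roll opposite to `g.` descriptions of the same edit.
* *dup detection*: an insertion equal to the reference segment immediately
  transcript-5′ of its point becomes a duplication of that segment.  Only
  an exact full-length match counts; whether a longer tandem run should be
  preferred is left open and documented here.

**Rolling windows.**  For `c.`/`n.` descriptions a shift never crosses a
splice site: the rolling window is the stretch between the splice junctions
around the variant.  Transcript ends are not splice sites, so terminal
windows include the flanking sequence; `g.` descriptions roll over the
whole sequence.  An insertion sitting exactly on a splice junction does not
roll at all — any shift would carry it across the junction.  Within an
allele, rolling is additionally capped at the neighbouring variant (a
variant shifted across another one would change the combined observed
sequence), and insertions never roll onto another insertion's point.
Variants are rolled in 3′→5′ order so each one is capped by the *final*
position of its already-rolled 3′ neighbour; this makes normalization
idempotent.

**Edge insertions.**  An insertion whose 3′-maximal position is flush
against a sequence end has no flanking base on one side and cannot be
spelled `a_b ins`; unless it is a duplication, it is anchored on the
terminal base as a one-base delins.  This keeps every emitted description
within the sequence bounds and is stable under re-normalization.

**Duplications on the minus strand.**  Internally a dup is the insertion of
the duplicated segment on its transcript-3′ side — genomically left of the
segment on reverse-strand transcripts — so that rolling and re-analysis
start from the same point in both passes.

Adjacent variants are never merged (the extractor, below, is the one
component that merges).  For `c.`/`n.` input the equivalent `g.`
description on the same reference is also emitted; it preserves the
transcript-direction rolling, so it is the g-spelling of the transcript
canonical form, not an independently g-canonicalized description.
Corrections are recorded per rule: `CMINIMIZED`, `CVARTYPE`, `C3PRIME`,
`CSORTED`, `CIVS`, `CFUZZY`, `CIDENTITY`, in the description's own system.

## Protein prediction

For every annotated coding transcript the observed mRNA is reconstructed by
classifying each observed base (kept reference bases and inserted bases) as
exonic or not, which adjusts exon boundaries to length changes without
explicit boundary arithmetic.  Translation runs from the CDS start through
the rest of the mRNA, so frameshifts continue into the 3′ region until a
stop codon is met; the standard genetic code is built in, and translation
truncates at a trailing partial codon (with a `WCDSLENGTH` warning when the
annotated CDS is not a multiple of three).

Geometry decides the prediction per variant:

* any endpoint strictly inside an intron, without the variant spanning that
  intron — including deep intronic changes — omits translation: `p.?` with
  `WSPLICE` (the transcript the description used) or `WSPLICE_OTHER` (any
  other transcript).  This is intentionally conservative.
* a deletion with both breakpoints in exons spanning one or more complete
  introns is interpreted as forming a **fusion exon** and is translated
  (flag `fusion_exon`); the frame is preserved iff the exonic loss is a
  multiple of three.
* a deletion with intronic breakpoints covering complete exons removes
  those exons before translation (flag `exons_removed`).
* variants touching the translation start codon give `p.?` with `WSTART`.
* everything else is applied, re-spliced and translated.

Predictions are written parenthesized with three-letter codes:
`p.(=)`, `p.(Tyr3Cys)`, in-frame del/ins/delins forms, `p.(Arg97Ter)` when
the first changed residue is a stop, and `p.(Gln2HisfsTer10)` for
frameshifts, where the number counts from the first changed residue to the
new stop (`Ter?` when no stop occurs before the mRNA ends).  Whether a
change is a frameshift is decided from the exonic CDS length delta of the
DNA variants, not guessed from the protein strings.

Restriction-site changes are computed per elementary variant over a window
of the variant span extended by (longest recognition pattern − 1) on both
sides, in the reference and the single-variant observed sequence; site
counts per enzyme are compared and the removed/added name lists reported.
The built-in table of 25 common enzymes (IUPAC patterns, mostly 6-cutters)
ships as a data file and can be overridden.

## Position converter

Conversion between a chromosomal `g.` frame and transcript `c.`/`n.` frames
uses refFlat-like mapping records (transcript, chromosome, strand, exon
starts/ends, CDS bounds; 0-based half-open).  It converts positions
point-by-point — intronic genomic positions become offset form — and copies
operations and inserted sequences verbatim: no reference sequence is read,
no semantic check or disambiguation is performed, and the output carries a
standing caveat to re-check it with the name checker.  Transcript-to-
transcript lifts compose through the shared genomic frame.  Positions 5′ of
the transcript start or 3′ of its end are addressed by extending the
transcript axis linearly into the flanks (`c.-n`, `c.*n`), a convention
chosen here because no standard exists for flank positions in pure mapping
conversions.

## Description extractor

Given a reference and an observed sequence, the extractor anchors on the
maximal equal prefix and suffix, aligns the middle with a longest-common-
subsequence matcher (difflib), and merges change blocks separated by fewer
than two matching bases into one delins — so adjacent substitutions merge,
unlike in the name checker.  The merge threshold of 2 generalizes the
adjacent-substitution case and is a module constant.  A changed block equal
to the reverse complement of its reference span becomes an inversion.  Each
block then runs through the same trim/simplify/roll/dup pipeline; when a
roll is stopped only by the next block, the two blocks merge and are
reprocessed, so extractor output re-normalizes with zero corrections.  The
defining contract, fuzz-tested on 10 000 random pairs: applying the
extracted variants reproduces the observed sequence exactly.

## Synthetic references

`make_fixture`/`make_synthetic_model` generate deterministic annotated
references: by default 1000 nt with two transcripts of three exons each,
one per strand, each with an ATG-initiated, stop-terminated CDS whose
exonic length is a multiple of three and which contains no internal
in-frame stop.  Introns are at least 4 nt and exons at least 9 nt.  These
fixtures emulate the structural features the checker depends on (multi-exon
layouts, both strands, UTRs, clean ORFs); they do not emulate realistic
base composition, splice-site motifs, repeat structure or annotation noise
beyond the orphan-CDS case, so passing tests demonstrate correctness of the
coordinate and rewriting logic, not performance on real genome annotation.
The documentation preset (`demo_reference`) is a 40 nt sequence with a G at
position 7, a C at 14 and 15 and a T at 16, so the classic allele example
normalizes to the 3′ deletion at 15.

## Numerical and procedural choices

* Offline reference store: `<accession>.fasta` + `.gff3`/`.gb` in a
  directory; an unversioned accession resolves only when exactly one
  version is present (no network, no "latest version" lookup), and a
  mismatched explicit version never silently resolves.
* GFF3 is the primary annotation dialect (parsed with gffutils); the
  GenBank reader accepts join/complement locations and treats fuzzy
  `<`/`>` locations as load errors.  Enrichment links each CDS to a parent
  transcript — by Parent attribute when it names a transcript, else by
  same-strand containment — and reconstructs a transcript from the CDS
  extent otherwise (`WNOMRNA_OTHER`); it is idempotent.
* Lowercase sequence letters in descriptions are accepted, upcased and
  flagged (`WLOWERCASE`).
* The grammar is a hand-written recursive-descent parser over the supported
  subset; anything recognizably HGVS but outside the subset (repeats,
  mosaics, uncertainty ranges, multi-reference insertions, `o.`) raises a
  distinct unsupported-construct error, and syntax errors carry the
  character offset of the first unparsable token.
* Batch processing auto-detects comma/semicolon/tab delimiters per line,
  drops empty lines, and writes one tab-delimited output row per input
  description with per-row error capture.

## Test strategy and problem sizes

Every disambiguation rule is tested against the apply oracle rather than
against expected strings alone.  The property suites run at these sizes:
10 000 random descriptions (alleles of 1–3 variants, `g.`/`c.`/`n.`, both
strands) over synthetic references for observed-sequence preservation and
idempotence; all single deletions/insertions of ≤ 6 nt at every position of
200 random 40-nt sequences against a brute-force 3′-maximality enumeration;
exhaustive coordinate round trips over every position of 100 random layouts
on both strands; 10 000 random extractor pairs (≤ 200 nt, edit distance
≤ 20); and ~1000 random allele predictions plus synonymous-substitution
sweeps for protein-prediction totality and silence.  The whole suite runs
in well under a minute on one CPU.

## Known limitations

Repeat, mosaic and uncertainty syntax is rejected rather than normalized.
Protein descriptions are emitted, never parsed.  Extension variants
(`ext`), selenocysteine and alternative genetic codes are out of scope.
The deep-intronic `p.?` policy is deliberately conservative.  Cross-build
or cross-species liftover and sequence-difference-aware lifting between a
chromosomal and a standalone transcript reference are out of scope; the
position converter's caveat exists precisely because such differences are
invisible to pure position mapping.
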