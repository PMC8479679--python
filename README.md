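# hgvscanon

A self-contained name checker for HGVS DNA variant descriptions.  Given a
description such as `NG_012337.1:g.[7G>T;14del]` and a locally supplied
annotated reference sequence, it parses the description, validates it
semantically, rewrites it to the unique HGVS-preferred (*canonical*) form,
and predicts the protein-level consequence per annotated transcript.  A
position converter (chromosomal g. ↔ transcript c./n. frames via mapping
records) and a description extractor (reference + observed sequence →
description) round out the toolkit.

## Who this is for

Clinical geneticists, database curators and pipeline authors who need
variant descriptions checked and normalized **offline** — references come
from local FASTA + GFF3 (or GenBank flat files), never from the network —
and who need machine-readable diagnostics with stable codes (`EREF`,
`ENOINTRON`, `EOFFSETFROMBOUNDARY`, `WSPLICE`, …).

## The model

A *variant* is the difference between a reference and an observed sequence,
written as a list of elementary variants (substitution, del, dup, ins, inv,
delins).  Because the same observed sequence admits many descriptions
(deleting either C of a CC run is the same edit), all arithmetic happens in
a single internal frame — zero-based, half-open intervals in genomic
forward orientation — where two descriptions are equivalent iff they
reconstruct the same observed sequence.  Canonicalization then applies, per
variant:

1. **minimization** — remove the longest common prefix, then suffix, of the
   deleted and inserted sequences (`2_6delinsATTTA` on `AACGTAA` →
   `3_4delinsTT`); inversions are trimmed where their ends form a partial
   palindrome;
2. **simplification** — relabel to the simplest type
   (`2_5delinsGT` → `2_3del`, `3delinsT` → `3C>T`, inv of length 1 →
   substitution);
3. **3′ rule** — shift deletions/insertions to the most 3′ equivalent
   position by walking circular permutations of the shifted sequence
   (`2_3insCGTC` → `5_6insCCGT`); on reverse-strand transcripts 3′ means
   genomically leftward, and shifts never cross a splice site;
4. **dup detection** — an insertion equal to the segment just 5′ of its
   insertion point becomes a duplication.

Adjacent variants are deliberately **not** merged; each elementary variant
is treated independently.  The HGVS `c.` axis — no position zero, `-1`/`1`
adjacency, `*1` after the CDS, intronic offsets like `12+1`, reverse-strand
transcripts where c.1 ≡ g.10 implies c.2 ≡ g.9 — is handled entirely by the
coordinates module.

## Worked example

```sh
$ python -c "
from hgvscanon.reference_model import demo_reference, write_model
write_model(demo_reference(), 'refs')"
$ hgvs-canon check 'DEMOREF.1:g.[7G>T;14del]' --references refs
CORRECTION C3PRIME [variant 2]: 14del shifted 3' to 15del
DEMOREF.1:g.[7G>T;15del]
DTX1.1: p.(Tyr3ThrfsTer?)
```

The demo reference has a C at positions 14 and 15: deleting either gives the
same observed sequence, and the 3′ rule picks `15del`, recorded as a
`C3PRIME` correction.  The annotated transcript DTX1.1 translates MAYG; the
one-base deletion shifts its reading frame from residue 3 onward and no new
stop codon occurs before the end of the mRNA, hence `p.(Tyr3ThrfsTer?)`.
Exit status is 0 (valid, possibly corrected), 1 (semantic error) or
2 (syntax error).

The same from Python:

```python
>>> from hgvscanon import ReferenceModel, normalize_text, format_description
>>> model = ReferenceModel(id="R1.1", sequence="AACGTAA")
>>> report = normalize_text("R1.1:g.2_6delinsATTTA", model)
>>> format_description(report.canonical)
'R1.1:g.3_4delinsTT'
>>> [d.code for d in report.diagnostics]
['CMINIMIZED']
```

Other commands: `hgvs-canon extract AACGTAA AATTTAA` prints
`REF:g.3_4delinsTT`; `hgvs-canon convert NM_1.1:c.2del --mappings maps.tsv
--target g` maps positions between transcript and chromosome frames (no
semantic checks — always re-check the output); `hgvs-canon batch` processes
CSV/TSV files of descriptions into a tab-delimited report; `hgvs-canon
make-reference` writes deterministic synthetic annotated references.

## Limitations

Repeat syntax (`[n]`), mosaic/chimeric alleles, uncertainty ranges
`(100_200)`, the circular `o.` system and insertions naming another
reference are rejected as unsupported constructs.  Protein descriptions are
emitted but not parsed.  See `docs/methods.md` for the full method
description and design decisions.
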