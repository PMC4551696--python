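# Methods

This note documents the model behind `varnom`: the coordinate conventions,
the indel-equivalence machinery, the nomenclature and classification rules,
what the synthetic fixtures do and do not emulate, and the numerical and
design choices made where the behaviour was genuinely open.

## Coordinates and transcript model

All public coordinates are 1-based and inclusive (VCF convention); the only
half-open arithmetic is private to the interval index. A transcript is an
ordered set of non-overlapping exons on one strand plus the genomic
positions of the first coding base (`c.1`, the A of ATG) and the last
coding base (the final base of the stop codon), both in transcript
orientation — on a reverse-strand transcript `coding_start` is the
genomically larger of the two. Coding positions follow the c. grammar:
`c.N` inside the CDS (the stop codon included, so the last CDS base is
`c.L`), `c.-N` upstream, `c.*N` past the stop, and intronic positions
anchored to the nearest exonic base with a signed offset (`c.N+k` for k
bases 3′ of an exon end, `c.N-k` for k bases 5′ of an exon start, both in
transcript orientation). A base exactly mid-intron anchors to the upstream
(+) side. Exon numbering is transcription-order: exon 1 is the most 5′
exon of the transcript, so numbering reverses between strands.

Transcripts load from GTF/GFF (exon + CDS features grouped by
`transcript_id`) or from a native TSV, one line per transcript:

```
transcript_id  gene  chrom  strand  exon_starts  exon_ends  coding_start  coding_end
```

with comma-separated exon bounds and coding bounds as defined above
(version 1 of this format; the writer emits a `#`-prefixed header). In
GTFs written by this package the CDS features span translation start
through stop inclusive; on reading, `stop_codon` features (the common
Ensembl convention) are merged into the coding extent, so both conventions
load identically. Transcripts whose coding length is not divisible by 3
cannot support protein annotation and are excluded with a logged warning
rather than padded; an input with no valid transcript is fatal. Contig
names are reconciled across FASTA/VCF/GTF by tolerating a `chr` prefix.

## Indel equivalence and canonicalization

Two indel representations are equivalent iff applying them to the
reference yields the identical edited sequence. For a pure insertion or
deletion the equivalence class is a contiguous slide through its repeat
context, computed by single-base shifting (rotate the allele, move one
base) until blocked; the brute-force definition (apply every candidate in
the window and string-compare) is used as an independent oracle in the
tests and the acceptance script, never as the implementation.
Substitutions and complex variants (both alleles non-empty after trimming)
are immobile: alignment is defined for indels only.

Allele trimming removes the common suffix first (keeping at least one base
per allele), then the common prefix (advancing the position), then any
remaining common suffix — the last pass handles records anchored on the
trailing side, which arise e.g. when mirroring a genome. The result is
minimal: end characters differ or one allele is empty. For a pure
insertion, `pos` is the base after which the insertion occurs.

Canonicalization is per transcript: the most 3′ representation in the
coding transcript is the genomic right extreme for `+` strand genes and
the left extreme for `-` strand genes; the opposite extreme is the "most
5′ alternative" and is reported whenever it differs. Because every member
of the equivalence class shifts to the same extreme, the emitted canonical
string is independent of which representation the caller supplies.
Shifting operates on the genome sequence without regard to exon
boundaries; whether the canonical placement is exonic or intronic is then
decided by classification. The shift window starts at 100 bp and doubles
when the slide reaches its edge, capped at 10 kb, so unbounded repeat
tracts terminate deterministically. A variant overlapping transcripts on
both strands is normalized independently per transcript, so two rows for
the same input variant may cite different genomic placements.

## Nomenclature

Each variant × transcript yields one string: the DNA part and, where
defined, the protein part joined by one underscore. DNA part:
`c.<pos><ref>><alt>` for substitutions (bases in transcript orientation),
`del`/`ins`/`dup`/`delins` forms for length changes, with intron/UTR
decorations on both ends where needed (`c.-3_2del` across the CDS start is
legal and unique). Duplication notation is emitted exactly when the
inserted bases equal the reference bases immediately 5′ (transcript
orientation) of the 3′-normalized insertion point, and the cited
coordinates are that preceding copy.

Protein part: three-letter codes with initial capitals; `p.=` for
synonymous; `X` for stop (`p.Tyr1894X`); frameshifting indels carry no
protein part at all — most are degraded by nonsense-mediated decay, so a
hypothetical `fsTer` extension would be wrong more often than right, and
the nucleotide-only form is the established clinical style. Inframe indel
protein forms follow HGVS patterns (`p.Pro703dup`, `p.Asp400del`,
`p.X.._Y..delins..`), computed by re-translating the edited CDS and
diffing proteins with the changed block shifted maximally C-terminal
(prefix trimmed first). Start-codon substitutions get no protein part (the
IM class carries the information); a stop-codon substitution to a
non-stop is written `p.X<pos><aa>` by analogy with the substitution
grammar. Indels that span a CDS boundary (into UTR or intron) are
nucleotide-only. No emitted string ever contains `*` (except as the `c.*N`
UTR coordinate), `ter`, or whitespace.

## Consequence facts and classification

Facts are computed at the placement being annotated (canonical or
alternative — that is the point: the two may differ in class).

* Affected bases: the substituted base; the deleted interval; for an
  insertion, the two flanking bases.
* A substitution or deletion "alters" a splice base set when any affected
  base lies in it. An insertion does so only when **both** flanks lie in
  the set (strict interior): an insertion between offsets −9 and −8
  touches neither base and is intronic. The same strict-interior rule
  applies to the exon-end (EE) windows, which cover the first/last three
  bases of intron-adjacent exon edges only — transcript-terminal edges are
  not splice-relevant.
* CDS length change: deletions count deleted CDS-exonic bases; an
  insertion affects the CDS when both flanks are CDS bases, and — a
  documented choice, the behaviour is not observable from repeats alone —
  when one flank is a CDS base and the other intronic (exon/intron
  boundary insertions are treated as coding and classed FS/IF by frame).
  An insertion between `c.-1` and `c.1` is an untranslated-region change.
* Frameshift ⇔ CDS-overlapping length change not divisible by 3;
  frameshift ⇒ empty protein part.
* Start/stop disruption is interval overlap with codon 1 / the stop codon.
  For inframe edits fully inside the CDS, stop facts are refined by
  re-translation: stop-gain means premature termination (a stop before the
  edited CDS's final codon), stop-loss means no stop remains — an inframe
  deletion that shortens the protein but recreates a terminal stop is
  neither.

Classification evaluates the 14 predicates in the fixed priority order
SG > ESS > SS5 > SS > EE > FS > IM > SL > IF > NSY > SY > INT > 5PU > 3PU
and returns the first match, guaranteeing exactly one class. SG requires a
base substitution; EE additionally requires frame preservation. Impact
categories partition the classes: 1 = {ESS, FS, SG}, 2 = {NSY, SS5, IF,
IM, SL, EE}, 3 = {SY, SS, INT, 5PU, 3PU}.

SO terms are a total mapping from (class, facts), lowercase with
underscores, compounds joined by `|`: SS →
`intron_variant|splice_region_variant`; EE → `splice_region_variant`
joined with the coding consequence; ESS → acceptor/donor by affected
offset sign; SS5 → `splice_donor_5th_base_variant`; the remainder map to
the standard single terms (`missense_variant`, `frameshift_variant`,
`initiator_codon_variant`, `stop_lost`, `inframe_insertion`/`_deletion`,
`5_prime_utr_variant`, …). Terms not exercised by the worked examples
(acceptor ESS, IM, SL, UTR terms) are standard SO names adopted by
inference.

## Output and pipeline

TSV output is exactly the 18 columns `Chr Pos Ref Alt Qual Filter Type
ENST Gene TRINFO Loc CSN Class SO Impact "Alt ann" "Alt class" "Alt SO"`,
with `.` for empty cells; `Alt ann` is filled only when an alternative
representation yields a different string, `Alt class`/`Alt SO` only when
they differ from the canonical ones. Echo columns repeat the input record
after multi-allelic splitting but before trimming. `TRINFO` is
`<strand>/<span kb>/<exons>/<length kb>` with one decimal and no internal
spaces; `Loc` is `Ex<k>`, `In<k>/<k+1>`, `5UTR` or `3UTR`, with
boundary-spanning variants taking the exon-containing designation of their
first affected exonic base. Variant types are `Substitution`, `Insertion`,
`Deletion`, `Complex`.

VCF-append mode preserves every input line byte-for-byte except for one
added `VANN=` INFO key (plus one header line). The encoding —
`ALT:TYPE:ENST:GENE:TRINFO:LOC:CSN:CLASS:SO:IMPACT:ALTANN:ALTCLASS:ALTSO:SNPID`,
comma-separated per (allele, transcript), reserved characters
(`%:;,=| `) URL-escaped — is this package's own definition. rsID
assignment normalizes both the catalogue and the query to the trimmed,
left-aligned frame so equivalent indel representations match; identifiers
travel in the INFO encoding and the API (the TSV column set is fixed at
18). Malformed and REF-mismatching records are skipped with a logged
count, never fatal. Region filters are read from 3-column BED and
converted to 1-based inclusive on input.

Every data line is processed independently; `--workers N` distributes
line chunks over processes and merges in input order, so output is
byte-identical for any worker count.

## The synthetic fixtures

The fixture generator builds, from a seed, a single ~19 kb contig with six
complete genes (ATG…stop, CDS divisible by 3; three per strand; one
opposite-strand pair overlapping in their 3′ UTRs) whose engineered motifs
realize the geometries the annotator must get right: an engineered codon
panel reproducing the canonical substitution notations at their published
CDS coordinates; a CCT/CTC proline repeat (dup-vs-ins pair); a GGG tract
straddling an acceptor (class-changing alternative); a donor substitution
ladder at +1…+9; a poly-T acceptor tract (SS/INT pair); homopolymers, UTR,
start and stop cases. Generated VCFs are deliberately left-aligned — the
worst case for a strand-aware annotator — and ship with a truth table
derived purely from the generator's layout arithmetic, independent of the
annotation engine. Tract flanks are pinned to non-repeat bases so every
representation-set cardinality is exactly as designed.

What the fixtures do **not** emulate: real splice-site sequence context
beyond GT/AG ends, alternative transcripts per gene, incomplete or
NMD-annotated transcripts, multi-contig genomes, sequencing noise, or
genotypes. Passing tests therefore demonstrate coordinate, nomenclature
and classification correctness — not robustness to malformed real-world
annotation sets.

Problem sizes used by the test suite and acceptance script — 1,000 random
indels (≤6 bp) on 200 bp references for the enumeration oracle, 10,000
random coding variants for the retranslation oracle, exhaustive
position × {substitution, 1 bp del, 1 bp ins, 3 bp del} sweeps over two
genes for the classifier oracle, and every transcript base for the
round-trip checks — were chosen as the package's own verification budget:
large enough to exhaust the discrete case space of the rules above, small
enough to run on a laptop in seconds.

## Known limitations

* Protein notation for inframe delins that introduce an internal stop
  falls back to the deletion/delins form without spelling the new stop;
  the consequence facts (and hence class) are still correct.
* Stop-loss protein notation for indels at the stop codon is omitted
  (nucleotide-only); the paper-style `p.X<pos><aa>` form is emitted for
  substitutions only.
* Complex variants are never shifted and never get alternative
  representations; equal-length complex changes fully inside the CDS are
  classified by their protein effect, boundary-spanning ones
  conservatively by their removed-CDS count.
* One CDS per transcript: selenoproteins, ribosomal slippage and
  polycistronic arrangements are out of scope, as are CNV-scale exonic
  deletions/duplications, whose nomenclature is deliberately not attempted.
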