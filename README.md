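# varnom

Strand-aware clinical annotation of sequence variants: a library and CLI
that reads VCF, normalizes indels to their most 3′ position **in the coding
transcript**, and emits a single fixed nomenclature string, consequence
class, Sequence Ontology term and impact category per variant per
transcript — flagging any variant whose equivalent alternative
representation would be annotated differently.

## The problem

VCF convention left-aligns indels: an insertion or deletion inside a repeat
is placed at its most 5′ equivalent position on the forward genomic strand.
Clinical reporting (following HGVS) instead places indels at the most 3′
position in the coding transcript. Since roughly half of coding transcripts
are on the reverse DNA strand, annotating the left-aligned VCF coordinates
directly gives clinically discrepant calls for indels in forward-strand
genes, and an indel straddling an intron/exon boundary can even change
consequence class between representations (intronic insertion vs. inframe
duplication). `varnom` resolves this by:

1. enumerating the equivalence class of each indel (every placement whose
   application to the reference yields the same edited sequence);
2. canonicalizing per transcript — genomic right-shift for `+` strand
   genes, left-shift for `-` strand genes;
3. annotating the canonical representation, and reporting the most 5′
   alternative (with its own class) whenever it differs.

## Nomenclature and classes

Each variant × transcript gets one CSN (clinical sequencing nomenclature)
string: the coding-DNA change and, where defined, the protein change joined
by an underscore — `c.1040A>G_p.Gln347Arg`. Conventions: stop codons are
written `X` (never `*`/`ter`), synonymous changes are `p.=`, frameshifting
indels are nucleotide-only (`c.246delT`), and an insertion equal to the
reference bases immediately 5′ of its (3′-normalized) insertion point is
written as a duplication (`c.2107_2109dupCCT`).

Classification uses a single-class ontology evaluated in priority order
(first match wins):

| code | meaning | impact |
|------|---------|--------|
| SG   | stop-gain by base substitution | 1 |
| ESS  | essential splice-site base (±1, ±2) | 1 |
| SS5  | +5 donor base | 2 |
| SS   | first eight intronic bases flanking an exon | 3 |
| EE   | first/last three bases of an exon, frame kept | 2 |
| FS   | frameshifting indel | 1 |
| IM   | start-codon disruption | 2 |
| SL   | stop-codon disruption | 2 |
| IF   | inframe indel | 2 |
| NSY  | missense substitution | 2 |
| SY   | synonymous substitution | 3 |
| INT  | intronic, no splice base touched | 3 |
| 5PU / 3PU | untranslated region | 3 |

The priority rule matters: a frameshifting deletion that also removes the
start codon is FS, not IM.

## Worked example

The package ships a deterministic fixture generator (`varnom.fixtures`)
that builds a six-gene synthetic genome with engineered repeat motifs, so
everything below is reproducible without downloads:

```python
from varnom.fixtures import FixtureSpec, generate_fixture_genome, generate_fixture_vcf
g = generate_fixture_genome(FixtureSpec(seed=1), "demo")
generate_fixture_vcf(g, ["cct_dup", "splice_intronic_dup", "boundary_dup_insertion"], "demo/demo.vcf")
```

```sh
varnom annotate --in demo/demo.vcf --ref demo/fixture.fa --db demo/fixture.gtf
```

selected columns of the output:

```text
Pos    Ref  Alt   ENST    Loc    CSN                            Class  Impact  Alt ann                        Alt class
14357  A    ACTC  TX0002  Ex4    c.2107_2109dupCCT_p.Pro703dup  IF     2       c.2104_2105insCTC_p.Pro703dup  .
15530  G    GA    TX0005  In1/2  c.401-5dupT                    SS     3       c.401-9_401-8insT              INT
17497  T    TGGG  TX0003  Ex2    c.91_93dupGGG_p.Gly31dup       IF     2       c.91-10_91-9insGGG             INT
```

Reading the rows: the left-aligned `CTC` insertion at 14357 is really a
proline-codon duplication once 3′-shifted (the most 5′ alternative is
reported alongside, same class, so `Alt class` is empty); the poly-T
acceptor duplication at 15530 is a splice-region call whose alternative
representation is plain intronic; and the `GGG` insertion at 17497 —
intronic if left-aligned — is an inframe glycine duplication in the coding
transcript, a class-changing alternative that the annotator flags
explicitly.

Output is an 18-column TSV (`Chr Pos Ref Alt Qual Filter Type ENST Gene
TRINFO Loc CSN Class SO Impact "Alt ann" "Alt class" "Alt SO"`) or, with
`--format vcf`, the input VCF byte-identical except for one added `VANN=`
INFO key. `--workers N` parallelizes by line with an order-preserving
merge; output is identical for any worker count. Filters: `--no-intergenic`,
`--genes`, `--regions`, and `--snpdb` for rsID assignment (indels are
matched across equivalent representations).

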