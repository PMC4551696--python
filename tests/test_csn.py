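import random

import pytest

from oracles import oracle_facts, oracle_revcomp, oracle_translate, walk_transcript
from varnom.csn import CSNAnnotation, csn_indel, csn_substitution, variant_effect
from varnom.normalize import normalize_for_transcript
from varnom.reference import ReferenceGenome
from varnom.transcripts import CodingPosition, Transcript
from varnom.variants import GenomicVariant


def toy_transcript(cds="ATGCCTGGGTAA", pad=10):
    """Single-exon forward transcript whose CDS is the whole exon."""
    seq = "T" * pad + cds + "T" * pad
    ref = ReferenceGenome.from_dict({"c": seq})
    tx = Transcript(
        transcript_id="TOY", gene_symbol="TOY", chrom="c", strand="+",
        exons=[(pad + 1, pad + len(cds))], coding_start=pad + 1, coding_end=pad + len(cds),
    )
    return tx, ref


def test_full_joins_with_single_underscore():
    assert CSNAnnotation("c.1040A>G", "p.Gln347Arg").full == "c.1040A>G_p.Gln347Arg"
    assert CSNAnnotation("c.484+5delA").full == "c.484+5delA"


def test_substitution_csn_strings(db, genome, reference):
    """The engineered substitution panel yields the expected fixed strings:
    three-letter missense, 'p.=' synonymous, 'X' stop-gain."""
    g1 = genome.genes["SUBST1"]
    tx = db[g1.tx]
    for c, ref_b, alt_b, want in [
        (1040, "A", "G", "c.1040A>G_p.Gln347Arg"),
        (1911, "T", "C", "c.1911T>C_p.="),
        (5682, "C", "G", "c.5682C>G_p.Tyr1894X"),
    ]:
        got = csn_substitution(tx, CodingPosition(kind="cds", base=c), ref_b, alt_b, reference)
        assert got.full == want


def test_intronic_substitution_has_no_protein_part(db, genome, reference):
    g2 = genome.genes["MULTI2"]
    tx = db[g2.tx]
    v = GenomicVariant("1", g2.g_of_q(g2.q_of_intron(2, 5)), genome.base(g2.g_of_q(g2.q_of_intron(2, 5))), "C")
    eff = variant_effect(tx, v, reference)
    assert eff.csn.full == "c.700+5G>C"
    assert eff.protein_part == ""


def test_toy_dup_from_either_representation():
    """Insertion of CCT after c.6 of ATG CCT GGG TAA is c.4_6dupCCT_p.Pro2dup,
    whether supplied 3'-placed or as the left representation c.3_4insCCT."""
    tx, ref = toy_transcript()
    for pos_after in (13, 16):  # genomic: after c.3 and after c.6 (pad=10)
        v = GenomicVariant("c", pos_after, "", "CCT" if pos_after == 16 else "CCT")
        canonical, _alt = normalize_for_transcript(v, tx, ref)
        assert csn_indel(tx, canonical, ref).full == "c.4_6dupCCT_p.Pro2dup"


def test_frameshift_deletion_is_nucleotide_only(db, genome, reference):
    g2 = genome.genes["MULTI2"]
    tx = db[g2.tx]
    v = GenomicVariant("1", g2.g_of_q(g2.q_of_cds(246)), "T", "")
    eff = variant_effect(tx, v, reference)
    assert eff.csn.full == "c.246delT"
    assert eff.frameshift and eff.protein_part == ""


def test_inframe_deletion_protein_form(db, genome, reference):
    g2 = genome.genes["MULTI2"]
    tx = db[g2.tx]
    start = g2.g_of_q(g2.q_of_cds(1198))
    v = GenomicVariant("1", start, genome.contig_seq[start - 1 : start + 2], "")
    eff = variant_effect(tx, v, reference)
    assert eff.csn.full == "c.1198_1200delGAC_p.Asp400del"
    assert not eff.frameshift and eff.net == -3


def test_intronic_dup_notation(db, genome, reference):
    """Reverse-strand poly-T acceptor: canonical dup vs most-5' ins notation."""
    g5 = genome.genes["REV5"]
    tx = db[g5.tx]
    tract = sorted(g5.g_of_q(g5.q_of_intron(1, o)) for o in (-8, -7, -6, -5))
    v = GenomicVariant("1", tract[0] - 1, "", "A")
    canonical, alt5 = normalize_for_transcript(v, tx, reference)
    assert csn_indel(tx, canonical, reference).full == "c.401-5dupT"
    assert csn_indel(tx, alt5, reference).full == "c.401-9_401-8insT"


def test_csn_never_contains_forbidden_tokens(annotated_rows):
    for row in annotated_rows:
        for cell in (row["CSN"], row["Alt ann"]):
            if cell == ".":
                continue
            assert "*" not in cell.replace("c.*", "").replace("_*", "")  # '*' only as UTR3 coordinate
            assert "ter" not in cell.lower().replace("alter", "")
            assert " " not in cell
            assert cell.count("_p.") <= 1


def test_dup_emitted_iff_preceding_copy_exists():
    """dup notation appears exactly when the inserted bases equal the
    reference immediately 5' of the 3'-normalized insertion point."""
    tx, ref = toy_transcript("ATGCCTGGGTAA")
    # GGG insertion after c.9 duplicates the Gly codon
    v = GenomicVariant("c", 19, "", "GGG")
    canonical, _ = normalize_for_transcript(v, tx, ref)
    assert csn_indel(tx, canonical, ref).dna_part == "c.7_9dupGGG"
    # AAA insertion at the same spot has no preceding copy: plain ins
    v2 = GenomicVariant("c", 19, "", "AAA")
    canonical2, _ = normalize_for_transcript(v2, tx, ref)
    assert "ins" in csn_indel(tx, canonical2, ref).dna_part


@pytest.mark.parametrize("gene_name", ["MULTI2", "REV5", "UTR6"])
def test_protein_facts_match_full_retranslation_oracle(db, genome, reference, gene_name):
    """Random in-CDS variants: facts agree with naive edited-CDS retranslation."""
    g = genome.genes[gene_name]
    tx = db[g.tx]
    rng = random.Random(hash(gene_name) % 10_000)
    _t, label = walk_transcript(tx)
    n_cds = len(g.cds)
    checked = 0
    for _ in range(400):
        kind = rng.choice(["sub", "del1", "del2", "del3", "ins1", "ins3"])
        c = rng.randint(4, n_cds - 6)
        # keep the edit inside one exon so the naive oracle stays simple
        qs = [g.q_of_cds(c + i) for i in range(0, 4)]
        if max(qs) - min(qs) != 3:
            continue
        gpos = g.g_of_q(g.q_of_cds(c))
        if kind == "sub":
            ref_b = genome.base(gpos)
            alt_b = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_b]
            v = GenomicVariant("1", gpos, ref_b, alt_b)
        elif kind.startswith("del"):
            L = int(kind[3])
            lo = min(gpos, g.g_of_q(g.q_of_cds(c + L - 1)))
            v = GenomicVariant("1", lo, genome.contig_seq[lo - 1 : lo - 1 + L], "")
        else:
            L = int(kind[3])
            ins = "".join(rng.choice("ACGT") for _ in range(L))
            v = GenomicVariant("1", gpos, "", ins)
        eff = variant_effect(tx, v, reference)
        want = oracle_facts(tx, v, reference, label=label)
        for f in ("frameshift", "start_lost", "stop_lost", "stop_gained", "synonymous"):
            assert getattr(eff, f) == want[f], (gene_name, v, f)
        checked += 1
    assert checked > 300


def test_reverse_strand_bases_reported_in_transcript_orientation(db, genome, reference):
    g5 = genome.genes["REV5"]
    tx = db[g5.tx]
    gpos = g5.g_of_q(g5.q_of_cds(299))
    v = GenomicVariant("1", gpos, "T", "C")  # genomic T>C == transcript A>G
    eff = variant_effect(tx, v, reference)
    assert eff.csn.full == "c.299A>G_p.Gln100Arg"


def test_oracle_translate_agrees_with_package_translation():
    from varnom.csn import translate

    rng = random.Random(7)
    for _ in range(50):
        seq = "".join(rng.choice("ACGT") for _ in range(30))
        assert translate(seq) == oracle_translate(seq)
    assert oracle_revcomp("ACGT") == "ACGT"
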