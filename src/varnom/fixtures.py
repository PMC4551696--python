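"""Deterministic synthetic genome, transcript set and VCF generation.

The generator builds a single-contig genome carrying six engineered genes
(three per strand, one overlapping opposite-strand pair) whose sequence
motifs reproduce, at synthetic coordinates, the structures that matter for
strand-aware clinical annotation:

* a long forward-strand gene with engineered codons for a panel of exonic
  base substitutions (stop-gain / missense / synonymous);
* a CCT/CTC proline repeat where a left-aligned insertion is an
  intronic-looking ``ins`` but the 3'-normalized call is a ``dupCCT``;
* a glycine GGG tract straddling an intron/exon boundary, so a GGG
  insertion is intronic when left-aligned but an inframe Gly duplication
  in the most 3' coding-transcript representation;
* a splice-site substitution ladder at donor offsets +1..+9;
* a poly-T tract in a reverse-strand acceptor where the canonical dup is a
  splice-region call and the most 5' alternative is plain intronic;
* homopolymer indels, UTR/start/stop substitutions, and a shared poly-A
  tract inside the dual-strand overlap.

Every engineered site is recorded with its expected annotation (generator
bookkeeping, derived purely from layout arithmetic) so generated VCFs ship
with a truth table. Identical seed and spec give byte-identical outputs.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

from varnom.transcripts import revcomp

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
NON_STOP_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _rand_codons(rng: random.Random, n: int) -> list[str]:
    return [rng.choice(NON_STOP_CODONS) for _ in range(n)]


@dataclass
class FixtureSpec:
    """Blueprint parameters for the synthetic genome."""

    seed: int = 1
    contig: str = "1"
    gap: int = 300  # random spacer between genes


@dataclass
class FixtureGene:
    """One placed gene: transcript-oriented layout plus genomic anchoring.

    ``gene_seq`` is the full transcript-orientation sequence including
    introns; on the reverse strand the genomic sequence is its reverse
    complement. All layout arithmetic used for truth bookkeeping lives
    here, independent of the annotation engine's coordinate mapper.
    """

    gene: str
    tx: str
    strand: str
    utr5: str
    cds: str
    utr3: str
    exon_lens: list[int]
    introns: list[str]
    gstart: int = 0  # genomic start of the span (1-based), set at placement
    gene_seq: str = field(init=False)

    def __post_init__(self):
        tx_seq = self.utr5 + self.cds + self.utr3
        if sum(self.exon_lens) != len(tx_seq):
            raise ValueError(f"{self.gene}: exon lengths do not cover the transcript")
        if len(self.exon_lens) != len(self.introns) + 1:
            raise ValueError(f"{self.gene}: need one intron between consecutive exons")
        if len(self.cds) % 3 or not self.cds.startswith("ATG") or self.cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.gene}: CDS must be ATG..stop and divisible by 3")
        parts = []
        t = 0
        for i, elen in enumerate(self.exon_lens):
            parts.append(tx_seq[t : t + elen])
            t += elen
            if i < len(self.introns):
                parts.append(self.introns[i])
        self.gene_seq = "".join(parts)

    # -- transcript-orientation geometry (q = 1-based index in gene_seq) ---

    @property
    def span(self) -> int:
        return len(self.gene_seq)

    @property
    def gend(self) -> int:
        return self.gstart + self.span - 1

    @property
    def tx_len(self) -> int:
        return sum(self.exon_lens)

    def _exon_q_ranges(self) -> list[tuple[int, int]]:
        out, q = [], 1
        for i, elen in enumerate(self.exon_lens):
            out.append((q, q + elen - 1))
            q += elen
            if i < len(self.introns):
                q += len(self.introns[i])
        return out

    def q_of_t(self, t: int) -> int:
        """Spliced transcript position -> gene-wide position."""
        cum = 0
        for (qs, qe), elen in zip(self._exon_q_ranges(), self.exon_lens):
            if t <= cum + elen:
                return qs + (t - cum - 1)
            cum += elen
        raise ValueError(f"t={t} beyond transcript")

    def q_of_cds(self, c: int) -> int:
        return self.q_of_t(len(self.utr5) + c)

    def q_of_utr5(self, u: int) -> int:  # u bases before the CDS (c.-u)
        return self.q_of_t(len(self.utr5) - u + 1)

    def q_of_utr3(self, u: int) -> int:  # u bases past the stop (c.*u)
        return self.q_of_t(len(self.utr5) + len(self.cds) + u)

    def q_of_intron(self, intron_idx: int, offset: int) -> int:
        """Gene-wide position of intron base at signed transcript offset."""
        ranges = self._exon_q_ranges()
        if offset > 0:
            return ranges[intron_idx - 1][1] + offset
        return ranges[intron_idx][0] + offset

    # -- genomic anchoring -------------------------------------------------

    def g_of_q(self, q: int) -> int:
        return self.gstart + q - 1 if self.strand == "+" else self.gend - q + 1

    def genomic_base_of_q(self, q: int) -> str:
        b = self.gene_seq[q - 1]
        return b if self.strand == "+" else _comp(b)

    def genomic_exons(self) -> list[tuple[int, int]]:
        out = []
        for qs, qe in self._exon_q_ranges():
            a, b = self.g_of_q(qs), self.g_of_q(qe)
            out.append((min(a, b), max(a, b)))
        return sorted(out)

    @property
    def coding_start_g(self) -> int:
        return self.g_of_q(self.q_of_cds(1))

    @property
    def coding_end_g(self) -> int:
        return self.g_of_q(self.q_of_cds(len(self.cds)))

    def trinfo(self) -> str:
        return f"{self.strand}/{self.span / 1000:.1f}kb/{len(self.exon_lens)}/{self.tx_len / 1000:.1f}kb"


# ---------------------------------------------------------------------------
# gene construction


# Engineered codon panel for the exonic-substitution gene: aa index -> codon,
# chosen so the twelve case substitutions below produce the intended
# stop-gain / missense / synonymous changes.
_SUBST_CODONS = {
    347: "CAG", 637: "GGT", 1088: "CCT", 1172: "TCG", 1894: "TAC", 1952: "TTA",
    2044: "GGT", 2225: "ACA", 2520: "CGA", 2728: "GTT", 3326: "AAA",
}

# (cds_pos, ref, alt, csn, class, so, impact) — all bases transcript-oriented
_PANEL_CASES = [
    (1040, "A", "G", "c.1040A>G_p.Gln347Arg", "NSY", "missense_variant", 2),
    (1911, "T", "C", "c.1911T>C_p.=", "SY", "synonymous_variant", 3),
    (3264, "T", "C", "c.3264T>C_p.=", "SY", "synonymous_variant", 3),
    (3515, "C", "T", "c.3515C>T_p.Ser1172Leu", "NSY", "missense_variant", 2),
    (3516, "G", "A", "c.3516G>A_p.=", "SY", "synonymous_variant", 3),
    (5682, "C", "G", "c.5682C>G_p.Tyr1894X", "SG", "stop_gained", 1),
    (5855, "T", "A", "c.5855T>A_p.Leu1952X", "SG", "stop_gained", 1),
    (6131, "G", "T", "c.6131G>T_p.Gly2044Val", "NSY", "missense_variant", 2),
    (6675, "A", "G", "c.6675A>G_p.=", "SY", "synonymous_variant", 3),
    (7558, "C", "T", "c.7558C>T_p.Arg2520X", "SG", "stop_gained", 1),
    (8182, "G", "A", "c.8182G>A_p.Val2728Ile", "NSY", "missense_variant", 2),
    (9976, "A", "T", "c.9976A>T_p.Lys3326X", "SG", "stop_gained", 1),
]

_LADDER_BASES = "GTAAGTGAT"  # donor intron offsets +1..+9
_LADDER_TRUTH = [
    ("ESS", "splice_donor_variant", 1),
    ("ESS", "splice_donor_variant", 1),
    ("SS", "intron_variant|splice_region_variant", 3),
    ("SS", "intron_variant|splice_region_variant", 3),
    ("SS5", "splice_donor_5th_base_variant", 2),
    ("SS", "intron_variant|splice_region_variant", 3),
    ("SS", "intron_variant|splice_region_variant", 3),
    ("SS", "intron_variant|splice_region_variant", 3),
    ("INT", "intron_variant", 3),
]
_TRANSVERT = {"A": "C", "C": "A", "G": "C", "T": "G"}


def _make_cds(rng: random.Random, n_codons: int, engineered: dict[int, str]) -> str:
    """CDS of ``n_codons`` codons total (ATG .. TAA), with engineered overrides."""
    codons = ["ATG"] + _rand_codons(rng, n_codons - 2) + ["TAA"]
    for idx, codon in engineered.items():
        codons[idx - 1] = codon
    return "".join(codons)


def _intron(rng: random.Random, length: int) -> str:
    return "GT" + _rand_seq(rng, length - 4) + "AG"


def _build_gene1(rng) -> FixtureGene:
    cds = _make_cds(rng, 3401, _SUBST_CODONS)
    return FixtureGene(
        gene="SUBST1", tx="TX0001", strand="+",
        utr5=_rand_seq(rng, 50), cds=cds, utr3=_rand_seq(rng, 50),
        exon_lens=[1500, 4000, 4803],
        introns=[_intron(rng, 200), _intron(rng, 300)],
    )


def _build_gene2(rng) -> FixtureGene:
    engineered = {
        82: "GCT", 83: "AAA", 234: "CTA",
        333: "TTC", 334: "AAA", 335: "AAA", 336: "GGA",
        399: "TTT", 400: "GAC", 401: "AAA",
        701: "TTG", 702: "ACT", 703: "CCT", 704: "AAG",
    }
    cds = _make_cds(rng, 801, engineered)
    utr5 = _rand_seq(rng, 19) + "C"  # last UTR base fixed to pin indel extremes
    i2 = "GT" + _LADDER_BASES[2:] + _rand_seq(rng, 250 - 2 - 7 - 2) + "AG"
    assert i2[:9] == _LADDER_BASES and len(i2) == 250
    return FixtureGene(
        gene="MULTI2", tx="TX0002", strand="+",
        utr5=utr5, cds=cds, utr3=_rand_seq(rng, 30),
        exon_lens=[120, 600, 1200, 533],
        introns=[_intron(rng, 300), i2, _intron(rng, 280)],
    )


def _build_gene3(rng) -> FixtureGene:
    engineered = {31: "GGG", 32: "ACC"}
    cds = _make_cds(rng, 201, engineered)
    i1 = "GT" + _rand_seq(rng, 108) + "T" + "G" * 9  # acceptor-straddling G tract
    utr3 = list(_rand_seq(rng, 130))
    utr3[58] = "C"  # *59
    utr3[59:65] = list("AAAAAA")  # *60..*65
    utr3[65] = "G"  # *66
    return FixtureGene(
        gene="GLYR3F", tx="TX0003", strand="+",
        utr5=_rand_seq(rng, 15), cds=cds, utr3="".join(utr3),
        exon_lens=[105, 210, 433],
        introns=[i1, _intron(rng, 150)],
    )


def _build_gene4(rng, overlap_tail: str) -> FixtureGene:
    cds = _make_cds(rng, 151, {})
    utr3 = _rand_seq(rng, 20) + revcomp(overlap_tail)
    return FixtureGene(
        gene="OVLP4R", tx="TX0004", strand="-",
        utr5=_rand_seq(rng, 40), cds=cds, utr3=utr3,
        exon_lens=[240, 373],
        introns=[_intron(rng, 100)],
    )


def _build_gene5(rng) -> FixtureGene:
    engineered = {100: "CAG"}
    cds = _make_cds(rng, 300, engineered)
    i1 = "GT" + _rand_seq(rng, 189) + "GTTTTCCAG"  # acceptor: T tract at -8..-5
    return FixtureGene(
        gene="REV5", tx="TX0005", strand="-",
        utr5=_rand_seq(rng, 25), cds=cds, utr3=_rand_seq(rng, 40),
        exon_lens=[425, 540],
        introns=[i1],
    )


def _build_gene6(rng) -> FixtureGene:
    cds = _make_cds(rng, 100, {})
    utr5 = list(_rand_seq(rng, 30))
    utr5[18] = "G"  # c.-12
    utr3 = list(_rand_seq(rng, 50))
    utr3[7] = "C"  # c.*8
    return FixtureGene(
        gene="UTR6", tx="TX0006", strand="-",
        utr5="".join(utr5), cds=cds, utr3="".join(utr3),
        exon_lens=[180, 200],
        introns=[_intron(rng, 150)],
    )


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class FixtureGenome:
    spec: FixtureSpec
    contig_seq: str
    genes: dict[str, FixtureGene]

    @property
    def contig(self) -> str:
        return self.spec.contig

    def base(self, pos: int) -> str:
        return self.contig_seq[pos - 1]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.contig_seq), 60):
                fh.write(self.contig_seq[i : i + 60] + "\n")

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##description: synthetic fixture transcript set\n")
            for name in sorted(self.genes):
                g = self.genes[name]
                attrs = f'gene_id "{g.gene}"; transcript_id "{g.tx}"; gene_name "{g.gene}";'
                lo, hi = sorted((g.coding_start_g, g.coding_end_g))
                fh.write(
                    f"{self.contig}\tfixture\ttranscript\t{g.gstart}\t{g.gend}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for es, ee in g.genomic_exons():
                    fh.write(f"{self.contig}\tfixture\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n")
                    cs, ce = max(es, lo), min(ee, hi)
                    if cs <= ce:
                        # CDS features include the stop codon in this format
                        fh.write(f"{self.contig}\tfixture\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t{attrs}\n")

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#gene\ttranscript\tstrand\tstart\tend\texons\tcoding_start\tcoding_end\ttrinfo\n")
            for name in sorted(self.genes):
                g = self.genes[name]
                exons = ",".join(f"{s}-{e}" for s, e in g.genomic_exons())
                fh.write(
                    f"{g.gene}\t{g.tx}\t{g.strand}\t{g.gstart}\t{g.gend}\t{exons}\t"
                    f"{g.coding_start_g}\t{g.coding_end_g}\t{g.trinfo()}\n"
                )


def generate_fixture_genome(spec: FixtureSpec | None = None, outdir=None) -> FixtureGenome:
    """Build the synthetic genome; optionally write FASTA/GTF/manifest to ``outdir``.

    Same seed and spec give byte-identical outputs; changing the seed
    changes the random fill but not the structural manifest.
    """
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    g1, g2 = _build_gene1(rng), _build_gene2(rng)
    g5, g6 = _build_gene5(rng), _build_gene6(rng)
    g3 = _build_gene3(rng)

    parts: list[str] = []
    pos = 0

    def place(gene: FixtureGene, seq: str):
        nonlocal pos
        gene.gstart = pos + 1
        parts.append(seq)
        pos += len(seq)

    for gene in (g1, g2, g5, g6, g3):
        parts.append(_rand_seq(rng, spec.gap))
        pos += spec.gap
        place(gene, gene.gene_seq if gene.strand == "+" else revcomp(gene.gene_seq))

    # overlapping opposite-strand partner: its 3' UTR tail is the reverse
    # complement of the last 100 bases of gene 3's span
    overlap_tail = "".join(parts)[-100:]
    g4 = _build_gene4(rng, overlap_tail)
    g4.gstart = pos - 100 + 1
    g4_genomic = revcomp(g4.gene_seq)
    assert g4_genomic[:100] == overlap_tail
    parts.append(g4_genomic[100:])
    pos += len(g4_genomic) - 100
    parts.append(_rand_seq(rng, spec.gap))

    genome = FixtureGenome(
        spec=spec,
        contig_seq="".join(parts),
        genes={g.gene: g for g in (g1, g2, g3, g4, g5, g6)},
    )
    for g in genome.genes.values():
        lo, hi = g.gstart - 1, g.gend
        expect = g.gene_seq if g.strand == "+" else revcomp(g.gene_seq)
        assert genome.contig_seq[lo:hi] == expect
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        genome.write_fasta(os.path.join(outdir, "fixture.fa"))
        genome.write_gtf(os.path.join(outdir, "fixture.gtf"))
        genome.write_manifest(os.path.join(outdir, "fixture_manifest.tsv"))
    return genome


# ---------------------------------------------------------------------------
# case catalogue: VCF records + truth annotations


@dataclass(frozen=True)
class FixtureCase:
    name: str
    pos: int
    ref: str
    alt: str
    truth: tuple[dict, ...]  # one dict per expected output row


def _truth(gene: FixtureGene, pos, ref, alt, vtype, csn, cls, so, imp, loc,
           alt_ann=".", alt_class=".", alt_so="."):
    return {
        "chrom": "1", "pos": pos, "ref": ref, "alt": alt, "type": vtype,
        "enst": gene.tx, "gene": gene.gene, "trinfo": gene.trinfo(), "loc": loc,
        "csn": csn, "class": cls, "so": so, "impact": str(imp),
        "alt_ann": alt_ann, "alt_class": alt_class, "alt_so": alt_so,
    }


def _sub_case(genome: FixtureGenome, gene_name, name, q, alt_tx, csn, cls, so, imp, loc,
              alt_ann=".", alt_class=".", alt_so="."):
    g = genome.genes[gene_name]
    pos = g.g_of_q(q)
    ref = genome.base(pos)
    alt = alt_tx if g.strand == "+" else _comp(alt_tx)
    truth = (_truth(g, pos, ref, alt, "Substitution", csn, cls, so, imp, loc,
                    alt_ann, alt_class, alt_so),)
    return FixtureCase(name=name, pos=pos, ref=ref, alt=alt, truth=truth)


def _del_case_record(genome: FixtureGenome, gpos_first: int, length: int):
    """Left-anchored VCF alleles deleting ``length`` bases starting at ``gpos_first``."""
    anchor = genome.base(gpos_first - 1)
    deleted = genome.contig_seq[gpos_first - 1 : gpos_first - 1 + length]
    return gpos_first - 1, anchor + deleted, anchor


def _ins_case_record(genome: FixtureGenome, gpos_after: int, seq: str):
    anchor = genome.base(gpos_after)
    return gpos_after, anchor, anchor + seq


def build_cases(genome: FixtureGenome) -> dict[str, list[FixtureCase]]:
    """The documented case catalogue, with truth annotations per record."""
    cases: dict[str, list[FixtureCase]] = {}
    g1, g2, g3 = genome.genes["SUBST1"], genome.genes["MULTI2"], genome.genes["GLYR3F"]
    g4, g5, g6 = genome.genes["OVLP4R"], genome.genes["REV5"], genome.genes["UTR6"]

    # exonic base-substitution panel (long forward gene)
    subs = []
    for i, (c, ref_tx, alt_tx, csn, cls, so, imp) in enumerate(_PANEL_CASES):
        t = c + 50
        loc = "Ex1" if t <= 1500 else ("Ex2" if t <= 5500 else "Ex3")
        assert g1.cds[c - 1] == ref_tx
        subs.append(_sub_case(genome, "SUBST1", f"substitution_panel_{i}", g1.q_of_cds(c), alt_tx, csn, cls, so, imp, loc))
    cases["substitution_panel"] = subs

    # single-base frameshifting deletion with a unique placement
    pos, ref, alt = _del_case_record(genome, g2.g_of_q(g2.q_of_cds(246)), 1)
    cases["frameshift_del"] = [FixtureCase(
        "frameshift_del", pos, ref, alt,
        (_truth(g2, pos, ref, alt, "Deletion", "c.246delT", "FS", "frameshift_variant", 1, "Ex2"),),
    )]

    # proline-repeat insertion: left-aligned ins, canonical dupCCT
    pos, ref, alt = _ins_case_record(genome, g2.g_of_q(g2.q_of_cds(2104)), "CTC")
    cases["cct_dup"] = [FixtureCase(
        "cct_dup", pos, ref, alt,
        (_truth(g2, pos, ref, alt, "Insertion", "c.2107_2109dupCCT_p.Pro703dup", "IF",
                "inframe_insertion", 2, "Ex4", alt_ann="c.2104_2105insCTC_p.Pro703dup"),),
    )]

    # GGG insertion straddling the acceptor: inframe Gly dup vs intronic ins
    pos, ref, alt = _ins_case_record(genome, g3.g_of_q(g3.q_of_intron(1, -10)), "GGG")
    cases["boundary_dup_insertion"] = [FixtureCase(
        "boundary_dup_insertion", pos, ref, alt,
        (_truth(g3, pos, ref, alt, "Insertion", "c.91_93dupGGG_p.Gly31dup", "IF",
                "inframe_insertion", 2, "Ex2",
                alt_ann="c.91-10_91-9insGGG", alt_class="INT", alt_so="intron_variant"),),
    )]

    # donor splice ladder at intron offsets +1..+9
    ladder = []
    for k in range(1, 10):
        ref_tx = _LADDER_BASES[k - 1]
        alt_tx = _TRANSVERT[ref_tx]
        cls, so, imp = _LADDER_TRUTH[k - 1]
        ladder.append(_sub_case(
            genome, "MULTI2", f"splice_ladder_{k}", g2.q_of_intron(2, k), alt_tx,
            f"c.700+{k}{ref_tx}>{alt_tx}", cls, so, imp, "In2/3",
        ))
    cases["splice_ladder"] = ladder

    # synonymous change at the last base of an internal exon
    cases["exon_end_synonymous"] = [_sub_case(
        genome, "MULTI2", "exon_end_synonymous", g2.q_of_cds(700), "T",
        "c.700C>T_p.=", "EE", "splice_region_variant|synonymous_variant", 2, "Ex2",
    )]

    # deletion of one A from a 6-A exonic homopolymer
    pos, ref, alt = _del_case_record(genome, g2.g_of_q(g2.q_of_cds(1000)), 1)
    cases["homopolymer_del"] = [FixtureCase(
        "homopolymer_del", pos, ref, alt,
        (_truth(g2, pos, ref, alt, "Deletion", "c.1005delA", "FS", "frameshift_variant", 1,
                "Ex3", alt_ann="c.1000delA"),),
    )]

    # inframe single-codon deletion
    pos, ref, alt = _del_case_record(genome, g2.g_of_q(g2.q_of_cds(1198)), 3)
    cases["inframe_del"] = [FixtureCase(
        "inframe_del", pos, ref, alt,
        (_truth(g2, pos, ref, alt, "Deletion", "c.1198_1200delGAC_p.Asp400del", "IF",
                "inframe_deletion", 2, "Ex3"),),
    )]

    # frameshifting deletion removing start-codon bases: FS outranks IM
    pos, ref, alt = _del_case_record(genome, g2.g_of_q(g2.q_of_cds(1)), 2)
    cases["start_codon_frameshift"] = [FixtureCase(
        "start_codon_frameshift", pos, ref, alt,
        (_truth(g2, pos, ref, alt, "Deletion", "c.1_2delAT", "FS", "frameshift_variant", 1, "Ex1"),),
    )]

    # reverse-strand essential acceptor substitution
    cases["splice_acceptor_sub"] = [_sub_case(
        genome, "REV5", "splice_acceptor_sub", g5.q_of_intron(1, -1), "C",
        "c.401-1G>C", "ESS", "splice_acceptor_variant", 1, "In1/2",
    )]

    # reverse-strand poly-T acceptor dup: splice-region canonical, intronic alternative
    tract_g = sorted(g5.g_of_q(g5.q_of_intron(1, o)) for o in (-8, -7, -6, -5))
    pos, ref, alt = _ins_case_record(genome, tract_g[0] - 1, "A")
    cases["splice_intronic_dup"] = [FixtureCase(
        "splice_intronic_dup", pos, ref, alt,
        (_truth(g5, pos, ref, alt, "Insertion", "c.401-5dupT", "SS",
                "intron_variant|splice_region_variant", 3, "In1/2",
                alt_ann="c.401-9_401-8insT", alt_class="INT", alt_so="intron_variant"),),
    )]

    # reverse-strand missense
    cases["reverse_missense"] = [_sub_case(
        genome, "REV5", "reverse_missense", g5.q_of_cds(299), "G",
        "c.299A>G_p.Gln100Arg", "NSY", "missense_variant", 2, "Ex1",
    )]

    # start/stop disruption on the reverse strand
    cases["start_loss"] = [_sub_case(
        genome, "UTR6", "start_loss", g6.q_of_cds(2), "C",
        "c.2T>C", "IM", "initiator_codon_variant", 2, "Ex1",
    )]
    cases["stop_loss"] = [_sub_case(
        genome, "UTR6", "stop_loss", g6.q_of_cds(298), "C",
        "c.298T>C_p.X100Gln", "SL", "stop_lost", 2, "Ex2",
    )]

    # untranslated-region substitutions
    cases["utr_cases"] = [
        _sub_case(genome, "UTR6", "utr5_sub", g6.q_of_utr5(12), "A",
                  "c.-12G>A", "5PU", "5_prime_utr_variant", 3, "5UTR"),
        _sub_case(genome, "UTR6", "utr3_sub", g6.q_of_utr3(8), "T",
                  "c.*8C>T", "3PU", "3_prime_utr_variant", 3, "3UTR"),
    ]

    # deletion in the shared poly-A tract of the dual-strand overlap:
    # opposite canonical placements on the two transcripts
    tract_start = g3.g_of_q(g3.q_of_utr3(60))
    pos, ref, alt = _del_case_record(genome, tract_start, 1)
    cases["overlap_pair"] = [FixtureCase(
        "overlap_pair", pos, ref, alt,
        (
            _truth(g3, pos, ref, alt, "Deletion", "c.*65delA", "3PU", "3_prime_utr_variant", 3,
                   "3UTR", alt_ann="c.*60delA"),
            _truth(g4, pos, ref, alt, "Deletion", "c.*91delT", "3PU", "3_prime_utr_variant", 3,
                   "3UTR", alt_ann="c.*86delT"),
        ),
    )]

    return cases


CASE_NAMES = [
    "substitution_panel", "frameshift_del", "cct_dup", "boundary_dup_insertion", "splice_ladder",
    "exon_end_synonymous", "homopolymer_del", "inframe_del", "start_codon_frameshift",
    "splice_acceptor_sub", "splice_intronic_dup", "reverse_missense", "start_loss",
    "stop_loss", "utr_cases", "overlap_pair",
]

TRUTH_COLUMNS = [
    "case", "chrom", "pos", "ref", "alt", "type", "enst", "gene", "trinfo", "loc",
    "csn", "class", "so", "impact", "alt_ann", "alt_class", "alt_so",
]


def generate_fixture_vcf(genome: FixtureGenome, cases: list[str] | None = None,
                         vcf_path=None, truth_path=None) -> list[dict]:
    """Write a left-aligned VCF for the named cases plus its truth TSV.

    Returns the truth rows (one dict per expected output row). Unknown case
    names are fatal.
    """
    catalogue = build_cases(genome)
    names = cases if cases is not None else CASE_NAMES
    unknown = [n for n in names if n not in catalogue]
    if unknown:
        raise ValueError(f"unknown fixture case(s): {unknown}")
    selected = [fc for n in names for fc in catalogue[n]]
    selected.sort(key=lambda fc: (fc.pos, fc.ref, fc.alt))
    if vcf_path is not None:
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={genome.contig},length={len(genome.contig_seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for fc in selected:
                fh.write(f"{genome.contig}\t{fc.pos}\t.\t{fc.ref}\t{fc.alt}\t200\tPASS\t.\n")
    truth_rows = []
    for fc in selected:
        for row in fc.truth:
            truth_rows.append({"case": fc.name, **row})
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("\t".join(TRUTH_COLUMNS) + "\n")
            for row in truth_rows:
                fh.write("\t".join(str(row[c]) for c in TRUTH_COLUMNS) + "\n")
    return truth_rows


# ---------------------------------------------------------------------------
# strand mirroring


def mirror_files(fasta_path, gtf_path, vcf_path, outdir) -> tuple[str, str, str]:
    """Reverse-complement the fixture genome and remap GTF/VCF onto it.

    Every transcript flips strand; indel representations flip their
    alignment side. Annotation of the mirrored files must reproduce the
    original CSN strings and classes exactly.
    """
    os.makedirs(outdir, exist_ok=True)
    name, seq = None, []
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    raise ValueError("mirroring supports single-contig fixtures")
                name = line[1:].split()[0]
            elif line:
                seq.append(line)
    contig = "".join(seq)
    L = len(contig)
    mirrored = revcomp(contig)

    fa_out = os.path.join(outdir, "mirror.fa")
    with open(fa_out, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, L, 60):
            fh.write(mirrored[i : i + 60] + "\n")

    gtf_out = os.path.join(outdir, "mirror.gtf")
    rows = []
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            s, e = int(f[3]), int(f[4])
            f[3], f[4] = str(L - e + 1), str(L - s + 1)
            f[6] = "+" if f[6] == "-" else "-"
            rows.append(f)
    rows.sort(key=lambda f: (int(f[3]), int(f[4]), f[2]))
    with open(gtf_out, "w") as fh:
        for f in rows:
            fh.write("\t".join(f) + "\n")

    vcf_out = os.path.join(outdir, "mirror.vcf")
    header, data = [], []
    with open(vcf_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                header.append(line)
                continue
            f = line.split("\t")
            pos, ref = int(f[1]), f[3]
            new_pos = L - (pos + len(ref) - 1) + 1
            f[1] = str(new_pos)
            f[3] = revcomp(ref)
            f[4] = ",".join(revcomp(a) for a in f[4].split(","))
            data.append(f)
    data.sort(key=lambda f: int(f[1]))
    with open(vcf_out, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for f in data:
            fh.write("\t".join(f) + "\n")
    return fa_out, gtf_out, vcf_out
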