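"""CSN string generation and protein-level consequence analysis.

The CSN (clinical sequencing nomenclature) call is a single fixed string
per variant per transcript: the coding-DNA change and, where appropriate,
the protein change joined by an underscore, e.g. ``c.1040A>G_p.Gln347Arg``.
Conventions:

* stop codons are written ``X`` (never ``*`` or ``ter``);
* synonymous changes are written ``p.=``;
* frameshifting indels carry no protein part (nucleotide-only notation);
* indels are described at the placement supplied by the caller — the
  annotator normalizes to the most 3' position in the coding transcript
  first, so one variant always yields one string;
* an insertion whose bases equal the reference bases immediately 5' of the
  insertion point (transcript orientation) is written as a duplication;
* all bases and coordinates are in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Seq import Seq

from varnom.transcripts import CodingPosition, Transcript, coding_sequence, revcomp
from varnom.variants import GenomicVariant

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "X", "X": "X",
}


def three_letter(aa: str) -> str:
    return AA3[aa]


def translate(seq: str) -> str:
    """Translate a DNA string with the standard genetic code ('*' for stop)."""
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate())


@lru_cache(maxsize=64)
def _ref_protein(cds_seq: str) -> str:
    return translate(cds_seq)


@dataclass(frozen=True)
class CSNAnnotation:
    """The fixed nucleotide(+protein) notation for one variant on one transcript."""

    dna_part: str
    protein_part: str = ""

    @property
    def full(self) -> str:
        return f"{self.dna_part}_{self.protein_part}" if self.protein_part else self.dna_part


@dataclass
class VariantEffect:
    """Everything the classifier and formatter need about one placed variant.

    Facts are computed at the supplied placement (the caller normalizes
    beforehand); the class of an alternative representation may therefore
    legitimately differ from the canonical one.
    """

    tx: Transcript
    variant: GenomicVariant
    kind: str
    dna_part: str = ""
    protein_part: str = ""
    # affected geometry (transcript orientation)
    cpos_list: list[CodingPosition] = field(default_factory=list)  # sub/del/complex bases
    flank_cpos: tuple[CodingPosition, CodingPosition] | None = None  # insertion flanks 5',3'
    affected_t: list[int] = field(default_factory=list)  # spliced indices of exonic bases
    flank_t: tuple[int | None, int | None] | None = None
    intron_offsets: list[int] = field(default_factory=list)
    # consequence facts
    coding_change: bool = False
    net: int = 0
    frameshift: bool = False
    start_lost: bool = False
    stop_lost: bool = False
    stop_gained: bool = False
    aa_changed: bool = False
    synonymous: bool = False

    @property
    def csn(self) -> CSNAnnotation:
        return CSNAnnotation(dna_part=self.dna_part, protein_part=self.protein_part)


def _cds_coord(cp: CodingPosition) -> int | None:
    return cp.base if (cp.kind == "cds" and cp.offset == 0) else None


def _protein_diff(p_ref: str, p_alt: str) -> str:
    """Format an inframe protein change, HGVS-style, shifted most C-terminal.

    ``p_ref``/``p_alt`` are stop-free protein strings. The common prefix is
    trimmed maximally first (this yields the most 3' placement of the
    changed block), then the common suffix.
    """
    if p_ref == p_alt:
        return "p.="
    pre = 0
    while pre < len(p_ref) and pre < len(p_alt) and p_ref[pre] == p_alt[pre]:
        pre += 1
    suf = 0
    while (
        suf < len(p_ref) - pre and suf < len(p_alt) - pre and p_ref[-1 - suf] == p_alt[-1 - suf]
    ):
        suf += 1
    d = p_ref[pre : len(p_ref) - suf]  # deleted amino acids
    i = p_alt[pre : len(p_alt) - suf]  # inserted amino acids
    if not d and i:
        k = len(i)
        if pre >= k and p_ref[pre - k : pre] == i:  # duplication of the preceding k residues
            if k == 1:
                return f"p.{three_letter(i[0])}{pre}dup"
            return f"p.{three_letter(i[0])}{pre - k + 1}_{three_letter(i[-1])}{pre}dup"
        if pre == 0 or pre >= len(p_ref):
            # insertion at a protein terminus: fall back to a delins-style form
            return f"p.{pre}_{pre + 1}ins" + "".join(three_letter(a) for a in i)
        return (
            f"p.{three_letter(p_ref[pre - 1])}{pre}_{three_letter(p_ref[pre])}{pre + 1}ins"
            + "".join(three_letter(a) for a in i)
        )
    if d and not i:
        if len(d) == 1:
            return f"p.{three_letter(d[0])}{pre + 1}del"
        return f"p.{three_letter(d[0])}{pre + 1}_{three_letter(d[-1])}{pre + len(d)}del"
    ins3 = "".join(three_letter(a) for a in i)
    if len(d) == 1:
        return f"p.{three_letter(d[0])}{pre + 1}delins{ins3}"
    return f"p.{three_letter(d[0])}{pre + 1}_{three_letter(d[-1])}{pre + len(d)}delins{ins3}"


def variant_effect(
    tx: Transcript, variant: GenomicVariant, reference, cds_seq: str | None = None
) -> VariantEffect:
    """Analyse one (trimmed, placed) variant against one transcript.

    Returns geometry, consequence facts and the formatted CSN parts. The
    variant is analysed exactly where it sits; canonicalization is the
    caller's responsibility.
    """
    eff = VariantEffect(tx=tx, variant=variant, kind=variant.vtype)
    if cds_seq is None:
        cds_seq = coding_sequence(tx, reference)
    L = len(cds_seq)
    is_ins = variant.vtype == "Insertion"

    if is_ins:
        g5, g3 = (variant.pos, variant.pos + 1) if tx.strand == "+" else (variant.pos + 1, variant.pos)
        cp5, cp3 = tx.genomic_to_coding(g5), tx.genomic_to_coding(g3)
        eff.flank_cpos = (cp5, cp3)
        eff.flank_t = (tx.transcript_index(g5), tx.transcript_index(g3))
        eff.intron_offsets = [cp.offset for cp in (cp5, cp3) if cp.offset]
    else:
        gs, ge = variant.pos, variant.pos + len(variant.ref) - 1
        grange = range(gs, ge + 1) if tx.strand == "+" else range(ge, gs - 1, -1)
        for g in grange:  # transcript orientation
            cp = tx.genomic_to_coding(g)
            eff.cpos_list.append(cp)
            if cp.offset:
                eff.intron_offsets.append(cp.offset)
            else:
                eff.affected_t.append(tx.transcript_index(g))

    # -- nucleotide part ---------------------------------------------------
    if variant.vtype == "Substitution":
        cp = eff.cpos_list[0]
        r, a = variant.ref, variant.alt
        if tx.strand == "-":
            r, a = revcomp(r), revcomp(a)
        eff.dna_part = f"c.{cp.format()}{r}>{a}"
    elif variant.vtype == "Deletion":
        bases = variant.ref if tx.strand == "+" else revcomp(variant.ref)
        cps, cpe = eff.cpos_list[0], eff.cpos_list[-1]
        if len(bases) == 1:
            eff.dna_part = f"c.{cps.format()}del{bases}"
        else:
            eff.dna_part = f"c.{cps.format()}_{cpe.format()}del{bases}"
    elif is_ins:
        s_tx = variant.alt if tx.strand == "+" else revcomp(variant.alt)
        k = len(variant.alt)
        # duplication iff the inserted bases equal the reference immediately
        # 5' of the insertion point in transcript orientation
        if tx.strand == "+":
            dup_lo, dup_hi = variant.pos - k + 1, variant.pos
        else:
            dup_lo, dup_hi = variant.pos + 1, variant.pos + k
        is_dup = False
        if dup_lo >= 1 and dup_hi <= reference.length(variant.chrom):
            is_dup = reference.fetch(variant.chrom, dup_lo, dup_hi) == variant.alt
        span_lo, span_hi = tx.span
        is_dup = is_dup and dup_lo >= span_lo and dup_hi <= span_hi
        if is_dup:
            g5, g3 = (dup_lo, dup_hi) if tx.strand == "+" else (dup_hi, dup_lo)
            dps, dpe = tx.genomic_to_coding(g5), tx.genomic_to_coding(g3)
            if k == 1:
                eff.dna_part = f"c.{dps.format()}dup{s_tx}"
            else:
                eff.dna_part = f"c.{dps.format()}_{dpe.format()}dup{s_tx}"
        else:
            cp5, cp3 = eff.flank_cpos
            eff.dna_part = f"c.{cp5.format()}_{cp3.format()}ins{s_tx}"
    else:  # Complex
        s_tx = variant.alt if tx.strand == "+" else revcomp(variant.alt)
        cps, cpe = eff.cpos_list[0], eff.cpos_list[-1]
        if len(variant.ref) == 1:
            eff.dna_part = f"c.{cps.format()}delins{s_tx}"
        else:
            eff.dna_part = f"c.{cps.format()}_{cpe.format()}delins{s_tx}"

    # -- CDS overlap and frame --------------------------------------------
    if is_ins:
        cp5, cp3 = eff.flank_cpos
        kinds = {cp5.kind, cp3.kind}
        fully_in_cds = kinds == {"cds"}
        # an insertion at an exon/intron boundary with a CDS-exonic flank is
        # treated as coding (frame decides FS vs IF)
        boundary_cds = ("cds" in kinds and "intron" in kinds)
        eff.coding_change = fully_in_cds or boundary_cds
        eff.net = len(variant.alt) if eff.coding_change else 0
        n_cds_removed = 0
        affected_cds = []
    else:
        affected_cds = [c for c in (_cds_coord(cp) for cp in eff.cpos_list) if c is not None]
        n_cds_removed = len(affected_cds)
        if variant.vtype == "Substitution":
            eff.coding_change = n_cds_removed > 0
            eff.net = 0
        elif variant.vtype == "Deletion":
            eff.coding_change = n_cds_removed > 0
            eff.net = -n_cds_removed
        else:  # Complex: inserted bases count only when the change is fully in CDS
            eff.coding_change = n_cds_removed > 0
            if n_cds_removed == len(variant.ref):
                eff.net = len(variant.alt) - len(variant.ref)
            else:
                eff.net = -n_cds_removed
    eff.frameshift = eff.coding_change and variant.vtype != "Substitution" and eff.net % 3 != 0

    # -- start/stop interval facts ----------------------------------------
    start_codon = {1, 2, 3}
    stop_codon = {L - 2, L - 1, L}
    if is_ins:
        cp5 = eff.flank_cpos[0]
        c5 = _cds_coord(cp5)
        if eff.coding_change and c5 is not None:
            eff.start_lost = c5 in {1, 2}
            stop_touched = c5 in {L - 2, L - 1}
        else:
            stop_touched = False
    else:
        eff.start_lost = bool(set(affected_cds) & start_codon)
        stop_touched = bool(set(affected_cds) & stop_codon)

    # -- protein-level analysis -------------------------------------------
    if not eff.coding_change:
        return eff
    if eff.frameshift:
        eff.stop_lost = stop_touched  # fact only; frameshifts have no protein part
        return eff

    if variant.vtype == "Substitution":
        c = affected_cds[0]
        r_tx = variant.ref if tx.strand == "+" else revcomp(variant.ref)
        a_tx = variant.alt if tx.strand == "+" else revcomp(variant.alt)
        if cds_seq[c - 1] != r_tx:
            raise ValueError(
                f"{tx.transcript_id}: reference base at c.{c} is {cds_seq[c - 1]}, variant says {r_tx}"
            )
        idx = (c - 1) // 3  # 0-based codon index
        off = (c - 1) % 3
        ref_codon = cds_seq[idx * 3 : idx * 3 + 3]
        alt_codon = ref_codon[:off] + a_tx + ref_codon[off + 1 :]
        aa_ref, aa_alt = translate(ref_codon), translate(alt_codon)
        pos1 = idx + 1
        if idx == 0:
            eff.start_lost = True  # any change to the ATG start codon
            eff.aa_changed = aa_ref != aa_alt
            return eff
        if aa_ref == "*":
            if aa_alt == "*":
                eff.synonymous = True
                eff.protein_part = "p.="
            else:
                eff.stop_lost = True
                eff.aa_changed = True
                eff.protein_part = f"p.X{pos1}{three_letter(aa_alt)}"
            return eff
        if aa_alt == "*":
            eff.stop_gained = True
            eff.aa_changed = True
            eff.protein_part = f"p.{three_letter(aa_ref)}{pos1}X"
            return eff
        if aa_ref == aa_alt:
            eff.synonymous = True
            eff.protein_part = "p.="
        else:
            eff.aa_changed = True
            eff.protein_part = f"p.{three_letter(aa_ref)}{pos1}{three_letter(aa_alt)}"
        return eff

    # inframe indel / complex: rebuild the edited CDS when fully within it
    if is_ins:
        fully = {cp.kind for cp in eff.flank_cpos} == {"cds"}
        if fully:
            c5 = _cds_coord(eff.flank_cpos[0])
            s_tx = variant.alt if tx.strand == "+" else revcomp(variant.alt)
            edited = cds_seq[:c5] + s_tx + cds_seq[c5:]
        else:
            edited = None
    else:
        fully = len(affected_cds) == len(variant.ref)
        if fully:
            c1, c2 = min(affected_cds), max(affected_cds)
            s_tx = variant.alt if tx.strand == "+" else revcomp(variant.alt)
            edited = cds_seq[: c1 - 1] + s_tx + cds_seq[c2:]
        else:
            edited = None
    if edited is None:
        # boundary-spanning inframe change: nucleotide-only notation
        eff.stop_lost = stop_touched
        return eff

    p_ref_full = _ref_protein(cds_seq)
    p_alt_full = translate(edited)
    ref_stop = p_ref_full.find("*")
    alt_stop = p_alt_full.find("*")
    p_ref = p_ref_full[:ref_stop] if ref_stop >= 0 else p_ref_full
    p_alt = p_alt_full[:alt_stop] if alt_stop >= 0 else p_alt_full
    # premature termination: a stop before the final codon of the edited CDS
    eff.stop_gained = 0 <= alt_stop < len(edited) // 3 - 1
    eff.stop_lost = alt_stop < 0  # no stop anywhere: translation runs on
    if eff.start_lost:
        return eff
    if eff.stop_lost:
        return eff  # translation continues past the CDS: nucleotide-only
    eff.aa_changed = p_ref != p_alt
    eff.synonymous = not eff.aa_changed and eff.net == 0
    eff.protein_part = _protein_diff(p_ref, p_alt)
    return eff


# -- spec operation surface -------------------------------------------------


def csn_substitution(
    tx: Transcript,
    cpos: CodingPosition,
    ref_base: str,
    alt_base: str,
    reference=None,
    cds_seq: str | None = None,
) -> CSNAnnotation:
    """CSN for a single-base substitution given in transcript orientation."""
    g = tx.coding_to_genomic(cpos)
    r, a = (ref_base, alt_base) if tx.strand == "+" else (revcomp(ref_base), revcomp(alt_base))
    v = GenomicVariant(chrom=tx.chrom, pos=g, ref=r, alt=a)
    return variant_effect(tx, v, reference, cds_seq=cds_seq).csn


def csn_indel(tx: Transcript, canonical: GenomicVariant, reference) -> CSNAnnotation:
    """CSN for an indel/complex variant already normalized for ``tx``."""
    return variant_effect(tx, canonical, reference).csn


def protein_consequence(tx: Transcript, canonical: GenomicVariant, reference) -> VariantEffect:
    """Protein part plus consequence facts for a normalized variant."""
    return variant_effect(tx, canonical, reference)
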