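"""Single-class variant ontology, SO terms and impact categories.

Every (variant, transcript) pair receives exactly one class. Membership is
evaluated in a fixed priority order; the first class whose predicate holds
is assigned (so, e.g., a frameshifting deletion that removes the start
codon is FS, not IM, and a stop-gain at a splice-flanking exon base is SG,
not EE):

  SG   stop-gain (nonsense) caused by base substitution
  ESS  alters an essential splice-site base (+1, +2, -1, -2)
  SS5  alters the +5 splice-site base
  SS   within the first eight intronic bases flanking an exon (+8 to -8)
  EE   alters the first or last three bases of an exon (intron-adjacent
       edges only) without changing the reading frame
  FS   frameshifting insertion/deletion (length and frame of CDS change)
  IM   alters the initiating methionine codon
  SL   alters the stop codon
  IF   inframe insertion/deletion (length but not frame changes)
  NSY  nonsynonymous (missense) substitution
  SY   synonymous substitution
  INT  intronic, no splice-site base altered
  5PU  5' untranslated region
  3PU  3' untranslated region

Intron offsets are in transcript orientation: +k is k bases 3' of an exon
end (donor side), -k is k bases 5' of an exon start (acceptor side). A
substitution or deletion "alters" a base set when any affected base lies in
it; an insertion does so only when both flanking bases lie in it (strict
interior — an insertion between offsets -9 and -8 touches neither base and
is intronic).
"""

from __future__ import annotations

from dataclasses import dataclass

from varnom.csn import VariantEffect

CLASS_ORDER = [
    "SG", "ESS", "SS5", "SS", "EE", "FS", "IM", "SL", "IF", "NSY", "SY", "INT", "5PU", "3PU",
]

_IMPACT = {
    **{c: 1 for c in ("ESS", "FS", "SG")},
    **{c: 2 for c in ("NSY", "SS5", "IF", "IM", "SL", "EE")},
    **{c: 3 for c in ("SY", "SS", "INT", "5PU", "3PU")},
}


@dataclass(frozen=True)
class VariantClass:
    code: str

    def __post_init__(self):
        if self.code not in CLASS_ORDER:
            raise ValueError(f"unknown class {self.code!r}")

    @property
    def priority(self) -> int:
        return CLASS_ORDER.index(self.code)

    def __str__(self) -> str:
        return self.code


ESS_SET = {1, 2, -1, -2}
SS5_SET = {5}


def _alters_offsets(eff: VariantEffect, offset_set) -> bool:
    if eff.kind == "Insertion":
        o5, o3 = (cp.offset for cp in eff.flank_cpos)
        return o5 != 0 and o3 != 0 and o5 in offset_set and o3 in offset_set
    return any(o in offset_set for o in eff.intron_offsets)


def _exon_edge_windows(eff: VariantEffect) -> list[tuple[int, int]]:
    """Spliced-coordinate windows of the first/last 3 bases of intron-adjacent exon edges."""
    tx = eff.tx
    windows = []
    n = tx.exon_count
    for i, (s, e) in enumerate(tx.exons_tx, start=1):
        length = e - s + 1
        first = tx._cum[i - 1] + 1
        last = tx._cum[i - 1] + length
        if i > 1:  # exon start is intron-adjacent
            windows.append((first, min(first + 2, last)))
        if i < n:  # exon end is intron-adjacent
            windows.append((max(first, last - 2), last))
    return windows


def _alters_exon_end(eff: VariantEffect) -> bool:
    windows = _exon_edge_windows(eff)
    if eff.kind == "Insertion":
        t5, t3 = eff.flank_t
        if t5 is None or t3 is None:
            return False
        return any(a <= t5 <= b and a <= t3 <= b for a, b in windows)
    return any(a <= t <= b for t in eff.affected_t for a, b in windows)


def classify(eff: VariantEffect) -> VariantClass:
    """Assign the single class for one placed variant on one transcript."""
    ss_window = set(range(1, 9)) | set(range(-8, 0))
    checks = [
        ("SG", eff.kind == "Substitution" and eff.stop_gained),
        ("ESS", _alters_offsets(eff, ESS_SET)),
        ("SS5", _alters_offsets(eff, SS5_SET)),
        ("SS", _alters_offsets(eff, ss_window)),
        ("EE", not eff.frameshift and _alters_exon_end(eff)),
        ("FS", eff.frameshift),
        ("IM", eff.start_lost),
        ("SL", eff.stop_lost),
        ("IF", eff.coding_change and eff.kind != "Substitution" and eff.net != 0),
        ("NSY", eff.coding_change and eff.aa_changed),
        ("SY", eff.coding_change and eff.synonymous),
        ("INT", _is_intronic(eff)),
        ("5PU", _is_utr(eff, "utr5")),
        ("3PU", _is_utr(eff, "utr3")),
    ]
    for code, hit in checks:
        if hit:
            return VariantClass(code)
    # residual coding changes with no protein fact (e.g. boundary-spanning
    # equal-length complex): fall back on NSY-like severity via SY/NSY facts
    if eff.coding_change:
        return VariantClass("NSY")
    raise ValueError(f"unclassifiable variant {eff.variant} on {eff.tx.transcript_id}")


def _is_intronic(eff: VariantEffect) -> bool:
    if eff.kind == "Insertion":
        o5, o3 = (cp.offset for cp in eff.flank_cpos)
        return o5 != 0 and o3 != 0
    return bool(eff.intron_offsets) and not eff.affected_t


def _is_utr(eff: VariantEffect, kind: str) -> bool:
    if eff.coding_change:
        return False
    if eff.kind == "Insertion":
        kinds = {cp.kind for cp in eff.flank_cpos}
    else:
        kinds = {cp.kind for cp in eff.cpos_list}
    return kind in kinds


def so_term(vclass: VariantClass, eff: VariantEffect) -> str:
    """Sequence Ontology term string for an assigned class.

    Compound classes join their terms with ``|`` (e.g. SS is
    ``intron_variant|splice_region_variant``); strings are normalized to
    lowercase with underscores.
    """
    code = vclass.code
    if code == "SG":
        return "stop_gained"
    if code == "ESS":
        donor = _alters_offsets(eff, {1, 2})
        acceptor = _alters_offsets(eff, {-1, -2})
        terms = []
        if acceptor:
            terms.append("splice_acceptor_variant")
        if donor:
            terms.append("splice_donor_variant")
        return "|".join(terms) or "splice_acceptor_variant"
    if code == "SS5":
        return "splice_donor_5th_base_variant"
    if code == "SS":
        return "intron_variant|splice_region_variant"
    if code == "EE":
        if eff.aa_changed:
            coding = "missense_variant"
        elif eff.synonymous:
            coding = "synonymous_variant"
        elif eff.net > 0:
            coding = "inframe_insertion"
        elif eff.net < 0:
            coding = "inframe_deletion"
        else:
            coding = ""
        return "splice_region_variant" + (f"|{coding}" if coding else "")
    if code == "FS":
        return "frameshift_variant"
    if code == "IM":
        return "initiator_codon_variant"
    if code == "SL":
        return "stop_lost"
    if code == "IF":
        return "inframe_insertion" if eff.net > 0 else "inframe_deletion"
    if code == "NSY":
        return "missense_variant"
    if code == "SY":
        return "synonymous_variant"
    if code == "INT":
        return "intron_variant"
    if code == "5PU":
        return "5_prime_utr_variant"
    return "3_prime_utr_variant"


def impact(vclass: VariantClass) -> int:
    """Severity bucket: 1 = {ESS, FS, SG}; 2 = {NSY, SS5, IF, IM, SL, EE}; 3 = rest."""
    return _IMPACT[vclass.code]
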