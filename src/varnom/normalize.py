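"""Indel alignment: left/right shifting, equivalent-representation sets and
transcript-strand-aware canonicalization.

In repetitive sequence the placement of an insertion or deletion is
ambiguous: every placement that produces the same edited sequence is an
equivalent representation. VCF convention left-aligns (most 5' on the
forward genomic strand); clinical annotation requires the most 3' position
*in the coding transcript*, which is the genomic right extreme for
forward-strand transcripts and the genomic left extreme for reverse-strand
transcripts. Substitutions and complex (length-changing, both alleles
non-empty) variants are immobile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from varnom.variants import GenomicVariant

DEFAULT_WINDOW = 100
MAX_WINDOW = 10_000


@dataclass(frozen=True)
class RepresentationSet:
    """All equivalent placements of a variant, plus the two extremes."""

    leftmost: GenomicVariant
    rightmost: GenomicVariant
    members: tuple[GenomicVariant, ...]

    @property
    def has_alternatives(self) -> bool:
        return len(self.members) > 1

    def canonical_for_strand(self, strand: str) -> GenomicVariant:
        """Most 3' in the coding transcript for a gene on ``strand``."""
        return self.rightmost if strand == "+" else self.leftmost

    def most_5prime_for_strand(self, strand: str) -> GenomicVariant:
        return self.leftmost if strand == "+" else self.rightmost


def apply_to_reference(v: GenomicVariant, seq: str, seq_start: int) -> str:
    """Apply ``v`` to the reference slice ``seq`` beginning at genomic ``seq_start``."""
    i = v.pos - seq_start  # 0-based index of first ref base (or insertion anchor)
    if not v.ref:  # insertion after pos
        return seq[: i + 1] + v.alt + seq[i + 1 :]
    if seq[i : i + len(v.ref)] != v.ref:
        raise ValueError("variant REF does not match the supplied sequence")
    return seq[:i] + v.alt + seq[i + len(v.ref) :]


class _Window:
    """Reference window around a variant, growing on demand up to MAX_WINDOW."""

    def __init__(self, reference, chrom: str, center: int, half: int):
        self.ref = reference
        self.chrom = reference.resolve(chrom)
        self.contig_len = reference.length(self.chrom)
        self.half = half
        self.center = center
        self._fetch()

    def _fetch(self):
        self.start = max(1, self.center - self.half)
        self.end = min(self.contig_len, self.center + self.half)
        self.seq = self.ref.fetch(self.chrom, self.start, self.end)

    def base(self, pos: int) -> str | None:
        if pos < 1 or pos > self.contig_len:
            return None
        while (pos < self.start or pos > self.end) and self.half < MAX_WINDOW:
            self.half = min(self.half * 2, MAX_WINDOW)
            self._fetch()
        if pos < self.start or pos > self.end:
            return None
        return self.seq[pos - self.start]


def _shift_once(pos: int, allele: str, win: _Window, direction: str, is_del: bool):
    """One single-base shift step; returns (pos, allele) or None if blocked."""
    L = len(allele)
    if is_del:
        if direction == "right":
            nxt = win.base(pos + L)
            if nxt is None or nxt != allele[0]:
                return None
            return pos + 1, allele[1:] + nxt
        prv = win.base(pos - 1)
        if prv is None or prv != allele[-1]:
            return None
        return pos - 1, prv + allele[:-1]
    # insertion after pos
    if direction == "right":
        nxt = win.base(pos + 1)
        if nxt is None or nxt != allele[0]:
            return None
        return pos + 1, allele[1:] + nxt
    cur = win.base(pos)
    if cur is None or cur != allele[-1]:
        return None
    return pos - 1, cur + allele[:-1]


def shift(variant: GenomicVariant, reference, direction: str, window: int = DEFAULT_WINDOW) -> GenomicVariant:
    """Slide a pure indel to its extreme equivalent position in ``direction``.

    Substitutions and complex variants are immobile and returned unchanged.
    The search window doubles if the shift reaches its edge, up to a hard
    cap, so unbounded repeat tracts terminate deterministically.
    """
    if direction not in ("left", "right"):
        raise ValueError(f"bad direction {direction!r}")
    if variant.vtype not in ("Insertion", "Deletion"):
        return variant
    is_del = variant.vtype == "Deletion"
    allele = variant.ref if is_del else variant.alt
    win = _Window(reference, variant.chrom, variant.pos, max(window, len(allele) + 1))
    pos = variant.pos
    while True:
        step = _shift_once(pos, allele, win, direction, is_del)
        if step is None:
            break
        pos, allele = step
    if is_del:
        return replace(variant, pos=pos, ref=allele)
    return replace(variant, pos=pos, alt=allele)


def enumerate_representations(
    variant: GenomicVariant, reference, window: int = DEFAULT_WINDOW
) -> RepresentationSet:
    """All trimmed equivalent representations, sliding between the extremes.

    Every member applied to the reference yields the identical edited
    sequence (the defining equivalence); immobile variants give a
    single-member set.
    """
    if variant.vtype not in ("Insertion", "Deletion"):
        return RepresentationSet(leftmost=variant, rightmost=variant, members=(variant,))
    is_del = variant.vtype == "Deletion"
    left = shift(variant, reference, "left", window)
    win = _Window(reference, variant.chrom, left.pos, max(window, len(variant.ref + variant.alt) + 1))
    members = [left]
    pos = left.pos
    allele = left.ref if is_del else left.alt
    while True:
        step = _shift_once(pos, allele, win, "right", is_del)
        if step is None:
            break
        pos, allele = step
        members.append(
            replace(variant, pos=pos, ref=allele) if is_del else replace(variant, pos=pos, alt=allele)
        )
    return RepresentationSet(leftmost=members[0], rightmost=members[-1], members=tuple(members))


def normalize_for_transcript(
    variant: GenomicVariant, tx, reference
) -> tuple[GenomicVariant, GenomicVariant | None]:
    """Canonical (most 3' in the coding transcript) placement plus the most 5' alternative.

    Returns ``(canonical, alt5)`` where ``alt5`` is None when the variant
    has a single representation. The same canonical placement results no
    matter which member of the representation set is supplied.
    """
    if variant.vtype not in ("Insertion", "Deletion"):
        return variant, None
    canonical = shift(variant, reference, "right" if tx.strand == "+" else "left")
    alt5 = shift(variant, reference, "left" if tx.strand == "+" else "right")
    if (alt5.pos, alt5.ref, alt5.alt) == (canonical.pos, canonical.ref, canonical.alt):
        return canonical, None
    return canonical, alt5
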