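"""VCF parsing and allele canonicalization (trimming).

Variants are held as :class:`GenomicVariant`: trimmed alleles in 1-based
genomic coordinates. For a pure insertion ``pos`` is the base *after which*
the insertion occurs and ``ref`` is empty; for a pure deletion ``pos`` is
the first deleted base and ``alt`` is empty.

The reader works line-by-line so the original VCF line can be carried
through unchanged for annotation-append output, and so lines can be
processed independently (and hence in parallel).
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, replace
from typing import Iterator

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicVariant:
    """One chrom/pos/ref/alt allele change in reference coordinates (trimmed).

    ``vcf_pos``/``vcf_ref``/``vcf_alt`` echo the input record after
    multi-allelic splitting but before trimming, for faithful output.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: str = "."
    filter: str = "."
    vcf_pos: int | None = None
    vcf_ref: str | None = None
    vcf_alt: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical: not a variant")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "Substitution"
        if not self.ref:
            return "Insertion"
        if not self.alt:
            return "Deletion"
        return "Complex"

    @property
    def is_indel(self) -> bool:
        return self.vtype in ("Insertion", "Deletion")

    @property
    def affected_span(self) -> tuple[int, int]:
        """Genomic interval touched by the variant (flanks for an insertion)."""
        if not self.ref:
            return self.pos, self.pos + 1
        return self.pos, self.pos + len(self.ref) - 1

    def with_echo(self, pos: int, ref: str, alt: str) -> "GenomicVariant":
        return replace(self, vcf_pos=pos, vcf_ref=ref, vcf_alt=alt)


def trim(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Minimize an allele pair: strip the common suffix, then the common prefix.

    Suffix stripping keeps at least one base on each allele (the VCF anchor)
    so that the subsequent prefix strip removes the anchor and preserves the
    leftmost breakpoint; the result is minimal (first and last characters
    differ, or one allele is empty).
    """
    if ref == alt:
        raise ValueError("not a variant")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # a trailing-anchored record (REF=AG ALT=G) still carries a shared last
    # base at this point; strip it fully (cannot empty both since ref != alt)
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return ref, alt, pos


def trim_variant(v: GenomicVariant) -> GenomicVariant:
    ref, alt, pos = trim(v.ref, v.alt, v.pos)
    if not ref:
        pos -= 1  # insertion: pos = base after which insertion occurs
    return replace(v, pos=pos, ref=ref, alt=alt)


@dataclass(frozen=True)
class VcfLine:
    """One data line of a VCF: raw text, parsed allele variants, parse status."""

    raw: str
    number: int
    variants: tuple[GenomicVariant, ...]
    status: str = "ok"  # ok | malformed | ref_mismatch


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_vcf_line(raw: str, number: int = 0, reference=None) -> VcfLine:
    """Parse one VCF data line into split, trimmed variants.

    Multi-allelic records are split into one variant per ALT allele. When a
    ``reference`` is supplied, REF is verified against it; mismatching or
    malformed lines yield no variants and a non-``ok`` status (the caller
    decides whether to skip or echo them).
    """
    raw = raw.rstrip("\n")
    fields = raw.split("\t")
    if len(fields) < 8:
        log.warning("line %d: malformed VCF line (%d fields), skipped", number, len(fields))
        return VcfLine(raw=raw, number=number, variants=(), status="malformed")
    chrom, pos_s, _id, ref, alt_field, qual, filt = fields[:7]
    try:
        pos = int(pos_s)
    except ValueError:
        log.warning("line %d: non-numeric POS %r, skipped", number, pos_s)
        return VcfLine(raw=raw, number=number, variants=(), status="malformed")
    ref = ref.upper()
    if not ref or any(c not in "ACGTN" for c in ref):
        log.warning("line %d: invalid REF %r, skipped", number, ref)
        return VcfLine(raw=raw, number=number, variants=(), status="malformed")
    if reference is not None:
        try:
            actual = reference.fetch(chrom, pos, pos + len(ref) - 1)
        except (KeyError, ValueError):
            actual = None
        if actual != ref:
            log.warning(
                "line %d: REF %r does not match reference at %s:%d, skipped",
                number, ref, chrom, pos,
            )
            return VcfLine(raw=raw, number=number, variants=(), status="ref_mismatch")
    variants = []
    for alt in alt_field.split(","):
        alt = alt.upper()
        if not alt or alt == "." or any(c not in "ACGTN" for c in alt) or alt == ref:
            if alt not in (".",):
                log.warning("line %d: unsupported ALT %r, skipped", number, alt)
            continue
        v = GenomicVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, filter=filt)
        variants.append(trim_variant(v).with_echo(pos, ref, alt))
    return VcfLine(raw=raw, number=number, variants=tuple(variants))


def iter_vcf_lines(path: str | os.PathLike, reference=None) -> Iterator[VcfLine]:
    """Yield parsed data lines of a VCF file (header lines are skipped)."""
    with _open_text(path) as fh:
        for number, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parsed = parse_vcf_line(line, number, reference)
            if parsed.status == "ok":
                yield parsed


def read_vcf(path: str | os.PathLike, reference=None) -> Iterator[GenomicVariant]:
    """Stream trimmed :class:`GenomicVariant` records from a VCF file."""
    for line in iter_vcf_lines(path, reference):
        yield from line.variants
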