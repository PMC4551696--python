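"""Transcript models and genomic <-> coding-coordinate mapping.

A :class:`Transcript` is the coordinate frame for all c./p. annotation.
Positions inside the spliced transcript are expressed as
:class:`CodingPosition` values: a 1-based CDS coordinate (c.N), a 5' UTR
distance (c.-N), a 3' UTR distance (c.*N), or an intronic position anchored
to the nearest exonic base with a signed offset (c.N+k / c.N-k), all in
transcript orientation.

All public coordinates are 1-based and inclusive; any half-open arithmetic
is private to the interval index.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class IntergenicError(ValueError):
    """Raised when a genomic position falls outside the transcript span."""


@dataclass(frozen=True)
class CodingPosition:
    """A position in coding-transcript coordinates.

    ``kind`` is one of ``cds``/``utr5``/``utr3``/``intron``. For exonic
    positions ``offset`` is 0 and ``base`` is the CDS coordinate (c.N), the
    distance before the CDS start (c.-N) or the distance past the stop codon
    (c.*N). For intronic positions ``offset`` is +k for k bases 3' of an
    exon end and -k for k bases 5' of an exon start (transcript
    orientation), ``base`` is the coordinate of the anchoring exonic base
    and ``anchor`` records whether that anchor is cds/utr5/utr3.
    """

    kind: str
    base: int
    offset: int = 0
    anchor: str = "cds"

    def __post_init__(self):
        if self.kind not in ("cds", "utr5", "utr3", "intron"):
            raise ValueError(f"bad kind {self.kind!r}")
        if (self.kind == "intron") != (self.offset != 0):
            raise ValueError("kind=intron iff offset != 0")

    @property
    def anchor_kind(self) -> str:
        return self.anchor if self.kind == "intron" else self.kind

    def format(self) -> str:
        """Render without the leading ``c.`` (e.g. ``1040``, ``-12``, ``*8``, ``484+5``)."""
        kind = self.anchor_kind
        if kind == "cds":
            s = str(self.base)
        elif kind == "utr5":
            s = f"-{self.base}"
        else:
            s = f"*{self.base}"
        if self.offset > 0:
            s += f"+{self.offset}"
        elif self.offset < 0:
            s += str(self.offset)
        return s


@dataclass
class Transcript:
    """One coding transcript: exon/CDS structure, strand and identifiers.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position. ``coding_start``/``coding_end`` are the genomic positions of
    the first coding base (the A of ATG, c.1) and the last coding base (the
    final base of the stop codon) *in transcript orientation*; on
    reverse-strand transcripts ``coding_start`` is therefore the genomically
    larger of the two. Exon numbering for reporting follows transcription
    order: exon 1 is the most 5' exon of the transcript.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    coding_start: int
    coding_end: int
    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
        if any(s > e for s, e in exons):
            raise ValueError(f"{self.transcript_id}: bad exon interval")
        self.exons = exons
        # cumulative spliced length preceding each transcript-order exon
        self._cum = []
        total = 0
        for s, e in self.exons_tx:
            self._cum.append(total)
            total += e - s + 1
        for gpos, name in ((self.coding_start, "coding_start"), (self.coding_end, "coding_end")):
            if self.transcript_index(gpos) is None:
                raise ValueError(f"{self.transcript_id}: {name} not exonic")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3")

    # -- basic geometry ----------------------------------------------------

    @property
    def exons_tx(self) -> list[tuple[int, int]]:
        """Exons in transcription order (genomic intervals)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def genomic_span(self) -> int:
        s, e = self.span
        return e - s + 1

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def cds_start_t(self) -> int:
        return self.transcript_index(self.coding_start)

    @property
    def cds_end_t(self) -> int:
        return self.transcript_index(self.coding_end)

    @property
    def cds_length(self) -> int:
        return self.cds_end_t - self.cds_start_t + 1

    # -- spliced-coordinate helpers ---------------------------------------

    def transcript_index(self, gpos: int) -> int | None:
        """1-based position in the spliced transcript, or None if intronic/outside."""
        for i, (s, e) in enumerate(self.exons_tx):
            if s <= gpos <= e:
                if self.strand == "+":
                    return self._cum[i] + (gpos - s + 1)
                return self._cum[i] + (e - gpos + 1)
        return None

    def genomic_of_transcript_index(self, t: int) -> int:
        if not 1 <= t <= self.transcript_length:
            raise ValueError(f"transcript index {t} out of range")
        for i, (s, e) in enumerate(self.exons_tx):
            length = e - s + 1
            if t <= self._cum[i] + length:
                k = t - self._cum[i]  # 1-based within exon, transcript order
                return s + k - 1 if self.strand == "+" else e - k + 1
        raise AssertionError("unreachable")

    def exon_number_of_t(self, t: int) -> int:
        """Transcription-order exon number containing spliced position ``t``."""
        for i, (s, e) in enumerate(self.exons_tx):
            if t <= self._cum[i] + (e - s + 1):
                return i + 1
        raise ValueError(f"transcript index {t} out of range")

    def _coding_of_t(self, t: int) -> tuple[str, int]:
        cs, ce = self.cds_start_t, self.cds_end_t
        if t < cs:
            return "utr5", cs - t
        if t > ce:
            return "utr3", t - ce
        return "cds", t - cs + 1

    def _t_of_coding(self, kind: str, base: int) -> int:
        cs, ce = self.cds_start_t, self.cds_end_t
        if kind == "cds":
            t = cs + base - 1
        elif kind == "utr5":
            t = cs - base
        elif kind == "utr3":
            t = ce + base
        else:
            raise ValueError(f"bad coding kind {kind!r}")
        if not 1 <= t <= self.transcript_length:
            raise ValueError(f"coding position {kind}/{base} outside transcript")
        return t

    # -- the genomic <-> coding mapping ------------------------------------

    def genomic_to_coding(self, gpos: int) -> CodingPosition:
        s, e = self.span
        if not s <= gpos <= e:
            raise IntergenicError(
                f"{self.chrom}:{gpos} is intergenic for transcript {self.transcript_id}"
            )
        t = self.transcript_index(gpos)
        if t is not None:
            kind, base = self._coding_of_t(t)
            return CodingPosition(kind=kind, base=base, offset=0, anchor=kind)
        # intronic: find the flanking transcript-order exons
        exons = self.exons_tx
        for i in range(len(exons) - 1):
            if self.strand == "+":
                prev_edge, next_edge = exons[i][1], exons[i + 1][0]
                inside = prev_edge < gpos < next_edge
                d_up, d_down = gpos - prev_edge, next_edge - gpos
            else:
                prev_edge, next_edge = exons[i][0], exons[i + 1][1]
                inside = next_edge < gpos < prev_edge
                d_up, d_down = prev_edge - gpos, gpos - next_edge
            if inside:
                if d_up <= d_down:
                    anchor_t, offset = self._cum[i + 1], d_up  # last base of exon i+1 (1-based i)
                else:
                    anchor_t, offset = self._cum[i + 1] + 1, -d_down
                kind, base = self._coding_of_t(anchor_t)
                return CodingPosition(kind="intron", base=base, offset=offset, anchor=kind)
        raise AssertionError("unreachable")

    def coding_to_genomic(self, cpos: CodingPosition) -> int:
        t = self._t_of_coding(cpos.anchor_kind, cpos.base)
        g = self.genomic_of_transcript_index(t)
        if cpos.offset:
            g = g + cpos.offset if self.strand == "+" else g - cpos.offset
            if self.transcript_index(g) is not None or not (self.span[0] <= g <= self.span[1]):
                raise ValueError(f"offset {cpos.offset} leaves the intron")
        return g


# module-level operation aliases matching the library surface


def genomic_to_coding(tx: Transcript, gpos: int) -> CodingPosition:
    return tx.genomic_to_coding(gpos)


def coding_to_genomic(tx: Transcript, cpos: CodingPosition) -> int:
    return tx.coding_to_genomic(cpos)


def coding_sequence(tx: Transcript, reference) -> str:
    """Concatenated CDS (ATG..stop), reverse-complemented for '-' strand."""
    lo, hi = sorted((tx.coding_start, tx.coding_end))
    parts = []
    for s, e in tx.exons:
        a, b = max(s, lo), min(e, hi)
        if a <= b:
            parts.append(reference.fetch(tx.chrom, a, b))
    seq = "".join(parts)
    return seq if tx.strand == "+" else revcomp(seq)


def _norm_contig(name: str) -> str:
    return name[3:] if name.startswith("chr") else name


class TranscriptDatabase:
    """Transcript set with a per-contig interval index over genomic spans."""

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts: dict[str, Transcript] = {}
        self._trees: dict[str, IntervalTree] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {tx.transcript_id}")
            self.transcripts[tx.transcript_id] = tx
            tree = self._trees.setdefault(_norm_contig(tx.chrom), IntervalTree())
            s, e = tx.span
            tree.addi(s, e + 1, tx.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tx_id: str) -> Transcript:
        return self.transcripts[tx_id]

    def query(self, chrom: str, start: int, end: int, flank: int = 0) -> list[Transcript]:
        """Transcripts whose (flank-padded) genomic span intersects 1-based ``start..end``."""
        tree = self._trees.get(_norm_contig(chrom))
        if tree is None:
            return []
        hits = tree.overlap(start - flank, end + flank + 1)
        ids = sorted(iv.data for iv in hits)
        return [self.transcripts[i] for i in ids]


def find_overlapping_transcripts(db: TranscriptDatabase, chrom: str, start: int, end: int) -> list[Transcript]:
    return db.query(chrom, start, end)


# -- loading ---------------------------------------------------------------

NATIVE_HEADER = "#transcript_id\tgene\tchrom\tstrand\texon_starts\texon_ends\tcoding_start\tcoding_end"


def _load_native_tsv(path: str) -> list[Transcript]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, gene, chrom, strand, starts, ends, cs, ce = line.split("\t")
            exons = list(zip((int(x) for x in starts.split(",")), (int(x) for x in ends.split(","))))
            try:
                out.append(
                    Transcript(
                        transcript_id=tid,
                        gene_symbol=gene,
                        chrom=chrom,
                        strand=strand,
                        exons=exons,
                        coding_start=int(cs),
                        coding_end=int(ce),
                    )
                )
            except ValueError as exc:
                log.warning("skipping transcript %s: %s", tid, exc)
    return out


def write_native(db: TranscriptDatabase, path: str | os.PathLike) -> None:
    """Write the database in the native tab-separated transcript format.

    One line per transcript: id, gene, chrom, strand, comma-separated exon
    starts, comma-separated exon ends, coding_start, coding_end (the latter
    two in transcript orientation, stop codon included).
    """
    with open(path, "w") as fh:
        fh.write(NATIVE_HEADER + "\n")
        for tid in sorted(db.transcripts):
            tx = db.transcripts[tid]
            fh.write(
                "\t".join(
                    [
                        tx.transcript_id,
                        tx.gene_symbol,
                        tx.chrom,
                        tx.strand,
                        ",".join(str(s) for s, _ in tx.exons),
                        ",".join(str(e) for _, e in tx.exons),
                        str(tx.coding_start),
                        str(tx.coding_end),
                    ]
                )
                + "\n"
            )


def _looks_like_gtf(path: str) -> bool:
    if path.endswith((".gtf", ".gff", ".gff3")):
        return True
    if path.endswith((".tsv", ".txt")):
        return False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return len(line.split("\t")) == 9
    return False


def _load_gtf(path: str) -> list[Transcript]:
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        rec = per_tx.setdefault(
            tid, {"exons": [], "cds": [], "chrom": feat.seqid, "strand": feat.strand, "gene": None}
        )
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [None])[0]
        if gene:
            rec["gene"] = rec["gene"] or gene
        if feat.featuretype == "exon":
            rec["exons"].append((feat.start, feat.end))
        else:  # CDS or stop_codon both count toward the coding extent
            rec["cds"].append((feat.start, feat.end))

    out = []
    for tid, rec in per_tx.items():
        if not rec["exons"] or not rec["cds"]:
            log.warning("skipping transcript %s: missing exon or CDS features", tid)
            continue
        lo = min(s for s, _ in rec["cds"])
        hi = max(e for _, e in rec["cds"])
        cs, ce = (lo, hi) if rec["strand"] == "+" else (hi, lo)
        try:
            out.append(
                Transcript(
                    transcript_id=tid,
                    gene_symbol=rec["gene"] or tid,
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=sorted(rec["exons"]),
                    coding_start=cs,
                    coding_end=ce,
                )
            )
        except ValueError as exc:
            log.warning("skipping transcript %s: %s", tid, exc)
    return out


def load_transcripts(path: str | os.PathLike, reference=None) -> TranscriptDatabase:
    """Load a transcript set from GTF/GFF (exon + CDS features) or native TSV.

    Transcripts failing validation (e.g. CDS length not divisible by 3) are
    skipped with a logged warning; an input yielding no valid transcript is
    fatal. ``reference`` is accepted for interface symmetry and future
    sequence-level checks; coordinate validation does not need it.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    txs = _load_gtf(path) if _looks_like_gtf(path) else _load_native_tsv(path)
    if not txs:
        raise ValueError(f"no valid transcript in {path}")
    return TranscriptDatabase(txs)
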