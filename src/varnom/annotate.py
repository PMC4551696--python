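"""Per-variant annotation across overlapping transcripts, filters, SNP ids,
and annotated VCF / TSV output.

Each input VCF line is processed independently of every other line, so the
pipeline can be parallelized by line with an order-preserving merge; output
is byte-identical regardless of worker count.
"""

from __future__ import annotations

import logging
import os
import sys
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

from varnom.classify import classify, impact, so_term
from varnom.csn import variant_effect
from varnom.normalize import normalize_for_transcript, shift
from varnom.reference import ReferenceGenome, load_reference
from varnom.transcripts import Transcript, TranscriptDatabase, coding_sequence, load_transcripts
from varnom.variants import GenomicVariant, parse_vcf_line, trim

log = logging.getLogger(__name__)

TSV_COLUMNS = [
    "Chr", "Pos", "Ref", "Alt", "Qual", "Filter", "Type", "ENST", "Gene", "TRINFO",
    "Loc", "CSN", "Class", "SO", "Impact", "Alt ann", "Alt class", "Alt SO",
]

INFO_KEY = "VANN"
INFO_HEADER = (
    f'##INFO=<ID={INFO_KEY},Number=.,Type=String,Description="Transcript annotation. '
    'Format: ALT:TYPE:ENST:GENE:TRINFO:LOC:CSN:CLASS:SO:IMPACT:ALTANN:ALTCLASS:ALTSO:SNPID; '
    'one comma-separated block per (allele, transcript); reserved characters %-escaped">'
)


@dataclass(frozen=True)
class AnnotationRecord:
    """One variant x one transcript output row (Table-style columns)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: str
    filter: str
    vtype: str
    transcript_id: str
    gene_symbol: str
    trinfo: str
    loc: str
    csn: str
    class_code: str
    so: str
    impact: int
    alt_ann: str = ""
    alt_class: str = ""
    alt_so: str = ""
    snp_id: str = ""

    def tsv_row(self) -> list[str]:
        cells = [
            self.chrom, str(self.pos), self.ref, self.alt, self.qual, self.filter,
            self.vtype, self.transcript_id, self.gene_symbol, self.trinfo, self.loc,
            self.csn, self.class_code, self.so, str(self.impact),
            self.alt_ann, self.alt_class, self.alt_so,
        ]
        return [c if c else "." for c in cells]


@dataclass
class AnnotationConfig:
    """Pipeline configuration (paths validated at startup)."""

    reference_path: str
    transcript_db_path: str
    snp_db_path: str | None = None
    output_format: str = "tsv"  # tsv | vcf
    drop_intergenic: bool = False
    gene_allowlist: set[str] | None = None
    region_filter: list[tuple[str, int, int]] | None = None  # 1-based inclusive
    workers: int = 1

    def __post_init__(self):
        if self.output_format not in ("tsv", "vcf"):
            raise ValueError(f"bad output format {self.output_format!r}")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        for p in (self.reference_path, self.transcript_db_path, self.snp_db_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)


def format_trinfo(tx: Transcript) -> str:
    """Transcript summary: strand / genomic span kb / exon count / length kb."""
    return (
        f"{tx.strand}/{tx.genomic_span / 1000:.1f}kb/{tx.exon_count}/"
        f"{tx.transcript_length / 1000:.1f}kb"
    )


def format_loc(tx: Transcript, eff) -> str:
    """Within-transcript location of the canonical placement.

    Exonic (any CDS-touching or mixed) -> ``Ex<k>`` in transcription-order
    numbering; fully intronic -> ``In<k>/<k+1>``; exonic UTR-only ->
    ``5UTR``/``3UTR``. A boundary-spanning variant takes the exon-containing
    designation of its first affected exonic base.
    """
    if eff.kind == "Insertion":
        ts = [t for t in eff.flank_t if t is not None]
        kinds = {cp.kind for cp in eff.flank_cpos}
    else:
        ts = eff.affected_t
        kinds = {cp.kind for cp in eff.cpos_list}
    if ts:
        exonic_kinds = kinds - {"intron"}
        if exonic_kinds == {"utr5"}:
            return "5UTR"
        if exonic_kinds == {"utr3"}:
            return "3UTR"
        return f"Ex{eff.tx.exon_number_of_t(ts[0])}"
    # fully intronic: locate the intron from the first affected genomic base
    g = eff.variant.pos if eff.kind != "Insertion" else eff.variant.pos
    exons = tx.exons_tx
    for i in range(len(exons) - 1):
        if tx.strand == "+":
            lo, hi = exons[i][1], exons[i + 1][0]
        else:
            lo, hi = exons[i + 1][1], exons[i][0]
        if lo < g < hi:
            return f"In{i + 1}/{i + 2}"
    return "In?/?"


def load_snp_db(path: str, reference: ReferenceGenome) -> dict:
    """Load a SNP catalogue TSV (chrom, pos, ref, alt, rsID) keyed on the
    trimmed, left-aligned representation."""
    db: dict[tuple[str, int, str, str], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt, rsid = line.split("\t")[:5]
            try:
                key = _snp_key(chrom, int(pos), ref.upper(), alt.upper(), reference)
            except (KeyError, ValueError):
                continue
            db[key] = rsid
    return db


def _snp_key(chrom: str, pos: int, ref: str, alt: str, reference: ReferenceGenome):
    ref_t, alt_t, pos_t = trim(ref, alt, pos) if ref != alt else (ref, alt, pos)
    if not ref_t:
        pos_t -= 1
    v = GenomicVariant(chrom=chrom, pos=pos_t, ref=ref_t, alt=alt_t)
    if v.vtype in ("Insertion", "Deletion"):
        v = shift(v, reference, "left")
    return (reference.resolve(chrom), v.pos, v.ref, v.alt)


def assign_snp_id(v: GenomicVariant, snp_db: dict, reference: ReferenceGenome) -> str:
    """rsID for a variant, matching equivalent indel representations.

    Both sides are normalized to the same trimmed, left-shifted frame before
    comparison, so an identifier stored left-aligned matches a query
    supplied right-aligned.
    """
    if not snp_db:
        return ""
    q = shift(v, reference, "left") if v.vtype in ("Insertion", "Deletion") else v
    try:
        key = (reference.resolve(v.chrom), q.pos, q.ref, q.alt)
    except KeyError:
        return ""
    return snp_db.get(key, "")


class Annotator:
    """Annotation engine: reference + transcript set (+ optional SNP catalogue)."""

    def __init__(
        self,
        reference: ReferenceGenome,
        db: TranscriptDatabase,
        snp_db: dict | None = None,
        config: AnnotationConfig | None = None,
    ):
        self.reference = reference
        self.db = db
        self.snp_db = snp_db or {}
        self.config = config
        self._cds_cache: dict[str, str] = {}

    def cds_seq(self, tx: Transcript) -> str:
        seq = self._cds_cache.get(tx.transcript_id)
        if seq is None:
            seq = coding_sequence(tx, self.reference)
            self._cds_cache[tx.transcript_id] = seq
        return seq

    def annotate_variant(self, v: GenomicVariant) -> list[AnnotationRecord]:
        """All per-transcript records for one trimmed variant.

        Intergenic variants yield an empty list. Per-transcript failures are
        logged and do not prevent annotation against other transcripts.
        """
        start, end = v.affected_span
        transcripts = self.db.query(v.chrom, start, end)
        if self.config and self.config.gene_allowlist is not None:
            transcripts = [t for t in transcripts if t.gene_symbol in self.config.gene_allowlist]
        records = []
        snp_id = assign_snp_id(v, self.snp_db, self.reference) if self.snp_db else ""
        for tx in transcripts:
            try:
                records.append(self._annotate_one(v, tx, snp_id))
            except Exception as exc:  # keep going: other transcripts may still work
                log.warning(
                    "failed to annotate %s:%d %s>%s on %s: %s",
                    v.chrom, v.pos, v.ref or "-", v.alt or "-", tx.transcript_id, exc,
                )
        return records

    def _annotate_one(self, v: GenomicVariant, tx: Transcript, snp_id: str) -> AnnotationRecord:
        canonical, alt5 = normalize_for_transcript(v, tx, self.reference)
        eff = variant_effect(tx, canonical, self.reference, cds_seq=self.cds_seq(tx))
        vclass = classify(eff)
        so = so_term(vclass, eff)
        alt_ann = alt_class = alt_so = ""
        if alt5 is not None:
            try:
                eff_alt = variant_effect(tx, alt5, self.reference, cds_seq=self.cds_seq(tx))
                if eff_alt.csn.full != eff.csn.full:
                    alt_ann = eff_alt.csn.full
                    vclass_alt = classify(eff_alt)
                    if vclass_alt.code != vclass.code:
                        alt_class = vclass_alt.code
                    so_alt = so_term(vclass_alt, eff_alt)
                    if so_alt != so:
                        alt_so = so_alt
            except Exception as exc:
                log.warning("alternative representation of %s:%d failed: %s", v.chrom, v.pos, exc)
        return AnnotationRecord(
            chrom=v.chrom,
            pos=v.vcf_pos if v.vcf_pos is not None else v.pos,
            ref=v.vcf_ref if v.vcf_ref is not None else v.ref,
            alt=v.vcf_alt if v.vcf_alt is not None else v.alt,
            qual=v.qual,
            filter=v.filter,
            vtype=v.vtype,
            transcript_id=tx.transcript_id,
            gene_symbol=tx.gene_symbol,
            trinfo=format_trinfo(tx),
            loc=format_loc(tx, eff),
            csn=eff.csn.full,
            class_code=vclass.code,
            so=so,
            impact=impact(vclass),
            alt_ann=alt_ann,
            alt_class=alt_class,
            alt_so=alt_so,
            snp_id=snp_id,
        )


# -- output -----------------------------------------------------------------

_ESCAPES = {"%": "%25", ":": "%3A", ";": "%3B", ",": "%2C", "=": "%3D", "|": "%7C", " ": "%20"}


def _escape_info(value: str) -> str:
    out = value.replace("%", "%25")
    for ch, rep in _ESCAPES.items():
        if ch != "%":
            out = out.replace(ch, rep)
    return out


def encode_info(records: list[AnnotationRecord]) -> str:
    """Encode per-transcript annotations as the VANN INFO value."""
    if not records:
        return "."
    blocks = []
    for r in records:
        fields = [
            r.alt, r.vtype, r.transcript_id, r.gene_symbol, r.trinfo, r.loc, r.csn,
            r.class_code, r.so, str(r.impact), r.alt_ann, r.alt_class, r.alt_so, r.snp_id,
        ]
        blocks.append(":".join(_escape_info(f) if f else "." for f in fields))
    return ",".join(blocks)


def append_info_to_line(raw: str, info_value: str) -> str:
    fields = raw.split("\t")
    if fields[7] == "." or not fields[7]:
        fields[7] = f"{INFO_KEY}={info_value}"
    else:
        fields[7] = f"{fields[7]};{INFO_KEY}={info_value}"
    return "\t".join(fields)


def strip_info_from_line(raw: str) -> str:
    """Inverse of :func:`append_info_to_line` (used by round-trip checks)."""
    fields = raw.split("\t")
    parts = [p for p in fields[7].split(";") if not p.startswith(f"{INFO_KEY}=")]
    fields[7] = ";".join(parts) if parts else "."
    return "\t".join(fields)


def write_output(line_results, out, fmt: str = "tsv", header_lines: list[str] | None = None):
    """Write annotated output.

    ``line_results`` is an iterable of ``(raw_line, [AnnotationRecord])``
    pairs (raw_line is None for library-level record lists in tsv mode).
    VCF mode preserves each original line byte-for-byte apart from the
    single added INFO key; TSV mode writes the 18 standard columns with
    ``.`` for empty cells. ``out`` is a path or a writable file object;
    both modes stream to standard output when ``out`` is None.
    """
    close = False
    if out is None:
        fh = sys.stdout
    elif hasattr(out, "write"):
        fh = out
    else:
        fh = open(out, "w")
        close = True
    try:
        if fmt == "tsv":
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for _raw, records in line_results:
                for r in records:
                    fh.write("\t".join(r.tsv_row()) + "\n")
        else:
            wrote_info_header = False
            for line in header_lines or []:
                if line.startswith("#CHROM") and not wrote_info_header:
                    fh.write(INFO_HEADER + "\n")
                    wrote_info_header = True
                fh.write(line + "\n")
            for raw, records in line_results:
                fh.write(append_info_to_line(raw, encode_info(records)) + "\n")
    finally:
        if close:
            fh.close()


# -- pipeline ---------------------------------------------------------------

_WORKER_STATE: dict = {}


def _worker_init(cfg: AnnotationConfig):
    _WORKER_STATE["annotator"] = build_annotator(cfg)
    _WORKER_STATE["config"] = cfg


def _worker_lines(chunk: list[tuple[int, str]]):
    ann = _WORKER_STATE["annotator"]
    cfg = _WORKER_STATE["config"]
    return [_process_line(ann, cfg, number, raw) for number, raw in chunk]


def build_annotator(cfg: AnnotationConfig) -> Annotator:
    reference = load_reference(cfg.reference_path)
    db = load_transcripts(cfg.transcript_db_path, reference)
    snp_db = load_snp_db(cfg.snp_db_path, reference) if cfg.snp_db_path else {}
    return Annotator(reference, db, snp_db, cfg)


def _region_hit(cfg: AnnotationConfig, v: GenomicVariant) -> bool:
    if not cfg.region_filter:
        return True
    s, e = v.affected_span
    for chrom, rs, re_ in cfg.region_filter:
        if chrom.lstrip("chr") == v.chrom.lstrip("chr") or chrom == v.chrom:
            if rs <= e and s <= re_:
                return True
    return False


def _process_line(ann: Annotator, cfg: AnnotationConfig, number: int, raw: str):
    parsed = parse_vcf_line(raw, number, ann.reference)
    records: list[AnnotationRecord] = []
    n_intergenic = 0
    for v in parsed.variants:
        if not _region_hit(cfg, v):
            continue
        recs = ann.annotate_variant(v)
        if not recs:
            n_intergenic += 1
        records.extend(recs)
    return {
        "raw": raw,
        "status": parsed.status,
        "n_variants": len(parsed.variants),
        "n_intergenic": n_intergenic,
        "records": records,
    }


def run_pipeline(cfg: AnnotationConfig, vcf_path: str, out=None) -> dict:
    """Annotate a VCF end-to-end; returns a summary-statistics dict.

    With ``workers > 1`` lines are distributed over processes and merged in
    input order, so output is identical to a single-worker run.
    """
    header_lines: list[str] = []
    data: list[tuple[int, str]] = []
    with open(vcf_path) as fh:
        for number, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                header_lines.append(line)
            elif line.strip():
                data.append((number, line))

    if cfg.workers > 1 and len(data) > 1:
        chunk_size = max(1, len(data) // (cfg.workers * 4))
        chunks = [data[i : i + chunk_size] for i in range(0, len(data), chunk_size)]
        with ProcessPoolExecutor(max_workers=cfg.workers, initializer=_worker_init, initargs=(cfg,)) as ex:
            results = [item for chunk_result in ex.map(_worker_lines, chunks) for item in chunk_result]
    else:
        ann = build_annotator(cfg)
        results = [_process_line(ann, cfg, number, raw) for number, raw in data]

    stats = {
        "input_lines": len(data),
        "variants": sum(r["n_variants"] for r in results),
        "annotated_records": sum(len(r["records"]) for r in results),
        "intergenic": sum(r["n_intergenic"] for r in results),
        "ref_mismatch": sum(1 for r in results if r["status"] == "ref_mismatch"),
        "malformed": sum(1 for r in results if r["status"] == "malformed"),
    }

    filtered = bool(cfg.gene_allowlist is not None or cfg.region_filter)
    line_results = []
    for r in results:
        if r["status"] != "ok":
            continue  # skipped records are logged, not echoed
        if not r["records"]:
            if cfg.drop_intergenic or (filtered and cfg.output_format == "vcf"):
                continue
            if cfg.output_format == "tsv":
                continue  # TSV rows are per (variant, transcript)
        line_results.append((r["raw"], r["records"]))
    write_output(line_results, out, fmt=cfg.output_format, header_lines=header_lines)
    log.info(
        "annotated %d lines: %d variants, %d records, %d intergenic, %d REF mismatches, %d malformed",
        stats["input_lines"], stats["variants"], stats["annotated_records"],
        stats["intergenic"], stats["ref_mismatch"], stats["malformed"],
    )
    return stats
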