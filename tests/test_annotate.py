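import subprocess
import sys

import pytest

from conftest import annotate_text, annotate_to_rows
from varnom.annotate import (
    TSV_COLUMNS,
    Annotator,
    append_info_to_line,
    assign_snp_id,
    encode_info,
    format_trinfo,
    load_snp_db,
    strip_info_from_line,
)
from varnom.variants import GenomicVariant


class _TxStub:
    def __init__(self, strand, span, exons, length):
        self.strand = strand
        self.genomic_span = span
        self.exon_count = exons
        self.transcript_length = length


@pytest.mark.parametrize(
    "strand,span,exons,length,want",
    [
        ("+", 40_800, 19, 2_900, "+/40.8kb/19/2.9kb"),
        ("-", 1_000, 2, 400, "-/1.0kb/2/0.4kb"),
        ("+", 949, 1, 949, "+/0.9kb/1/0.9kb"),
        ("+", 950, 1, 950, "+/0.9kb/1/0.9kb"),  # 0.95 rounds half-even in IEEE
        ("+", 951, 1, 951, "+/1.0kb/1/1.0kb"),
    ],
)
def test_trinfo_format(strand, span, exons, length, want):
    assert format_trinfo(_TxStub(strand, span, exons, length)) == want


def test_tsv_has_exact_column_set(annotated_rows):
    assert list(annotated_rows[0].keys()) == TSV_COLUMNS
    assert TSV_COLUMNS == [
        "Chr", "Pos", "Ref", "Alt", "Qual", "Filter", "Type", "ENST", "Gene", "TRINFO",
        "Loc", "CSN", "Class", "SO", "Impact", "Alt ann", "Alt class", "Alt SO",
    ]


def test_echo_fidelity(fixture_dir, annotated_rows):
    """Chr/Pos/Ref/Alt/Qual/Filter columns echo the input record values."""
    inputs = set()
    with open(fixture_dir["vcf"]) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.split("\t")
            inputs.add((f[0], f[1], f[3], f[4], f[5], f[6]))
    for row in annotated_rows:
        assert (row["Chr"], row["Pos"], row["Ref"], row["Alt"], row["Qual"], row["Filter"]) in inputs


def test_every_fixture_row_matches_truth(fixture_dir, annotated_rows):
    """Top-level integration check: annotating the generated VCF reproduces
    the generator's truth table exactly."""
    truth = {
        (str(t["pos"]), t["ref"], t["alt"], t["enst"]): t for t in fixture_dir["truth"]
    }
    assert len(annotated_rows) == len(truth)
    for row in annotated_rows:
        t = truth[(row["Pos"], row["Ref"], row["Alt"], row["ENST"])]
        for col, key in [
            ("Type", "type"), ("Gene", "gene"), ("TRINFO", "trinfo"), ("Loc", "loc"),
            ("CSN", "csn"), ("Class", "class"), ("SO", "so"), ("Impact", "impact"),
            ("Alt ann", "alt_ann"), ("Alt class", "alt_class"), ("Alt SO", "alt_so"),
        ]:
            assert row[col] == str(t[key]), (t["case"], col)


def test_overlap_variant_gets_two_records_opposite_placements(annotated_rows):
    rows = [r for r in annotated_rows if r["CSN"] in ("c.*65delA", "c.*91delT")]
    assert {(r["ENST"], r["CSN"]) for r in rows} == {
        ("TX0003", "c.*65delA"), ("TX0004", "c.*91delT"),
    }
    assert all(r["Class"] == "3PU" for r in rows)


def test_alt_columns_empty_unless_different(annotated_rows):
    for row in annotated_rows:
        if row["Alt ann"] == ".":
            assert row["Alt class"] == "." and row["Alt SO"] == "."
        if row["Alt class"] != ".":
            assert row["Alt class"] != row["Class"]


def test_snp_id_matching_across_representations(tmp_path, reference, genome):
    """An indel stored left-aligned matches a right-aligned query; same
    position with a different allele does not match."""
    g2 = genome.genes["MULTI2"]
    tract_left = g2.g_of_q(g2.q_of_cds(1000))  # 6-A homopolymer
    snp_tsv = tmp_path / "snp.tsv"
    base = genome.base(tract_left - 1)
    spos = g2.g_of_q(g2.q_of_cds(500))
    sref = genome.base(spos)
    salt, sother = [b for b in "ACGT" if b != sref][:2]
    with open(snp_tsv, "w") as fh:
        fh.write(f"1\t{tract_left - 1}\t{base}A\t{base}\trs111\n")  # left-aligned del A
        fh.write(f"1\t{spos}\t{sref}\t{salt}\trs222\n")
    db = load_snp_db(str(snp_tsv), reference)
    right = GenomicVariant("1", tract_left + 5, "A", "")  # right-aligned same deletion
    assert assign_snp_id(right, db, reference) == "rs111"
    assert assign_snp_id(GenomicVariant("1", spos, sref, salt), db, reference) == "rs222"
    assert assign_snp_id(GenomicVariant("1", spos, sref, sother), db, reference) == ""


def test_vcf_append_round_trip(fixture_dir):
    out = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"], output_format="vcf")
    original = open(fixture_dir["vcf"]).read().splitlines()
    restored = [
        strip_info_from_line(l) if not l.startswith("#") else l
        for l in out.splitlines()
        if not l.startswith("##INFO=<ID=VANN")
    ]
    assert restored == original


def test_info_encoding_escapes_reserved_characters():
    line = "1\t10\t.\tA\tG\t50\tPASS\tDP=3"
    appended = append_info_to_line(line, "x")
    assert appended.endswith("DP=3;VANN=x")
    assert strip_info_from_line(appended) == line
    # '|' and ':' inside SO compounds are escaped in encoded blocks
    from varnom.annotate import AnnotationRecord

    rec = AnnotationRecord(
        chrom="1", pos=1, ref="A", alt="G", qual="50", filter="PASS", vtype="Substitution",
        transcript_id="T", gene_symbol="G", trinfo="+/1.0kb/1/0.1kb", loc="Ex1",
        csn="c.1A>G", class_code="SS", so="intron_variant|splice_region_variant", impact=3,
    )
    encoded = encode_info([rec])
    assert "|" not in encoded and "%7C" in encoded


def test_empty_vcf_body_gives_headers_only(tmp_path, fixture_dir):
    vcf = tmp_path / "empty.vcf"
    vcf.write_text("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    out = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], str(vcf))
    assert out == "\t".join(TSV_COLUMNS) + "\n"
    vcf_out = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], str(vcf), output_format="vcf")
    assert "#CHROM" in vcf_out and "VANN" in vcf_out  # header incl. INFO meta line


def test_workers_byte_identical(fixture_dir):
    one = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"], workers=1)
    four = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"], workers=4)
    assert one == four
    v_one = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"],
                          workers=1, output_format="vcf")
    v_four = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"],
                           workers=4, output_format="vcf")
    assert v_one == v_four


def test_gene_filter_restricts_rows(fixture_dir):
    rows = annotate_to_rows(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"],
                            gene_allowlist={"MULTI2"})
    assert rows and all(r["Gene"] == "MULTI2" for r in rows)


def test_region_filter(fixture_dir, genome):
    g6 = genome.genes["UTR6"]
    rows = annotate_to_rows(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"],
                            region_filter=[("1", g6.gstart, g6.gend)])
    assert rows and all(r["Gene"] == "UTR6" for r in rows)


def test_intergenic_dropped_with_flag(tmp_path, fixture_dir, genome):
    vcf = tmp_path / "iv.vcf"
    base = genome.base(5)
    alt = "A" if base != "A" else "C"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        fh.write(f"1\t5\t.\t{base}\t{alt}\t50\tPASS\t.\n")  # in the leading gap
    out = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], str(vcf),
                        output_format="vcf", drop_intergenic=True)
    assert all(l.startswith("#") for l in out.splitlines())
    kept = annotate_text(fixture_dir["fasta"], fixture_dir["gtf"], str(vcf), output_format="vcf")
    assert any(l.endswith("VANN=.") for l in kept.splitlines())


def test_cli_end_to_end(tmp_path, fixture_dir):
    out = tmp_path / "out.tsv"
    proc = subprocess.run(
        [sys.executable, "-m", "varnom.cli", "annotate",
         "--in", fixture_dir["vcf"], "--ref", fixture_dir["fasta"], "--db", fixture_dir["gtf"],
         "--out", str(out), "--log", str(tmp_path / "log.txt")],
        capture_output=True, text=True,
    )
    assert proc.returncode == 0, proc.stderr
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == TSV_COLUMNS and len(lines) > 30


def test_cli_missing_input_exits_nonzero(tmp_path, fixture_dir):
    proc = subprocess.run(
        [sys.executable, "-m", "varnom.cli", "annotate",
         "--in", fixture_dir["vcf"], "--ref", str(tmp_path / "no.fa"), "--db", fixture_dir["gtf"]],
        capture_output=True, text=True,
    )
    assert proc.returncode == 1
    bad_flag = subprocess.run(
        [sys.executable, "-m", "varnom.cli", "annotate", "--nonsense"],
        capture_output=True, text=True,
    )
    assert bad_flag.returncode == 2
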