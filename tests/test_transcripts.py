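import logging

import pytest

from oracles import oracle_cds, walk_transcript
from varnom.reference import ReferenceGenome
from varnom.transcripts import (
    CodingPosition,
    IntergenicError,
    Transcript,
    coding_sequence,
    find_overlapping_transcripts,
    load_transcripts,
    write_native,
)


def test_database_loads_all_fixture_transcripts(db, genome):
    assert len(db) == len(genome.genes)
    for g in genome.genes.values():
        tx = db[g.tx]
        assert tx.gene_symbol == g.gene
        assert tx.strand == g.strand
        assert tx.exons == g.genomic_exons()
        assert tx.coding_start == g.coding_start_g
        assert tx.coding_end == g.coding_end_g


def test_cds_not_divisible_by_three_excluded(tmp_path, caplog):
    gtf = tmp_path / "bad.gtf"
    attrs_ok = 'gene_id "G1"; transcript_id "T1"; gene_name "G1";'
    attrs_bad = 'gene_id "G2"; transcript_id "T2"; gene_name "G2";'
    with open(gtf, "w") as fh:
        fh.write(f"1\tx\texon\t1\t30\t.\t+\t.\t{attrs_ok}\n")
        fh.write(f"1\tx\tCDS\t4\t15\t.\t+\t.\t{attrs_ok}\n")  # 12 bases: ok
        fh.write(f"1\tx\texon\t101\t130\t.\t+\t.\t{attrs_bad}\n")
        fh.write(f"1\tx\tCDS\t104\t116\t.\t+\t.\t{attrs_bad}\n")  # 13 bases: excluded
    with caplog.at_level(logging.WARNING, logger="varnom.transcripts"):
        db = load_transcripts(gtf)
    assert set(db.transcripts) == {"T1"}
    assert any("T2" in r.message for r in caplog.records)


def test_no_valid_transcript_fatal(tmp_path):
    gtf = tmp_path / "empty.gtf"
    gtf.write_text("# nothing\n")
    with pytest.raises(ValueError):
        load_transcripts(gtf)


def test_native_tsv_round_trip(db, tmp_path):
    tsv = tmp_path / "native.tsv"
    write_native(db, tsv)
    db2 = load_transcripts(tsv)
    assert set(db2.transcripts) == set(db.transcripts)
    for tid, tx in db.transcripts.items():
        tx2 = db2[tid]
        assert (tx2.exons, tx2.strand, tx2.coding_start, tx2.coding_end, tx2.gene_symbol) == (
            tx.exons, tx.strand, tx.coding_start, tx.coding_end, tx.gene_symbol,
        )


def test_overlap_queries_match_linear_scan(db, genome):
    """Interval-index results equal a naive all-transcripts scan."""
    probes = []
    for g in genome.genes.values():
        probes += [(g.gstart, g.gstart), (g.gend, g.gend), ((g.gstart + g.gend) // 2,) * 2]
    probes += [(1, 1), (len(genome.contig_seq), len(genome.contig_seq))]
    for start, end in probes:
        naive = sorted(
            tx.transcript_id
            for tx in db.transcripts.values()
            if tx.span[0] <= end and start <= tx.span[1]
        )
        got = [t.transcript_id for t in find_overlapping_transcripts(db, "1", start, end)]
        assert got == naive


def test_engineered_overlap_returns_both_strands(db, genome):
    g3, g4 = genome.genes["GLYR3F"], genome.genes["OVLP4R"]
    mid = (g4.gstart + g3.gend) // 2
    hits = find_overlapping_transcripts(db, "1", mid, mid)
    assert [t.transcript_id for t in hits] == [g3.tx, g4.tx]
    assert {t.strand for t in hits} == {"+", "-"}
    assert find_overlapping_transcripts(db, "1", 1, 1) == []
    assert find_overlapping_transcripts(db, "unknown_contig", 5, 5) == []


def test_coordinate_mapping_matches_walker_oracle(db, reference):
    """genomic_to_coding agrees with a brute-force base-by-base walker on
    every position of every transcript span, and round-trips exactly."""
    for tx in db.transcripts.values():
        _t, label = walk_transcript(tx)
        lo, hi = tx.span
        for g in range(lo, hi + 1):
            cp = tx.genomic_to_coding(g)
            assert (cp.kind, cp.base, cp.offset, cp.anchor_kind) == label[g], (tx.transcript_id, g)
            assert tx.coding_to_genomic(cp) == g
        with pytest.raises(IntergenicError):
            tx.genomic_to_coding(lo - 1)
        with pytest.raises(IntergenicError):
            tx.genomic_to_coding(hi + 1)


def test_c1_maps_to_coding_start_on_both_strands(db):
    for tx in db.transcripts.values():
        cp = tx.genomic_to_coding(tx.coding_start)
        assert (cp.kind, cp.base, cp.offset) == ("cds", 1, 0)
        assert tx.coding_to_genomic(CodingPosition(kind="cds", base=1)) == tx.coding_start
        if tx.strand == "-":
            assert tx.coding_start > tx.coding_end


def test_exon_numbering_reverses_between_strands(db):
    for tx in db.transcripts.values():
        first_exon_genomic = tx.exons_tx[0]
        if tx.strand == "+":
            assert first_exon_genomic == tx.exons[0]
        else:
            assert first_exon_genomic == tx.exons[-1]
        assert tx.exon_number_of_t(1) == 1
        assert tx.exon_number_of_t(tx.transcript_length) == tx.exon_count


def test_plus_one_intron_offset_definition(db, genome):
    """The first base genomically after a forward-strand exon end (inside CDS)
    maps to the last CDS base of that exon with offset +1."""
    g2 = genome.genes["MULTI2"]
    tx = db[g2.tx]
    exon2_end = tx.exons[1][1]
    cp = tx.genomic_to_coding(exon2_end + 1)
    assert (cp.kind, cp.base, cp.offset, cp.anchor_kind) == ("intron", 700, 1, "cds")


def test_coding_sequence_matches_generator_and_oracle(db, genome, reference):
    for g in genome.genes.values():
        tx = db[g.tx]
        seq = coding_sequence(tx, reference)
        assert seq == g.cds  # generator bookkeeping
        assert seq == oracle_cds(tx, reference)  # independent reverse-complement walk
        assert seq.startswith("ATG") and len(seq) % 3 == 0


def test_single_exon_cds_identity():
    ref = ReferenceGenome.from_dict({"c": "NN" + "ATGAAATAA" + "NN"})
    tx = Transcript(
        transcript_id="T", gene_symbol="G", chrom="c", strand="+",
        exons=[(3, 11)], coding_start=3, coding_end=11,
    )
    assert coding_sequence(tx, ref) == "ATGAAATAA"
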