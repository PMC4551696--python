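import io
import logging

import pytest

from varnom.annotate import AnnotationConfig, run_pipeline
from varnom.fixtures import FixtureSpec, generate_fixture_genome, generate_fixture_vcf
from varnom.reference import load_reference
from varnom.transcripts import load_transcripts

logging.getLogger("varnom").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Generated genome + transcript set + full case VCF on disk."""
    d = tmp_path_factory.mktemp("fixture")
    genome = generate_fixture_genome(FixtureSpec(seed=1), d)
    truth = generate_fixture_vcf(
        genome, None, vcf_path=d / "cases.vcf", truth_path=d / "truth.tsv"
    )
    return {
        "dir": d,
        "genome": genome,
        "fasta": str(d / "fixture.fa"),
        "gtf": str(d / "fixture.gtf"),
        "vcf": str(d / "cases.vcf"),
        "truth": truth,
    }


@pytest.fixture(scope="session")
def genome(fixture_dir):
    return fixture_dir["genome"]


@pytest.fixture(scope="session")
def reference(fixture_dir):
    return load_reference(fixture_dir["fasta"])


@pytest.fixture(scope="session")
def db(fixture_dir, reference):
    return load_transcripts(fixture_dir["gtf"], reference)


def annotate_to_rows(fasta, gtf, vcf, **cfg_kwargs):
    """Run the pipeline to TSV and return a list of row dicts."""
    buf = io.StringIO()
    cfg = AnnotationConfig(reference_path=fasta, transcript_db_path=gtf, **cfg_kwargs)
    run_pipeline(cfg, vcf, out=buf)
    lines = buf.getvalue().splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def annotate_text(fasta, gtf, vcf, **cfg_kwargs):
    buf = io.StringIO()
    cfg = AnnotationConfig(reference_path=fasta, transcript_db_path=gtf, **cfg_kwargs)
    run_pipeline(cfg, vcf, out=buf)
    return buf.getvalue()


@pytest.fixture(scope="session")
def annotated_rows(fixture_dir):
    return annotate_to_rows(fixture_dir["fasta"], fixture_dir["gtf"], fixture_dir["vcf"])
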