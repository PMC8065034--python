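import pytest

from besplice.fixtures import (
    FixtureConfig,
    fix1_contig,
    fix1_sites,
    fix1_transcript,
    make_fixture_genes,
    make_fixture_meta,
    MetaFixtureConfig,
)


@pytest.fixture(scope="session")
def fix1():
    """The hand-built 60-nt two-exon worked example."""
    contig = fix1_contig()
    return {
        "contigs": {contig.name: contig},
        "transcript": fix1_transcript(),
        "sites": fix1_sites(),
    }


@pytest.fixture(scope="session")
def seeded_genes():
    """50 synthetic genes with oracle truth for the default NGG editors."""
    contigs, transcripts, truths = make_fixture_genes(50, seed=2024)
    return contigs, transcripts, truths


@pytest.fixture(scope="session")
def meta_table():
    """One default-scale synthetic meta-analysis table + planted params."""
    return make_fixture_meta(MetaFixtureConfig(), seed=11)


@pytest.fixture(scope="session")
def collapsed_meta(meta_table):
    from besplice.meta_analysis import collapse_duplicates, normalize_records

    df, _ = meta_table
    return collapse_duplicates(normalize_records(df))
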