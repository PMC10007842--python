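"""Shared test fixtures: toy gene models and a generated synthetic panel."""

from dataclasses import dataclass
from pathlib import Path

import pytest

from allelecat.catalog_builder import AlleleCatalog, build_catalog
from allelecat.fixtures import FixtureSpec, TruthManifest, generate_fixture
from allelecat.io_formats import (
    CategorySpec,
    GeneModel,
    GenomeSequence,
    Transcript,
    read_fasta,
    read_gff,
    read_metadata,
    read_vcf,
)

# chr1: 10 filler bases, then a 15-base single-exon gene (ATG ACT GGG TTG TAA
# -> protein MTGL*), then filler
TOY_CHROM = "CCCCCCCCCC" + "ATGACTGGGTTGTAA" + "CCCCCGGGGG"

# chr2 carries the same coding sequence split by a GT..AG intron:
# exon1 11..19 (ATGACTGGG), intron 20..27, exon2 28..33 (TTGTAA)
TOY2_CHROM = "CCCCCCCCCC" + "ATGACTGGG" + "GTCCCCAG" + "TTGTAA" + "CCCCC"


@pytest.fixture
def toy_genome() -> GenomeSequence:
    return GenomeSequence({"chr1": TOY_CHROM, "chr2": TOY2_CHROM})


@pytest.fixture
def toy_gene() -> GeneModel:
    tx = Transcript("gA.t1", ((11, 25),), ((11, 25, 0),))
    return GeneModel("gA", "chr1", 11, 25, "+", (tx,))


@pytest.fixture
def toy_two_exon_gene() -> GeneModel:
    tx = Transcript("gB.t1", ((11, 19), (28, 33)), ((11, 19, 0), (28, 33, 0)))
    return GeneModel("gB", "chr2", 11, 33, "+", (tx,))


@dataclass
class Panel:
    """A generated synthetic panel, parsed back through the io layer."""

    paths: dict
    manifest: TruthManifest
    genome: GenomeSequence
    genes: list
    accessions: list
    records: list
    metadata: list
    category_spec: CategorySpec
    catalog: AlleleCatalog


def build_panel(spec: FixtureSpec, out_dir: Path) -> Panel:
    paths, manifest = generate_fixture(spec, out_dir)
    genome = read_fasta(paths["fasta"])
    genes = read_gff(paths["gff"])
    accessions, records = read_vcf(paths["vcf"])
    category_spec = CategorySpec.from_json(paths["category_spec"])
    metadata = read_metadata(paths["metadata"], category_spec)
    catalog = build_catalog(genome, genes, records, accessions, metadata, category_spec)
    return Panel(
        paths=paths,
        manifest=manifest,
        genome=genome,
        genes=genes,
        accessions=accessions,
        records=records,
        metadata=metadata,
        category_spec=category_spec,
        catalog=catalog,
    )


@pytest.fixture(scope="session")
def panel(tmp_path_factory) -> Panel:
    """Default 20-accession, 6-gene panel with missing calls (seed 11)."""
    return build_panel(FixtureSpec(seed=11), tmp_path_factory.mktemp("panel"))


@pytest.fixture(scope="session")
def complete_panel(tmp_path_factory) -> Panel:
    """A panel with no missing calls (for imputation-identity checks)."""
    return build_panel(
        FixtureSpec(seed=12, missing_rate=0.0), tmp_path_factory.mktemp("panel_complete")
    )
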