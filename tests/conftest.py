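"""Shared fixtures: hand-sized genomes and a small synthetic bundle."""

from __future__ import annotations

import pytest

from paraphage import GeneRecord, GenomeAnnotation, SyntheticConfig, generate_genome

TOY_SEQ = "ATGGCATTAGCG"  # 12 nt; gene X=1..9 translates M-A-L


@pytest.fixture
def toy_genome() -> GenomeAnnotation:
    """12-nt circle with a single gene X covering 1..9."""
    return GenomeAnnotation(TOY_SEQ, [GeneRecord("X", 1, 9)])


@pytest.fixture
def overlap_genome() -> GenomeAnnotation:
    """Two genes in different frames: X=1..9 and Y=3..11."""
    return GenomeAnnotation(
        TOY_SEQ, [GeneRecord("X", 1, 9), GeneRecord("Y", 3, 11)]
    )


@pytest.fixture
def wrap_genome() -> GenomeAnnotation:
    """Gene W wraps the origin: start 10, end 6 on a 12-nt circle (span 9)."""
    return GenomeAnnotation(TOY_SEQ, [GeneRecord("W", 10, 6)])


SMALL_CONFIG = SyntheticConfig(
    genome_length=900,
    n_genes=4,
    n_lineages=6,
    total_events=40,
    n_hotspots=3,
    hotspot_weight=60.0,
    n_isolates=8,
    n_wild_differences=60,
    n_regulatory=20,
    seed=1234,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_genome() -> GenomeAnnotation:
    return generate_genome(SMALL_CONFIG)


def write_genome_files(tmp_path, genome: GenomeAnnotation, name="toy"):
    """Write FASTA + annotation TSV for a GenomeAnnotation; return the paths."""
    fasta = tmp_path / f"{name}.fasta"
    fasta.write_text(f">{name}\n{genome.sequence}\n")
    ann = tmp_path / f"{name}_genes.tsv"
    lines = ["name\tstart\tend\tessential"]
    for g in genome.genes:
        lines.append(f"{g.name}\t{g.start}\t{g.end}\t{str(g.essential).lower()}")
    ann.write_text("\n".join(lines) + "\n")
    return fasta, ann
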