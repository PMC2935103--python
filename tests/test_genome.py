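"""Genome model: loading, circular coordinates, codon mapping over overlaps."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from paraphage import (
    AnnotationError,
    GeneRecord,
    GenomeAnnotation,
    SyntheticConfig,
    build_overlap_mask,
    generate_genome,
    load_genome,
    map_substitution,
)

from conftest import TOY_SEQ, write_genome_files


def retranslation_changes(genome: GenomeAnnotation, position, ref, alt):
    """Independent oracle: full-gene re-translation difference for every gene.

    Coverage, codon arithmetic and translation are all recomputed here from
    first principles (explicit unwrapped position lists + Biopython), not via
    the package's mapping path.
    """
    G = genome.length
    assert genome.sequence[position - 1] == ref
    mutated = (
        genome.sequence[: position - 1] + alt + genome.sequence[position:]
    )
    expected = []
    for gene in genome.genes:
        if gene.end >= gene.start:
            positions = list(range(gene.start, gene.end + 1))
        else:
            positions = list(range(gene.start, G + 1)) + list(range(1, gene.end + 1))
        if position not in positions:
            continue
        ref_cds = "".join(genome.sequence[p - 1] for p in positions)
        alt_cds = "".join(mutated[p - 1] for p in positions)
        ref_prot = str(Seq(ref_cds).translate(table=11))
        alt_prot = str(Seq(alt_cds).translate(table=11))
        residue = positions.index(position) // 3 + 1
        expected.append(
            (gene.name, residue, ref_prot[residue - 1], alt_prot[residue - 1])
        )
    return sorted(expected)


class TestLoadGenome:
    def test_toy_tsv_annotation_translates(self, tmp_path, toy_genome):
        fasta, ann = write_genome_files(tmp_path, toy_genome)
        genome = load_genome(fasta, ann)
        assert genome.length == 12
        assert genome.translate(genome.gene("X")) == "MAL"

    def test_gff3_annotation(self, tmp_path, toy_genome):
        fasta, _ = write_genome_files(tmp_path, toy_genome)
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "toy\ttest\tCDS\t1\t9\t.\t+\t0\tID=cds-X;Name=X\n"
        )
        genome = load_genome(fasta, gff)
        assert [g.name for g in genome.genes] == ["X"]
        assert genome.translate(genome.gene("X")) == "MAL"

    def test_multi_record_fasta_rejected(self, tmp_path, toy_genome):
        _, ann = write_genome_files(tmp_path, toy_genome)
        fasta = tmp_path / "two.fasta"
        fasta.write_text(">a\nATGGCATTAGCG\n>b\nATGGCATTAGCG\n")
        with pytest.raises(AnnotationError, match="one sequence"):
            load_genome(fasta, ann)

    def test_span_not_multiple_of_three_names_gene(self):
        with pytest.raises(AnnotationError, match="gene X.*multiple of 3"):
            GenomeAnnotation(TOY_SEQ, [GeneRecord("X", 1, 8)])

    def test_internal_stop_names_gene_and_codon(self):
        # TAA at codons 3..5 of a 1..9 gene: ATG GTA ATA -> no; use ATG TAA GCA
        with pytest.raises(AnnotationError, match="gene Z.*codon 2"):
            GenomeAnnotation("ATGTAAGCACGT", [GeneRecord("Z", 1, 9)])

    def test_terminal_stop_allowed(self):
        genome = GenomeAnnotation("ATGGCATAAGCG", [GeneRecord("X", 1, 9)])
        assert genome.translate(genome.gene("X")) == "MA*"
        assert genome.codon_count(genome.gene("X")) == 2


class TestCircularCoordinates:
    def test_wrap_gene_accepted_and_reads_through_origin(self, wrap_genome):
        gene = wrap_genome.gene("W")
        assert gene.positions(12) == [10, 11, 12, 1, 2, 3, 4, 5, 6]
        assert gene.span(12) == 9

    def test_wrap_gene_codon_indexing(self, wrap_genome):
        gene = wrap_genome.gene("W")
        assert gene.offset_of(10, 12) == 0
        assert gene.offset_of(1, 12) == 3
        assert gene.offset_of(6, 12) == 8
        assert gene.offset_of(8, 12) == -1  # intergenic

    @pytest.mark.parametrize("shift", [1, 3, 5, 7, 11])
    def test_origin_shift_leaves_mapping_invariant(self, overlap_genome, shift):
        """Rotating the origin of sequence and annotation changes nothing."""
        G = overlap_genome.length
        rotated_seq = overlap_genome.sequence[shift:] + overlap_genome.sequence[:shift]

        def rot(p):
            return (p - 1 - shift) % G + 1

        rotated = GenomeAnnotation(
            rotated_seq,
            [
                GeneRecord(g.name, rot(g.start), rot(g.end), g.essential)
                for g in overlap_genome.genes
            ],
        )
        for pos in range(1, G + 1):
            ref = overlap_genome.base_at(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                orig = map_substitution(overlap_genome, pos, ref, alt)
                moved = map_substitution(rotated, rot(pos), ref, alt)
                assert sorted(map(str, orig)) == sorted(map(str, moved))


class TestMapSubstitution:
    def test_overlap_substitution_affects_both_genes(self, overlap_genome):
        changes = {str(c) for c in map_substitution(overlap_genome, 4, "G", "A")}
        assert changes == {"X2 A->T", "Y1 G->D"}

    def test_silent_change_flagged(self, toy_genome):
        (change,) = map_substitution(toy_genome, 6, "A", "G")  # GCA -> GCG
        assert (change.gene, change.residue, change.silent) == ("X", 2, True)
        assert change.ref_aa == change.alt_aa == "A"

    def test_noncoding_position_returns_empty(self, toy_genome):
        assert map_substitution(toy_genome, 11, "C", "T") == []

    def test_nonsense_change_reported_with_star(self, toy_genome):
        (change,) = map_substitution(toy_genome, 8, "T", "A")  # TTA -> TAA
        assert (change.ref_aa, change.alt_aa, change.silent) == ("L", "*", False)

    def test_ref_mismatch_names_position_and_base(self, toy_genome):
        with pytest.raises(AnnotationError, match="at 4: expected G"):
            map_substitution(toy_genome, 4, "C", "A")

    def test_position_out_of_range(self, toy_genome):
        with pytest.raises(AnnotationError, match="outside genome"):
            map_substitution(toy_genome, 13, "A", "G")

    def test_wrap_gene_mapping_matches_retranslation(self, wrap_genome):
        for pos in [10, 12, 1, 5]:
            ref = wrap_genome.base_at(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = sorted(
                    (c.gene, c.residue, c.ref_aa, c.alt_aa)
                    for c in map_substitution(wrap_genome, pos, ref, alt)
                )
                assert got == retranslation_changes(wrap_genome, pos, ref, alt)

    def test_k_covering_genes_give_k_changes(self, overlap_genome):
        for pos in range(1, 13):
            ref = overlap_genome.base_at(pos)
            alt = "A" if ref != "A" else "C"
            k = len(overlap_genome.genes_covering(pos))
            assert len(map_substitution(overlap_genome, pos, ref, alt)) == k


class TestOverlapMask:
    def test_out_of_frame_pair(self, overlap_genome):
        assert sorted(build_overlap_mask(overlap_genome).positions) == list(
            range(3, 10)
        )

    def test_single_gene_empty(self, toy_genome):
        assert len(build_overlap_mask(toy_genome)) == 0

    def test_in_frame_nested_gene_not_masked(self):
        # X* starts at codon 3 of X, same frame (an A/A*-style internal start)
        genome = GenomeAnnotation(
            "ATGGCATTAGCG", [GeneRecord("X", 1, 12), GeneRecord("Xs", 7, 12)]
        )
        assert len(build_overlap_mask(genome)) == 0
        changes = map_substitution(genome, 8, "T", "C")
        assert {(c.gene, c.residue) for c in changes} == {("X", 3), ("Xs", 1)}

    def test_three_genes_match_brute_force(self):
        seq = "ATGGCATTAGCGATTGCC"  # 18 nt
        genes = [
            GeneRecord("P", 1, 9),
            GeneRecord("Q", 3, 11),
            GeneRecord("R", 7, 18),
        ]
        genome = GenomeAnnotation(seq, genes)
        mask = build_overlap_mask(genome)
        # brute force: per-position pairwise phase comparison
        expected = set()
        for pos in range(1, 19):
            cov = [
                (g.name, g.offset_of(pos, 18) % 3)
                for g in genes
                if g.covers(pos, 18)
            ]
            phases = {p for _, p in cov}
            if len(cov) >= 2 and len(phases) >= 2:
                expected.add(pos)
        assert mask.positions == expected


class TestRetranslationProperty:
    def test_random_genomes_match_full_retranslation(self):
        """Mapped changes equal re-translation diffs on random overlapping,
        origin-wrapping genomes (200 spot checks)."""
        rng = np.random.default_rng(42)
        cases = 0
        for seed in range(8):
            config = SyntheticConfig(
                genome_length=300, n_genes=3, n_lineages=1, total_events=1,
                n_hotspots=0, seed=seed,
            )
            genome = generate_genome(config)
            for _ in range(25):
                pos = int(rng.integers(1, genome.length + 1))
                ref = genome.base_at(pos)
                alt = "ACGT".replace(ref, "")[rng.integers(3)]
                got = sorted(
                    (c.gene, c.residue, c.ref_aa, c.alt_aa)
                    for c in map_substitution(genome, pos, ref, alt)
                )
                assert got == retranslation_changes(genome, pos, ref, alt)
                cases += 1
        assert cases == 200
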