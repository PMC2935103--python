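"""Substitution input, deduplication, founder subtraction and tallies."""

from __future__ import annotations

import logging

import pytest

from paraphage import (
    CountingMode,
    LineageSet,
    SubstitutionError,
    SubstitutionRecord,
    generate_lineages,
    read_substitutions,
    subtract_founder,
    tally_regulatory,
    tally_sites,
)

from conftest import write_genome_files


def write_tsv(path, rows):
    lines = ["lineage\tposition\tref\talt\tkind"]
    lines += ["\t".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadSubstitutions:
    def test_within_lineage_duplicate_counted_once(self, tmp_path):
        path = write_tsv(
            tmp_path / "s.tsv",
            [
                ("L1", 4, "G", "A", "substitution"),
                ("L1", 4, "G", "A", "substitution"),
                ("L2", 4, "G", "A", "substitution"),
            ],
        )
        ls = read_substitutions(path)
        assert ls.n_events == 2
        assert ls.lineages == {"L1", "L2"}

    def test_different_alt_at_same_position_both_retained(self, tmp_path):
        path = write_tsv(
            tmp_path / "s.tsv",
            [("L1", 4, "G", "A", "substitution"), ("L1", 4, "G", "T", "substitution")],
        )
        assert read_substitutions(path).n_events == 2

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = (tmp_path / "empty.tsv")
        path.write_text("")
        ls = read_substitutions(path)
        assert ls.n_events == 0 and ls.lineages == set()

    def test_unknown_base_symbol_rejected_with_line(self, tmp_path):
        path = write_tsv(tmp_path / "s.tsv", [("L1", 4, "G", "Z", "substitution")])
        with pytest.raises(SubstitutionError, match=":2:.*unknown base"):
            read_substitutions(path)

    def test_malformed_position_rejected_with_line(self, tmp_path):
        path = write_tsv(tmp_path / "s.tsv", [("L1", "abc", "G", "A", "substitution")])
        with pytest.raises(SubstitutionError, match=":2:.*not an integer"):
            read_substitutions(path)

    def test_position_and_ref_validated_against_genome(self, tmp_path, toy_genome):
        path = write_tsv(tmp_path / "s.tsv", [("L1", 4, "C", "A", "substitution")])
        with pytest.raises(SubstitutionError, match="reference mismatch at 4"):
            read_substitutions(path, genome=toy_genome)
        path2 = write_tsv(tmp_path / "s2.tsv", [("L1", 99, "G", "A", "substitution")])
        with pytest.raises(SubstitutionError, match="outside genome"):
            read_substitutions(path2, genome=toy_genome)

    def test_vcf_two_samples_match_hand_parsed_fixture(self, tmp_path):
        vcf = tmp_path / "two.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=toy,length=12>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tlinA\tlinB\n"
            "toy\t4\t.\tG\tA\t.\t.\t.\tGT\t1\t0\n"
            "toy\t6\t.\tA\tG,T\t.\t.\t.\tGT\t1\t2\n"
            "toy\t9\t.\tAG\tA\t.\t.\t.\tGT\t0\t1\n"
        )
        ls = read_substitutions(vcf, format="vcf")
        got = {(r.lineage, r.position, r.alt, r.kind) for r in ls.records}
        assert got == {
            ("linA", 4, "A", "substitution"),
            ("linA", 6, "G", "substitution"),
            ("linB", 6, "T", "substitution"),
            ("linB", 9, "-1", "deletion"),
        }

    def test_roundtrip_preserves_tallies(self, tmp_path, overlap_genome):
        rows = [
            ("L1", 4, "G", "A", "substitution"),
            ("L2", 4, "G", "A", "substitution"),
            ("L2", 6, "A", "G", "substitution"),
        ]
        ls = read_substitutions(write_tsv(tmp_path / "a.tsv", rows))
        ls.write_tsv(tmp_path / "b.tsv")
        ls2 = read_substitutions(tmp_path / "b.tsv")
        t1 = tally_sites(ls, overlap_genome)
        t2 = tally_sites(ls2, overlap_genome)
        assert t1.nucleotide_counts == t2.nucleotide_counts
        assert t1.residue_counts == t2.residue_counts


class TestSubtractFounder:
    def test_founder_changes_removed(self):
        ls = LineageSet(
            records=[
                SubstitutionRecord("L1", 1001, "A", "G"),
                SubstitutionRecord("L1", 2002, "C", "T"),
            ],
            founder_genotypes={"L1": {(1001, "G")}},
        )
        out = subtract_founder(ls)
        assert [(r.position, r.alt) for r in out.records] == [(2002, "T")]

    def test_empty_founder_map_is_identity(self):
        ls = LineageSet(records=[SubstitutionRecord("L1", 5, "A", "G")])
        assert subtract_founder(ls).records == ls.records

    def test_unknown_lineage_rejected(self):
        ls = LineageSet(
            records=[SubstitutionRecord("L1", 5, "A", "G")],
            founder_genotypes={"ghost": {(5, "G")}},
        )
        with pytest.raises(SubstitutionError, match="ghost"):
            subtract_founder(ls)

    def test_absent_founder_change_warns_but_keeps_lineage(self, caplog):
        ls = LineageSet(
            records=[SubstitutionRecord("L1", 5, "A", "G")],
            founder_genotypes={"L1": {(7, "T")}},
        )
        with caplog.at_level(logging.WARNING):
            out = subtract_founder(ls)
        assert out.records == ls.records
        assert "absent from records" in caplog.text


class TestTallySites:
    def test_identical_events_pooled_in_both_modes(self, toy_genome):
        ls = LineageSet(
            records=[SubstitutionRecord(f"L{i}", 4, "G", "A") for i in range(3)]
        )
        site = tally_sites(ls, toy_genome, "site_level")
        ident = tally_sites(ls, toy_genome, "identical_change")
        assert site.nucleotide_counts[4] == 3
        assert ident.nucleotide_counts[(4, "A")] == 3

    def test_alternate_substitutions_split_by_mode(self, toy_genome):
        ls = LineageSet(
            records=[
                SubstitutionRecord("L1", 4, "G", "A"),
                SubstitutionRecord("L2", 4, "G", "A"),
                SubstitutionRecord("L3", 4, "G", "T"),
            ]
        )
        site = tally_sites(ls, toy_genome, CountingMode.site_level)
        ident = tally_sites(ls, toy_genome, CountingMode.identical_change)
        assert site.nucleotide_counts[4] == 3
        assert ident.nucleotide_counts[(4, "A")] == 2
        assert ident.nucleotide_counts[(4, "T")] == 1

    def test_overlap_event_increments_two_residue_keys(self, overlap_genome):
        ls = LineageSet(records=[SubstitutionRecord("L1", 4, "G", "A")])
        tally = tally_sites(ls, overlap_genome)
        assert tally.residue_counts[("X", 2)] == 1
        assert tally.residue_counts[("Y", 1)] == 1
        assert tally.total_events == 1  # one nucleotide event, two residues

    def test_silent_events_excluded_from_residue_counts(self, toy_genome):
        ls = LineageSet(records=[SubstitutionRecord("L1", 6, "A", "G")])  # silent
        tally = tally_sites(ls, toy_genome)
        assert tally.nucleotide_counts[6] == 1
        assert tally.total_aa_substitutions == 0

    def test_indels_excluded_from_residue_counts(self, toy_genome):
        ls = LineageSet(
            records=[
                SubstitutionRecord("L1", 4, "G", "A"),
                SubstitutionRecord("L1", 5, "C", "+AT", kind="insertion"),
            ]
        )
        tally = tally_sites(ls, toy_genome)
        assert tally.total_events == 1  # the insertion is not a substitution event
        assert all(len(k) == 2 for k in tally.residue_counts)

    @pytest.mark.parametrize("mode", list(CountingMode))
    def test_conservation_and_mode_dominance(self, mode, small_genome, small_config):
        """Sum of nucleotide counts equals retained events; identical-change
        counts never exceed the site-level count at the same position."""
        lineages, _ = generate_lineages(small_genome, small_config)
        tally = tally_sites(lineages, small_genome, mode)
        assert sum(tally.nucleotide_counts.values()) == tally.total_events
        assert tally.total_events == len(lineages.substitutions())
        if mode is CountingMode.identical_change:
            site = tally_sites(lineages, small_genome, CountingMode.site_level)
            for (pos, _alt), c in tally.nucleotide_counts.items():
                assert c <= site.nucleotide_counts[pos]


class TestTallyRegulatory:
    def test_events_and_positions_hit(self):
        ls = LineageSet(
            records=[
                SubstitutionRecord("L1", 10, "A", "G"),
                SubstitutionRecord("L2", 10, "A", "-2", kind="deletion"),
                SubstitutionRecord("L1", 20, "C", "T"),
                SubstitutionRecord("L1", 99, "C", "T"),
            ]
        )
        events, hit = tally_regulatory(ls, {10, 20, 30})
        assert (events, hit) == (3, 2)

    def test_repeated_hits_at_one_position(self):
        ls = LineageSet(
            records=[SubstitutionRecord(f"L{i}", 10, "A", "G") for i in range(5)]
        )
        assert tally_regulatory(ls, {10, 11}) == (5, 1)

    def test_empty_event_set(self):
        assert tally_regulatory(LineageSet(), {1, 2}) == (0, 0)

    def test_empty_regulatory_list_rejected(self):
        with pytest.raises(SubstitutionError, match="empty"):
            tally_regulatory(LineageSet(), set())
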