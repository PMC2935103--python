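"""Circular genome model with overlapping reading frames.

A microvirid-style genome is a single circular DNA sequence a few kilobases
long in which several genes overlap, sometimes in different reading frames,
and one gene may wrap across the sequence origin.  Because of out-of-frame
overlaps a single nucleotide substitution can change the encoded amino acid
in more than one protein at once; this module maps substitutions onto every
gene that covers them.

Coordinates are 1-based inclusive on the forward strand, following GenBank
convention for these phages.  A gene whose ``end`` is smaller than its
``start`` wraps the origin: its coding span runs ``start..G`` then ``1..end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "AminoAcidChange",
    "OverlapMask",
    "AnnotationError",
    "load_genome",
    "read_annotation_table",
    "map_substitution",
    "changes_on_background",
    "build_overlap_mask",
]

#: NCBI translation table used throughout (bacterial / archaeal / plant plastid).
TRANSLATION_TABLE = 11

BASES = frozenset("ACGT")


class AnnotationError(ValueError):
    """Raised when a genome or its annotation violates a structural invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One forward-strand coding interval on the circular genome.

    ``end < start`` encodes a gene that wraps the origin.
    """

    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; < start means origin wrap
    essential: bool = True

    def span(self, genome_length: int) -> int:
        """Coding span in nucleotides after unwrapping the circle."""
        if self.end >= self.start:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end

    def positions(self, genome_length: int) -> list[int]:
        """Genomic positions of the coding span, 5' to 3'."""
        if self.end >= self.start:
            return list(range(self.start, self.end + 1))
        return list(range(self.start, genome_length + 1)) + list(
            range(1, self.end + 1)
        )

    def offset_of(self, position: int, genome_length: int) -> int:
        """0-based offset of a genomic position within the gene, or -1 if outside."""
        off = (position - self.start) % genome_length
        if off < self.span(genome_length):
            return off
        return -1

    def covers(self, position: int, genome_length: int) -> bool:
        return self.offset_of(position, genome_length) >= 0


@dataclass(frozen=True)
class AminoAcidChange:
    """Residue-level consequence of one nucleotide substitution in one gene."""

    gene: str
    residue: int  # 1-based codon index within the gene
    ref_aa: str
    alt_aa: str

    @property
    def silent(self) -> bool:
        return self.ref_aa == self.alt_aa

    def __str__(self) -> str:  # e.g. "F242 L->F"
        return f"{self.gene}{self.residue} {self.ref_aa}->{self.alt_aa}"


@dataclass(frozen=True)
class OverlapMask:
    """Genomic positions covered by >=2 genes in *different* reading frames.

    Same-frame overlaps (an in-frame internal start such as gene A* inside
    gene A) are deliberately excluded: a substitution there has the same
    codon-level effect in both genes.
    """

    positions: frozenset[int]

    def __contains__(self, position: int) -> bool:
        return position in self.positions

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class GenomeAnnotation:
    """A circular reference sequence plus its (possibly overlapping) genes."""

    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise AnnotationError(
                f"position {position} outside genome [1, {self.length}]"
            )
        return self.sequence[position - 1]

    def gene(self, name: str) -> GeneRecord:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def genes_covering(self, position: int) -> list[GeneRecord]:
        return [g for g in self.genes if g.covers(position, self.length)]

    def coding_sequence(self, gene: GeneRecord, sequence: str | None = None) -> str:
        """Unwrapped CDS of ``gene`` read from ``sequence`` (default: reference)."""
        seq = self.sequence if sequence is None else sequence
        return "".join(seq[p - 1] for p in gene.positions(self.length))

    def translate(self, gene: GeneRecord, sequence: str | None = None) -> str:
        """Protein sequence of ``gene``, every codon translated as written.

        The initiator codon is translated as the code dictates (a GTG start
        reads as V, not a forced M), so mapped changes always equal full-gene
        re-translation differences.
        """
        cds = self.coding_sequence(gene, sequence)
        return str(Seq(cds).translate(table=TRANSLATION_TABLE))

    def codon_count(self, gene: GeneRecord) -> int:
        """Number of amino-acid codons, excluding a terminal stop if present."""
        protein = self.translate(gene)
        if protein.endswith("*"):
            return len(protein) - 1
        return len(protein)

    def validate(self) -> None:
        bad = set(self.sequence) - BASES
        if bad:
            raise AnnotationError(f"sequence contains non-ACGT symbols: {sorted(bad)}")
        if not self.circular:
            raise AnnotationError("only circular genomes are supported")
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise AnnotationError("duplicate gene names in annotation")
        for g in self.genes:
            if not (1 <= g.start <= self.length and 1 <= g.end <= self.length):
                raise AnnotationError(
                    f"gene {g.name}: interval {g.start}..{g.end} outside "
                    f"[1, {self.length}]"
                )
            span = g.span(self.length)
            if span % 3 != 0:
                raise AnnotationError(
                    f"gene {g.name}: span of {span} nt is not a multiple of 3"
                )
            if span > self.length:
                raise AnnotationError(
                    f"gene {g.name}: span {span} exceeds genome length"
                )
            protein = self.translate(g)
            internal = protein[:-1]  # a terminal stop codon is allowed
            if "*" in internal:
                raise AnnotationError(
                    f"gene {g.name}: internal stop codon at codon "
                    f"{internal.index('*') + 1}"
                )


def read_annotation_table(path: str | Path) -> list[GeneRecord]:
    """Read gene intervals from GFF3 (CDS features) or a 4-column TSV.

    The TSV dialect is ``name<TAB>start<TAB>end<TAB>essential`` with a header
    row; GFF3 files use ``type == CDS`` rows and the ``Name`` (or ``ID``)
    attribute.  Frame is always derived from ``start``; GFF3 phase is ignored.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("##gff") or path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    return _read_tsv(text, path)


def _read_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        essential = feat.attributes.get("essential", ["true"])[0].lower() != "false"
        genes.append(GeneRecord(name, feat.start, feat.end, essential))
    if not genes:
        raise AnnotationError(f"{path}: no CDS features found")
    return genes


def _read_tsv(text: str, path: Path) -> list[GeneRecord]:
    import csv
    import io as _io

    rows = list(csv.reader(_io.StringIO(text), delimiter="\t"))
    rows = [r for r in rows if r and not r[0].startswith("#")]
    if not rows:
        raise AnnotationError(f"{path}: empty annotation table")
    if rows[0][0].lower() == "name":
        rows = rows[1:]
    genes = []
    for i, row in enumerate(rows, start=2):
        if len(row) < 3:
            raise AnnotationError(f"{path}:{i}: expected >=3 columns, got {len(row)}")
        essential = True
        if len(row) >= 4:
            essential = row[3].strip().lower() in {"1", "true", "yes"}
        genes.append(GeneRecord(row[0].strip(), int(row[1]), int(row[2]), essential))
    return genes


def load_genome(
    fasta_source: str | Path, annotation_source: str | Path
) -> GenomeAnnotation:
    """Load a single-record FASTA plus a GFF3/TSV annotation and validate both.

    Raises :class:`AnnotationError` for a multi-record FASTA, a gene span that
    is not a multiple of 3, or a gene containing an internal stop codon.
    """
    records = list(SeqIO.parse(str(fasta_source), "fasta"))
    if len(records) != 1:
        raise AnnotationError(
            f"{fasta_source}: expected exactly one sequence, found {len(records)}"
        )
    genes = read_annotation_table(annotation_source)
    return GenomeAnnotation(sequence=str(records[0].seq), genes=genes)


def changes_on_background(
    genome: GenomeAnnotation,
    position: int,
    ref: str,
    alt: str,
    background: str | None = None,
) -> list[AminoAcidChange]:
    """Amino-acid consequences of ``ref -> alt`` at ``position`` in every
    covering gene, with codon context taken from ``background`` (default: the
    reference sequence).

    The background lets natural variation be classified against a panel
    consensus rather than the laboratory reference.
    """
    ref, alt = ref.upper(), alt.upper()
    seq = genome.sequence if background is None else background.upper()
    if len(seq) != genome.length:
        raise AnnotationError("background sequence length differs from genome")
    if not 1 <= position <= genome.length:
        raise AnnotationError(
            f"position {position} outside genome [1, {genome.length}]"
        )
    if ref not in BASES or alt not in BASES:
        raise AnnotationError(f"bases must be one of ACGT, got {ref!r}->{alt!r}")
    if seq[position - 1] != ref:
        raise AnnotationError(
            f"reference mismatch at {position}: expected {seq[position - 1]}, "
            f"got {ref}"
        )
    if ref == alt:
        raise AnnotationError(f"substitution at {position} has ref == alt ({ref})")

    changes: list[AminoAcidChange] = []
    for gene in genome.genes_covering(position):
        off = gene.offset_of(position, genome.length)
        codon_idx = off // 3  # 0-based
        phase = off % 3
        pos_list = gene.positions(genome.length)
        codon_pos = pos_list[codon_idx * 3 : codon_idx * 3 + 3]
        ref_codon = "".join(seq[p - 1] for p in codon_pos)
        alt_codon = ref_codon[:phase] + alt + ref_codon[phase + 1 :]
        ref_aa = str(Seq(ref_codon).translate(table=TRANSLATION_TABLE))
        alt_aa = str(Seq(alt_codon).translate(table=TRANSLATION_TABLE))
        changes.append(AminoAcidChange(gene.name, codon_idx + 1, ref_aa, alt_aa))
    return changes


def map_substitution(
    genome: GenomeAnnotation, position: int, ref: str, alt: str
) -> list[AminoAcidChange]:
    """Map one nucleotide substitution onto every gene covering it.

    Returns one :class:`AminoAcidChange` per covering gene (an empty list for
    non-coding positions); silent changes are included and flagged.  ``ref``
    must match the reference base at ``position``.
    """
    return changes_on_background(genome, position, ref, alt, background=None)


def build_overlap_mask(genome: GenomeAnnotation) -> OverlapMask:
    """Positions where >=2 genes read the sequence in different codon phases.

    A position covered by two genes in the same phase (in-frame nested gene)
    is *not* masked.
    """
    masked: set[int] = set()
    G = genome.length
    for i, a in enumerate(genome.genes):
        pos_a = a.positions(G)
        set_a = set(pos_a)
        for b in genome.genes[i + 1 :]:
            for p in b.positions(G):
                if p in set_a:
                    if a.offset_of(p, G) % 3 != b.offset_of(p, G) % 3:
                        masked.add(p)
    return OverlapMask(frozenset(masked))
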