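"""Reading, validating and tallying per-lineage substitution data.

Input is one table of molecular changes compiled across independently evolved
lineages: either the canonical TSV dialect (``lineage position ref alt kind``)
or a VCF in which each sample column is one lineage.  Within a lineage an
identical change — the same position and the same alternate state — is counted
only once; distinct alternate bases at one position are distinct mutations.

Tallies are kept at two levels and in two counting modes:

* nucleotide level — every retained substitution event, keyed by position
  (``site_level``) or by ``(position, alt)`` (``identical_change``);
* residue level — amino-acid substitutions only (silent changes excluded),
  keyed per gene so that one nucleotide event inside an out-of-frame overlap
  increments a residue in every covering gene.

Insertions and deletions are retained as events for the nucleotide and
regulatory tallies but never enter residue tallies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .genome import BASES, GenomeAnnotation, map_substitution

__all__ = [
    "SubstitutionRecord",
    "LineageSet",
    "SiteTally",
    "CountingMode",
    "SubstitutionError",
    "read_substitutions",
    "subtract_founder",
    "tally_sites",
    "tally_regulatory",
    "write_tally",
]

log = logging.getLogger(__name__)

TSV_COLUMNS = ["lineage", "position", "ref", "alt", "kind"]


class SubstitutionError(ValueError):
    """Raised for malformed or inconsistent substitution input."""


class CountingMode(str, Enum):
    """How repeated events are pooled.

    ``site_level``: any event at a site/residue counts toward it (reversions
    and alternate substitutions included).  ``identical_change``: only events
    with the same alternate state are pooled under one key.
    """

    site_level = "site_level"
    identical_change = "identical_change"


@dataclass(frozen=True)
class SubstitutionRecord:
    """One observed change in one lineage at one nucleotide position."""

    lineage: str
    position: int
    ref: str
    alt: str  # alternate base, or indel token such as "+AT" / "-3"
    kind: str = "substitution"  # substitution | insertion | deletion

    @property
    def is_substitution(self) -> bool:
        return self.kind == "substitution"

    def key(self) -> tuple[str, int, str]:
        """Identity of a change within a lineage: (lineage, position, alt)."""
        return (self.lineage, self.position, self.alt)


@dataclass
class LineageSet:
    """Deduplicated substitution records across a set of evolved lineages."""

    records: list[SubstitutionRecord] = field(default_factory=list)
    founder_genotypes: dict[str, set[tuple[int, str]]] = field(default_factory=dict)

    @property
    def lineages(self) -> set[str]:
        return {r.lineage for r in self.records}

    @property
    def n_events(self) -> int:
        return len(self.records)

    def substitutions(self) -> list[SubstitutionRecord]:
        return [r for r in self.records if r.is_substitution]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.lineage, r.position, r.ref, r.alt, r.kind) for r in self.records],
            columns=TSV_COLUMNS,
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SiteTally:
    """Per-site and per-residue event counts across lineages.

    ``nucleotide_counts`` is keyed by position in ``site_level`` mode and by
    ``(position, alt)`` in ``identical_change`` mode; the values always sum to
    the number of retained substitution events.  ``residue_counts`` holds
    amino-acid substitutions only, keyed ``(gene, residue)`` or
    ``(gene, residue, alt_aa)`` according to the mode.
    """

    nucleotide_counts: Counter
    residue_counts: Counter
    mode: CountingMode
    total_events: int  # retained nucleotide substitution events

    @property
    def total_aa_substitutions(self) -> int:
        return sum(self.residue_counts.values())

    def position_counts(self) -> Counter:
        """Counts pooled per position regardless of mode."""
        pooled: Counter = Counter()
        for key, n in self.nucleotide_counts.items():
            pos = key[0] if isinstance(key, tuple) else key
            pooled[pos] += n
        return pooled

    def residue_site_counts(self) -> Counter:
        """Counts pooled per (gene, residue) regardless of mode."""
        pooled: Counter = Counter()
        for key, n in self.residue_counts.items():
            pooled[key[:2]] += n
        return pooled


def _dedup(records: list[SubstitutionRecord]) -> list[SubstitutionRecord]:
    seen: set[tuple[str, int, str]] = set()
    out = []
    dropped = 0
    for r in records:
        if r.key() in seen:
            dropped += 1
            continue
        seen.add(r.key())
        out.append(r)
    if dropped:
        log.info("deduplicated %d repeated within-lineage change(s)", dropped)
    return out


def read_substitutions(
    source: str | Path,
    format: str = "tsv",
    genome: GenomeAnnotation | None = None,
) -> LineageSet:
    """Read a per-lineage change table and apply within-lineage deduplication.

    ``format`` is ``"tsv"`` (canonical dialect) or ``"vcf"`` (one lineage per
    sample; any non-reference genotype call is one event).  When ``genome`` is
    given, positions and reference bases are validated against it.
    """
    if format == "tsv":
        records = _read_tsv(Path(source))
    elif format == "vcf":
        records = _read_vcf(Path(source))
    else:
        raise SubstitutionError(f"unknown format {format!r}")

    if genome is not None:
        for r in records:
            if not 1 <= r.position <= genome.length:
                raise SubstitutionError(
                    f"position {r.position} outside genome [1, {genome.length}]"
                )
            if r.is_substitution and genome.base_at(r.position) != r.ref:
                raise SubstitutionError(
                    f"reference mismatch at {r.position}: genome has "
                    f"{genome.base_at(r.position)}, table says {r.ref}"
                )
    return LineageSet(records=_dedup(records))


def _read_tsv(path: Path) -> list[SubstitutionRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SubstitutionError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.position)
        except (TypeError, ValueError):
            raise SubstitutionError(
                f"{path}:{i}: position {row.position!r} is not an integer"
            ) from None
        kind = (row.kind or "substitution").strip().lower()
        if kind not in {"substitution", "insertion", "deletion"}:
            raise SubstitutionError(f"{path}:{i}: unknown kind {kind!r}")
        ref = (row.ref or "").strip().upper()
        alt = (row.alt or "").strip().upper()
        if kind == "substitution":
            if ref not in BASES or alt not in BASES:
                raise SubstitutionError(
                    f"{path}:{i}: unknown base symbol {ref!r}->{alt!r}"
                )
            if ref == alt:
                raise SubstitutionError(f"{path}:{i}: ref == alt ({ref})")
        records.append(SubstitutionRecord(str(row.lineage), pos, ref, alt, kind))
    return records


def _read_vcf(path: Path) -> list[SubstitutionRecord]:
    from pysam import VariantFile

    records = []
    with VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise SubstitutionError(f"{path}: VCF has no sample columns")
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                if len(rec.ref) == 1 and len(alt) == 1:
                    kind, a = "substitution", alt
                elif len(alt) > len(rec.ref):
                    kind, a = "insertion", f"+{alt[len(rec.ref):]}"
                else:
                    kind, a = "deletion", f"-{len(rec.ref) - len(alt)}"
                for sample in samples:
                    gt = rec.samples[sample].get("GT") or ()
                    if alt_idx in gt:
                        records.append(
                            SubstitutionRecord(sample, rec.pos, rec.ref[0], a, kind)
                        )
    return records


def subtract_founder(lineages: LineageSet) -> LineageSet:
    """Remove founder-carried changes from each affected lineage.

    Some lineages are extensions of earlier experiments and already carry
    substitutions relative to the common ancestor; those events are not new
    evolution and are subtracted before tallying.
    """
    unknown = set(lineages.founder_genotypes) - lineages.lineages
    if unknown and lineages.records:
        raise SubstitutionError(
            f"founder genotype(s) reference unknown lineage(s): {sorted(unknown)}"
        )
    kept: list[SubstitutionRecord] = []
    removed = 0
    matched: dict[str, set[tuple[int, str]]] = {
        lin: set() for lin in lineages.founder_genotypes
    }
    for r in lineages.records:
        founder = lineages.founder_genotypes.get(r.lineage)
        if founder and (r.position, r.alt) in founder:
            removed += 1
            matched[r.lineage].add((r.position, r.alt))
            continue
        kept.append(r)
    for lin, founder in lineages.founder_genotypes.items():
        unmatched = founder - matched.get(lin, set())
        if unmatched:
            log.warning(
                "lineage %s: founder change(s) %s absent from records",
                lin,
                sorted(unmatched),
            )
    if removed:
        log.info("subtracted %d founder-carried event(s)", removed)
    return LineageSet(records=kept, founder_genotypes=lineages.founder_genotypes)


def tally_sites(
    lineages: LineageSet,
    genome: GenomeAnnotation,
    mode: CountingMode | str = CountingMode.site_level,
) -> SiteTally:
    """Aggregate events across lineages at nucleotide and residue level.

    Residue counts are derived through :func:`~paraphage.genome.map_substitution`,
    so one event inside an out-of-frame overlap increments a residue in every
    covering gene; silent changes never enter residue counts.
    """
    mode = CountingMode(mode)
    nt: Counter = Counter()
    res: Counter = Counter()
    subs = lineages.substitutions()
    for r in subs:
        nt_key = r.position if mode is CountingMode.site_level else (r.position, r.alt)
        nt[nt_key] += 1
        for change in map_substitution(genome, r.position, r.ref, r.alt):
            if change.silent:
                continue
            if mode is CountingMode.site_level:
                res[(change.gene, change.residue)] += 1
            else:
                res[(change.gene, change.residue, change.alt_aa)] += 1
    return SiteTally(
        nucleotide_counts=nt, residue_counts=res, mode=mode, total_events=len(subs)
    )


def tally_regulatory(
    lineages: LineageSet, regulatory_positions: set[int]
) -> tuple[int, int]:
    """Events (substitutions *and* indels) at listed regulatory positions.

    Returns ``(events, positions_hit)``: the total event count at listed
    positions and the number of distinct listed positions with >=1 event.
    """
    if not regulatory_positions:
        raise SubstitutionError("regulatory position set is empty")
    events = 0
    hit: set[int] = set()
    for r in lineages.records:
        if r.position in regulatory_positions:
            events += 1
            hit.add(r.position)
    return events, len(hit)


def write_tally(
    tally: SiteTally, genome: GenomeAnnotation, path: str | Path
) -> pd.DataFrame:
    """Write the canonical residue tally TSV.

    Columns: ``position gene residue ref_aa alt_aa count mode``; rows are the
    residue-level tally expanded back to representative nucleotide context
    (position of the first covering event is not tracked, so position is the
    gene-relative codon start).
    """
    rows = []
    for key, count in sorted(tally.residue_counts.items(), key=lambda kv: -kv[1]):
        gene_name, residue = key[0], key[1]
        gene = genome.gene(gene_name)
        codon_start = gene.positions(genome.length)[(residue - 1) * 3]
        ref_aa = genome.translate(gene)[residue - 1]
        alt_aa = key[2] if len(key) > 2 else "*any*"
        rows.append(
            (codon_start, gene_name, residue, ref_aa, alt_aa, count, tally.mode.value)
        )
    df = pd.DataFrame(
        rows,
        columns=["position", "gene", "residue", "ref_aa", "alt_aa", "count", "mode"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
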