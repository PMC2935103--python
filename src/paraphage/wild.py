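"""Natural variation from a wild-isolate panel and its overlap with lab sites.

If laboratory adaptation uses the same molecular pathways as adaptation in
nature, residues that evolved repeatedly in the laboratory should be variable
among wild isolates more often than chance predicts.  This module derives
variable nucleotide columns and variable amino-acid residues from an aligned
panel of wild genomes, computes the chance expectation ``a*b/N`` for the
intersection of two residue sets drawn from an N-residue universe, attaches an
exact hypergeometric tail test (an extension beyond the plain
expectation-vs-observation comparison, and labelled as such), and estimates
the silent:missense ratio of wild differences — the classic signature of
purifying selection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from scipy import stats as sps

from .genome import (
    BASES,
    GenomeAnnotation,
    OverlapMask,
    build_overlap_mask,
    changes_on_background,
)

__all__ = [
    "WildPanel",
    "OverlapResult",
    "SilentMissenseRatio",
    "WildPanelError",
    "read_panel_fasta",
    "panel_consensus",
    "derive_wild_variation",
    "expected_overlap",
    "overlap_test",
    "silent_missense_ratio",
    "residue_universe_size",
]


class WildPanelError(ValueError):
    """Raised for inconsistent wild-panel input."""


@dataclass
class WildPanel:
    """Aligned wild-isolate genomes (equal length, ungapped) or a precomputed
    variable-residue table."""

    sequences: dict[str, str] = field(default_factory=dict)
    variable_residues: set[tuple[str, int]] | None = None

    @property
    def n_isolates(self) -> int:
        return len(self.sequences)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


def read_panel_fasta(path: str | Path) -> WildPanel:
    """Read an aligned, ungapped, equal-length FASTA panel."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise WildPanelError(f"{path}: isolates have unequal lengths {sorted(lengths)}")
    for name, s in seqs.items():
        if set(s) - BASES:
            raise WildPanelError(f"{path}: isolate {name} contains non-ACGT symbols")
    return WildPanel(sequences=seqs)


def panel_consensus(panel: WildPanel, genome: GenomeAnnotation) -> str:
    """Per-column majority state; ties broken by the reference base."""
    if not panel.sequences:
        raise WildPanelError("panel has no sequences")
    seqs = list(panel.sequences.values())
    if len(seqs[0]) != genome.length:
        raise WildPanelError(
            f"panel length {len(seqs[0])} differs from genome {genome.length}"
        )
    out = []
    for i in range(genome.length):
        states = Counter(s[i] for s in seqs)
        top = max(states.values())
        winners = {b for b, c in states.items() if c == top}
        ref = genome.sequence[i]
        out.append(ref if ref in winners else sorted(winners)[0])
    return "".join(out)


def derive_wild_variation(
    panel: WildPanel, genome: GenomeAnnotation
) -> tuple[set[int], set[tuple[str, int]]]:
    """Variable nucleotide columns and variable amino-acid residues.

    A column is variable when >=2 distinct states occur among isolates.  A
    residue ``(gene, residue)`` is flagged when any observed non-consensus
    state at a covering column is non-silent in that gene, classified against
    the panel-consensus codon context.
    """
    if panel.variable_residues is not None and not panel.sequences:
        return set(), set(panel.variable_residues)
    if panel.n_isolates == 0:
        raise WildPanelError("panel has neither sequences nor a residue table")
    for name, s in panel.sequences.items():
        if len(s) != genome.length:
            raise WildPanelError(
                f"isolate {name}: length {len(s)} differs from genome {genome.length}"
            )
    consensus = panel_consensus(panel, genome)
    seqs = list(panel.sequences.values())
    variable_nt: set[int] = set()
    variable_res: set[tuple[str, int]] = set()
    for i in range(genome.length):
        states = {s[i] for s in seqs}
        if len(states) < 2:
            continue
        pos = i + 1
        variable_nt.add(pos)
        cons = consensus[i]
        for alt in sorted(states - {cons}):
            for change in changes_on_background(
                genome, pos, cons, alt, background=consensus
            ):
                if not change.silent:
                    variable_res.add((change.gene, change.residue))
    return variable_nt, variable_res


def expected_overlap(N: int, a: int, b: int) -> float:
    """Chance expectation for the intersection of two site sets: a*b/N.

    Equal to the mean of the hypergeometric distribution of ``|A ∩ B|`` when
    an a-set and a b-set are placed independently in an N-site universe.
    """
    if N <= 0:
        raise ValueError(f"universe size must be positive, got {N}")
    if not (0 <= a <= N and 0 <= b <= N):
        raise ValueError(f"set sizes ({a}, {b}) must lie in [0, {N}]")
    return a * b / N


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs expected intersection of experimental and wild residue sets.

    The hypergeometric ``p_value`` (P[X >= observed]) is an artifact extension;
    the underlying comparison is expectation vs observation.
    """

    N: int
    a: int
    b: int
    observed: int
    expected: float
    p_value: float

    @property
    def fraction_of_universe(self) -> float:
        return self.expected / self.N

    def summary(self) -> str:
        return (
            f"universe N={self.N}: |A|={self.a} ({self.a / self.N:.0%}), "
            f"|B|={self.b} ({self.b / self.N:.0%}); expected overlap "
            f"{self.expected:.1f} ({self.fraction_of_universe:.1%} of universe), "
            f"observed {self.observed} "
            f"[hypergeometric P(X>={self.observed}) = {self.p_value:.3g}; "
            f"test is an extension]"
        )


def overlap_test(N: int, a: int, b: int, observed: int) -> OverlapResult:
    """Exact hypergeometric upper-tail test for an observed set intersection."""
    expected = expected_overlap(N, a, b)
    if not 0 <= observed <= min(a, b):
        raise ValueError(
            f"observed overlap {observed} inconsistent with |A|={a}, |B|={b}"
        )
    # X ~ Hypergeom(M=N, n=a, N_draws=b); sf(k-1) = P(X >= k)
    p = float(sps.hypergeom.sf(observed - 1, N, a, b))
    return OverlapResult(N=N, a=a, b=b, observed=observed, expected=expected, p_value=p)


def residue_universe_size(genome: GenomeAnnotation) -> int:
    """Total amino-acid positions across annotated genes (overlaps counted per
    gene); directly overridable where a published universe size is in use."""
    return sum(genome.codon_count(g) for g in genome.genes)


@dataclass(frozen=True)
class SilentMissenseRatio:
    """Silent vs missense difference counts among wild isolates."""

    silent: int
    missense: int
    excluded_overlaps: bool
    n_dropped_masked: int = 0
    n_dropped_noncoding: int = 0

    @property
    def ratio(self) -> float:
        if self.missense == 0:
            raise WildPanelError("ratio undefined: no missense differences")
        return self.silent / self.missense


def silent_missense_ratio(
    panel: WildPanel,
    genome: GenomeAnnotation,
    exclude_overlaps: bool = True,
    mask: OverlapMask | None = None,
) -> SilentMissenseRatio:
    """Silent:missense ratio of pairwise-distinct wild differences.

    A difference is one (position, state) pair departing from the panel
    consensus.  Classification uses the single-gene codon context; positions
    inside out-of-frame overlaps are dropped when ``exclude_overlaps`` is true
    (in an overlap a change silent in one frame is usually missense in the
    other, so the two categories are not separable there).  Non-coding
    positions are never classifiable and are dropped with a count.
    """
    if panel.n_isolates < 2:
        raise WildPanelError("need at least two isolates to count differences")
    consensus = panel_consensus(panel, genome)
    if mask is None:
        mask = build_overlap_mask(genome)
    seqs = list(panel.sequences.values())
    silent = missense = dropped_masked = dropped_noncoding = 0
    for i in range(genome.length):
        states = {s[i] for s in seqs}
        if len(states) < 2:
            continue
        pos = i + 1
        cons = consensus[i]
        for alt in sorted(states - {cons}):
            if exclude_overlaps and pos in mask:
                dropped_masked += 1
                continue
            changes = changes_on_background(
                genome, pos, cons, alt, background=consensus
            )
            if not changes:
                dropped_noncoding += 1
                continue
            if any(not c.silent for c in changes):
                missense += 1
            else:
                silent += 1
    if silent + missense == 0:
        raise WildPanelError("no classifiable sites after exclusions")
    return SilentMissenseRatio(
        silent=silent,
        missense=missense,
        excluded_overlaps=exclude_overlaps,
        n_dropped_masked=dropped_masked,
        n_dropped_noncoding=dropped_noncoding,
    )
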