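"""Synthetic genomes, lineage substitution sets and wild panels.

Every statistic in this package can be exercised without downloading any real
data: this module generates circular genomes with overlapping reading frames,
per-lineage substitution tables whose placement follows the uniform null plus
a hotspot mixture, and wild-isolate panels with a silent-biased background and
a configurable share of hotspot residues made variable — the statistical
structure of the compiled phage experiments (~58 lineages, ~667 events on a
~5386-nt genome, a minority of strongly repeated sites, and natural variation
overlapping the laboratory hotspots).

Placement is multinomial over variable sites, not a population-genetic
simulation: the null model being tested is a placement model, and selection
dynamics are out of scope.  All outputs are deterministic given the config
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import GenomeAnnotation, GeneRecord, map_substitution
from .substitutions import LineageSet, SubstitutionRecord, _dedup
from .wild import WildPanel

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_lineages",
    "generate_wild_panel",
    "write_fixture_bundle",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults emulate the compiled experimental dataset: a 5386-nt circular
    genome carrying 11 genes with one out-of-frame nested pair and one
    origin-wrapping gene; 58 lineages contributing 667 substitution events;
    25% of sites invariant; 13 hotspot sites hit ~150x more often than
    background (so each collects events in roughly a quarter of lineages,
    matching the most strongly repeated sites in the compiled data); a
    30-isolate wild panel with silent differences 3.8x as intense as missense
    and 11 of the 13 hotspot residues variable in the wild.
    """

    genome_length: int = 5386
    n_genes: int = 11
    overlap: bool = True  # include an out-of-frame nested gene pair
    wrap_gene: bool = True  # one gene wraps the origin
    coding_fraction_target: float = 0.92

    n_lineages: int = 58
    total_events: int = 667  # placements before within-lineage deduplication
    invariant_fraction: float = 0.25
    n_hotspots: int = 13
    hotspot_weight: float = 150.0
    hotspot_missense: bool = True  # hotspot changes must be non-silent somewhere

    n_isolates: int = 30
    silent_missense_intensity: float = 3.8
    n_wild_differences: int = 1000
    wild_shared_fraction: float = 11 / 13
    carrier_probability: float = 0.25

    n_regulatory: int = 133
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 60 or self.n_genes < 1:
            raise ValueError("genome too small or no genes")
        if not 0 <= self.invariant_fraction < 1:
            raise ValueError("invariant_fraction must be in [0, 1)")
        if self.hotspot_weight < 1:
            raise ValueError("hotspot_weight must be >= 1")
        if self.silent_missense_intensity <= 0:
            raise ValueError("silent_missense_intensity must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data for recovery tests."""

    hotspot_alt: dict[int, str] = field(default_factory=dict)  # position -> alt
    hotspot_residues: set[tuple[str, int]] = field(default_factory=set)
    invariant_positions: frozenset[int] = frozenset()
    n_variable_sites: int = 0
    event_labels: list[str] = field(default_factory=list)  # per record
    wild_shared_positions: set[int] = field(default_factory=set)
    wild_shared_residues: set[tuple[str, int]] = field(default_factory=set)

    @property
    def hotspot_positions(self) -> set[int]:
        return set(self.hotspot_alt)


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _gene_layout(config: SyntheticConfig, rng: np.random.Generator) -> list[GeneRecord]:
    """Deterministic-ish layout: main genes head-to-tail around the circle,
    optionally one nested out-of-frame gene and one origin-wrapping gene."""
    G = config.genome_length
    n_main = max(1, config.n_genes - (1 if config.overlap else 0))
    budget = int(config.coding_fraction_target * G)
    span = max(30, (budget // n_main) // 3 * 3)
    spans = [span] * n_main
    total = sum(spans)
    while total > G - 3 * n_main:  # leave room for intergenic gaps
        i = spans.index(max(spans))
        if spans[i] <= 6:
            raise ValueError(
                f"gene layout infeasible: {n_main} genes do not fit on {G} nt"
            )
        spans[i] -= 3
        total -= 3
    gap_total = G - total
    gaps = [gap_total // n_main] * n_main
    gaps[-1] += gap_total - sum(gaps)

    names = [chr(ord("A") + i) for i in range(n_main)]
    genes: list[GeneRecord] = []
    start = G - spans[0] // 2 // 3 * 3 if config.wrap_gene else 1
    for name, sp, gap in zip(names, spans, gaps):
        end = (start + sp - 1 - 1) % G + 1
        genes.append(GeneRecord(name, start, end, essential=True))
        start = (end + gap) % G + 1

    if config.overlap:
        # nest a smaller gene in +1 frame inside the largest gene
        host = max(genes, key=lambda g: g.span(G))
        hspan = host.span(G)
        offset = 3 * max(1, hspan // 9)  # codon-aligned offset into the host
        avail = (hspan - offset - 1) // 3 * 3
        inner_span = min(max(6, hspan // 3 // 3 * 3), avail)
        if inner_span < 6:
            raise ValueError("gene layout infeasible: host too small to nest a gene")
        n_start = (host.start - 1 + offset + 1) % G + 1  # +1 frame shift
        n_end = (n_start - 1 + inner_span - 1) % G + 1
        genes.append(GeneRecord(names[-1] + "n", n_start, n_end, False))
    return genes


def _repair_stops(
    seq: list[str], genes: list[GeneRecord], G: int, rng: np.random.Generator
) -> bool:
    """Resample codons until no gene has an internal stop; True on success."""
    for _ in range(60):
        dirty = False
        for gene in genes:
            pos = gene.positions(G)
            for c in range(len(pos) // 3 - 1):  # terminal codon may be a stop
                p3 = pos[3 * c : 3 * c + 3]
                codon = "".join(seq[p - 1] for p in p3)
                if codon in STOP_CODONS:
                    repl = _SAFE_CODONS[rng.integers(len(_SAFE_CODONS))]
                    for p, b in zip(p3, repl):
                        seq[p - 1] = b
                    dirty = True
            # the final codon must not be a stop either: synthetic genes are
            # pure coding spans (see methods note)
            p3 = pos[-3:]
            if "".join(seq[p - 1] for p in p3) in STOP_CODONS:
                repl = _SAFE_CODONS[rng.integers(len(_SAFE_CODONS))]
                for p, b in zip(p3, repl):
                    seq[p - 1] = b
                dirty = True
        if not dirty:
            return True
    return False


def generate_genome(config: SyntheticConfig) -> GenomeAnnotation:
    """Generate a valid circular genome for the configured gene layout.

    The layout always passes the load-time validators (spans multiples of 3,
    no internal stops) and, under the defaults, contains at least one
    out-of-frame overlap and one origin-wrapping gene.  Raises ``RuntimeError``
    if no stop-free sequence is found after bounded retries.
    """
    rng = _rng(config, stage=0)
    genes = _gene_layout(config, rng)
    for _ in range(25):
        seq = list(rng.choice(list("ACGT"), size=config.genome_length))
        if _repair_stops(seq, genes, config.genome_length, rng):
            return GenomeAnnotation(sequence="".join(seq), genes=genes)
    raise RuntimeError("could not build a stop-free genome for this layout")


def _coding_positions(genome: GenomeAnnotation) -> set[int]:
    out: set[int] = set()
    for g in genome.genes:
        out.update(g.positions(genome.length))
    return out


def _pick_hotspots(
    genome: GenomeAnnotation,
    variable: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[int, str]:
    coding = _coding_positions(genome) & set(variable.tolist())
    candidates = sorted(coding)
    if len(candidates) < config.n_hotspots:
        raise ValueError("not enough variable coding sites for requested hotspots")
    hotspots: dict[int, str] = {}
    order = rng.permutation(len(candidates))
    for idx in order:
        if len(hotspots) == config.n_hotspots:
            break
        pos = candidates[idx]
        ref = genome.base_at(pos)
        alts = [b for b in "ACGT" if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            changes = map_substitution(genome, pos, ref, alt)
            if not config.hotspot_missense or any(not c.silent for c in changes):
                hotspots[pos] = alt
                break
    if len(hotspots) < config.n_hotspots:
        raise ValueError("could not place all hotspots as missense changes")
    return hotspots


def generate_lineages(
    genome: GenomeAnnotation,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[LineageSet, SyntheticTruth]:
    """Place substitution events across lineages under the hotspot mixture.

    A fixed invariant-site set of ``round(f*G)`` positions is excluded from
    placement; each of ``total_events`` placements falls on a variable site
    with probability proportional to its weight (1 for background,
    ``hotspot_weight`` for the ``n_hotspots`` planted sites, whose alternate
    base is fixed to exercise identical-change counting).  Within-lineage
    duplicate changes are deduplicated, exactly as on real input.
    """
    if rng is None:
        rng = _rng(config, stage=1)
    G = genome.length
    n_inv = int(round(config.invariant_fraction * G))
    invariant = rng.choice(np.arange(1, G + 1), size=n_inv, replace=False)
    inv_set = frozenset(int(p) for p in invariant)
    variable = np.array(sorted(set(range(1, G + 1)) - inv_set))

    truth = SyntheticTruth(
        invariant_positions=inv_set, n_variable_sites=len(variable)
    )
    if config.n_lineages == 0 or config.total_events == 0:
        return LineageSet(), truth

    if config.n_hotspots:
        truth.hotspot_alt = _pick_hotspots(genome, variable, config, rng)
        for pos, alt in truth.hotspot_alt.items():
            for ch in map_substitution(genome, pos, genome.base_at(pos), alt):
                if not ch.silent:
                    truth.hotspot_residues.add((ch.gene, ch.residue))

    weights = np.ones(len(variable))
    hot_idx = {
        int(np.searchsorted(variable, pos)): pos for pos in truth.hotspot_alt
    }
    for i in hot_idx:
        weights[i] = config.hotspot_weight
    probs = weights / weights.sum()

    per_lineage = rng.multinomial(
        config.total_events, np.full(config.n_lineages, 1 / config.n_lineages)
    )
    records: list[SubstitutionRecord] = []
    labels: list[str] = []
    hotspot_positions = truth.hotspot_positions
    for li, k in enumerate(per_lineage):
        name = f"lineage{li + 1:02d}"
        idx = rng.choice(len(variable), size=int(k), p=probs, replace=True)
        for i in idx:
            pos = int(variable[i])
            ref = genome.base_at(pos)
            if pos in hotspot_positions:
                alt = truth.hotspot_alt[pos]
            else:
                alts = [b for b in "ACGT" if b != ref]
                alt = alts[rng.integers(3)]
            records.append(SubstitutionRecord(name, pos, ref, alt))
            labels.append("hotspot" if pos in hotspot_positions else "background")

    deduped = _dedup(records)
    kept = set(id(r) for r in deduped)
    truth.event_labels = [
        lab for r, lab in zip(records, labels) if id(r) in kept
    ]
    return LineageSet(records=deduped), truth


def _difference_pools(
    genome: GenomeAnnotation, exclude: set[int]
) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """Candidate (position, alt) pairs outside out-of-frame overlaps and
    ``exclude``, split into silent and missense by single-gene context."""
    from .genome import build_overlap_mask

    mask = build_overlap_mask(genome)
    silent: list[tuple[int, str]] = []
    missense: list[tuple[int, str]] = []
    for pos in sorted(_coding_positions(genome)):
        if pos in mask.positions or pos in exclude:
            continue
        ref = genome.base_at(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            changes = map_substitution(genome, pos, ref, alt)
            if any(not c.silent for c in changes):
                missense.append((pos, alt))
            else:
                silent.append((pos, alt))
    return silent, missense


def generate_wild_panel(
    genome: GenomeAnnotation,
    config: SyntheticConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> WildPanel:
    """Wild-isolate panel: silent-biased background plus shared hotspots.

    Background differences are drawn from coding positions outside
    out-of-frame overlaps and outside hotspots, silent with probability
    ``r/(1+r)`` for intensity ratio r, emulating purifying selection in
    nature.  A configured fraction of planted hotspot residues is additionally
    made variable in the panel.  Each difference is a derived state carried by
    a minority of isolates, so the panel consensus stays at the ancestral
    (reference) state.
    """
    if rng is None:
        rng = _rng(config, stage=2)
    n = config.n_isolates
    seqs = {f"wild{i + 1:02d}": list(genome.sequence) for i in range(n)}
    panel_rows = list(seqs.values())
    if n >= 2:
        silent_pool, missense_pool = _difference_pools(
            genome, exclude=truth.hotspot_positions
        )
        rng.shuffle(silent_pool)
        rng.shuffle(missense_pool)
        r = config.silent_missense_intensity
        p_silent = r / (1.0 + r)
        used: set[int] = set()
        differences: list[tuple[int, str]] = []
        si = mi = 0
        for _ in range(config.n_wild_differences):
            pool, i = (
                (silent_pool, si) if rng.random() < p_silent else (missense_pool, mi)
            )
            while i < len(pool) and pool[i][0] in used:
                i += 1
            if i >= len(pool):
                continue  # pool exhausted; realised count falls short
            differences.append(pool[i])
            used.add(pool[i][0])
            if pool is silent_pool:
                si = i + 1
            else:
                mi = i + 1

        n_shared = int(round(config.wild_shared_fraction * len(truth.hotspot_alt)))
        shared = sorted(truth.hotspot_positions)
        rng.shuffle(shared)
        for pos in shared[:n_shared]:
            differences.append((pos, truth.hotspot_alt[pos]))
            truth.wild_shared_positions.add(pos)
            for ch in map_substitution(
                genome, pos, genome.base_at(pos), truth.hotspot_alt[pos]
            ):
                if not ch.silent:
                    truth.wild_shared_residues.add((ch.gene, ch.residue))

        max_carriers = max(1, (n - 1) // 2)
        for pos, alt in differences:
            m = 1 + rng.binomial(n - 2, config.carrier_probability)
            m = min(m, max_carriers)
            for ci in rng.choice(n, size=m, replace=False):
                panel_rows[int(ci)][pos - 1] = alt
    return WildPanel(sequences={k: "".join(v) for k, v in seqs.items()})


def write_fixture_bundle(
    out_dir: str | Path, config: SyntheticConfig | None = None
) -> dict[str, Path]:
    """Write a deterministic bundle of every input format the pipeline reads.

    Emits ``genome.fasta``, ``genes.tsv``, ``substitutions.tsv``,
    ``wild_panel.fasta``, ``regulatory.tsv`` and ``truth.tsv``; returns the
    path of each.  Intended for tests and for trying the command-line
    pipeline end to end.
    """
    config = config or SyntheticConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    lineages, truth = generate_lineages(genome, config)
    panel = generate_wild_panel(genome, config, truth)
    rng = _rng(config, stage=3)
    regulatory = sorted(
        int(p)
        for p in rng.choice(
            np.arange(1, genome.length + 1),
            size=min(config.n_regulatory, genome.length),
            replace=False,
        )
    )

    paths = {k: out / v for k, v in {
        "genome": "genome.fasta",
        "genes": "genes.tsv",
        "substitutions": "substitutions.tsv",
        "wild": "wild_panel.fasta",
        "regulatory": "regulatory.tsv",
        "truth": "truth.tsv",
    }.items()}
    paths["genome"].write_text(f">synthetic_genome\n{genome.sequence}\n")
    with open(paths["genes"], "w") as fh:
        fh.write("name\tstart\tend\tessential\n")
        for g in genome.genes:
            fh.write(f"{g.name}\t{g.start}\t{g.end}\t{str(g.essential).lower()}\n")
    lineages.write_tsv(paths["substitutions"])
    panel.write_fasta(paths["wild"])
    with open(paths["regulatory"], "w") as fh:
        fh.write("position\n")
        fh.writelines(f"{p}\n" for p in regulatory)
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tposition\talt\tgene\tresidue\n")
        for pos in sorted(truth.hotspot_alt):
            fh.write(f"hotspot\t{pos}\t{truth.hotspot_alt[pos]}\t\t\n")
        for gene, res in sorted(truth.hotspot_residues):
            fh.write(f"hotspot_residue\t\t\t{gene}\t{res}\n")
        for pos in sorted(truth.wild_shared_positions):
            fh.write(f"wild_shared\t{pos}\t\t\t\n")
    return paths
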