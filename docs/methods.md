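# Methods

## Problem setting

Experimental evolution of a small phage produces, across many independent
lineages, a compiled table of nucleotide substitutions on one reference
genome. Three questions are asked of such a table. How much repeated
evolution would uniform chance produce? Which residues are hit often
enough to call adaptive? And do those residues coincide with standing
variation among wild isolates? The genome is circular, genes overlap —
sometimes in different reading frames, sometimes as an in-frame internal
start — and one gene may wrap the origin, so every statistic has to be
built on a coordinate and codon model that handles all three.

## Genome model and codon mapping

Coordinates are 1-based inclusive on the forward strand, following
GenBank convention for these phages; a gene with `end < start` wraps the
origin and its coding span unwraps as `start..G, 1..end`. Validation at
load time enforces spans that are multiples of 3 and proteins free of
internal stop codons (a terminal stop is accepted). Only forward-strand,
single-segment genomes are supported.

A substitution at position *p* is mapped in **every** gene covering *p*:
the within-gene offset gives the codon index and phase, the codon is
mutated locally and both codons translated with NCBI table 11. Every
codon, including the initiator, is translated as written (a GTG start
reads as V, not a forced M): this makes the mapped change identical, by
construction and by property test, to the difference between translating
the whole reference gene and the whole mutated gene. Nonsense changes
are reported with `*` as the alternate amino acid and count as missense.

The *out-of-frame overlap mask* is the set of positions covered by two
or more genes whose codon phases differ there. An in-frame nested gene
(the A/A\*-style internal start) is deliberately *not* masked: a change
there has the same codon-level effect in both genes, and both genes
report the change under their own residue numbering.

## Counting conventions

Within one lineage, an identical change — same position, same alternate
state — is counted once; different alternate bases at one position are
different mutations and are both kept. Founder-carried changes (lineages
seeded from previously evolved isolates) can be subtracted before
tallying. Insertions and deletions are events for nucleotide-level and
regulatory tallies but never enter residue tallies.

Tallies exist in two modes: `site_level` pools every event at a site or
residue (reversions and alternate substitutions included), keyed by
position or `(gene, residue)`; `identical_change` pools only identical
events, keyed by `(position, alt)` or `(gene, residue, alt_aa)`. In both
modes the nucleotide counts sum to the number of retained substitution
events. Residue tallies count amino-acid substitutions only — silent
changes are excluded — so a single nucleotide event inside an
out-of-frame overlap can contribute a residue event to two genes while
remaining one nucleotide event.

## The null model

With `S` events placed independently and uniformly on `L = (1 − f)·G`
variable sites, the expected number of *n*-fold coincidences is

    E_n = C(S, n) / L^(n−1),

the expectation of `Σ_sites C(k_site, n)` — exact at every event density,
with `E₁ = S`. `f` (default 0.25) is the fraction of sites assumed
invariant under purifying selection; assuming more invariant sites is
conservative because it shrinks `L` and inflates the null expectation.

`E_n` is a coincidence count, not an occupancy count. The expected
number of sites with ≥ n events is slightly smaller (at `λ = S/L ≤ 0.2`
the two agree within ~15% for n = 2, 3, which the tests document with an
exact binomial occupancy oracle); a Poisson occupancy form
`L·(1 − e^{−λ} Σ_{k<n} λ^k/k!)` is provided for sensitivity analysis. At
the compiled scale the coincidence form gives 54.98 (n = 2) and 3.02
(n = 3) versus 49.4 and 2.7 for the occupancy form. Expected counts are
rounded to integers and fractions to whole percent only at the
presentation layer; raw values are always retained.

The null model is framed in nucleotide sites (`S` nucleotide events, `L`
from genome length). Residue-level thresholds operate on the residue
tally: by default, three or more amino-acid substitution events at one
residue across lineages are treated as strong evidence of adaptive
substitution, because the genome-wide chance expectation for three-fold
repetition is ~3 sites.

## Gene enrichment and the wild comparison

Each gene's share of protein-coding capacity is its codon count over the
total across annotated genes (overlap codons count for every covering
gene; terminal stops excluded). Under even placement a gene with share
*p* expects `p × total` of the amino-acid substitutions; a two-sided
binomial p-value is attached and labelled an extension, since the
underlying comparison is expectation versus observation.

Wild variation is derived from an aligned, ungapped isolate panel:
variable nucleotide columns are those with ≥ 2 states; a residue is
wild-variable when any non-consensus state at a covering column is
non-silent in that gene, classified against the panel-consensus codon
context (majority state, ties broken by the reference — the weakest
polarization assumption). The chance expectation for the overlap of an
*a*-set and a *b*-set of residues in an *N*-residue universe is `a·b/N`,
the hypergeometric mean; `P(X ≥ observed)` from the exact hypergeometric
distribution is attached, again labelled an extension. `N` defaults to
the annotation's total residue count (overlaps counted per gene) and can
be overridden where a published universe size must be matched.

The silent:missense ratio counts pairwise-distinct differences from the
panel consensus, classified in single-gene context. Positions inside
out-of-frame overlaps are excluded by default: there, a change silent in
one frame is generally missense in the other, so the two categories are
not separable. When overlaps are retained, a difference is missense if
it is non-silent in any covering gene.

## Synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes, so every stage is testable without downloads. Defaults are the
compiled-experiment conditions: a 5386-nt circular genome with 11 genes,
one out-of-frame nested pair and one origin-wrapping gene (~92% coding);
58 lineages contributing 667 event placements; invariant fraction 0.25;
13 hotspot sites; a 30-isolate wild panel.

*Genomes*: genes are laid head-to-tail with a nested +1-frame gene
inside the largest gene; random sequence is repaired by resampling any
codon that is a stop in any gene's frame until all frames are stop-free
(bounded retries). Synthetic genes are pure coding spans without
terminal stop codons — a nested gene's stop would be an internal stop in
its host's frame, and the validators accept real annotations either way.

*Lineage sets*: a fixed invariant set of `round(f·G)` positions is
excluded; each placement falls on a variable site with probability
proportional to its weight — 1 for background, `hotspot_weight` for
hotspots. Placement is multinomial, not a population-genetic simulation:
the null being calibrated is a placement model, and selection dynamics
are out of scope. Hotspots are constrained to coding sites, carry a
fixed alternate base (to exercise identical-change counting) and must be
missense in at least one gene. The default weight of 150 gives each
hotspot events in roughly a quarter of lineages (~15 events), the
regime of the most strongly repeated sites in compiled experiments,
where the top ~13 residues carry about a quarter of all amino-acid
substitutions. Within-lineage duplicates are deduplicated exactly as on
real input; with uniform weights the loss is a fraction of an event per
replicate, so coincidence calibration against `E_n` is unaffected.

*Wild panels*: 1000 background differences (about a fifth of sites, the
divergence scale of wild microvirid panels) are drawn from coding
positions outside overlaps and hotspots, silent with probability
`r/(1+r)` for intensity ratio `r` (default 3.8), at most one difference
per position; a configured fraction (default 11/13) of hotspot residues
is additionally made variable. Each difference is a derived state
carried by a minority of isolates (1 + Binomial(n−2, 0.25), capped below
half the panel), so the consensus stays at the ancestral reference state
and generator labels agree with estimator classification. Shared
hotspot differences sit outside the background ratio, biasing the
estimated ratio downward by a few percent at default settings.

Everything is deterministic given the config seed; stage-specific
streams are derived from it, so the genome, lineages and panel can be
regenerated independently.

What the generator does **not** emulate: linkage and shared history
among lineages (events are exchangeable placements), mutational spectrum
bias, selection dynamics (sweeps, clonal interference, epistasis),
recombination, and alignment uncertainty in wild panels. Passing
recovery tests therefore demonstrates the statistics, not the biology:
on real data the null remains a placement null, and founder subtraction
is the only correction for shared history.

## Problem sizes used in validation

Statistical validation runs at the compiled-experiment scale: 200
replicates for null calibration (mean three-fold coincidence count
versus `E₃` within 3 standard errors), 100 replicates for hotspot
recovery (≥ 12 of 13 planted hotspots at ≥ 8 events in ≥ 90% of
replicates), 10⁴ Monte-Carlo placements at S = 50, L = 200 for the
coincidence formula, exhaustive enumeration for universes N ≤ 12, and
1000 random substitutions on random overlapping genomes for the
re-translation property.

## Numerical and design choices

- `E_n` returns 0 for `n > S`; `effective_sites` is real-valued
  (4039.5 at the default scale), never rounded internally.
- Adaptive-site reports sort by count descending, then genome order;
  ties in consensus calls break toward the reference base.
- The hypergeometric test, binomial enrichment p-values and all rounding
  are presentation-layer; raw values are retained in every result object.
- The residue universe for overlap expectations counts A/A\*-style
  shared residues once per gene; because published universes may count
  differently, `N` is directly settable.
- TSV is the canonical interchange format (`lineage position ref alt
  kind`); VCF input treats each sample column as a lineage and any
  non-reference genotype call as one event.
- The library is the primary interface; the `paraphage` CLI is a thin
  wrapper for file-in/report-out use, with exit codes 0 (success), 2
  (input error) and 3 (invariant violation).

## Known limitations

- No reverse-strand genes, introns, gaps in panels, or multi-segment
  genomes.
- No phylogenetic correction beyond founder subtraction; lineages are
  treated as independent.
- The silent:missense ratio is a summary statistic, not a codon-model
  dN/dS; no selection coefficients are estimated.
- Indels are counted as events only at nucleotide and regulatory level;
  their coding consequences are not modelled.
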