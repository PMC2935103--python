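"""End-to-end analysis pipeline: files in, report bundle out.

Orchestrates the full analysis — load genome, read and deduplicate lineage
substitutions, tally at both counting levels, compare repeated evolution with
the uniform-placement null, call putatively adaptive residues, compute
per-gene enrichment, and (when a wild panel is supplied) quantify overlap
with natural variation and the silent:missense ratio.  Every number in the
human-readable summary is also written to a machine-readable TSV in the
bundle.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome import build_overlap_mask, load_genome
from .plotting import plot_adaptive_sites
from .stats import (
    NullModelParams,
    classify_adaptive_sites,
    gene_enrichment,
    null_table,
    observed_coincidences,
    sites_with_at_least,
)
from .substitutions import (
    CountingMode,
    read_substitutions,
    subtract_founder,
    tally_regulatory,
    tally_sites,
    write_tally,
)
from .wild import (
    derive_wild_variation,
    overlap_test,
    read_panel_fasta,
    residue_universe_size,
    silent_missense_ratio,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    genome: str
    annotation: str
    substitutions: str
    out_dir: str
    substitution_format: str = "tsv"
    wild_panel: str | None = None
    regulatory: str | None = None
    founder: str | None = None  # TSV: lineage position alt

    invariant_fraction: float = 0.25
    threshold: int = 3
    mode: str = "site_level"
    n_max: int = 8
    residue_universe: int | None = None  # override N (e.g. a published 1986)
    exclude_overlaps: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _read_founder(path: str) -> dict[str, set[tuple[int, str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[tuple[int, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.lineage), set()).add(
            (int(row.position), str(row.alt).upper())
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dictionary of the headline numbers.  On failure, partial
    outputs are removed and :class:`PipelineError` names the failing stage.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("setup", exc) from exc


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


def _run(config: PipelineConfig, out: Path) -> dict:
    summary_lines: list[str] = []
    result: dict = {}

    genome = _stage("load_genome")(load_genome)(config.genome, config.annotation)
    mask = build_overlap_mask(genome)
    summary_lines.append(
        f"genome: {genome.length} nt, {len(genome.genes)} genes, "
        f"{len(mask)} positions in out-of-frame overlaps"
    )

    @_stage("read_substitutions")
    def _load():
        ls = read_substitutions(
            config.substitutions, format=config.substitution_format, genome=genome
        )
        if config.founder:
            ls.founder_genotypes = _read_founder(config.founder)
            ls = subtract_founder(ls)
        return ls

    lineages = _load()
    summary_lines.append(
        f"substitution data: {lineages.n_events} events "
        f"({len(lineages.substitutions())} substitutions) in "
        f"{len(lineages.lineages)} lineages"
    )

    @_stage("tally")
    def _tally():
        tally = tally_sites(lineages, genome, CountingMode(config.mode))
        write_tally(tally, genome, out / "residue_tally.tsv")
        pos_counts = tally.position_counts()
        pd.DataFrame(
            sorted(pos_counts.items()), columns=["position", "count"]
        ).to_csv(out / "nucleotide_tally.tsv", sep="\t", index=False)
        return tally

    tally = _tally()
    n_events = tally.total_events
    summary_lines.append(
        f"tally ({tally.mode.value}): {n_events} nucleotide events at "
        f"{len(tally.position_counts())} sites; "
        f"{tally.total_aa_substitutions} amino-acid substitutions at "
        f"{len(tally.residue_site_counts())} residues"
    )

    @_stage("null_model")
    def _null():
        params = NullModelParams(
            S=n_events, G=genome.length, f=config.invariant_fraction
        )
        table = null_table(params, config.n_max)
        df = table.to_frame()
        pos_counts = tally.position_counts()
        df["observed_coincidences"] = [
            observed_coincidences(pos_counts, n) for n in df["n"]
        ]
        df["observed_sites_ge_n"] = [
            sites_with_at_least(pos_counts, n) for n in df["n"]
        ]
        df.to_csv(out / "null_model.tsv", sep="\t", index=False)
        return params, df

    params, null_df = _null()
    row2 = null_df[null_df["n"] == 2].iloc[0] if (null_df["n"] == 2).any() else None
    if row2 is not None:
        summary_lines.append(
            f"null model (S={params.S}, L={params.L:.1f}): expect "
            f"{row2['expected']:.1f} two-fold coincidences "
            f"({row2['fraction_of_events']:.0%} of events) by chance; "
            f"observed {int(row2['observed_coincidences'])} at "
            f"{int(row2['observed_sites_ge_n'])} multiply-hit sites"
        )
    result["null_model"] = null_df

    wild_nt = wild_res = None
    panel = None
    if config.wild_panel:
        @_stage("wild_panel")
        def _wild():
            p = read_panel_fasta(config.wild_panel)
            return p, *derive_wild_variation(p, genome)

        panel, wild_nt, wild_res = _wild()
        summary_lines.append(
            f"wild panel: {panel.n_isolates} isolates, "
            f"{len(wild_nt)} variable nucleotide columns, "
            f"{len(wild_res)} variable residues"
        )

    @_stage("adaptive_sites")
    def _adaptive():
        report = classify_adaptive_sites(
            tally, config.threshold, wild=wild_res, genome=genome
        )
        report.to_frame().to_csv(out / "adaptive_sites.tsv", sep="\t", index=False)
        plot_adaptive_sites(report, out / "adaptive_sites.svg")
        return report

    report = _adaptive()
    wild_note = (
        f"; {report.n_wild_variable} also vary in the wild"
        if report.n_wild_variable is not None
        else ""
    )
    summary_lines.append(
        f"adaptive sites (>= {report.threshold} events): {len(report.sites)} "
        f"residues covering {report.substitutions_covered} "
        f"({report.fraction_covered:.0%}) of amino-acid substitutions{wild_note}"
    )
    result["adaptive"] = report

    @_stage("gene_enrichment")
    def _enrich():
        enr = gene_enrichment(tally, genome)
        df = enr.to_frame()
        df.to_csv(out / "gene_enrichment.tsv", sep="\t", index=False)
        return enr

    enr = _enrich()
    top = enr.to_frame().sort_values("observed", ascending=False).iloc[0]
    summary_lines.append(
        f"gene enrichment: most-hit gene {top['gene']} with {top['observed']} "
        f"observed vs {top['expected']:.0f} expected "
        "(binomial p-values in gene_enrichment.tsv are an extension)"
    )
    result["enrichment"] = enr

    if config.regulatory:
        @_stage("regulatory")
        def _reg():
            reg = pd.read_csv(config.regulatory, sep="\t")
            positions = set(int(p) for p in reg.iloc[:, 0])
            events, hit = tally_regulatory(lineages, positions)
            pd.DataFrame(
                [(len(positions), events, hit, hit / len(positions))],
                columns=["listed_positions", "events", "positions_hit", "fraction_hit"],
            ).to_csv(out / "regulatory.tsv", sep="\t", index=False)
            return len(positions), events, hit

        n_listed, ev, hit = _reg()
        summary_lines.append(
            f"regulatory positions: {ev} events at {hit} of {n_listed} listed "
            f"positions ({hit / n_listed:.1%})"
        )

    if panel is not None:
        @_stage("wild_overlap")
        def _overlap():
            N = config.residue_universe or residue_universe_size(genome)
            exp_res = set(tally.residue_site_counts())
            a, b = len(exp_res), len(wild_res)
            observed = len(exp_res & wild_res)
            res = overlap_test(N, a, b, observed)
            pd.DataFrame(
                [(N, a, b, res.expected, observed, res.p_value)],
                columns=["N", "experimental", "wild", "expected", "observed", "p_value"],
            ).to_csv(out / "wild_overlap.tsv", sep="\t", index=False)
            return res

        res = _overlap()
        summary_lines.append("wild overlap: " + res.summary())
        result["overlap"] = res

        @_stage("silent_missense")
        def _ratio():
            smr = silent_missense_ratio(
                panel, genome, exclude_overlaps=config.exclude_overlaps, mask=mask
            )
            pd.DataFrame(
                [
                    (
                        smr.silent,
                        smr.missense,
                        smr.ratio,
                        smr.excluded_overlaps,
                        smr.n_dropped_masked,
                        smr.n_dropped_noncoding,
                    )
                ],
                columns=[
                    "silent",
                    "missense",
                    "ratio",
                    "excluded_overlaps",
                    "dropped_overlap_positions",
                    "dropped_noncoding",
                ],
            ).to_csv(out / "silent_missense.tsv", sep="\t", index=False)
            return smr

        smr = _ratio()
        summary_lines.append(
            f"wild silent:missense ratio "
            f"({'excluding' if smr.excluded_overlaps else 'including'} "
            f"out-of-frame overlaps): {smr.silent}:{smr.missense} = "
            f"{smr.ratio:.2f}"
        )
        result["silent_missense"] = smr
    else:
        summary_lines.append("wild overlap: not computed (no wild panel supplied)")
        summary_lines.append("silent:missense ratio: not computed (no wild panel)")

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "paraphage_version": __version__,
                "seed": config.seed,
                "parameters": {
                    "invariant_fraction": config.invariant_fraction,
                    "threshold": config.threshold,
                    "mode": config.mode,
                    "residue_universe": config.residue_universe,
                    "exclude_overlaps": config.exclude_overlaps,
                },
                "inputs": {
                    "genome": str(config.genome),
                    "annotation": str(config.annotation),
                    "substitutions": str(config.substitutions),
                    "wild_panel": config.wild_panel,
                    "regulatory": config.regulatory,
                },
            },
            indent=2,
        )
        + "\n"
    )
    result["summary"] = summary_lines
    return result
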