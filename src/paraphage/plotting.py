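"""Bar chart of repeatedly hit residues, wild-variable sites distinguished."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import AdaptiveSiteReport


def plot_adaptive_sites(
    report: AdaptiveSiteReport, path: str | Path, title: str | None = None
) -> None:
    """Histogram of per-residue substitution counts for qualifying residues.

    Residues that also vary among wild isolates are drawn in grey, residues
    invariant in the wild in black (unknown wild status hatched).
    """
    sites = report.sites
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(sites) + 2), 4))
    labels = [f"{g}{r}" for g, r, *_ in sites]
    counts = [c for *_, c, _w in sites]
    colors, hatches = [], []
    for *_, w in sites:
        colors.append("0.6" if w else "black")
        hatches.append("//" if w is None else "")
    bars = ax.bar(range(len(sites)), counts, color=colors)
    for bar, h in zip(bars, hatches):
        bar.set_hatch(h)
    ax.set_xticks(range(len(sites)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("amino acid substitutions")
    ax.set_xlabel("residue")
    ax.set_title(
        title
        or f"residues with >= {report.threshold} substitutions across lineages"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
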