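"""Figure and report rendering for pipeline runs.

Produces the four standard figures of a marker-development run: the
per-chromosome INDEL distribution (sliding-window counts), the INDEL size
histogram, the cultivar UPGMA dendrogram, and the mapping diagram with
recombinant counts per marker.  Every number plotted is read back from the
stage output tables, so the figures carry no hidden state.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from indelmark.filtering import FilterSummary


def plot_window_counts(window_counts: pd.DataFrame, path: str | Path) -> None:
    """Per-chromosome sliding-window INDEL counts, one panel per chromosome."""
    chroms = list(window_counts["chrom"].unique()) if len(window_counts) else []
    n = max(len(chroms), 1)
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.6 * n), squeeze=False, sharex=True)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = window_counts[window_counts["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2 / 1e6
        ax.fill_between(mid, sub["count"], step="mid", alpha=0.6)
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
    if not chroms:
        axes[0, 0].text(0.5, 0.5, "no retained INDELs", ha="center")
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle("Retained INDELs per sliding window")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_size_histogram(size_histogram: dict[int, int], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    if size_histogram:
        ax.bar(list(size_histogram.keys()), list(size_histogram.values()), width=0.9)
    else:
        ax.text(0.5, 0.5, "no retained INDELs", ha="center")
    ax.set_xlabel("INDEL length (bp)")
    ax.set_ylabel("count")
    ax.set_title("Size distribution of retained INDELs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(diversity_results, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    diversity_results.plot_dendrogram(ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mapping(linkage_results, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3.2))
    linkage_results.plot(ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_text_report(
    out_dir: str | Path,
    filter_summary: FilterSummary | None = None,
    diversity_results=None,
    linkage_results=None,
) -> str:
    """Aggregate stage summaries into one human-readable report string."""
    sections = ["indelmark pipeline report", "=" * 25, ""]
    if filter_summary is not None:
        s = filter_summary
        sections += [
            "Variant filtering",
            "-----------------",
            s.as_series().to_string(),
            f"density per Mb (anchored): {s.density_per_mb:.1f}" if s.density_per_mb is not None else "",
            f"pericentromeric retained: {s.pericentromeric}" if s.pericentromeric is not None else "",
            "",
        ]
    else:
        sections += ["Variant filtering", "-----------------", "stage not run (0 records)", ""]
    if diversity_results is not None:
        sections += [diversity_results.summary(), ""]
    else:
        sections += ["Panel diversity", "---------------", "stage not run (0 records)", ""]
    if linkage_results is not None:
        sections += [linkage_results.summary(), ""]
    else:
        sections += ["F2 mapping", "----------", "stage not run (0 records)", ""]
    text = "\n".join(sections)
    Path(out_dir, "report.txt").write_text(text)
    return text
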