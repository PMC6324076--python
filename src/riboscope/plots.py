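"""Static renderings of the analysis objects (matplotlib, file output only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metagene import MetageneProfile
from .profiles import ComparisonProfile, TranscriptProfile
from .reference import Reference

FRAME_COLORS = ("#d62728", "#2ca02c", "#1f77b4")  # red, green, blue


def plot_transcript(
    profile: TranscriptProfile, reference: Reference, path: str | Path
) -> None:
    """Frame-coloured density plot over three ORF-architecture bars.

    Start codons are drawn as short white ticks and stop codons as longer
    grey ticks on each frame's bar.
    """
    rec = reference[profile.transcript_id]
    x = np.arange(1, rec.length + 1)
    fig, (ax, ax_orf) = plt.subplots(
        2, 1, figsize=(10, 4.5), sharex=True,
        gridspec_kw={"height_ratios": [4, 1]},
    )
    for f in range(3):
        ax.plot(x, profile.frame_series[f], color=FRAME_COLORS[f], lw=0.8,
                label=f"frame {f}")
    ax.set_ylabel("A-site count")
    ax.set_title(f"{profile.transcript_id} ({rec.gene_name})")
    ax.legend(loc="upper right", fontsize=8)

    arch = profile.architecture
    for f in range(3):
        y0 = 2 - f
        ax_orf.broken_barh([(1, rec.length)], (y0, 0.8), color=FRAME_COLORS[f],
                           alpha=0.6)
        for p in arch.starts[f]:
            ax_orf.vlines(p, y0 + 0.25, y0 + 0.55, color="white", lw=1.0)
        for p in arch.stops[f]:
            ax_orf.vlines(p, y0 + 0.05, y0 + 0.75, color="#555555", lw=1.2)
    ax_orf.set_ylim(0, 3)
    ax_orf.set_yticks([])
    ax_orf.set_xlabel("transcript position (nt)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_comparison(cmp: ComparisonProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(10, 3.5))
    for grp in cmp.groups:
        x = np.arange(1, grp.vector.shape[0] + 1)
        ax.plot(x, grp.vector, lw=0.8, color=grp.color or None,
                label=f"{grp.label} ({grp.sequence_type})")
    unit = "reads per million" if cmp.groups[0].normalized else "reads"
    ax.set_ylabel(unit)
    ax.set_xlabel("transcript position (nt)")
    ax.set_title(cmp.transcript_id)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_readlength_distribution(dist: dict[int, int], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(list(dist), list(dist.values()), color="#1f77b4")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_periodicity(table: pd.DataFrame, path: str | Path) -> None:
    """Three bars per read length, one per phase relative to the CDS frame."""
    fig, ax = plt.subplots(figsize=(8, 3.5))
    width = 0.28
    lengths = table.index.to_numpy()
    for phase, col in enumerate(["f0", "f1", "f2"]):
        ax.bar(lengths + (phase - 1) * width, table[col], width=width,
               color=FRAME_COLORS[phase], label=f"phase {phase}")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("CDS-mapped reads")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metagene(
    mg5: MetageneProfile, mg3: MetageneProfile, path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(8, 3.5))
    w = mg5.window
    rel = np.arange(-w, w + 1)
    ax.plot(rel, mg5.combined(), color="#d62728", lw=1.0, label="5' ends")
    ax.plot(rel, mg3.combined(), color="#1f77b4", lw=1.0, label="3' ends")
    ax.axvline(0, color="k", lw=0.6, ls=":")
    ax.set_xlabel(f"position relative to {mg5.anchor} (nt)")
    ax.set_ylabel("reads")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_differential(
    table: pd.DataFrame, z_threshold: float, path: str | Path
) -> None:
    """MA-style plot: log ratio vs geometric mean, calls coloured, yellow
    per-bin threshold curves."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = table["call"].map({"up": "#2ca02c", "down": "#d62728", "ns": "#999999"})
    ax.scatter(np.log10(table["geometric_mean"]), table["log_ratio"], s=6,
               c=colors, alpha=0.7, linewidths=0)
    for sign in (+1, -1):
        curve = []
        for _, grp in table.groupby("bin_index"):
            mu, sd = grp["log_ratio"].mean(), grp["log_ratio"].std(ddof=1)
            gm = np.log10(grp["geometric_mean"].median())
            curve.append((gm, mu + sign * z_threshold * (0 if np.isnan(sd) else sd)))
        curve.sort()
        ax.plot(*zip(*curve), color="#ffcc00", lw=1.5)
    ax.set_xlabel("log10 geometric mean")
    ax.set_ylabel("log2 fold change (B / A)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
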