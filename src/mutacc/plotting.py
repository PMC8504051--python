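"""Figures for the two standard views: per-set score boxplots and the
gene x sample pathogenicity class matrix. Numbers are always emitted as TSV
by the pipeline first; these renderings are optional conveniences."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pathogenicity import classify_score

__all__ = ["gene_set_boxplot", "pathogenicity_matrix_plot"]

_CLASS_COLORS = {
    "benign": "#2ca02c",        # green: s < 0
    "VUS": "#ffffff",           # white: s = 0
    "pathogenic_low": "#ff9633",   # orange: 0 < s < 10
    "pathogenic_mid": "#d62728",   # red: 10 <= s <= 20
    "pathogenic_high": "#7f7f7f",  # gray: s > 20
    "absent": "#e8e8e8",
}


def gene_set_boxplot(per_gene: pd.DataFrame):
    """Side-by-side boxplots of member-gene scores per set and cohort."""
    sets = sorted(per_gene["set"].unique())
    cohorts = sorted(per_gene["cohort"].unique())
    fig, ax = plt.subplots(figsize=(max(6, 1.6 * len(sets)), 4.5))
    width = 0.8 / max(len(cohorts), 1)
    for ci, cohort in enumerate(cohorts):
        data, positions = [], []
        for si, set_name in enumerate(sets):
            mask = (per_gene["set"] == set_name) & (per_gene["cohort"] == cohort)
            data.append(per_gene.loc[mask, "score"].to_numpy())
            positions.append(si + ci * width)
        bp = ax.boxplot(data, positions=positions, widths=width * 0.9,
                        patch_artist=True)
        color = plt.get_cmap("tab10")(ci)
        for box in bp["boxes"]:
            box.set_facecolor(color)
            box.set_alpha(0.6)
        ax.plot([], [], color=color, label=str(cohort))
    ax.set_xticks(np.arange(len(sets)) + width * (len(cohorts) - 1) / 2)
    ax.set_xticklabels(sets, rotation=30, ha="right")
    ax.set_ylabel("accumulation score")
    ax.legend(title="cohort")
    fig.tight_layout()
    return fig


def pathogenicity_matrix_plot(matrix: pd.DataFrame):
    """Class-colored gene x sample grid of pathogenicity scores."""
    genes = list(matrix.index)
    samples = list(matrix.columns)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * len(samples) + 2), max(3, 0.35 * len(genes) + 1))
    )
    for gi, gene in enumerate(genes):
        for si, sample in enumerate(samples):
            s = matrix.iloc[gi, si]
            klass = "absent" if pd.isna(s) else classify_score(float(s))
            ax.add_patch(
                plt.Rectangle((si, len(genes) - gi - 1), 1, 1,
                              facecolor=_CLASS_COLORS[klass],
                              edgecolor="black", linewidth=0.4)
            )
    ax.set_xlim(0, len(samples))
    ax.set_ylim(0, len(genes))
    ax.set_xticks(np.arange(len(samples)) + 0.5)
    ax.set_xticklabels(samples, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(genes)) + 0.5)
    ax.set_yticklabels(reversed(genes), fontsize=7)
    ax.set_aspect("equal")
    fig.tight_layout()
    return fig
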