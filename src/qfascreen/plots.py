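"""Static fitness plots and multi-screen profile plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .growth import ScreenFitnessTable  # noqa: E402
from .profiles import ProfileMatrix  # noqa: E402

HIGHLIGHT_CYCLE = ["tab:red", "tab:blue", "tab:green", "tab:orange",
                   "tab:purple", "tab:brown", "tab:pink", "tab:cyan"]


def read_highlight_sets(path) -> dict[str, list[str]]:
    """Plain-text highlight list: two tab-separated columns, orf and group."""
    groups: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["orf", "group"],
                     comment="#", dtype=str)
    for rec in df.itertuples(index=False):
        groups.setdefault(rec.group, []).append(rec.orf)
    return groups


def fitness_plot(control: ScreenFitnessTable, query: ScreenFitnessTable,
                 m: float, path, highlights: dict[str, list[str]] | None = None,
                 title: str | None = None) -> None:
    """Control-vs-query fitness scatter with the two reference lines.

    Dashed gray: equal fitness in both backgrounds (y = x).  Solid gray:
    predicted fitness under genetic independence (y = m x).  Highlight sets
    (named gene groups) are drawn in color over the gray library cloud.
    """
    x = control.mean_by_orf
    y = query.mean_by_orf
    shared = x.index.intersection(y.index)
    x, y = x.loc[shared], y.loc[shared]

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(x, y, s=8, c="0.6", alpha=0.5, linewidths=0, label=None)
    lim = max(float(x.max()), float(y.max())) * 1.05 if len(x) else 1.0
    grid = np.array([0.0, lim])
    ax.plot(grid, grid, "--", color="0.4", lw=1, label="equal fitness")
    ax.plot(grid, m * grid, "-", color="0.4", lw=1.2,
            label=f"independence (m = {m:.3g})")
    for i, (group, orfs) in enumerate(sorted((highlights or {}).items())):
        sel = [o for o in orfs if o in shared]
        if sel:
            ax.scatter(x.loc[sel], y.loc[sel], s=22,
                       c=HIGHLIGHT_CYCLE[i % len(HIGHLIGHT_CYCLE)],
                       label=group, zorder=3)
    ax.set_xlabel(f"fitness, {control.screen_id} (doublings$^2$/day)")
    ax.set_ylabel(f"fitness, {query.screen_id} (doublings$^2$/day)")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, max(lim, m * lim))
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def profile_plot(matrix: ProfileMatrix, orfs: list[str], path,
                 title: str | None = None) -> None:
    """Per-gene line profiles across screen conditions."""
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(matrix.screens)), 4))
    positions = np.arange(len(matrix.screens))
    for i, orf in enumerate(orfs):
        if orf not in matrix.values.index:
            continue
        vals = matrix.values.loc[orf].to_numpy(float)
        label = matrix.gene_names.get(orf, orf)
        ax.plot(positions, vals, "-o", ms=4,
                color=HIGHLIGHT_CYCLE[i % len(HIGHLIGHT_CYCLE)], label=label)
    ax.set_xticks(positions)
    ax.set_xticklabels(matrix.screens, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel(matrix.value_kind)
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
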