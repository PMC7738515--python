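"""Optional figure output (density/rug plots, antigen-map heatmap, volcano)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .antigen_map import AntigenMapMatrix
from .corrstats import GroupSummary, kde


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_correlation_densities(groups: dict[str, GroupSummary], path: str | Path) -> Path:
    """Kernel density curves with rug marks, one per comparison group."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for i, (name, g) in enumerate(groups.items()):
        if g.n < 2:
            continue
        dens = kde(g.values)
        ax.plot(dens.grid, dens.density, label=f"{name} (median {g.median:.2f})")
        ax.plot(g.values, np.full(g.n, -0.02 * (i + 1)), "|", ms=4, alpha=0.4)
        ax.axvline(g.median, ls="--", lw=0.8, color=f"C{i}")
    ax.set_xlabel("Spearman rank correlation coefficient")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_antigen_map(amap: AntigenMapMatrix, path: str | Path) -> Path:
    """Heatmap of the clustered antibody antigen map (index shades per antibody)."""
    plt = _pyplot()
    M = amap.frame.to_numpy(dtype=float)
    M[M == 0] = np.nan
    fig, ax = plt.subplots(figsize=(max(4, M.shape[1] * 0.12), max(3, M.shape[0] * 0.18)))
    ax.imshow(M, aspect="auto", cmap="Purples", interpolation="nearest")
    ax.set_yticks(range(M.shape[0]), amap.frame.index, fontsize=5)
    ax.set_xticks([])
    ax.set_xlabel("clustered antibody columns")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_volcano(table, cut: float, path: str | Path) -> Path:
    """Mean difference vs |t_mod| with the FDR cut-off marked."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    sig = table["significant"]
    ax.scatter(table.loc[~sig, "mean_difference"], table.loc[~sig, "abs_t"], s=8, c="grey")
    ax.scatter(table.loc[sig, "mean_difference"], table.loc[sig, "abs_t"], s=10, c="crimson")
    if np.isfinite(cut):
        ax.axhline(cut, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("mean log2 difference (treated - control)")
    ax.set_ylabel("|moderated t|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
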