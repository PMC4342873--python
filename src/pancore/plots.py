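"""Publication figures: presence/absence QC heatmap and core-size curve."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap
from matplotlib.patches import Patch

from .matrix import GenomeContentMatrix, heatmap_table
from .rarefaction import RarefactionResult

__all__ = ["plot_heatmap", "plot_curve"]

# red = gene present, blue = gene absent
_PRESENT = "#b2182b"
_ABSENT = "#2166ac"
_CMAP = ListedColormap([_ABSENT, _PRESENT])


def plot_heatmap(
    matrix: GenomeContentMatrix,
    path: Union[str, Path],
    order: str = "by_prevalence",
) -> None:
    """Render the genome-quality heatmap (clusters x genomes).

    Present genes are red, absent blue; with prevalence ordering the core
    genome appears as a solid red band, and poor-quality genomes stand out
    as blue streaks inside it.
    """
    table = heatmap_table(matrix, order=order)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * matrix.n_genomes + 2), 6.0)
    )
    ax.imshow(table.to_numpy(), aspect="auto", cmap=_CMAP, vmin=0, vmax=1,
              interpolation="nearest")
    ax.set_xlabel("genome")
    ax.set_ylabel("ortholog cluster")
    if matrix.n_genomes <= 40:
        ax.set_xticks(range(matrix.n_genomes))
        ax.set_xticklabels(table.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.legend(
        handles=[Patch(color=_PRESENT, label="present"),
                 Patch(color=_ABSENT, label="absent")],
        loc="upper right", frameon=True, fontsize=8,
    )
    ax.set_title("Gene presence/absence")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_curve(result: RarefactionResult, path: Union[str, Path]) -> None:
    """Plot mean core-genome size against the number of genomes sampled."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ks = list(result.subset_sizes)
    ax.plot(ks, result.means, "o-", color="#b2182b", markersize=3, lw=1.2)
    ax.fill_between(
        ks, result.means - result.sds, result.means + result.sds,
        alpha=0.2, color="#b2182b", linewidth=0,
    )
    ax.set_xlabel("genomes sampled (k)")
    ax.set_ylabel("mean core-genome size")
    ax.set_title(f"Core-genome rarefaction ({result.plan.iterations} iterations)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
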