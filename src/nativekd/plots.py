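"""Titration plots (headless-safe; CSV outputs remain the contract)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402


def plot_abundance_vs_concentration(results, ax=None):
    """Mean total ion abundance (error bars: replicate SD) of the free and
    ligand-bound protein versus ligand concentration, per ligand."""
    stats = results.abundance_stats()
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4))
    markers = {"free": "o", "bound": "s"}
    for (ligand, species), grp in stats.groupby(["ligand", "species"]):
        grp = grp.sort_values("L0")
        label = f"{'free protein' if species == 'free' else 'bound (' + ligand + ')'}"
        ax.errorbar(
            grp["L0"] * 1e6,
            grp["mean"],
            yerr=grp["sd"],
            marker=markers[species],
            capsize=3,
            label=label,
        )
    ax.set_xlabel("ligand concentration (µM)")
    ax.set_ylabel("total ion abundance (counts)")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax
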