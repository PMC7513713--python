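"""Observed-vs-expected figures for the randomization tests.

One panel per marker set: the expected statistic under random mating (dot)
with its 95% percentile band (thick line) and the simulated minimum/maximum
beyond the band (thin gray line), with the observed statistic overplotted as
a triangle, one column per enclosure-year plus the pooled estimate.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_observed_vs_expected"]


def plot_observed_vs_expected(table: pd.DataFrame, path: str | Path) -> None:
    panels = sorted(table["panel_id"].unique())
    fig, axes = plt.subplots(1, len(panels), figsize=(1.2 * len(table) / len(panels) + 3, 4),
                             squeeze=False, sharey=False)
    for ax, panel in zip(axes[0], panels):
        sub = table[table["panel_id"] == panel].reset_index(drop=True)
        x = range(len(sub))
        ax.vlines(x, sub["sim_min"], sub["sim_max"], color="0.7", lw=1, zorder=1)
        ax.vlines(x, sub["ci_low"], sub["ci_high"], color="black", lw=2.5, zorder=2)
        ax.plot(x, sub["expected"], "o", color="black", ms=5, zorder=3, label="expected")
        ax.plot(x, sub["observed"], "^", color="tab:red", ms=7, zorder=4, label="observed")
        ax.set_xticks(list(x))
        ax.set_xticklabels(
            [f"{s} (k={k})" for s, k in zip(sub["scope"], sub["k"])], rotation=60, ha="right"
        )
        statistic = "mean" if (sub["hypothesis"] == "dissimilar_mates").all() else "SD"
        ax.set_ylabel(f"pairwise similarity ({statistic})")
        ax.set_title(panel)
    axes[0][-1].legend(frameon=False, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
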