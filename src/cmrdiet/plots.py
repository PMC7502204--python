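"""Minimal plotting helpers: contribution bar chart and association forest."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def contribution_barchart(contributions: pd.Series, k: int = 9, path=None):
    """Horizontal bars of the top-k food-group contributions (% of total)."""
    top = contributions.sort_values(ascending=False).head(k)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * k + 1))
    ax.barh(top.index, top.values, color="#3b6ea5")
    ax.set_xlabel("contribution to explained variance (%)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def association_forest(levels: pd.DataFrame, path=None, title=""):
    """Forest plot of per-band betas with 95% CIs."""
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(levels) + 1))
    y = range(len(levels))
    ax.errorbar(levels["beta"], y,
                xerr=[levels["beta"] - levels["ci_low"],
                      levels["ci_high"] - levels["beta"]],
                fmt="o", color="#3b6ea5", capsize=3)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(list(y), levels["level"])
    ax.set_xlabel("beta (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
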