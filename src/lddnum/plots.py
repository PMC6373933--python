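"""Summary figures for the two experiments (condition means with 95% CIs)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_exp1_summary", "plot_exp2_summary"]


def plot_exp1_summary(summary: pd.DataFrame, out_path: str | Path) -> None:
    """One panel per grouping feature: mean PSE vs set size, 1 vs 2 groups."""
    features = sorted(summary["grouping_feature"].unique())
    fig, axes = plt.subplots(1, len(features), figsize=(3 * len(features), 3),
                             sharey=True)
    if len(features) == 1:
        axes = [axes]
    for ax, feat in zip(axes, features):
        for n_groups, marker in ((1, "o"), (2, "s")):
            sub = summary[
                (summary["grouping_feature"] == feat)
                & (summary["n_groups"] == n_groups)
            ].sort_values("n_test")
            if sub.empty:
                continue
            ax.errorbar(
                sub["n_test"],
                sub["mean_pse"],
                yerr=[sub["mean_pse"] - sub["ci_low"],
                      sub["ci_high"] - sub["mean_pse"]],
                marker=marker,
                capsize=3,
                label=f"{n_groups} group{'s' if n_groups == 2 else ''}",
            )
        ax.plot([15, 21], [15, 21], ls=":", c="gray", lw=0.8)
        ax.set_title(feat)
        ax.set_xlabel("test numerosity")
    axes[0].set_ylabel("PSE (dots)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_exp2_summary(summary: pd.DataFrame, out_path: str | Path) -> None:
    """Reported count vs test numerosity, split by response area and size."""
    sizes = sorted(summary["response_dotsize_factor"].unique())
    fig, axes = plt.subplots(1, len(sizes), figsize=(3 * len(sizes), 3),
                             sharey=True)
    if len(sizes) == 1:
        axes = [axes]
    for ax, fd in zip(axes, sizes):
        for fa in sorted(summary["response_area_factor"].unique()):
            sub = summary[
                (summary["response_dotsize_factor"] == fd)
                & (summary["response_area_factor"] == fa)
            ].sort_values("n_test")
            ax.errorbar(
                sub["n_test"],
                sub["mean_pse"],
                yerr=[sub["mean_pse"] - sub["ci_low"],
                      sub["ci_high"] - sub["mean_pse"]],
                marker="o",
                capsize=3,
                label=f"area x{fa:g}",
            )
        ax.set_title(f"response dot size x{fd:g}")
        ax.set_xlabel("test numerosity")
    axes[0].set_ylabel("reported dots (PSE)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
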