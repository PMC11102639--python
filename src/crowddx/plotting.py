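"""Matplotlib views of the evaluation tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_accuracy_curves", "plot_case_level", "plot_associations"]


def plot_accuracy_curves(curves: pd.DataFrame, title: str | None = None):
    """Accuracy vs group size, one panel per condition, one line per rule."""
    conditions = sorted(curves["condition"].unique())
    fig, axes = plt.subplots(
        1, len(conditions), figsize=(4 * len(conditions), 3.2), sharey=True, squeeze=False
    )
    for ax, condition in zip(axes[0], conditions):
        sub = curves[curves["condition"] == condition]
        for rule, line in sub.groupby("rule", observed=True):
            line = line.sort_values("k")
            ax.errorbar(
                line["k"], line["accuracy"], yerr=line["mc_se"], marker="o",
                markersize=3, capsize=2, label=str(rule),
            )
        ax.set_title(condition)
        ax.set_xlabel("group size k")
    axes[0][0].set_ylabel("mean diagnostic accuracy")
    axes[0][-1].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_case_level(case_table: pd.DataFrame):
    """Plurality accuracy vs group size per case, ordered easiest-to-hardest."""
    k_cols = [c for c in case_table.columns if c.startswith("plurality_k")]
    ks = [int(c.removeprefix("plurality_k")) for c in k_cols]
    n = len(case_table)
    ncols = min(n, 6)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.1 * ncols, 1.9 * nrows), sharex=True, sharey=True,
        squeeze=False,
    )
    for ax, (_, row) in zip(axes.flat, case_table.iterrows()):
        ax.plot(ks, [row[c] for c in k_cols], marker="o", markersize=3)
        ax.axhline(row["mean_individual_accuracy"], ls="--", lw=0.8, color="gray")
        ax.set_title(f"{row['case_id']} ({row['condition']})", fontsize=8)
        ax.set_ylim(-0.02, 1.02)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.supxlabel("group size k")
    fig.supylabel("plurality accuracy")
    fig.tight_layout()
    return fig


def plot_associations(assoc: dict[str, pd.DataFrame]):
    """Binned accuracy by confidence level and by seniority band."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
    conf = assoc["confidence"]
    ax1.errorbar(conf["confidence"], conf["accuracy"], yerr=conf["se"], marker="o")
    ax1.set_xlabel("confidence rating")
    ax1.set_ylabel("accuracy")
    sen = assoc["seniority"]
    ax2.errorbar(range(len(sen)), sen["accuracy"], yerr=sen["se"], marker="o")
    ax2.set_xticks(range(len(sen)), sen["seniority_band"].astype(str))
    ax2.set_xlabel("years of experience")
    fig.tight_layout()
    return fig
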