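"""Optional matplotlib views of the analysis outputs.

Each function takes already-computed tables and writes one figure; nothing
here recomputes model quantities.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "plot_survival_differences",
    "plot_decompositions",
    "plot_parameter_comparison",
    "plot_bootstrap_distributions",
]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_survival_differences(diffs: Mapping[str, pd.DataFrame], path) -> None:
    """Overlay per-age survival-proportion differences between group pairs."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, df in diffs.items():
        ax.plot(df["age"], df["difference"], label=label)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("difference in survival proportion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decompositions(curves: pd.DataFrame, path) -> None:
    """Intrinsic (solid) and extrinsic (dashed) fitted survival by group."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, (label, df) in enumerate(curves.groupby("group")):
        color = f"C{i}"
        ax.plot(df["age"], df["intrinsic"], color=color, ls="-", label=f"{label} intrinsic")
        ax.plot(df["age"], df["extrinsic"], color=color, ls="--", label=f"{label} extrinsic")
    ax.set_xlabel("age (model clock, years)")
    ax.set_ylabel("survival proportion")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_parameter_comparison(table: pd.DataFrame, path) -> None:
    """Point estimates with +/- 2 SE bars, one panel per parameter."""
    plt = _pyplot()
    params = list(table["parameter"].unique())
    fig, axes = plt.subplots(1, len(params), figsize=(3 * len(params), 4), squeeze=False)
    for ax, name in zip(axes[0], params):
        sub = table[table["parameter"] == name]
        xs = range(len(sub))
        ax.errorbar(
            xs,
            sub["estimate"],
            yerr=2.0 * sub["se"],
            fmt="o",
            capsize=3,
            ls="none",
        )
        ax.set_xticks(list(xs))
        ax.set_xticklabels(sub["group"], rotation=60, fontsize=7)
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bootstrap_distributions(distributions: Sequence, path) -> None:
    """Boxplots of bias-corrected parameter values over subsample replicates."""
    plt = _pyplot()
    params = sorted({d.parameter for d in distributions})
    fig, axes = plt.subplots(1, len(params), figsize=(3 * len(params), 4), squeeze=False)
    for ax, name in zip(axes[0], params):
        ds = [d for d in distributions if d.parameter == name]
        ax.boxplot([d.values for d in ds], tick_labels=[d.group_label for d in ds])
        ax.set_title(name)
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
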