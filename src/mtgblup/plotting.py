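"""Summary figures for scenario results."""

from __future__ import annotations

import pandas as pd


def plot_accuracy_by_size(summary: pd.DataFrame, ax=None):
    """Mean accuracy vs reference size, one line per (cell, model).

    Expects the output of :func:`mtgblup.summarize`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for (cell, model), sub in summary.groupby(["cell", "model"]):
        sub = sub.sort_values("n_ref")
        style = "-" if model == "multi" else "--"
        ax.plot(sub["n_ref"], sub["mean_accuracy"], style, marker="o", label=f"{cell} {model}")
    ax.set_xlabel("reference population size")
    ax.set_ylabel("mean accuracy (r$^2$ of GEBV vs TBV)")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_improvement(summary: pd.DataFrame, ax=None):
    """Multi-minus-single accuracy gain per cell (bar chart)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    gains = (
        summary[summary["model"] == "multi"]
        .drop_duplicates(subset=["cell", "n_ref", "trait"])
        .sort_values(["rg", "h2_1"])
    )
    labels = [f"{c} (n={n})" for c, n in zip(gains["cell"], gains["n_ref"])]
    ax.bar(range(len(gains)), gains["improvement"])
    ax.set_xticks(range(len(gains)), labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("accuracy gain (multi - single)")
    ax.axhline(0.0, color="k", lw=0.8)
    return ax
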