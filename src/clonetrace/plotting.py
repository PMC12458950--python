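"""Minimal plotting: a stacked-area view of clone dynamics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_clone_stack(proportions: pd.DataFrame, out: str, top_n: int = 20) -> None:
    """Stacked-area plot of the ``top_n`` largest clones over time.

    Remaining clones are pooled into an "other" band. ``proportions`` is a
    clones x times frame; the figure is written to ``out``.
    """
    times = [float(c) for c in proportions.columns]
    order = proportions.max(axis=1).sort_values(ascending=False).index
    top = proportions.loc[order[:top_n]]
    other = proportions.loc[order[top_n:]].sum(axis=0)
    fig, ax = plt.subplots(figsize=(7, 4))
    series = [top.loc[i].to_numpy() for i in top.index] + [other.to_numpy()]
    ax.stackplot(times, series, labels=list(top.index) + ["other"])
    ax.set_xlabel("day")
    ax.set_ylabel("clone proportion")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
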