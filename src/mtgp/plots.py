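"""Plotting helpers: CV box plots, MDS scatter, training-size curves."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_cv_boxes", "plot_mds", "plot_size_curve"]


def plot_cv_boxes(results, ax=None):
    """Box plot of per-iteration predictive abilities, one box per scheme run.

    ``results`` is a sequence of :class:`~mtgp.crossval.CVResult`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    labels, data = [], []
    for r in results:
        lab = r.scheme.name
        if r.scheme.secondary:
            lab += f"\n({r.scheme.secondary})"
        labels.append(lab)
        data.append(r.table["r_p"].to_numpy())
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("predictive ability $r_p$")
    ax.axhline(0.0, color="grey", lw=0.5)
    return ax


def plot_mds(coords: pd.DataFrame, pop_labels=None, ax=None):
    """Scatter of the first two principal coordinates, colored by population."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if pop_labels is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=8)
    else:
        pops = pd.Series(pop_labels, index=coords.index)
        for pop, sub in coords.groupby(pops):
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=8, label=str(pop))
        ax.legend(title="population", fontsize=8)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    return ax


def plot_size_curve(sweep: pd.DataFrame, ax=None, label=None):
    """Mean ± SD predictive ability against training-set size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    g = sweep.groupby("n_train")["r_p"].agg(["mean", "std"])
    ax.errorbar(g.index, g["mean"], yerr=g["std"], marker="o", capsize=3, label=label)
    ax.set_xlabel("training families")
    ax.set_ylabel("predictive ability $r_p$")
    if label:
        ax.legend()
    return ax
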