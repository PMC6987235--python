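"""Plots of adjusted means and growth trajectories.

Two figure types mirror the standard presentation of this analysis:
back-transformed least-square means of the resilience indices with 95%
confidence intervals, contrasted between now-dead and surviving trees
(optionally split by taxonomic group), and mean log-ratio growth
trajectories around the drought event with bootstrap envelopes.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

STATUS_COLORS = {"surviving": "0.35", "now-dead": "tab:red"}


def plot_adjusted_means(adjusted, ax=None, ylabel="index (ratio scale)"):
    """Point-and-interval plot of back-transformed adjusted means.

    ``adjusted`` is the DataFrame returned by
    :meth:`ResilienceLMMResults.adjusted_means`; contrast rows are
    ignored.  Returns the matplotlib Axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    pts = adjusted[adjusted["status"].isin(STATUS_COLORS)]
    panels = list(dict.fromkeys(pts["group"]))
    xticks, xlabels = [], []
    for i, g in enumerate(panels):
        sub = pts[pts["group"] == g] if g is not None else pts
        for j, (_, row) in enumerate(sub.iterrows()):
            x = 2 * i + 0.6 * j
            ax.errorbar(x, row["mean"],
                        yerr=[[row["mean"] - row["ci_lo"]],
                              [row["ci_hi"] - row["mean"]]],
                        fmt="s", color=STATUS_COLORS[row["status"]],
                        capsize=3)
        xticks.append(2 * i + 0.3)
        xlabels.append(g if g is not None else "all trees")
    ax.set_xticks(xticks, xlabels)
    ax.set_ylabel(ylabel)
    ax.axhline(1.0, lw=0.5, ls=":", color="0.6")
    handles = [plt.Line2D([], [], marker="s", ls="", color=c, label=s)
               for s, c in STATUS_COLORS.items()]
    ax.legend(handles=handles, frameon=False, fontsize=8)
    return ax


def plot_growth_patterns(curves, axes=None):
    """Mean log-ratio growth around the event with bootstrap envelopes.

    ``curves`` is the DataFrame from :func:`growth_pattern_bootstrap`;
    one panel per taxonomic group, one line per status.  Returns the
    array of Axes.
    """
    groups = sorted(curves["group"].unique())
    if axes is None:
        _, axes = plt.subplots(1, max(len(groups), 1),
                               figsize=(4 * max(len(groups), 1), 3),
                               sharey=True, squeeze=False)
        axes = axes[0]
    for ax, g in zip(axes, groups):
        for status, color in STATUS_COLORS.items():
            sub = curves[(curves["group"] == g) & (curves["status"] == status)]
            if sub.empty:
                continue
            sub = sub.sort_values("rel_year")
            ax.plot(sub["rel_year"], sub["mean_log_ratio"], color=color,
                    label=status)
            ax.fill_between(sub["rel_year"], sub["ci_lo"], sub["ci_hi"],
                            color=color, alpha=0.25, lw=0)
        ax.axvline(0, lw=0.5, ls=":", color="0.6")
        ax.axhline(0, lw=0.5, ls=":", color="0.6")
        ax.set_title(g, fontsize=9)
        ax.set_xlabel("years from drought event")
    axes[0].set_ylabel("log(TRW / pre-drought mean)")
    axes[0].legend(frameon=False, fontsize=8)
    return axes
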