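"""Optional matplotlib views of the experiment tables.

Stacked-area/bar renderings of the step and quartile frequency tables and
a point-range rendering of the percentile-interval sets. Import requires
matplotlib (the ``plot`` extra); everything else in the package works
without it.
"""

from __future__ import annotations

import matplotlib.pyplot as plt
import pandas as pd

from .experiments import PercentileIntervalSet

__all__ = ["plot_frequency_table", "plot_intervals"]

_CLASS_COLORS = {
    "freq_sign": "#d62728",
    "freq_synergistic": "#2ca02c",
    "freq_antagonistic": "#1f77b4",
    "freq_none": "#bbbbbb",
}


def plot_frequency_table(table: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Stacked bars of epistasis-class frequencies per step or quartile."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bottom = None
    for col, color in _CLASS_COLORS.items():
        vals = table[col].fillna(0.0)
        ax.bar(table.index.astype(str), vals, bottom=bottom, color=color,
               label=col.removeprefix("freq_"))
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlabel(table.index.name or "stratum")
    ax.set_ylabel("frequency")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax


def plot_intervals(intervals: PercentileIntervalSet, ax: plt.Axes | None = None) -> plt.Axes:
    """2.5–97.5 percentile ranges with median dots, one bar per quadruple role."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for x, (role, (lo, med, hi)) in enumerate(intervals.intervals.items()):
        color = "tab:blue" if role == "control" else "tab:gray"
        ax.vlines(x, lo, hi, color=color, linewidth=6, alpha=0.6)
        ax.plot(x, med, "o", color="black")
    ax.set_xticks(range(len(intervals.intervals)),
                  list(intervals.intervals))
    ax.set_ylabel("fitness")
    ax.set_title(f"{intervals.window} window ({intervals.n_walks} walks)")
    return ax
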