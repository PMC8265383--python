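"""Optional matplotlib views of PCoA ordinations and delta-K profiles."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .evanno import EvannoTable
from .pcoa import PcoaResult

__all__ = ["plot_pcoa", "plot_delta_k"]


def plot_pcoa(result: PcoaResult, pop_of: dict[str, str], axes=(1, 2),
              ax=None):
    """Scatter of two PCoA axes coloured by population."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    a, b = axes
    coords = result.coordinates
    pops = list(dict.fromkeys(pop_of[i] for i in coords.index))
    cmap = plt.get_cmap("tab20")
    for k, p in enumerate(pops):
        members = [i for i in coords.index if pop_of[i] == p]
        ax.scatter(coords.loc[members, f"axis{a}"],
                   coords.loc[members, f"axis{b}"],
                   s=24, color=cmap(k % 20), label=p)
    ax.set_xlabel(f"Coordinate {a} ({result.axis_pct[a - 1]:.2f}%)")
    ax.set_ylabel(f"Coordinate {b} ({result.axis_pct[b - 1]:.2f}%)")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_delta_k(table: EvannoTable, ax=None):
    """Delta-K against K, marking the selected optimum."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = table.table
    ax.plot(t.index, t["delta_k"], "o-", color="black")
    if table.k_opt is not None:
        ax.axvline(table.k_opt, ls="--", color="grey")
    ax.set_xlabel("K")
    ax.set_ylabel("delta K")
    return ax
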