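"""Small diagnostic plots (scree, map histograms, regional correlations)."""

from __future__ import annotations

import numpy as np

from .decomposition import MapPCAResults
from .surface import VertexMap


def scree_plot(results: MapPCAResults, n_show: int = 10, ax=None):
    """Percentage of variance explained by the leading components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    total = results.stack.n_maps
    pct = results.eigenvalues[:n_show] / total * 100.0
    ax.plot(np.arange(1, pct.size + 1), pct, "o-")
    ax.set_xlabel("component")
    ax.set_ylabel("% variance explained")
    return ax


def map_histogram(vmap: VertexMap, bins: int = 60, ax=None):
    """Density of valid map values (the usual sanity check for a beta map)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(vmap.valid_values(), bins=bins, density=True)
    ax.axvline(0.0, linestyle=":", color="k")
    ax.set_xlabel(vmap.name or "value")
    ax.set_ylabel("density")
    return ax


def within_region_plot(table, overall_r: float | None = None, ax=None):
    """Per-region correlation strip, sorted, with the cortex-wide r marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    t = table.dropna(subset=["r"]).sort_values("r")
    ax.bar(np.arange(len(t)), t["r"], width=0.8)
    if overall_r is not None:
        ax.axhline(overall_r, color="k", linewidth=1, label=f"cortex-wide r = {overall_r:.2f}")
        ax.legend(frameon=False)
    ax.axhline(0.0, color="k", linewidth=0.5)
    ax.set_xlabel("region (sorted)")
    ax.set_ylabel("within-region r")
    return ax
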