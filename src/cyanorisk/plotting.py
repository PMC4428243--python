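"""Minimal choropleth helpers (debug convenience, not an analysis surface)."""

from __future__ import annotations

import numpy as np

from .regions import CountyMap

__all__ = ["choropleth", "lisa_map"]

_LISA_COLORS = {
    "High-High": "#d7191c",
    "Low-Low": "#2c7bb6",
    "High-Low": "#fdae61",
    "Low-High": "#abd9e9",
    "Not-significant": "#eeeeee",
}


def choropleth(counties: CountyMap, values, ax=None, cmap="viridis",
               title: str | None = None):
    """Shade county polygons by a numeric vector."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    if ax is None:
        _, ax = plt.subplots()
    patches = [MplPolygon(np.asarray(p.exterior.coords)) for p in counties.polygons]
    coll = PatchCollection(patches, cmap=cmap)
    coll.set_array(np.asarray(values, dtype=float))
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    plt.colorbar(coll, ax=ax, shrink=0.8)
    return ax


def lisa_map(counties: CountyMap, quadrants, ax=None):
    """Color counties by LISA quadrant class."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    if ax is None:
        _, ax = plt.subplots()
    patches = [MplPolygon(np.asarray(p.exterior.coords)) for p in counties.polygons]
    colors = [_LISA_COLORS.get(q, "#ffffff") for q in quadrants]
    coll = PatchCollection(patches, facecolors=colors, edgecolors="grey",
                           linewidths=0.3)
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    return ax
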