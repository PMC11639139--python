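"""Minimal figures: firing fields and autocorrelograms."""

from __future__ import annotations

import numpy as np

from .analysis import Autocorrelogram, RateMap, autocorrelogram


def plot_rate_map(rate_map: RateMap, ax=None, title: str | None = None):
    """Heat map of a firing field (NaN bins transparent)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = rate_map.values
    ax.imshow(
        v.T,
        origin="lower",
        extent=(rate_map.x_edges[0], rate_map.x_edges[-1],
                rate_map.y_edges[0], rate_map.y_edges[-1]),
        interpolation="nearest",
    )
    if title:
        ax.set_title(title)
    ax.set_xlabel("x (units)")
    ax.set_ylabel("y (units)")
    return ax


def plot_autocorrelogram(ac: Autocorrelogram | RateMap, ax=None,
                         title: str | None = None):
    import matplotlib.pyplot as plt

    if isinstance(ac, RateMap):
        ac = autocorrelogram(ac)
    if ax is None:
        _, ax = plt.subplots()
    h, w = ac.values.shape
    ax.imshow(
        ac.values.T,
        origin="lower",
        extent=(-(h // 2) * ac.dx, (h // 2) * ac.dx,
                -(w // 2) * ac.dy, (w // 2) * ac.dy),
        vmin=-1.0,
        vmax=1.0,
        cmap="RdBu_r",
        interpolation="nearest",
    )
    if title:
        ax.set_title(title)
    return ax


def save_field_figure(rate_map: RateMap, path) -> None:
    """Field + autocorrelogram side by side, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    plot_rate_map(rate_map, ax=axes[0], title="firing field")
    try:
        plot_autocorrelogram(rate_map, ax=axes[1], title="autocorrelogram")
    except ValueError:
        axes[1].set_title("autocorrelogram undefined")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
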