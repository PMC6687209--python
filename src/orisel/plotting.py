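"""Figure rendering for mosaics, orientation maps and tuning curves."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .mosaic import ChannelArray
from .mapping import OrientationMap, VonMisesFit


def plot_mosaic(channels: ChannelArray, weights: np.ndarray | None = None,
                ax=None, max_marker: float = 40.0):
    """Scatter of channel positions, on-centre red and off-centre blue;
    marker area proportional to the synaptic weight if given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    size = np.full(len(channels), 8.0) if weights is None else \
        max_marker * np.asarray(weights) / 2.0 + 0.5
    for sign, color in ((1, "tab:red"), (-1, "tab:blue")):
        m = channels.sign == sign
        ax.scatter(channels.x[m], channels.y[m], s=size[m], c=color,
                   alpha=0.6, linewidths=0)
    half = channels.spec.patch_half_width
    ax.set(xlim=(-half, half), ylim=(-half, half), aspect="equal",
           xlabel="x (deg)", ylabel="y (deg)")
    return ax


def plot_orientation_map(omap: OrientationMap, ax=None):
    """Hue-coded preferred-orientation map (0-180 deg)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ny, nx = omap.shape
    half_y = (ny - 1) / 2 * omap.spacing
    half_x = (nx - 1) / 2 * omap.spacing
    im = ax.imshow(omap.orientation_deg, origin="lower", cmap="hsv",
                   vmin=0, vmax=180,
                   extent=(-half_x, half_x, -half_y, half_y))
    ax.set(xlabel="x (deg)", ylabel="y (deg)")
    plt.colorbar(im, ax=ax, label="preferred orientation (deg)")
    return ax


def plot_tuning_curve(directions_deg, responses, fit: VonMisesFit = None,
                      ax=None):
    """Direction tuning points with the optional double-von-Mises fit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(directions_deg, responses, "o", color="k")
    if fit is not None and fit.converged:
        grid = np.linspace(0, 360, 721)
        ax.plot(grid, fit(grid), "-", color="tab:red")
    ax.set(xlabel="motion direction (deg)",
           ylabel="peak impulse rate (Hz)", xlim=(0, 360))
    return ax
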