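"""On/off subcortical channel mosaic: generation and spatial statistics.

The mosaic emulates the measured layout of on- and off-centre beta
ganglion cells: same-sign cells on perturbed square grids, the two grids
offset so that nearest neighbours are almost always of opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .params import MosaicSpec


@dataclass
class ChannelArray:
    """Positions, signs and time constants of the subcortical channels.

    Attributes
    ----------
    x, y : channel coordinates (deg), origin at patch centre, x rightward,
        y upward.
    sign : +1 for on-centre, -1 for off-centre.
    spec : the generating :class:`MosaicSpec`.
    """

    x: np.ndarray
    y: np.ndarray
    sign: np.ndarray
    spec: MosaicSpec

    def __post_init__(self) -> None:
        if not np.all(np.abs(self.sign) == 1):
            raise ValueError("channel signs must be +/-1")

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_on(self) -> int:
        return int(np.sum(self.sign > 0))

    @property
    def n_off(self) -> int:
        return int(np.sum(self.sign < 0))

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def tau(self, tau_on: float, tau_off: float) -> np.ndarray:
        """Per-channel time constant determined by sign."""
        return np.where(self.sign > 0, tau_on, tau_off)

    def select(self, mask: np.ndarray) -> "ChannelArray":
        return ChannelArray(self.x[mask], self.y[mask], self.sign[mask],
                            self.spec)


def _grid_index_halfcount(spec: MosaicSpec) -> int:
    # Node-inclusion convention: both grids span the index range set by the
    # on-spacing. n = floor(half_width / on_spacing); the off grid then has
    # (2n+1)^2 nodes at i*off_spacing (node at centre) and the on grid
    # (2n)^2 nodes at (i+1/2)*on_spacing (four centre-nearest nodes
    # equidistant from the centre). Standard spec: 41^2 + 40^2 = 3281.
    return int(np.floor(spec.patch_half_width / spec.on_spacing + 1e-9))


def build_channel_array(spec: MosaicSpec) -> ChannelArray:
    """Generate the perturbed offset-grid channel mosaic.

    Off channels: square grid with a node at the patch centre. On channels:
    square grid offset by half a spacing in both axes. Every node is then
    displaced by independent Gaussian deviates in x and y (not clipped back
    into the patch). Deterministic given ``spec.seed``.
    """
    n = _grid_index_halfcount(spec)
    rng = np.random.default_rng(spec.seed)

    idx_off = np.arange(-n, n + 1)
    ox, oy = np.meshgrid(idx_off * spec.off_spacing,
                         idx_off * spec.off_spacing, indexing="xy")
    off_xy = np.column_stack([ox.ravel(), oy.ravel()])

    idx_on = np.arange(-n, n) + 0.5
    gx, gy = np.meshgrid(idx_on * spec.on_spacing, idx_on * spec.on_spacing,
                         indexing="xy")
    on_xy = np.column_stack([gx.ravel(), gy.ravel()])

    off_xy = off_xy + rng.normal(0.0, spec.off_perturb_sd, off_xy.shape)
    on_xy = on_xy + rng.normal(0.0, spec.on_perturb_sd, on_xy.shape)

    xy = np.vstack([off_xy, on_xy])
    sign = np.concatenate([
        -np.ones(len(off_xy), dtype=int),
        np.ones(len(on_xy), dtype=int),
    ])
    return ChannelArray(xy[:, 0].copy(), xy[:, 1].copy(), sign, spec)


def nearest_neighbour_distances(array: ChannelArray,
                                sign: int) -> np.ndarray:
    """Distance from each channel of ``sign`` to its nearest same-sign
    neighbour."""
    pts = array.xy[array.sign == sign]
    if len(pts) < 2:
        raise ValueError("need at least two channels of the requested sign")
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def nearest_neighbour_stats(array: ChannelArray,
                            bins: int = 30) -> dict[int, dict]:
    """Per-sign histogram of normalised nearest-neighbour distances.

    Distances to the nearest same-sign neighbour are divided by their mean;
    histogram frequencies are normalised to a maximum of one. Returns a
    mapping sign -> {distances, sd, bin_edges, frequency}.
    """
    out: dict[int, dict] = {}
    for s in (+1, -1):
        d = nearest_neighbour_distances(array, s)
        d_norm = d / d.mean()
        hi = max(2.0, float(d_norm.max()))
        freq, edges = np.histogram(d_norm, bins=bins, range=(0.0, hi))
        freq = freq / freq.max()
        out[s] = {
            "distances": d_norm,
            "sd": float(d_norm.std(ddof=1)),
            "bin_edges": edges,
            "frequency": freq,
        }
    return out


def opposite_sign_neighbour_fraction(array: ChannelArray) -> float:
    """Fraction of channels whose nearest neighbour (any sign) has opposite
    sign; close to one for the offset-grid mosaic."""
    d, idx = cKDTree(array.xy).query(array.xy, k=2)
    return float(np.mean(array.sign[idx[:, 1]] != array.sign))


def density_recovery_profile(array: ChannelArray,
                             annulus_width: float = 0.05,
                             n_annuli: int = 20) -> dict:
    """Density of on-cells in annuli around off-cell reference points.

    A flat profile indicates that the on and off mosaics are statistically
    independent. Edge effects are avoided by restricting reference (off)
    cells to the patch interior, at least ``n_annuli*annulus_width`` from
    every edge. Returns annulus centres (deg), densities (cells/deg^2) and
    the F statistic / p-value of a zero-slope linear-regression test.
    """
    if n_annuli < 3:
        raise ValueError("need at least three annuli")
    r_max = annulus_width * n_annuli
    half = array.spec.patch_half_width
    interior = half - r_max
    on_pts = array.xy[array.sign > 0]
    off_pts = array.xy[array.sign < 0]
    if len(on_pts) == 0 or len(off_pts) == 0:
        raise ValueError("need channels of both signs")
    ref_mask = (np.abs(off_pts[:, 0]) <= interior) & \
               (np.abs(off_pts[:, 1]) <= interior)
    refs = off_pts[ref_mask]
    if len(refs) == 0:
        raise ValueError("annuli extend beyond patch: no interior "
                         "reference cells")

    tree = cKDTree(on_pts)
    pairs = tree.query_ball_point(refs, r_max)
    dists = np.concatenate([
        np.hypot(on_pts[p, 0] - r[0], on_pts[p, 1] - r[1])
        for r, p in zip(refs, pairs)
    ]) if len(refs) else np.empty(0)

    edges = annulus_width * np.arange(n_annuli + 1)
    counts, _ = np.histogram(dists, bins=edges)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    density = counts / (areas * len(refs))
    centres = 0.5 * (edges[1:] + edges[:-1])

    fit = stats.linregress(centres, density)
    df = n_annuli - 2
    f_stat = float(fit.rvalue**2 / (1 - fit.rvalue**2) * df) \
        if abs(fit.rvalue) < 1 else np.inf
    return {
        "radius": centres,
        "density": density,
        "n_reference": int(len(refs)),
        "slope": float(fit.slope),
        "f_statistic": f_stat,
        "df": (1, df),
        "p_value": float(fit.pvalue),
    }


def aliasing_period(on_density: float, off_density: float) -> float:
    """Beat period (deg) of the diagonal on/off lattices.

    Diagonal spacings are d = sqrt(2/density) per sign; the beat length of
    the two 1-D lattices is d_on*d_off/(d_on - d_off). For the standard
    densities (24.4, 26.6 cells/deg^2) this is 6.5 deg.
    """
    if on_density <= 0 or off_density <= 0:
        raise ValueError("densities must be positive")
    d_on = np.sqrt(2.0 / on_density)
    d_off = np.sqrt(2.0 / off_density)
    if np.isclose(d_on, d_off):
        raise ValueError("equal densities give an infinite aliasing period")
    return float(abs(d_on * d_off / (d_on - d_off)))
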