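"""Stimulus construction: drifting gratings, sparse-noise flashes, movies.

Stimuli are defined in terms of contrast, not luminance (the model has no
surround mechanism, so contrast is the natural input variable). Every
stimulus knows how to compute the stage-1 drive: the dot product of the
contrast pattern with each channel's Gaussian centre profile,

    g_js(x, y) = g_s/(pi r_s^2) exp(-((x-x_j)^2 + (y-y_j)^2)/r_s^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .params import ModelParams, TWO_PI
from .mosaic import ChannelArray


@dataclass(frozen=True)
class GratingSpec:
    """Drifting sinusoidal grating s(t,u) = c cos(psi*u - omega*t), with
    u = cos(theta) x + sin(theta) y the coordinate along the motion axis."""

    contrast: float = 0.3
    spatial_freq: float = 0.5   # cycles/deg
    temporal_freq: float = 2.0  # Hz
    direction_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.spatial_freq <= 0 or self.temporal_freq <= 0:
            raise ValueError("grating frequencies must be positive")

    @property
    def psi(self) -> float:
        """Spatial frequency in rad/deg."""
        return TWO_PI * self.spatial_freq

    @property
    def omega(self) -> float:
        """Temporal frequency in rad/s."""
        return TWO_PI * self.temporal_freq

    @property
    def period(self) -> float:
        return 1.0 / self.temporal_freq

    @property
    def theta(self) -> float:
        return math.radians(self.direction_deg % 360.0)

    def u(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance along the motion axis."""
        return np.cos(self.theta) * x + np.sin(self.theta) * y

    def contrast_at(self, t: float, x: np.ndarray,
                    y: np.ndarray) -> np.ndarray:
        return self.contrast * np.cos(self.psi * self.u(x, y)
                                      - self.omega * t)

    def drive_params(self, params: ModelParams,
                     channels: ChannelArray) -> tuple[float, np.ndarray]:
        """Closed-form dot product with the centre profile.

        The Gaussian integral gives amplitude g_s c exp(-r_s^2 psi^2 / 4)
        (identical for every channel) and per-channel phase psi*u_j."""
        amp = params.g_s * self.contrast * \
            math.exp(-(params.r_s * self.psi) ** 2 / 4.0)
        phase = self.psi * self.u(channels.x, channels.y)
        return amp, phase

    def channel_drive(self, t: float, params: ModelParams,
                      channels: ChannelArray) -> np.ndarray:
        amp, phase = self.drive_params(params, channels)
        return amp * np.cos(phase - self.omega * t)

    def to_movie(self, patch_half_width: float, raster: float = 0.05,
                 dt: float = 0.001, duration: float = 1.0) -> "Movie":
        """Render the grating onto a space-time raster (for testing the
        gridded drive path against the closed form)."""
        ax = _raster_axis(patch_half_width, raster)
        x, y = np.meshgrid(ax, ax, indexing="xy")
        times = np.arange(0.0, duration, dt)
        frames = np.stack([self.contrast_at(t, x, y) for t in times])
        return Movie(frames, ax, ax, dt)


@dataclass(frozen=True)
class FlashSpec:
    """Single square flash on a zero background: ``contrast`` over the
    square of side ``size`` centred at (x0, y0), for ``duration`` seconds
    starting at t = 0."""

    x0: float
    y0: float
    size: float = 1.0
    contrast: float = 1.0
    duration: float = 0.05

    def contrast_at(self, t: float, x: np.ndarray,
                    y: np.ndarray) -> np.ndarray:
        if not (0.0 <= t < self.duration):
            return np.zeros_like(x)
        inside = (np.abs(x - self.x0) <= self.size / 2) & \
                 (np.abs(y - self.y0) <= self.size / 2)
        return self.contrast * inside

    def channel_drive(self, t: float, params: ModelParams,
                      channels: ChannelArray) -> np.ndarray:
        """Exact Gaussian-rectangle integral (product of erf terms)."""
        if not (0.0 <= t < self.duration):
            return np.zeros(len(channels))
        r = params.r_s
        hx = self.size / 2
        ex = erf((self.x0 + hx - channels.x) / r) - \
            erf((self.x0 - hx - channels.x) / r)
        ey = erf((self.y0 + hx - channels.y) / r) - \
            erf((self.y0 - hx - channels.y) / r)
        return params.g_s * self.contrast * 0.25 * ex * ey


@dataclass
class Movie:
    """Arbitrary contrast movie on a space-time raster.

    ``frames`` has shape (n_t, n_y, n_x); frames are held piecewise
    constant over ``dt``. The channel drive is a Riemann sum of the frame
    against each channel's centre profile.
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    _weights: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_t, n_y, n_x)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("contrast values must be finite")

    @property
    def duration(self) -> float:
        return self.frames.shape[0] * self.dt

    def covers(self, half_width: float) -> bool:
        return (self.x.min() <= -half_width and self.x.max() >= half_width
                and self.y.min() <= -half_width
                and self.y.max() >= half_width)

    def _weight_matrix(self, params: ModelParams,
                       channels: ChannelArray) -> np.ndarray:
        key = (id(channels), params.g_s, params.r_s)
        if key not in self._weights:
            gx, gy = np.meshgrid(self.x, self.y, indexing="xy")
            pix = np.column_stack([gx.ravel(), gy.ravel()])
            dx = float(np.mean(np.diff(self.x)))
            dy = float(np.mean(np.diff(self.y)))
            d2 = (pix[None, :, 0] - channels.x[:, None]) ** 2 + \
                 (pix[None, :, 1] - channels.y[:, None]) ** 2
            w = np.exp(-d2 / params.r_s ** 2) * \
                (params.g_s / (np.pi * params.r_s ** 2)) * dx * dy
            self._weights[key] = w
        return self._weights[key]

    def channel_drive(self, t: float, params: ModelParams,
                      channels: ChannelArray) -> np.ndarray:
        i = int(t / self.dt)
        if i < 0 or i >= self.frames.shape[0]:
            return np.zeros(len(channels))
        w = self._weight_matrix(params, channels)
        return w @ self.frames[i].ravel()


def _raster_axis(half_width: float, raster: float) -> np.ndarray:
    n = int(round(half_width / raster))
    return np.arange(-n, n + 1) * raster


def make_grating(contrast: float = 0.3, spatial_freq: float = 0.5,
                 temporal_freq: float = 2.0,
                 direction_deg: float = 0.0) -> GratingSpec:
    """Parametric drifting grating (defaults: Table-1 stimulus values,
    psi = 2*pi*0.5 rad/deg and omega = 2*pi*2 rad/s)."""
    return GratingSpec(contrast, spatial_freq, temporal_freq, direction_deg)


def make_sparse_noise(patch_half_width: float, square_size: float = 1.0,
                      grid_spacing: float = 0.25, duration: float = 0.05,
                      contrast: float = 1.0) -> list[FlashSpec]:
    """Sparse-noise protocol: one flash per (grid location, polarity).

    Squares of side ``square_size`` are flashed at the nodes of a square
    grid with the given spacing, for ``duration`` seconds, at contrast
    +/-``contrast``, each on its own zero-background trial.
    """
    margin = patch_half_width - square_size / 2
    if margin < 0:
        raise ValueError("square does not fit in patch")
    n = int(np.floor(margin / grid_spacing + 1e-9))
    nodes = np.arange(-n, n + 1) * grid_spacing
    if nodes.size == 0:
        raise ValueError("no grid nodes inside patch")
    flashes = []
    for c in (abs(contrast), -abs(contrast)):
        for y0 in nodes:
            for x0 in nodes:
                flashes.append(FlashSpec(float(x0), float(y0), square_size,
                                         float(c), duration))
    return flashes
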