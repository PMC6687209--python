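"""Receptive-field estimation from sparse noise.

Light and dark squares are flashed one location at a time on a zero
background, the model is simulated from rest for each trial, and the
peak excitatory impulse rate per trial is compiled into per-polarity
maps. Iso-rate contours at fractions of each polarity's peak outline the
on and off subfields; thresholding makes the receptive fields smaller
than the corresponding weight maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .dynamics import Model, simulate
from .stimuli import FlashSpec


@dataclass
class RFMap:
    """Sparse-noise receptive field of one neuron: peak impulse rate (Hz)
    per stimulus-grid location and polarity."""

    x: np.ndarray                 # stimulus grid axis (deg)
    y: np.ndarray
    light: np.ndarray             # (ny, nx) peak rates, light squares
    dark: np.ndarray              # (ny, nx) peak rates, dark squares

    @property
    def peak_light(self) -> float:
        return float(self.light.max())

    @property
    def peak_dark(self) -> float:
        return float(self.dark.max())


def map_receptive_field(model: Model, flashes: list[FlashSpec],
                        neurons, dt: float = 0.001,
                        T: float = 0.3) -> dict[int, RFMap]:
    """Map receptive fields of the selected excitatory neurons.

    Each flash is simulated independently with the model at rest as the
    initial condition; the peak rate over the whole trial (flash plus
    decay) is recorded. Returns {neuron index: RFMap}.
    """
    neurons = np.atleast_1d(np.asarray(neurons, dtype=int))
    n_nodes = len(model.sheet)
    if neurons.min() < 0 or neurons.max() >= n_nodes:
        raise IndexError("neuron index out of range")

    xs = np.unique([f.x0 for f in flashes])
    ys = np.unique([f.y0 for f in flashes])
    ix = {v: i for i, v in enumerate(xs)}
    iy = {v: i for i, v in enumerate(ys)}
    maps = {k: {+1: np.zeros((ys.size, xs.size)),
                -1: np.zeros((ys.size, xs.size))} for k in neurons}

    for f in flashes:
        rs = simulate(model, f, dt=dt, T=T, record_stages=(7,),
                      init="rest")
        rates = rs.rates(7)[:, neurons]          # (n_t, n_sel)
        peak = rates.max(axis=0)
        pol = 1 if f.contrast >= 0 else -1
        for k, v in zip(neurons, peak):
            maps[int(k)][pol][iy[f.y0], ix[f.x0]] = v

    return {int(k): RFMap(xs, ys, maps[k][+1], maps[k][-1])
            for k in neurons}


def contour_rf(rf: RFMap, levels=(0.05, 0.5, 0.95)) -> dict:
    """Iso-rate contours per polarity at fractions of that polarity's
    peak rate.

    Contours are traced by marching squares with linear sub-grid
    interpolation and returned in stimulus-grid coordinates (deg):
    {polarity: {level: [contour arrays (n, 2) of (x, y)]}}. An all-zero
    map yields empty contour sets.
    """
    out: dict[int, dict] = {}
    dx = float(np.mean(np.diff(rf.x))) if rf.x.size > 1 else 1.0
    dy = float(np.mean(np.diff(rf.y))) if rf.y.size > 1 else 1.0
    for pol, field in ((+1, rf.light), (-1, rf.dark)):
        peak = field.max()
        out[pol] = {}
        for lev in levels:
            if peak <= 0:
                out[pol][lev] = []
                continue
            raw = measure.find_contours(field, lev * peak)
            out[pol][lev] = [
                np.column_stack([rf.x[0] + c[:, 1] * dx,
                                 rf.y[0] + c[:, 0] * dy])
                for c in raw
            ]
    return out


def suprathreshold_area(field: np.ndarray, spacing: float,
                        fraction: float = 0.05) -> float:
    """Area (deg^2) where the map exceeds ``fraction`` of its peak."""
    peak = field.max()
    if peak <= 0:
        return 0.0
    return float(np.sum(field > fraction * peak)) * spacing**2
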