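"""Time-domain simulation of the seven-stage subcortical-cortical cascade.

Stages 1-4 form the subcortical channels (photoreceptor, bipolar cell,
ganglion cell, geniculate relay cell), stages 5-7 the cortex (inhibitory
soma, inhibitory axon/network, excitatory neuron). Each stage is a driven
first-order low-pass filter of its rectified input,

    tau dp/dt = drive(t) - p(t),        a(t) = g_rect * max(p, 0),

with the drive of the cortical stages a Gaussian-weighted convergence of
the upstream stage. The convergence sums carry the area-per-source
quadrature element, so the total gain of geniculocortical convergence is
g_c and of inhibitory-excitatory convergence g_e (the same normalisation
the centre mechanism obeys: its integral over the plane equals g_s).

Integration uses an exponential update per stage and step, exact for
piecewise-constant drive; the drive over each step is taken as the average
of its start and end values, which makes the scheme second-order accurate
in dt for smooth stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams
from .mosaic import ChannelArray

SPIKING_STAGES = (3, 4, 5, 7)


def rectify(p, g_rect: float = 7.2):
    """Impulse rate from generator potential: a = g_rect * max(p, 0)."""
    return g_rect * np.maximum(p, 0.0)


def relu(p):
    return np.maximum(p, 0.0)


def gaussian_gain(center_xy, point_xy, g: float, r: float):
    """Gaussian weighting profile (g/(pi r^2)) exp(-d^2/r^2).

    The same form serves the stimulus centre mechanism (g_s, r_s), the
    geniculocortical convergence (g_c, r_c) and the inhibitory-excitatory
    convergence (g_e, r_e); its integral over the plane is g.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    cx, cy = center_xy
    px, py = point_xy
    d2 = (np.asarray(px) - cx) ** 2 + (np.asarray(py) - cy) ** 2
    return (g / (np.pi * r**2)) * np.exp(-d2 / r**2)


@dataclass
class CorticalSheet:
    """Square grid of cortical nodes with a node at the patch centre; one
    excitatory and one inhibitory neuron per node."""

    half_width: float
    spacing: float
    x: np.ndarray = field(init=False)
    y: np.ndarray = field(init=False)
    shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        n = int(np.floor(self.half_width / self.spacing + 1e-9))
        ax = np.arange(-n, n + 1) * self.spacing
        gx, gy = np.meshgrid(ax, ax, indexing="xy")
        self.x = gx.ravel()
        self.y = gy.ravel()
        self.shape = gx.shape
        self.axis = ax

    def __len__(self) -> int:
        return self.x.size

    def central_mask(self, half: float) -> np.ndarray:
        """Boolean mask of nodes within the central ``2*half`` square."""
        return (np.abs(self.x) <= half + 1e-9) & \
               (np.abs(self.y) <= half + 1e-9)


def convergence_matrix(sheet: CorticalSheet, channels: ChannelArray,
                       g: float, r: float, truncate: float | None = 3.0,
                       dtype=np.float64) -> np.ndarray:
    """Geniculocortical convergence weights, shape (n_nodes, n_channels).

    Includes the area-per-channel quadrature element, so each row sums to
    about g for interior nodes. Entries beyond ``truncate`` radii are
    dropped (relative weight < e^-9 at the default 3)."""
    area = channels.spec.patch_width ** 2 / len(channels)
    d2 = (sheet.x[:, None] - channels.x[None, :]) ** 2 + \
         (sheet.y[:, None] - channels.y[None, :]) ** 2
    G = (g / (np.pi * r**2)) * np.exp(-d2 / r**2) * area
    if truncate is not None:
        G[d2 > (truncate * r) ** 2] = 0.0
    return G.astype(dtype)


def pooling_matrix(sheet: CorticalSheet, g: float, r: float) -> np.ndarray:
    """One-dimensional factor of the inhibitory pooling operator.

    The Gaussian convergence g_ke is separable, so pooling the stage-6
    field F over the cortical grid is two matrix products P @ F @ P.T
    with P the 1-D convolution matrix below (grid-cell area element
    included; total gain g). Exact — no truncation."""
    ax = sheet.axis
    d2 = (ax[:, None] - ax[None, :]) ** 2
    return np.sqrt(g / (np.pi * r**2)) * np.exp(-d2 / r**2) * sheet.spacing


def pool_field(field: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Apply the separable pooling operator to (..., ny, nx) fields."""
    return P @ field @ P.T


@dataclass
class Model:
    """Bundle of everything the solvers need: parameters, channel array,
    cortical sheet, geniculocortical weights and the current
    inhibitory-to-excitatory gain (ramped during development)."""

    params: ModelParams
    channels: ChannelArray
    sheet: CorticalSheet
    weights: np.ndarray | None = None   # (n_nodes, n_channels) in [0, 2]
    inhibitory_gain: float | None = None  # None -> mature g_e

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights)
            if w.shape != (len(self.sheet), len(self.channels)):
                raise ValueError("weights must be (n_nodes, n_channels)")
            if w.min() < 0 or w.max() > 2:
                raise ValueError("weights must lie in [0, 2]")

    @property
    def gain_e(self) -> float:
        return self.params.g_e if self.inhibitory_gain is None \
            else self.inhibitory_gain

    def geniculocortical(self, dtype=np.float64) -> np.ndarray:
        """Effective drive matrix G_kc * w_jk (weights applied)."""
        G = convergence_matrix(self.sheet, self.channels,
                               self.params.g_c, self.params.r_c, dtype=dtype)
        if self.weights is not None:
            G = G * self.weights.astype(dtype)
        return G


def default_model(spec_or_channels, params: ModelParams | None = None,
                  weights: np.ndarray | None = None,
                  inhibitory_gain: float | None = None) -> Model:
    """Convenience constructor pairing a mosaic with its cortical sheet."""
    from .mosaic import build_channel_array
    from .params import MosaicSpec
    if isinstance(spec_or_channels, MosaicSpec):
        channels = build_channel_array(spec_or_channels)
    else:
        channels = spec_or_channels
    params = params or ModelParams()
    sheet = CorticalSheet(channels.spec.patch_half_width,
                          params.cortical_spacing)
    return Model(params, channels, sheet, weights, inhibitory_gain)


@dataclass
class ResponseSet:
    """Per-stage generator potentials over time.

    ``potentials[z]`` has shape (n_t, n_channels) for subcortical stages
    z = 1..4 and (n_t, n_nodes) for cortical stages z = 5..7. Stages 1-2
    carry no impulse rate (photoreceptors and bipolar cells do not spike).
    """

    t: np.ndarray
    potentials: dict[int, np.ndarray]
    params: ModelParams

    def rates(self, stage: int) -> np.ndarray:
        if stage not in SPIKING_STAGES:
            raise ValueError(f"stage {stage} does not produce impulses")
        return rectify(self.potentials[stage], self.params.g_rect)


def resting_state(model: Model, GW: np.ndarray | None = None,
                  P: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Fixed point of the cascade under zero contrast.

    Stages 1-2 relax to zero, stage 3 to p_s, geniculate output to the
    resting rate g_rect*p_s (~14 Hz); inhibitory neurons inherit the pooled
    depolarisation and hyperpolarise the excitatory cells below threshold.
    """
    p = model.params
    n_ch, n_k = len(model.channels), len(model.sheet)
    if GW is None:
        GW = model.geniculocortical()
    if P is None:
        P = pooling_matrix(model.sheet, 1.0, p.r_e)
    rest = {1: np.zeros(n_ch), 2: np.zeros(n_ch),
            3: np.full(n_ch, p.p_s), 4: np.full(n_ch, p.p_s)}
    feed = GW @ relu(rest[4])
    rest[5] = feed
    rest[6] = relu(feed)
    pooled = pool_field(rest[6].reshape(model.sheet.shape), P)
    rest[7] = feed - model.gain_e * pooled.ravel()
    return rest


def simulate(model: Model, stimulus, dt: float = 0.001, T: float = 1.0,
             record_stages=(1, 2, 3, 4, 5, 6, 7), record_every: int = 1,
             init: str = "rest") -> ResponseSet:
    """Integrate all seven stages simultaneously under ``stimulus``.

    Parameters
    ----------
    stimulus : object with a ``channel_drive(t, params, channels)`` method
        (grating, flash or movie).
    dt : time step (s); must satisfy dt <= min(tau_j)/5 for accuracy.
    T : duration (s).
    init : 'rest' starts from the zero-contrast fixed point, 'zero' from
        all-zero potentials.
    """
    p = model.params
    tau_min = min(p.tau, p.tau_on, p.tau_off)
    if dt > tau_min / 5 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; need dt <= {tau_min / 5:.4g}")
    if hasattr(stimulus, "covers") and \
            not stimulus.covers(model.channels.spec.patch_half_width):
        raise ValueError("stimulus grid does not cover the patch")

    channels = model.channels
    n_ch, n_k = len(channels), len(model.sheet)
    tau_j = channels.tau(p.tau_on, p.tau_off)
    GW = model.geniculocortical()
    P = pooling_matrix(model.sheet, 1.0, p.r_e)
    gain_e = model.gain_e

    # per-stage exponential relaxation factors
    decay = {"tau": np.exp(-dt / p.tau), "inh": np.exp(-dt / p.tau_inh)}
    decay_j = np.exp(-dt / tau_j)

    if init == "rest":
        rest = resting_state(model, GW, P)
        p1, p2, p3, p4 = (rest[z].copy() for z in (1, 2, 3, 4))
        p5, p6, p7 = (rest[z].copy() for z in (5, 6, 7))
    elif init == "zero":
        p1 = np.zeros(n_ch); p2 = np.zeros(n_ch)
        p3 = np.zeros(n_ch); p4 = np.zeros(n_ch)
        p5 = np.zeros(n_k); p6 = np.zeros(n_k); p7 = np.zeros(n_k)
    else:
        raise ValueError("init must be 'rest' or 'zero'")

    n_steps = int(round(T / dt))
    rec_idx = np.arange(0, n_steps + 1, record_every)
    n_rec = rec_idx.size
    out = {z: np.empty((n_rec, n_ch if z <= 4 else n_k))
           for z in record_stages}
    t_rec = rec_idx * dt

    def step_lp(p_old, decay_fac, drive):
        return p_old * decay_fac + (1.0 - decay_fac) * drive

    def record(i_rec):
        state = {1: p1, 2: p2, 3: p3, 4: p4, 5: p5, 6: p6, 7: p7}
        for z in record_stages:
            out[z][i_rec] = state[z]

    drive_old = stimulus.channel_drive(0.0, p, channels)
    feed_old = GW @ relu(p4)
    pooled_old = pool_field(p6.reshape(model.sheet.shape), P).ravel()
    i_rec = 0
    if rec_idx[0] == 0:
        record(0)
        i_rec = 1

    for n in range(n_steps):
        t_new = (n + 1) * dt
        drive_new = stimulus.channel_drive(t_new, p, channels)
        # stage 1: photoreceptor, hyperpolarised by light
        p1_new = step_lp(p1, decay["tau"], -0.5 * (drive_old + drive_new))
        # stage 2: bipolar, channel-sign flip
        u2 = -channels.sign * 0.5 * (p1 + p1_new)
        p2_new = step_lp(p2, decay_j, u2)
        # stage 3: ganglion cell, resting depolarisation p_s
        u3 = 0.5 * (p2 + p2_new) + p.p_s
        p3_new = step_lp(p3, decay_j, u3)
        # stage 4: geniculate relay, rectifies its input
        u4 = 0.5 * (relu(p3) + relu(p3_new))
        p4_new = step_lp(p4, decay_j, u4)
        # stage 5: inhibitory soma, weighted geniculate convergence
        feed_new = GW @ relu(p4_new)
        u5 = 0.5 * (feed_old + feed_new)
        p5_new = step_lp(p5, decay["tau"], u5)
        # stage 6: inhibitory axon/network, slow integration
        u6 = 0.5 * (relu(p5) + relu(p5_new))
        p6_new = step_lp(p6, decay["inh"], u6)
        # stage 7: excitatory cell = feedforward drive minus pooled inhibition
        pooled_new = pool_field(p6_new.reshape(model.sheet.shape),
                                P).ravel()
        u7 = u5 - gain_e * 0.5 * (pooled_old + pooled_new)
        p7_new = step_lp(p7, decay["tau"], u7)

        p1, p2, p3, p4, p5, p6, p7 = (p1_new, p2_new, p3_new, p4_new,
                                      p5_new, p6_new, p7_new)
        drive_old, feed_old, pooled_old = drive_new, feed_new, pooled_new
        if i_rec < n_rec and rec_idx[i_rec] == n + 1:
            record(i_rec)
            i_rec += 1

    return ResponseSet(t_rec, out, p)
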