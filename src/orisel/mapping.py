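"""Orientation tuning and orientation-preference map analysis.

Covers: direction tuning of every cortical node under drifting gratings,
double-von-Mises tuning fits with half-width-at-half-height bandwidths,
relative modulation (F1/F0), orientation-preference maps, their Fourier
periodicity and pinwheel statistics, the Gabor-bank prediction of the map
from the bare mosaic, and the subcortical difference-map periodicity
analyses that trace the map's spatial scale back to the retina.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .params import ModelParams, CORTICAL_MAGNIFICATION_MM2_PER_DEG2
from .mosaic import ChannelArray
from .dynamics import Model, CorticalSheet
from .spectral import GratingBankSolver

# --------------------------------------------------------------- tuning


def probe_directions(n: int = 16) -> np.ndarray:
    """n motion directions evenly distributed over 360 deg."""
    return np.arange(n) * (360.0 / n)


def measure_tuning(model: Model, n_directions: int = 16,
                   gain: float | None = None,
                   n_samples: int = 128, n_harmonics: int = 32,
                   solver: GratingBankSolver | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Peak steady-state excitatory rate per node and motion direction.

    Returns (directions_deg, responses) with responses shaped
    (n_nodes, n_directions)."""
    directions = probe_directions(n_directions)
    if solver is None:
        solver = GratingBankSolver(model, directions,
                                   n_samples=n_samples,
                                   n_harmonics=n_harmonics)
    responses = solver.responses(model.weights, gain)
    return directions, responses


def relative_modulation(trace: np.ndarray) -> float:
    """F1/F0 of one steady-state response cycle: fundamental Fourier
    amplitude of the impulse rate divided by its mean.

    Lies in [0, 2]; a constant rate gives 0, a half-wave-rectified
    sinusoid pi/2, and a single-bin impulse train approaches 2. Undefined
    (nan) for zero mean rate.
    """
    trace = np.asarray(trace, dtype=float)
    f0 = trace.mean()
    if f0 <= 0:
        return float("nan")
    f1 = 2.0 * np.abs(np.fft.rfft(trace)[1]) / trace.size
    return float(f1 / f0)


# ------------------------------------------------------ von Mises fitting

def double_von_mises(theta_deg, baseline, amp1, amp2, pref_deg, kappa):
    """Sum of two von Mises lobes separated by 180 deg (peak-normalised
    lobes: each attains its amplitude at its centre)."""
    d = np.radians(np.asarray(theta_deg, dtype=float) - pref_deg)
    return (baseline
            + amp1 * np.exp(kappa * (np.cos(d) - 1.0))
            + amp2 * np.exp(kappa * (np.cos(d - np.pi) - 1.0)))


def von_mises_hwhh_deg(kappa: float) -> float:
    """Closed-form half width at half height (deg) of a single von Mises
    lobe, with half height midway between the lobe's peak and its
    antipodal minimum."""
    return math.degrees(
        math.acos(1.0 + math.log((1.0 + math.exp(-2.0 * kappa)) / 2.0)
                  / kappa))


def hwhh_from_curve(theta_deg: np.ndarray, values: np.ndarray) -> float:
    """Half width at half height (deg) of a densely evaluated periodic
    tuning curve; half height is midway between the curve's maximum and
    minimum."""
    theta_deg = np.asarray(theta_deg)
    values = np.asarray(values)
    n = values.size
    half = 0.5 * (values.max() + values.min())
    i_pk = int(values.argmax())
    step = float(np.mean(np.diff(theta_deg)))

    def extent(direction: int) -> float:
        for k in range(1, n):
            if values[(i_pk + direction * k) % n] < half:
                return (k - 0.5) * step
        return 180.0
    return 0.5 * (extent(+1) + extent(-1))


@dataclass
class VonMisesFit:
    baseline: float
    amp1: float
    amp2: float
    pref_deg: float      # centre of lobe 1; lobe 2 sits at pref+180
    kappa: float
    hwhh_deg: float
    residual: float
    converged: bool

    @property
    def preferred_direction_deg(self) -> float:
        """Direction of the taller fitted lobe."""
        pref = self.pref_deg if self.amp1 >= self.amp2 \
            else self.pref_deg + 180.0
        return pref % 360.0

    @property
    def preferred_orientation_deg(self) -> float:
        return self.preferred_direction_deg % 180.0

    def __call__(self, theta_deg):
        return double_von_mises(theta_deg, self.baseline, self.amp1,
                                self.amp2, self.pref_deg, self.kappa)


def fit_double_von_mises(directions_deg: np.ndarray,
                         responses: np.ndarray,
                         n_starts: int = 8) -> VonMisesFit:
    """Least-squares fit of the double-von-Mises tuning model, with
    multiple starts over the preferred direction."""
    x = np.asarray(directions_deg, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 directions to fit")
    lo, hi = float(y.min()), float(y.max())
    span = max(hi - lo, 1e-12)

    def residual(params):
        b, a1, a2, pref, kappa = params
        return double_von_mises(x, b, a1, a2, pref, kappa) - y

    starts = [float(x[int(y.argmax())])]
    starts += list(np.linspace(0.0, 360.0, n_starts, endpoint=False))
    best = None
    for pref0 in starts:
        opp = double_von_mises(np.array([pref0 + 180.0]), 0, 0, 0, 0, 1)
        y_opp = float(np.interp((pref0 + 180.0) % 360.0,
                                np.sort(x), y[np.argsort(x)], period=360.0))
        p0 = [lo, span, max(y_opp - lo, 0.1 * span), pref0, 2.0]
        try:
            sol = optimize.least_squares(
                residual, p0,
                bounds=([0.0, 0.0, 0.0, -360.0, 1e-3],
                        [hi + span, 10 * span, 10 * span, 720.0, 500.0]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return VonMisesFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                           np.nan, np.inf, False)
    b, a1, a2, pref, kappa = best.x
    grid = np.arange(0.0, 360.0, 0.05)
    hwhh = hwhh_from_curve(grid,
                           double_von_mises(grid, b, a1, a2, pref, kappa))
    return VonMisesFit(b, a1, a2, pref % 360.0, kappa, hwhh,
                       float(best.cost), bool(best.success))


# ------------------------------------------------------- orientation maps

@dataclass
class OrientationMap:
    """Preferred orientation per cortical grid node.

    ``orientation_deg`` is an (ny, nx) array with values in [0, 180) (nan
    marks unfit nodes); ``spacing`` is the grid spacing in deg, with the
    grid centred on the patch centre. ``amplitude`` optionally carries the
    peak response per node.
    """

    orientation_deg: np.ndarray
    spacing: float
    amplitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.orientation_deg = np.mod(self.orientation_deg, 180.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.orientation_deg.shape

    def doubled_angle(self) -> np.ndarray:
        """2*orientation in radians (direction-free angle)."""
        return np.radians(2.0 * self.orientation_deg)

    def crop(self, crop_deg: float) -> np.ndarray:
        """Central square of side ``crop_deg``, returned as an n x n array
        with n = round(crop/spacing) (so FFT frequency bins are multiples
        of 1/crop)."""
        n = int(round(crop_deg / self.spacing))
        ny, nx = self.shape
        if n > min(ny, nx):
            raise ValueError("crop larger than map")
        y0 = (ny - n) // 2
        x0 = (nx - n) // 2
        return self.orientation_deg[y0:y0 + n, x0:x0 + n]


def preferred_orientation_map(directions_deg: np.ndarray,
                              responses: np.ndarray,
                              sheet: CorticalSheet) -> OrientationMap:
    """Map of preferred orientation from the maximum of each node's
    direction tuning curve, folded modulo 180 deg.

    The preferred motion direction is converted to the orientation of the
    grating's bars (perpendicular to motion) and folded modulo 180 deg.
    Nodes that never respond (all-zero tuning curve, possible after
    development when inhibition silences a cell) carry nan and are
    excluded from map correlations."""
    responses = np.asarray(responses)
    idx = responses.argmax(axis=-1)
    pref = (np.asarray(directions_deg)[idx] + 90.0) % 180.0
    amp = responses.max(axis=-1)
    pref = np.where(amp > 0, pref, np.nan)
    return OrientationMap(pref.reshape(sheet.shape), sheet.spacing,
                          amp.reshape(sheet.shape))


def _radial_peak(field: np.ndarray, spacing: float) -> float:
    """Radial spatial frequency (cycles/deg) of the peak FFT magnitude,
    DC suppressed."""
    F = np.abs(np.fft.fft2(field))
    F[0, 0] = 0.0
    fy = np.fft.fftfreq(field.shape[0], d=spacing)
    fx = np.fft.fftfreq(field.shape[1], d=spacing)
    i, j = np.unravel_index(int(F.argmax()), F.shape)
    return float(np.hypot(fy[i], fx[j]))


def map_periodicity(omap: OrientationMap, crop_deg: float = 5.0) -> dict:
    """Fourier periodicity of the orientation map.

    Each orientation becomes a doubled-angle unit vector; the real and
    imaginary parts of the cropped vector map are Fourier transformed
    (DC suppressed) and the radial location of each peak magnitude found.
    Periodicity is the reciprocal of the peak frequency; conversion to
    cortical mm uses the areal magnification factor (0.45 mm^2/deg^2).
    """
    n = int(round(crop_deg / omap.spacing))
    ny, nx = omap.shape
    if n > min(ny, nx):
        raise ValueError("crop larger than map")
    y0, x0 = (ny - n) // 2, (nx - n) // 2
    z = np.exp(1j * omap.doubled_angle()[y0:y0 + n, x0:x0 + n])
    z = np.where(np.isfinite(z), z, 0.0)  # silent nodes: zero vector
    peak_re = _radial_peak(z.real, omap.spacing)
    peak_im = _radial_peak(z.imag, omap.spacing)
    peak = 0.5 * (peak_re + peak_im)
    periodicity = 1.0 / peak if peak > 0 else float("nan")
    return {
        "peak_freq_real": peak_re,
        "peak_freq_imag": peak_im,
        "peak_freq": peak,
        "periodicity_deg": periodicity,
        "periodicity_mm":
            periodicity * math.sqrt(CORTICAL_MAGNIFICATION_MM2_PER_DEG2),
    }


def count_pinwheels(omap: OrientationMap, crop_deg: float = 5.0,
                    n_bins: int | None = 8,
                    smooth_sd: float | None = None) -> dict:
    """Pinwheel count and density in the central crop.

    A pinwheel is a 2x2 plaquette of grid nodes around which the doubled
    orientation angle winds by +/-360 deg (the discrete version of "at
    least three orientations contiguous around a point"). The doubled-
    angle vector field is first smoothed circularly with ``smooth_sd``
    (deg; default one grid spacing) so that sampling jitter from a finite
    direction bank does not masquerade as singularities, then the angle is
    discretised into ``n_bins`` bins (None = no binning). ``smooth_sd=0``
    disables smoothing.
    """
    theta = omap.crop(crop_deg).astype(float)
    if smooth_sd is None:
        smooth_sd = omap.spacing
    if smooth_sd > 0:
        z = np.exp(2j * np.radians(theta))
        z = np.where(np.isfinite(z), z, 0.0)
        sig = smooth_sd / omap.spacing
        z = ndimage.gaussian_filter(z.real, sig) + \
            1j * ndimage.gaussian_filter(z.imag, sig)
        theta = np.degrees(np.angle(z)) / 2.0 % 180.0
    else:
        theta = np.where(np.isfinite(theta), theta, 0.0)
    if n_bins:
        width = 180.0 / n_bins
        theta = (np.floor(theta / width) + 0.5) * width
    phi = 2.0 * theta  # doubled angle, deg, period 360

    def wrap(d):
        return (d + 180.0) % 360.0 - 180.0

    a = phi[:-1, :-1]
    b = phi[:-1, 1:]
    c = phi[1:, 1:]
    d = phi[1:, :-1]
    winding = wrap(b - a) + wrap(c - b) + wrap(d - c) + wrap(a - d)
    charge = np.rint(winding / 360.0).astype(int)
    count = int(np.sum(charge != 0))
    area = crop_deg**2
    return {
        "count": count,
        "charge": charge,
        "density_per_deg2": count / area,
    }


def map_correlation(a, b, n_permutations: int = 0,
                    rng: np.random.Generator | None = None):
    """Circular association between two orientation maps.

    Orientations are doubled and the Pearson correlation computed jointly
    over the stacked (cos 2theta, sin 2theta) components. Identical maps
    give r = 1; maps differing by 90 deg everywhere give r = -1. With
    ``n_permutations`` > 0 a permutation p-value (shuffled node
    correspondence) is also returned.
    """
    ta = np.radians(2.0 * np.asarray(a, dtype=float).ravel())
    tb = np.radians(2.0 * np.asarray(b, dtype=float).ravel())
    if ta.shape != tb.shape:
        raise ValueError("maps must share a grid")
    ok = np.isfinite(ta) & np.isfinite(tb)
    ta, tb = ta[ok], tb[ok]

    def stack(t):
        return np.concatenate([np.cos(t), np.sin(t)])

    def pearson(u, v):
        if u.size < 4:
            return float("nan")
        u = u - u.mean()
        v = v - v.mean()
        denom = np.sqrt((u @ u) * (v @ v))
        if denom == 0:
            return float("nan")
        return float(u @ v / denom)

    r = pearson(stack(ta), stack(tb))
    if n_permutations <= 0:
        return r
    rng = rng or np.random.default_rng(0)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(tb.size)
        null[i] = pearson(stack(ta), stack(tb[perm]))
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_permutations + 1))
    return r, p


# ------------------------------------------- map prediction from mosaic

def gabor_bank_response(channels: ChannelArray, points_xy: np.ndarray,
                        sd: float = 0.7, spatial_freq: float = 0.5,
                        n_orientations: int = 8,
                        n_phases: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Dot products of the on/off impulse mosaic with a stationary Gabor
    bank centred at each probe point.

    Channels act as unit impulses of value +1 (on) or -1 (off), so the
    dot product reduces to an exact sum of Gabor values at the channel
    locations (no rasterisation needed). The orientation label is the
    direction of the Gabor's bars; the carrier varies perpendicular to
    it. Returns (orientations_deg, responses) with responses shaped
    (n_points, n_orientations, n_phases).
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    psi = 2.0 * np.pi * spatial_freq
    sign = channels.sign.astype(float)
    d2 = (pts[:, 0:1] - channels.x[None, :]) ** 2 + \
         (pts[:, 1:2] - channels.y[None, :]) ** 2
    env = np.exp(-d2 / (2.0 * sd**2)) * sign[None, :]
    orientations = np.arange(n_orientations) * (180.0 / n_orientations)
    phases = np.arange(n_phases) * (2.0 * np.pi / n_phases)
    out = np.empty((len(pts), n_orientations, n_phases))
    for i, th_bar in enumerate(np.radians(orientations)):
        th = th_bar + np.pi / 2.0  # carrier axis, perpendicular to bars
        u_ch = np.cos(th) * channels.x + np.sin(th) * channels.y
        u_pt = np.cos(th) * pts[:, 0] + np.sin(th) * pts[:, 1]
        C = (env * np.exp(1j * psi * u_ch)[None, :]).sum(axis=1) * \
            np.exp(-1j * psi * u_pt)
        out[:, i, :] = np.real(C[:, None] *
                               np.exp(1j * phases)[None, :])
    return orientations, out


def predict_map_from_mosaic(channels: ChannelArray,
                            sheet: CorticalSheet,
                            sd: float = 0.7, spatial_freq: float = 0.5,
                            n_orientations: int = 8,
                            n_phases: int = 8) -> OrientationMap:
    """Orientation-preference map predicted from the mosaic alone: at each
    node, the orientation of the Gabor (over orientations and phases)
    most co-aligned with the local on/off impulse pattern."""
    pts = np.column_stack([sheet.x, sheet.y])
    orientations, resp = gabor_bank_response(
        channels, pts, sd, spatial_freq, n_orientations, n_phases)
    best = resp.reshape(len(pts), -1).argmax(axis=1)
    pref = orientations[best // n_phases]
    return OrientationMap(pref.reshape(sheet.shape), sheet.spacing)


# ------------------------------------- subcortical difference-map analyses

def onoff_difference_map(channels: ChannelArray, smoothing_sd: float = 0.1,
                         raster: float = 0.02,
                         pad: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed on-minus-off impulse density field.

    On (off) channels contribute +1 (-1) impulses of unit mass; the field
    is a density (integral = n_on - n_off), smoothed with an isotropic
    Gaussian of the given standard deviation. The raster extends ``pad``
    beyond the patch (default 4 smoothing SDs plus room for perturbed
    outliers) so no impulse mass is lost at the boundary. Returns
    (field, axis)."""
    if pad is None:
        pad = 4.0 * smoothing_sd + 0.2
    half = channels.spec.patch_half_width + pad
    n = int(round(2 * half / raster))
    axis = (np.arange(n) + 0.5) * raster - half
    ix = np.clip(((channels.x + half) / raster).astype(int), 0, n - 1)
    iy = np.clip(((channels.y + half) / raster).astype(int), 0, n - 1)
    field = np.zeros((n, n))
    np.add.at(field, (iy, ix), channels.sign / raster**2)
    if smoothing_sd > 0:
        field = ndimage.gaussian_filter(field, smoothing_sd / raster,
                                        mode="constant")
    return field, axis


def subcortical_periodicity(channels: ChannelArray, r_s: float = 0.4,
                            raster: float = 0.02,
                            crop_deg: float | None = None) -> float:
    """Radial frequency (cycles/deg) of the peak Fourier magnitude of the
    on-minus-off impulse map smoothed with the geniculate centre profile
    exp(-d^2/r_s^2) (a Gaussian of SD r_s/sqrt(2)); DC suppressed.

    The transform is taken over the central region (default: 6x6 deg of
    the standard 8 deg patch, or the whole patch if smaller), trimming
    the smoothing boundary."""
    field, axis = onoff_difference_map(channels, smoothing_sd=0.0,
                                       raster=raster)
    field = ndimage.gaussian_filter(field, (r_s / math.sqrt(2.0)) / raster,
                                    mode="constant")
    if crop_deg is None:
        crop_deg = min(6.0, channels.spec.patch_width)
    n = int(round(crop_deg / raster))
    n0 = field.shape[0]
    if n > n0:
        raise ValueError("crop larger than patch")
    a0 = (n0 - n) // 2
    central = field[a0:a0 + n, a0:a0 + n]
    return _radial_peak(central, raster)


def onoff_pair_periodicity(r_s: float) -> tuple[float, float]:
    """Closed-form periodicity implied by differencing the centre profiles
    of a neighbouring on/off pair.

    For a small on/off separation the profile difference approaches the
    derivative of g(x) = exp(-x^2/r_s^2), whose transform magnitude
    |psi exp(-r_s^2 psi^2/4)| peaks at sqrt(2)/(2 pi r_s) cycles/deg.
    Returns (peak frequency in cycles/deg, periodicity in deg)."""
    if r_s <= 0:
        raise ValueError("r_s must be positive")
    f = math.sqrt(2.0) / (2.0 * math.pi * r_s)
    return f, 1.0 / f


def offset_difference_periodicity(r_s: float, offset: float = 0.1,
                                  dx: float = 0.001,
                                  x_max: float = 25.0) -> float:
    """Numerical version of :func:`onoff_pair_periodicity`: the difference
    of two centre profiles offset by ``offset`` deg is Fourier
    transformed and the peak frequency located (parabolic interpolation
    around the peak bin). Returns the peak frequency in cycles/deg."""
    x = np.arange(-x_max, x_max, dx)
    g = np.exp(-((x - offset / 2.0) ** 2) / r_s**2) - \
        np.exp(-((x + offset / 2.0) ** 2) / r_s**2)
    F = np.abs(np.fft.rfft(g))
    freqs = np.fft.rfftfreq(x.size, d=dx)
    i = int(F.argmax())
    if 0 < i < F.size - 1:
        y0, y1, y2 = F[i - 1], F[i], F[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    return float(freqs[i] + shift * (freqs[1] - freqs[0]))


# ----------------------------------------------------------- map summary

@dataclass
class MapSummary:
    """Headline statistics of an orientation map."""

    peak_freq: float            # cycles/deg
    periodicity_deg: float
    periodicity_mm: float
    pinwheel_count: int
    pinwheel_density_per_deg2: float
    pinwheels_per_hypercolumn: float
    crop_deg: float

    def to_dict(self) -> dict:
        return {
            "peak_freq_cycles_per_deg": self.peak_freq,
            "periodicity_deg": self.periodicity_deg,
            "periodicity_mm": self.periodicity_mm,
            "pinwheel_count": self.pinwheel_count,
            "pinwheel_density_per_deg2": self.pinwheel_density_per_deg2,
            "pinwheels_per_hypercolumn": self.pinwheels_per_hypercolumn,
            "crop_deg": self.crop_deg,
        }


def analyze_map(omap: OrientationMap, crop_deg: float = 5.0,
                n_bins: int | None = 8) -> MapSummary:
    """Periodicity and pinwheel summary of an orientation map (central
    crop). Pinwheels per hypercolumn = density x periodicity^2."""
    per = map_periodicity(omap, crop_deg)
    pin = count_pinwheels(omap, crop_deg, n_bins)
    return MapSummary(
        peak_freq=per["peak_freq"],
        periodicity_deg=per["periodicity_deg"],
        periodicity_mm=per["periodicity_mm"],
        pinwheel_count=pin["count"],
        pinwheel_density_per_deg2=pin["density_per_deg2"],
        pinwheels_per_hypercolumn=pin["density_per_deg2"]
        * per["periodicity_deg"] ** 2,
        crop_deg=crop_deg,
    )
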