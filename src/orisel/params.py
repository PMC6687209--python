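"""Model parameters and configuration.

All quantities are expressed in the units used throughout the package:
degrees of visual angle (deg), seconds (s), millivolts (mV), impulses per
second (Hz), and dimensionless contrast. Defaults describe a patch of cat
visual field on the horizontal meridian, 11 deg from the area centralis,
served by the X-type (beta) ganglion-cell pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

TWO_PI = 2.0 * math.pi

#: Retinal magnification factor at 11 deg eccentricity (mm retina per deg).
RETINAL_MAGNIFICATION_MM_PER_DEG = 0.20

#: Mean beta ganglion-cell density at 11 deg eccentricity (cells/mm^2).
BETA_CELL_DENSITY_PER_MM2 = 1275.0

#: On / off cell counts in the reference anatomical sample (Wassle et al.).
ON_SAMPLE_COUNT = 65
OFF_SAMPLE_COUNT = 71

#: Areal cortical magnification at 11 deg eccentricity (mm^2 cortex per deg^2).
CORTICAL_MAGNIFICATION_MM2_PER_DEG2 = 0.45


def xcell_density_per_deg2() -> float:
    """X-cell density in cells/deg^2 from the retinal cell density and
    magnification factor (1275 cells/mm^2 x (0.20 mm/deg)^2 = 51)."""
    return BETA_CELL_DENSITY_PER_MM2 * RETINAL_MAGNIFICATION_MM_PER_DEG**2


def on_off_densities_per_deg2() -> tuple[float, float]:
    """(on, off) X-cell densities in cells/deg^2, splitting the total density
    according to the on/off counts of the reference sample."""
    total = xcell_density_per_deg2()
    n_on, n_off = ON_SAMPLE_COUNT, OFF_SAMPLE_COUNT
    on = total * n_on / (n_on + n_off)
    off = total * n_off / (n_on + n_off)
    return on, off


def resting_depolarisation_mv(resting_rate_hz: float = 14.0,
                              g_rect: float = 7.2) -> float:
    """Static subcortical depolarisation p_s implied by a geniculate resting
    rate (14 Hz) and the rectifier gain (7.2 Hz/mV): 14/7.2 = 1.94 mV."""
    return resting_rate_hz / g_rect


@dataclass(frozen=True)
class ModelParams:
    """Glossary of model parameters (values to two significant figures).

    Attributes
    ----------
    c : stimulus contrast (dimensionless).
    g_s : contrast sensitivity of the subcortical centre mechanism
        (mV per contrast unit); the integral of the centre profile.
    g_c : total gain of geniculocortical convergence (dimensionless).
    g_e : total gain of inhibitory-to-excitatory convergence (dimensionless);
        the mature endpoint of the developmental ramp.
    g_rect : rectifier gain converting generator potential to impulse rate
        (Hz/mV).
    p_s : static subcortical depolarisation (mV) giving ganglion and relay
        cells their resting rate.
    r_s : radius of the centre mechanism (deg).
    r_c : radius of geniculocortical convergence (deg).
    r_e : radius of inhibitory-to-excitatory convergence (deg).
    tau : membrane time constant of stages 1, 5 and 7 (s).
    tau_inh : time constant of the inhibitory axon/network stage 6 (s).
    tau_on, tau_off : subcortical channel time constants, stages 2-4 (s);
        off channels lead on channels.
    spatial_freq : default stimulus spatial frequency (cycles/deg).
    temporal_freq : default stimulus temporal frequency (Hz).
    cortical_spacing : cortical grid spacing (deg).
    """

    c: float = 0.3
    g_s: float = 62.0
    g_c: float = 3.5
    g_e: float = 2.2
    g_rect: float = 7.2
    p_s: float = 1.9
    r_s: float = 0.4
    r_c: float = 0.95
    r_e: float = 0.95
    tau: float = 0.01
    tau_inh: float = 0.2
    tau_on: float = 0.011
    tau_off: float = 0.009
    spatial_freq: float = 0.5
    temporal_freq: float = 2.0
    cortical_spacing: float = 0.1

    def __post_init__(self) -> None:
        for name in ("g_s", "g_c", "g_e", "g_rect", "r_s", "r_c", "r_e",
                     "tau", "tau_inh", "tau_on", "tau_off",
                     "spatial_freq", "temporal_freq", "cortical_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")

    @property
    def psi_stim(self) -> float:
        """Default stimulus spatial frequency in rad/deg (2*pi*0.5)."""
        return TWO_PI * self.spatial_freq

    @property
    def omega_stim(self) -> float:
        """Default stimulus temporal frequency in rad/s (2*pi*2)."""
        return TWO_PI * self.temporal_freq

    def tau_channel(self, sign: int) -> float:
        """Subcortical time constant for channel sign (+1 on, -1 off)."""
        return self.tau_on if sign > 0 else self.tau_off


@dataclass(frozen=True)
class MosaicSpec:
    """Geometry of the on/off subcortical channel mosaic.

    Off channels sit on a square grid (node at patch centre), on channels on
    a half-spacing-offset grid, and every node is perturbed by independent
    Gaussian deviates, emulating the measured beta-cell mosaic statistics.
    """

    patch_half_width: float = 4.0
    on_spacing: float = 0.20
    off_spacing: float = 0.19
    on_perturb_sd: float = 0.038
    off_perturb_sd: float = 0.037
    seed: int = 0

    def __post_init__(self) -> None:
        if self.on_spacing <= 0 or self.off_spacing <= 0:
            raise ValueError("grid spacings must be positive")
        if self.on_perturb_sd < 0 or self.off_perturb_sd < 0:
            raise ValueError("perturbation SDs must be non-negative")
        if self.patch_half_width <= max(self.on_spacing, self.off_spacing):
            raise ValueError("degenerate grid: patch smaller than spacing")

    @property
    def patch_width(self) -> float:
        return 2.0 * self.patch_half_width


@dataclass(frozen=True)
class DevSchedule:
    """Schedule of the Hebbian weight-refinement loop.

    ``n_cycles=None`` resolves to five trial cycles per channel rounded to
    the nearest thousand (16 000 for the 3281-channel standard mosaic).
    """

    n_cycles: int | None = None
    step: float = 0.2
    n_directions: int = 16
    seed: int = 0
    snapshot_every: int | None = None

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("weight step must be positive")
        if self.n_directions < 2:
            raise ValueError("need at least two probe directions")

    def resolve_cycles(self, n_channels: int) -> int:
        if self.n_cycles is not None:
            return int(self.n_cycles)
        return max(1000, round(5 * n_channels / 1000) * 1000)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: mosaic, model, development and seeds."""

    mosaic: MosaicSpec = field(default_factory=MosaicSpec)
    params: ModelParams = field(default_factory=ModelParams)
    schedule: DevSchedule = field(default_factory=DevSchedule)
    scale: str = "full"

    def __post_init__(self) -> None:
        if self.scale not in ("full", "scaled"):
            raise ValueError("scale must be 'full' or 'scaled'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale"] = self.scale
        return d


def scaled_config(seed: int = 0, dev_seed: int | None = None) -> RunConfig:
    """Desk-scale preset: 4x4 deg patch, 0.2 deg cortical spacing, defaults
    otherwise. Used for development runs and tests."""
    if dev_seed is None:
        dev_seed = seed + 1
    return RunConfig(
        mosaic=MosaicSpec(patch_half_width=2.0, seed=seed),
        params=replace(ModelParams(), cortical_spacing=0.2),
        schedule=DevSchedule(seed=dev_seed),
        scale="scaled",
    )


def full_config(seed: int = 0, dev_seed: int | None = None) -> RunConfig:
    """Standard preset: 8x8 deg patch, 0.1 deg cortical spacing (3281
    channels, 6561 cortical nodes)."""
    if dev_seed is None:
        dev_seed = seed + 1
    return RunConfig(
        mosaic=MosaicSpec(seed=seed),
        params=ModelParams(),
        schedule=DevSchedule(seed=dev_seed),
        scale="full",
    )
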