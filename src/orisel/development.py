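"""Hebbian refinement of the geniculocortical weights.

Each development cycle raises all synaptic weights of one randomly chosen
geniculate channel by a fixed step and probes the model with gratings
drifting in evenly spaced directions. Every excitatory cortical neuron
keeps the raise if its maximum response increased relative to the
previous cycle; otherwise that neuron's weight for the channel is set a
step below its previous value. Weights are clamped to [0, 2]. The
inhibitory-to-excitatory gain ramps linearly from 1 to g_e over the run,
mirroring the maturation of intracortical inhibition.

The probe responses are evaluated with the harmonic grating solver; the
drive harmonics are maintained incrementally, so a cycle costs far less
than a full re-simulation (the cascade is feedforward, so the update is
exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import DevSchedule
from .dynamics import Model
from .spectral import GratingBankSolver


def response_metric(responses: np.ndarray) -> np.ndarray:
    """Per-neuron development metric: maximum over probe directions of the
    peak steady-state excitatory impulse rate. ``responses`` has shape
    (..., n_directions)."""
    return np.asarray(responses).max(axis=-1)


def inhibitory_gain(cycle: int, n_cycles: int, g_e: float) -> float:
    """Linear ramp of the inhibitory-to-excitatory gain, 1 at cycle 0 to
    g_e at the final cycle."""
    if n_cycles <= 0:
        return g_e
    return 1.0 + (g_e - 1.0) * cycle / n_cycles


@dataclass
class DevelopmentResult:
    """Outcome of a development run."""

    weights: np.ndarray                  # final (n_nodes, n_channels)
    initial_metric: np.ndarray           # per-neuron max rate at cycle 0
    final_metric: np.ndarray             # per-neuron max rate at final cycle
    directions: np.ndarray
    n_cycles: int
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    metric_history: dict[int, np.ndarray] = field(default_factory=dict)
    accept_fraction: float = float("nan")


def run_development(model: Model, schedule: DevSchedule,
                    solver: GratingBankSolver | None = None,
                    n_samples: int = 64, n_harmonics: int = 16,
                    metric_every: int | None = None,
                    refresh_every: int = 1000,
                    measure: str = "peak") -> DevelopmentResult:
    """Run the Hebbian loop and return the final weight matrix.

    Parameters
    ----------
    solver : optional pre-built :class:`GratingBankSolver`; its directions
        must match the schedule.
    metric_every : store the per-neuron metric every this many cycles
        (always stored at cycle 0 and the final cycle).
    refresh_every : rebuild the drive harmonics from the weight matrix
        every this many cycles to bound incremental round-off.
    measure : response measure compared across cycles, 'peak'
        (instantaneous rate maximum) or 'f1' (rate modulation amplitude).
    """
    n_ch = len(model.channels)
    n_k = len(model.sheet)
    n_cycles = schedule.resolve_cycles(n_ch)
    directions = np.arange(schedule.n_directions) * \
        (360.0 / schedule.n_directions)
    if solver is None:
        solver = GratingBankSolver(model, directions,
                                   n_samples=n_samples,
                                   n_harmonics=n_harmonics)
    else:
        if solver.n_dir != schedule.n_directions:
            raise ValueError("solver directions do not match schedule")
    rng = np.random.default_rng(schedule.seed)
    g_e = model.params.g_e
    step = schedule.step

    W = np.ones((n_k, n_ch))
    D = solver.drive(W)
    prev = response_metric(solver.excitatory_rates(
        D, inhibitory_gain(0, n_cycles, g_e), measure))
    initial = prev.copy()

    snapshots: dict[int, np.ndarray] = {}
    history: dict[int, np.ndarray] = {0: initial.copy()}
    n_accept = 0

    for cycle in range(1, n_cycles + 1):
        gain = inhibitory_gain(cycle, n_cycles, g_e)
        j = int(rng.integers(n_ch))
        old = W[:, j].copy()
        raised = np.clip(old + step, 0.0, 2.0)
        solver.update_drive(D, j, raised - old)
        resp = response_metric(solver.excitatory_rates(D, gain, measure))
        accept = resp > prev
        n_accept += int(accept.sum())
        new = np.where(accept, raised, np.clip(old - step, 0.0, 2.0))
        W[:, j] = new
        if np.array_equal(new, raised):
            prev = resp
        else:
            solver.update_drive(D, j, new - raised)
            prev = response_metric(solver.excitatory_rates(D, gain, measure))
        if refresh_every and cycle % refresh_every == 0:
            D = solver.drive(W)
        if schedule.snapshot_every and cycle % schedule.snapshot_every == 0:
            snapshots[cycle] = W.copy()
        if metric_every and cycle % metric_every == 0:
            history[cycle] = prev.copy()

    history[n_cycles] = prev.copy()
    return DevelopmentResult(
        weights=W, initial_metric=initial, final_metric=prev.copy(),
        directions=directions, n_cycles=n_cycles, snapshots=snapshots,
        metric_history=history,
        accept_fraction=n_accept / (n_cycles * n_k),
    )
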