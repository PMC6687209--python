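"""Frequency-domain solver and time/frequency cross-check."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate

from orisel.params import ModelParams
from orisel.dynamics import Model, simulate
from orisel.stimuli import GratingSpec
from orisel.spectral import (grating_drive, subcortical_harmonics,
                             solve_spectral, crosscheck,
                             GratingBankSolver, eval_amps)


class TestGratingDrive:
    def test_matches_2d_quadrature(self, tiny_model):
        # analytic dot product vs direct integration of the Gaussian
        # against the grating, for one channel at one instant
        p = tiny_model.params
        ch = tiny_model.channels
        g = GratingSpec(direction_deg=25.0)
        amp, phase = grating_drive(g, p, ch)
        j, t = 5, 0.0

        def integrand(y, x):
            w = (p.g_s / (np.pi * p.r_s**2)) * np.exp(
                -((x - ch.x[j]) ** 2 + (y - ch.y[j]) ** 2) / p.r_s**2)
            return w * g.contrast_at(t, np.asarray(x), np.asarray(y))

        val, _ = integrate.dblquad(integrand, -np.inf, np.inf,
                                   -np.inf, np.inf, epsabs=1e-10)
        closed = amp * np.cos(phase[j] - g.omega * t)
        assert abs(val - closed) / abs(closed) < 1e-6

    def test_full_field_limit(self, tiny_model):
        # psi -> 0: the drive amplitude approaches g_s * c
        p = tiny_model.params
        g = GratingSpec(spatial_freq=1e-6)
        amp, _ = grating_drive(g, p, tiny_model.channels)
        assert amp == pytest.approx(p.g_s * g.contrast, rel=1e-6)

    def test_phase_periodicity(self, tiny_model):
        # shifting a channel by one spatial period leaves the phase
        # unchanged modulo 2 pi
        p = tiny_model.params
        g = GratingSpec(direction_deg=0.0)
        ch = tiny_model.channels
        from orisel.mosaic import ChannelArray
        moved = ChannelArray(ch.x + 1.0 / g.spatial_freq, ch.y, ch.sign,
                             ch.spec)
        _, ph_a = grating_drive(g, p, ch)
        _, ph_b = grating_drive(g, p, moved)
        wrapped = np.angle(np.exp(1j * (ph_b - ph_a)))
        np.testing.assert_allclose(wrapped, 0.0, atol=1e-9)


class TestSubcorticalHarmonics:
    def test_halfwave_f1_f0_ratio(self):
        # with zero resting depolarisation the rectified ganglion-cell
        # output is a half-wave-rectified sinusoid: F1/F0 = pi/2
        params = dataclasses.replace(ModelParams(), p_s=1e-12)
        sub = subcortical_harmonics(params, GratingSpec(), 256, 64)
        for sign in (+1, -1):
            C3 = sub[sign][3]
            from orisel.spectral import samples_from_amps, \
                amps_from_samples
            p3 = samples_from_amps(C3, 256)
            C = amps_from_samples(np.maximum(p3, 0.0), 64)
            assert abs(C[1]) / C[0] == pytest.approx(np.pi / 2, rel=1e-3)

    def test_harmonic_tail_negligible(self):
        # energy above the default harmonic budget is tiny
        sub = subcortical_harmonics(ModelParams(), GratingSpec(), 512, 255)
        for sign in (+1, -1):
            power = np.abs(sub[sign]["r4"]) ** 2
            assert power[33:].sum() / power.sum() < 1e-4


class TestSolveSpectral:
    def test_zero_contrast_dc_only(self, tiny_model):
        spec = solve_spectral(tiny_model, GratingSpec(contrast=0.0),
                              n_samples=64, n_harmonics=16)
        assert np.abs(spec.amps[3][:, 1:]).max() < 1e-12
        np.testing.assert_allclose(spec.amps[3][:, 0],
                                   tiny_model.params.p_s)

    def test_linear_limit_transfer_function(self, tiny_model):
        # sub-threshold contrast: no rectification bites, so stage-4 F1
        # equals the closed-form cascade transfer function
        p = tiny_model.params
        g = GratingSpec(contrast=1e-4)
        spec = solve_spectral(tiny_model, g, n_samples=64, n_harmonics=16)
        ch = tiny_model.channels
        amp, phase = grating_drive(g, p, ch)
        w = g.omega
        for j in (0, 7):
            tau_j = p.tau_channel(int(ch.sign[j]))
            H = (1 / (1 + 1j * p.tau * w)) * \
                (1 / (1 + 1j * tau_j * w)) ** 3
            expect = ch.sign[j] * amp * np.exp(-1j * phase[j]) * H
            assert spec.amps[4][j, 1] == pytest.approx(expect, rel=1e-6)

    def test_rejects_non_grating(self, tiny_model):
        from orisel.stimuli import FlashSpec
        with pytest.raises(TypeError):
            solve_spectral(tiny_model, FlashSpec(0, 0))

    def test_steady_state_periodicity(self, tiny_model):
        # reconstructing one period later reproduces the same values
        spec = solve_spectral(tiny_model, GratingSpec(), 128, 32)
        t = np.array([0.01, 0.2])
        a = spec.reconstruct(7, t)
        b = spec.reconstruct(7, t + spec.grating.period)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestCrosscheck:
    def test_time_and_frequency_domains_agree(self, tiny_model):
        dev = crosscheck(tiny_model, GratingSpec(direction_deg=30.0))
        assert dev < 1e-3

    def test_zero_contrast_degenerate(self, tiny_model):
        dev = crosscheck(tiny_model, GratingSpec(contrast=0.0),
                         warmup=1.5)
        assert dev < 1e-3

    def test_perturbed_time_constant_detected(self, tiny_model):
        # negative control: solving the two paths with different tau must
        # blow past the agreement tolerance
        g = GratingSpec(direction_deg=30.0)
        spec = solve_spectral(tiny_model, g)
        wrong = Model(
            dataclasses.replace(tiny_model.params, tau=0.013),
            tiny_model.channels, tiny_model.sheet)
        rs = simulate(wrong, g, dt=0.001, T=2.0 + g.period)
        mask = rs.t > 2.0
        ref = spec.reconstruct(7, rs.t[mask])
        got = rs.potentials[7][mask].T
        dev = np.abs(got - ref).max() / np.abs(ref).max()
        assert dev > 1e-3


class TestGratingBankSolver:
    def test_incremental_drive_update_is_exact(self, tiny_model):
        solver = GratingBankSolver(tiny_model, [0.0, 90.0],
                                   n_samples=64, n_harmonics=16)
        rng = np.random.default_rng(0)
        W = np.ones((len(tiny_model.sheet), len(tiny_model.channels)))
        D = solver.drive(W)
        for _ in range(5):
            j = int(rng.integers(len(tiny_model.channels)))
            dw = rng.uniform(-0.2, 0.2, len(tiny_model.sheet))
            solver.update_drive(D, j, dw)
            W[:, j] += dw
        np.testing.assert_allclose(D, solver.drive(W), atol=1e-4)

    def test_solver_guards(self, tiny_model):
        with pytest.raises(ValueError):
            GratingBankSolver(tiny_model, [0.0], n_harmonics=4)
        with pytest.raises(ValueError):
            GratingBankSolver(tiny_model, [0.0], n_samples=32,
                              n_harmonics=16)
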