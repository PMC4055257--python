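"""Acquisition schedules, measurement models, and the encoding matrix."""

import numpy as np
import pytest

from rotob1.bloch import GAMMA_PROTON, SolverConfig
from rotob1.coil_maps import B1Map
from rotob1.encoding import (
    build_encoding_matrix,
    build_schedule,
    simulate_measurement_bloch,
    simulate_measurement_linear,
)
from rotob1.phantoms import GridSpec, Mask, ScalarImage
from rotob1.rf_pulses import calibrate_amplitude, gauss_pulse, phase_encode_scale

SCFG = SolverConfig(dt=250e-6, n_steps=20)


class TestSchedule:
    def test_reference_configuration(self, pulse5ms):
        sch = build_schedule(64, 64, 1256.0, pulse5ms, dims=2)
        assert sch.n_events == 4096
        assert sch.delta_theta == pytest.approx(5.625)
        # one pulse spans one coil revolution
        assert 1256.0 * pulse5ms.duration == pytest.approx(2 * np.pi, rel=1e-3)

    def test_single_sample_per_rotation(self, pulse5ms):
        sch = build_schedule(8, 1, 1256.0, pulse5ms, dims=2)
        assert sch.n_events == 8
        assert len(sch.t_sample) == 8

    def test_3d_offset_rule(self, pulse5ms):
        sch = build_schedule(21, 4, 628.0, pulse5ms, dims=3)
        assert sch.delta_theta == pytest.approx(360.0 / 441)
        assert sch.delta_theta == pytest.approx(0.8163, rel=1e-3)

    def test_g_schedule_on_events(self, pulse5ms):
        sch = build_schedule(4, 2, 1256.0, pulse5ms)
        expected = [phase_encode_scale(a, 4) for a in (1, 1, 2, 2, 3, 3, 4, 4)]
        np.testing.assert_allclose(sch.g, expected)

    def test_invalid_args(self, pulse5ms):
        with pytest.raises(ValueError):
            build_schedule(0, 4, 1256.0, pulse5ms)
        with pytest.raises(ValueError):
            build_schedule(4, 4, 1256.0, pulse5ms, dims=4)


def _uniform_setup(M=4, i0=8, value=2.5e-9):
    """Single-voxel phantom in a uniform map: closed-form signal."""
    grid = GridSpec(5, 5, 1, 5e-3)
    vals = np.zeros(grid.shape)
    vals[2, 2] = 1.0
    phantom = ScalarImage(grid, vals)
    b1 = B1Map(grid, np.full(grid.shape, value, dtype=complex))
    pulse = gauss_pulse(5e-3, 128, 0.5)
    cal = calibrate_amplitude(pulse, M, value, GAMMA_PROTON, 90.0)
    sch = build_schedule(M, i0, 1256.0, pulse)
    return phantom, b1, cal, sch, pulse


class TestLinearModel:
    def test_zero_phantom(self, grid16, linmap16, cal16, pulse5ms):
        phantom = ScalarImage(grid16, np.zeros(grid16.shape))
        sch = build_schedule(16, 16, 1256.0, pulse5ms)
        D = simulate_measurement_linear(phantom, linmap16, cal16, sch, solver_cfg=SCFG)
        assert not D.any()

    def test_single_voxel_closed_form_instantaneous(self):
        """|D| = sin(flip) for one unit voxel in a uniform map (per-TR model)."""
        phantom, b1, cal, sch, pulse = _uniform_setup()
        D = simulate_measurement_linear(
            phantom, b1, cal, sch, solver_cfg=SCFG, flip_model="instantaneous"
        )
        i0 = sch.samples_per_rotation
        for a in range(1, 5):
            g = phase_encode_scale(a, 4)
            t_k = sch.t_sample[:i0]
            flips = cal.gamma * g * cal.amplitude_scale * pulse.cumulative_integral_at(t_k) * 2.5e-9
            np.testing.assert_allclose(
                np.abs(D[(a - 1) * i0 : a * i0]), np.abs(np.sin(flips)), rtol=1e-9
            )

    def test_single_voxel_closed_form_global(self):
        """Global model: the sin argument uses elapsed acquisition time x envelope."""
        phantom, b1, cal, sch, pulse = _uniform_setup()
        D = simulate_measurement_linear(phantom, b1, cal, sch, solver_cfg=SCFG)
        i0, T = sch.samples_per_rotation, pulse.duration
        for a in range(1, 5):
            g = phase_encode_scale(a, 4)
            t_k = sch.t_sample[:i0]
            w = ((a - 1) * T + t_k) * pulse.envelope_at(t_k)
            flips = cal.gamma * g * cal.amplitude_scale * w * 2.5e-9
            np.testing.assert_allclose(
                np.abs(D[(a - 1) * i0 : a * i0]), np.abs(np.sin(flips)), rtol=1e-9
            )

    def test_zero_amplitude_encode_row(self):
        """The g_alpha = 0 phase encode (odd M midpoint) measures nothing."""
        phantom, b1, cal, _, pulse = _uniform_setup()
        sch = build_schedule(3, 4, 1256.0, pulse)
        assert phase_encode_scale(2, 3) == 0.0
        D = simulate_measurement_linear(phantom, b1, cal, sch, solver_cfg=SCFG)
        np.testing.assert_array_equal(D[4:8], 0.0)

    def test_linearity_in_phantom(self, grid16, linmap16, cal16, pulse5ms, rng):
        sch = build_schedule(16, 16, 1256.0, pulse5ms)
        a = ScalarImage(grid16, rng.uniform(0, 1, grid16.shape))
        b = ScalarImage(grid16, rng.uniform(0, 1, grid16.shape))
        ab = ScalarImage(grid16, a.values + b.values)
        Da = simulate_measurement_linear(a, linmap16, cal16, sch, solver_cfg=SCFG)
        Db = simulate_measurement_linear(b, linmap16, cal16, sch, solver_cfg=SCFG)
        Dab = simulate_measurement_linear(ab, linmap16, cal16, sch, solver_cfg=SCFG)
        np.testing.assert_allclose(Dab, Da + Db, rtol=1e-9, atol=1e-15)


class TestEncodingMatrix:
    @pytest.mark.parametrize("mode", ["linear", "bloch"])
    def test_superposition_oracle(self, mode, shepp16, mask16, linmap16, cal16, pulse5ms):
        """E @ phantom equals the simulated measurement for noiseless maps."""
        sch = build_schedule(16, 16, 1256.0, pulse5ms)
        E = build_encoding_matrix(mode, mask16, linmap16, cal16, sch, SCFG)
        x = shepp16.values.ravel()[mask16.flat_indices]
        if mode == "linear":
            D = simulate_measurement_linear(shepp16, linmap16, cal16, sch, solver_cfg=SCFG)
        else:
            D = simulate_measurement_bloch(shepp16, linmap16, cal16, sch, SCFG)
        np.testing.assert_allclose(E @ x, D, rtol=1e-12, atol=1e-18)

    def test_tiny_matrix_columns_are_point_sources(self, pulse5ms):
        grid = GridSpec(4, 4, 1, 5e-3)
        field = np.full(grid.shape, 2e-9, dtype=complex)
        b1 = B1Map(grid, field)
        ind = np.zeros(grid.shape, bool)
        ind[1, 1] = ind[2, 2] = True
        mask = Mask(grid, ind)
        cal = calibrate_amplitude(pulse5ms, 3, 2e-9, GAMMA_PROTON, 90.0)
        sch = build_schedule(3, 1, 1256.0, pulse5ms)
        E = build_encoding_matrix("linear", mask, b1, cal, sch, SCFG)
        assert E.shape == (3, 2)
        for col, (i, j) in enumerate([(1, 1), (2, 2)]):
            vals = np.zeros(grid.shape)
            vals[i, j] = 1.0
            D = simulate_measurement_linear(ScalarImage(grid, vals), b1, cal, sch, solver_cfg=SCFG)
            np.testing.assert_allclose(E[:, col], D, rtol=1e-12)

    def test_full_numerical_rank_at_32(self, shepp32, mask32, pulse5ms):
        """The reference linear-gradient configuration yields an encoding
        matrix of full numerical column rank — the property that makes the
        reconstruction work."""
        from rotob1.coil_maps import linear_gradient_map

        grid = mask32.grid
        b1 = linear_gradient_map(grid, 37.5e-9)
        cal = calibrate_amplitude(pulse5ms, 32, b1.peak, GAMMA_PROTON, 90.0)
        sch = build_schedule(32, 32, 1256.0, pulse5ms)
        E = build_encoding_matrix("linear", mask32, b1, cal, sch, SCFG)
        assert np.linalg.matrix_rank(E) == mask32.n_inside

    def test_noise_seed_determinism(self, mask16, linmap16, cal16, pulse5ms):
        sch = build_schedule(16, 16, 1256.0, pulse5ms)
        kw = dict(noise_fraction=0.002, noise_seed=9)
        E1 = build_encoding_matrix("linear", mask16, linmap16, cal16, sch, SCFG, **kw)
        E2 = build_encoding_matrix("linear", mask16, linmap16, cal16, sch, SCFG, **kw)
        np.testing.assert_array_equal(E1, E2)
        E3 = build_encoding_matrix(
            "linear", mask16, linmap16, cal16, sch, SCFG, noise_fraction=0.002, noise_seed=10
        )
        assert np.abs(E1 - E3).max() > 0


class TestModelConsistency:
    def test_bloch_matches_path_sine_at_small_flip(self, shepp16, grid16, pulse5ms):
        """In the small-tip regime the Bloch solver reproduces the analytic
        path-integral sine model to well under 1%."""
        from rotob1.coil_maps import linear_gradient_map

        b1 = linear_gradient_map(grid16, 37.5e-9)
        cal = calibrate_amplitude(pulse5ms, 16, b1.peak, GAMMA_PROTON, 5.0)
        sch = build_schedule(16, 16, 1256.0, pulse5ms)
        Dl = simulate_measurement_linear(
            shepp16, b1, cal, sch, solver_cfg=SCFG, flip_model="path"
        )
        Db = simulate_measurement_bloch(shepp16, b1, cal, sch, SCFG)
        rel = np.linalg.norm(Db - Dl) / np.linalg.norm(Dl)
        assert rel < 1e-3

    def test_bloch_converges_to_path_sine_as_amplitude_shrinks(
        self, shepp16, grid16, pulse5ms
    ):
        """Relative disagreement decreases along a decreasing-flip ladder."""
        from rotob1.coil_maps import linear_gradient_map

        b1 = linear_gradient_map(grid16, 37.5e-9)
        sch = build_schedule(16, 16, 1256.0, pulse5ms)
        rels = []
        for fa in (90.0, 30.0, 10.0, 3.0):
            cal = calibrate_amplitude(pulse5ms, 16, b1.peak, GAMMA_PROTON, fa)
            Dl = simulate_measurement_linear(
                shepp16, b1, cal, sch, solver_cfg=SCFG, flip_model="path"
            )
            Db = simulate_measurement_bloch(shepp16, b1, cal, sch, SCFG)
            rels.append(np.linalg.norm(Db - Dl) / np.linalg.norm(Dl))
        assert np.all(np.diff(rels) < 0)

    def test_path_equals_instantaneous_for_static_map(self):
        """With a non-rotating coil (omega = 0) sampled at one instant the
        accumulated-path and per-TR quasi-static models coincide."""
        phantom, b1, cal, _, pulse = _uniform_setup()
        sch = build_schedule(4, 1, 0.0, pulse)  # one end-of-pulse sample per TR
        fine = SolverConfig(dt=5e-3 / 500, n_steps=500)  # dense path quadrature
        Dp = simulate_measurement_linear(phantom, b1, cal, sch, solver_cfg=fine, flip_model="path")
        Di = simulate_measurement_linear(
            phantom, b1, cal, sch, solver_cfg=fine, flip_model="instantaneous"
        )
        np.testing.assert_allclose(Dp, Di, rtol=1e-4)
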