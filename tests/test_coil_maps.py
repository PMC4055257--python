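"""Coil sensitivity maps, rotation, and noise injection."""

import numpy as np
import pytest

from rotob1.coil_maps import (
    MU0,
    RotationOptions,
    add_map_noise,
    linear_gradient_map,
    loop_coil_map,
    rotate_map,
)
from rotob1.phantoms import GridSpec


class TestLinearGradientMap:
    def test_quarter_max_convention(self):
        # odd grid: the center voxel sits exactly at the isocenter
        grid = GridSpec(65, 65, 1, 5e-3)
        m = linear_gradient_map(grid, 37.5e-9, axis_length=0.32)
        b1max = 37.5e-9 * 0.16 / 0.75
        assert b1max == pytest.approx(8.0e-9)
        assert m.field[32, 32].real == pytest.approx(b1max / 4, rel=1e-12)

    def test_slope_between_voxels(self):
        grid = GridSpec(65, 65, 1, 5e-3)
        m = linear_gradient_map(grid, 37.5e-9)
        # two voxels along the gradient axis, on the positive side
        d = m.field[32, 60].real - m.field[32, 58].real
        assert d == pytest.approx(37.5e-9 * 2 * 5e-3, rel=1e-12)

    def test_zero_phase_at_nominal_angle(self):
        m = linear_gradient_map(GridSpec(16, 16, 1, 5e-3), 37.5e-9)
        assert np.all(m.field.imag == 0.0)
        assert m.nominal_angle == 0.0

    def test_invalid_gradient(self):
        with pytest.raises(ValueError):
            linear_gradient_map(GridSpec(8, 8, 1, 5e-3), -1e-9)


class TestLoopCoilMap:
    def test_on_axis_closed_form(self):
        """On the loop axis the Biot-Savart magnitude is
        mu0 I R^2 / (2 (R^2 + d^2)^(3/2)) (purely axial field)."""
        grid = GridSpec(9, 9, 1, 5e-3)
        R, off = 0.05, 0.1
        m = loop_coil_map(grid, R, off)
        for j in range(9):
            x = (j - 4) * 5e-3
            d = off - x
            expected = MU0 * R**2 / (2 * (R**2 + d**2) ** 1.5) / 2  # B1+ = Bx/2
            assert abs(m.field[4, j]) == pytest.approx(expected, rel=1e-9)

    def test_mirror_symmetry_about_axis(self):
        m = loop_coil_map(GridSpec(9, 9, 1, 5e-3), 0.05, 0.1)
        np.testing.assert_allclose(np.abs(m.field), np.abs(m.field[::-1, :]), rtol=1e-9)

    def test_current_linearity(self):
        g = GridSpec(9, 9, 1, 5e-3)
        m1 = loop_coil_map(g, 0.05, 0.1, current=1.0)
        m2 = loop_coil_map(g, 0.05, 0.1, current=2.0)
        np.testing.assert_allclose(m2.field, 2.0 * m1.field, rtol=1e-12)
        np.testing.assert_allclose(np.angle(m2.field), np.angle(m1.field), atol=1e-12)

    def test_magnitude_decays_into_grid(self):
        m = loop_coil_map(GridSpec(9, 9, 1, 5e-3), 0.05, 0.1)
        row = np.abs(m.field[4, :])
        assert np.all(np.diff(row) > 0)  # grows toward the coil at +x

    def test_loop_must_be_outside_grid(self):
        with pytest.raises(ValueError):
            loop_coil_map(GridSpec(9, 9, 1, 5e-3), 0.05, 0.01)

    def test_z_offset_breaks_slice_symmetry(self):
        g3 = GridSpec(7, 7, 7, 5e-3)
        sym = loop_coil_map(g3, 0.05, 0.1)
        asym = loop_coil_map(g3, 0.05, 0.1, loop_z_offset=0.03)
        np.testing.assert_allclose(
            np.abs(sym.field[:, :, 1]), np.abs(sym.field[:, :, 5]), rtol=1e-9
        )
        assert np.abs(asym.field[:, :, 1]).mean() != pytest.approx(
            np.abs(asym.field[:, :, 5]).mean(), rel=1e-3
        )


def _blob_map(n=32):
    """Asymmetric compactly supported complex map away from the boundary."""
    grid = GridSpec(n, n, 1, 5e-3)
    x, y = grid.coordinates()
    r2 = (x - 0.01) ** 2 + (y - 0.005) ** 2
    field = np.exp(-r2 / (0.02**2)) * (1.0 + 0.3j) * 1e-9
    from rotob1.coil_maps import B1Map

    return B1Map(grid, field)


class TestRotateMap:
    def test_zero_angle_identity(self):
        m = _blob_map()
        r = rotate_map(m, 0.0)
        np.testing.assert_array_equal(r.field, m.field)

    def test_quarter_turn_matches_index_permutation(self):
        """A 90-degree CCW rotation equals the exact array quarter-turn."""
        m = _blob_map()
        r = rotate_map(m, 90.0, RotationOptions(order="cubic-spline"))
        oracle = np.rot90(m.field, 1)
        err = np.abs(r.field - oracle).max() / np.abs(m.field).max()
        assert err < 1e-6

    def test_full_turn_identity(self):
        m = _blob_map()
        r = m
        for _ in range(4):
            r = rotate_map(r, 90.0)
        err = np.abs(r.field - m.field).max() / np.abs(m.field).max()
        assert err < 1e-6
        assert r.nominal_angle == pytest.approx(360.0)

    def test_energy_conservation(self):
        m = _blob_map()
        r = rotate_map(m, 37.0)
        e0 = np.sum(np.abs(m.field) ** 2)
        e1 = np.sum(np.abs(r.field) ** 2)
        assert e1 == pytest.approx(e0, rel=1e-3)

    def test_composition(self):
        m = _blob_map()
        ab = rotate_map(rotate_map(m, 20.0), 33.0)
        once = rotate_map(m, 53.0)
        err = np.abs(ab.field - once.field).max() / np.abs(m.field).max()
        assert err < 1e-3  # accumulated interpolation tolerance

    def test_global_phase_option(self):
        m = _blob_map()
        opts = RotationOptions(apply_global_phase=True)
        r = rotate_map(m, 90.0, opts)
        plain = rotate_map(m, 90.0)
        np.testing.assert_allclose(r.field, plain.field * np.exp(1j * np.pi / 2), rtol=1e-12)

    def test_bad_interpolation_order(self):
        with pytest.raises(ValueError):
            rotate_map(_blob_map(), 10.0, RotationOptions(order="nearest"))

    def test_3d_rotates_slice_wise(self):
        g3 = GridSpec(9, 9, 5, 5e-3)
        field = np.zeros(g3.shape, complex)
        field[4, 7, :] = np.arange(1, 6) * 1e-9  # blob at +x, distinct per slice
        from rotob1.coil_maps import B1Map

        r = rotate_map(B1Map(g3, field), 90.0)
        for k in range(5):
            oracle = np.rot90(field[:, :, k], 1)
            assert np.abs(r.field[:, :, k] - oracle).max() < 1e-6 * np.abs(field).max()


class TestMapNoise:
    def test_zero_fraction_unchanged(self):
        m = _blob_map()
        np.testing.assert_array_equal(add_map_noise(m, 0.0, 7).field, m.field)

    def test_bounded_by_fraction_of_peak(self):
        m = _blob_map()
        noisy = add_map_noise(m, 0.002, 7)
        delta = noisy.field - m.field
        bound = 0.002 * np.abs(m.field).max()
        assert np.abs(delta.real).max() <= bound
        assert np.abs(delta.imag).max() <= bound
        assert np.abs(delta).max() > 0

    def test_seed_determinism(self):
        m = _blob_map()
        a = add_map_noise(m, 0.002, 42)
        b = add_map_noise(m, 0.002, 42)
        np.testing.assert_array_equal(a.field, b.field)
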