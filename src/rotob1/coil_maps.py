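"""Complex B1+ transmit sensitivity maps and their mechanical rotation.

Two field models are provided:

* a linear-gradient field (the rotating-frame zeugmatography idealization):
  the signed field amplitude varies linearly along +x, fixed by the
  convention that at the grid midpoint the amplitude is one quarter of its
  maximum at the near edge;
* a quasi-static Biot-Savart surface-loop field (elliptic-integral off-axis
  solution of a circular current loop), whose transverse component supplies
  a spatially nonlinear magnitude and phase.

Rotating the coil by theta is modeled by rotating the real and imaginary
field channels about the isocenter (spline or linear interpolation) and,
optionally, multiplying by the coil-position phase e^{i theta}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.special import ellipe, ellipk

from .phantoms import GridSpec

MU0 = 4e-7 * np.pi  # vacuum permeability, T m / A

__all__ = [
    "B1Map",
    "RotationOptions",
    "linear_gradient_map",
    "loop_coil_map",
    "rotate_map",
    "add_map_noise",
]


@dataclass
class B1Map:
    """Complex transmit field per voxel (tesla per unit drive)."""

    grid: GridSpec
    field: np.ndarray  # complex, grid-shaped
    nominal_angle: float = 0.0  # coil angular position, degrees

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=complex)
        if self.field.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("field must be finite")
        if not np.any(self.field):
            raise ValueError("field is identically zero")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.field)

    @property
    def peak(self) -> float:
        return float(np.abs(self.field).max())


@dataclass(frozen=True)
class RotationOptions:
    order: str = "cubic-spline"  # or "linear"
    apply_global_phase: bool = False

    @property
    def spline_order(self) -> int:
        if self.order == "cubic-spline":
            return 3
        if self.order == "linear":
            return 1
        raise ValueError("interpolation order must be 'cubic-spline' or 'linear'")


def linear_gradient_map(
    grid: GridSpec, unit_gradient: float, axis_length: float | None = None
) -> B1Map:
    """Signed linear B1+ gradient field along +x at coil angle 0.

    The quarter-max convention of the reference configuration fixes the edge
    amplitude: B1max = unit_gradient * (axis_length/2) / (3/4), so the field
    at the grid midpoint is exactly B1max/4. The field is real (phase 0 where
    positive, pi where the linear ramp has crossed zero on the far side).
    """
    if unit_gradient <= 0:
        raise ValueError("unit_gradient must be positive")
    if axis_length is None:
        axis_length = grid.extent_x
    if axis_length <= 0:
        raise ValueError("axis_length must be positive")
    b1_max = unit_gradient * (axis_length / 2.0) / 0.75
    if b1_max <= 0:
        raise ValueError("geometry yields non-positive peak field")
    coords = grid.coordinates()
    x = coords[0]
    field = b1_max + unit_gradient * (x - axis_length / 2.0)
    return B1Map(grid, field.astype(complex), nominal_angle=0.0)


def loop_coil_map(
    grid: GridSpec,
    loop_radius: float,
    loop_center_offset: float,
    loop_z_offset: float = 0.0,
    current: float = 1.0,
) -> B1Map:
    """Transverse field of a circular current loop facing the grid from +x.

    The loop of radius ``loop_radius`` lies in the plane x = loop_center_offset
    with its axis along x, at height z = loop_z_offset. The full off-axis
    Biot-Savart field (complete elliptic integrals K, E) is evaluated at every
    voxel; the complex map is B1+ = (Bx + i By)/2, i.e. magnitude and in-plane
    orientation of the transverse field. The longitudinal (z) component does
    not drive excitation and is dropped.

    For 3D encoding a nonzero ``loop_z_offset`` matters: a loop centered on
    the mid-slice plane has a z-mirror-symmetric magnitude and cannot
    distinguish +z from -z.
    """
    if loop_radius <= 0:
        raise ValueError("loop_radius must be positive")
    half_x = grid.extent_x / 2.0
    if loop_center_offset <= half_x:
        raise ValueError("loop must sit outside the imaging grid support")
    coords = grid.coordinates()
    x, y = coords[0], coords[1]
    z = coords[2] if len(coords) == 3 else np.zeros_like(x)

    a = loop_center_offset - x  # axial distance from the loop plane (toward grid)
    rho = np.hypot(y, z - loop_z_offset)  # radial distance from the loop axis
    B_ax, B_rho = _loop_field_cylindrical(loop_radius, current, rho, a)

    # loop axis points from the loop toward the isocenter, i.e. along -x
    bx = -B_ax
    with np.errstate(invalid="ignore", divide="ignore"):
        ey = np.where(rho > 0, y / np.where(rho > 0, rho, 1.0), 0.0)
        ez = np.where(rho > 0, z / np.where(rho > 0, rho, 1.0), 0.0)
    by = B_rho * ey
    # bz = B_rho * ez is longitudinal; it does not contribute to B1+
    field = 0.5 * (bx + 1j * by)
    return B1Map(grid, field, nominal_angle=0.0)


def _loop_field_cylindrical(R, I, rho, a):
    """Axial and radial field of a circular loop (standard elliptic-integral form)."""
    rho = np.asarray(rho, dtype=float)
    a = np.asarray(a, dtype=float)
    denom_far = (R + rho) ** 2 + a**2
    denom_near = (R - rho) ** 2 + a**2
    m = 4.0 * R * rho / denom_far
    K, E = ellipk(m), ellipe(m)
    pref = MU0 * I / (2.0 * np.pi * np.sqrt(denom_far))
    B_ax = pref * (K + (R**2 - rho**2 - a**2) / denom_near * E)
    with np.errstate(invalid="ignore", divide="ignore"):
        B_rho = (
            pref
            * (a / np.where(rho > 0, rho, 1.0))
            * (-K + (R**2 + rho**2 + a**2) / denom_near * E)
        )
    B_rho = np.where(rho > 0, B_rho, 0.0)  # on-axis field is purely axial
    return B_ax, B_rho


def rotate_map(b1map: B1Map, angle: float, options: RotationOptions | None = None) -> B1Map:
    """Rotate the coil (and thus its field pattern) by ``angle`` degrees CCW.

    Real and imaginary channels are rotated independently about the grid
    isocenter (3D maps slice-wise about the slice axis); values falling
    outside the original support are filled with zero. With
    ``apply_global_phase`` the result additionally picks up e^{i angle},
    the angular-position-dependent phase of a rotated coil.
    """
    options = options or RotationOptions()
    if angle == 0.0 and not options.apply_global_phase:
        return replace(b1map, field=b1map.field.copy())
    order = options.spline_order
    re = ndimage.rotate(
        b1map.field.real, angle, axes=(0, 1), reshape=False, order=order, mode="constant"
    )
    im = ndimage.rotate(
        b1map.field.imag, angle, axes=(0, 1), reshape=False, order=order, mode="constant"
    )
    field = re + 1j * im
    if options.apply_global_phase:
        field = field * np.exp(1j * np.radians(angle))
    return B1Map(b1map.grid, field, nominal_angle=b1map.nominal_angle + angle)


def add_map_noise(
    b1map: B1Map, fraction: float, seed: int | np.random.Generator | None = None
) -> B1Map:
    """Perturb each channel by uniform draws in +/-fraction of the peak magnitude.

    Emulates the measurement noise picked up by each incremental map rotation;
    reproducible for a fixed seed.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    if fraction == 0:
        return replace(b1map, field=b1map.field.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amp = fraction * b1map.peak
    noise = rng.uniform(-amp, amp, b1map.field.shape) + 1j * rng.uniform(
        -amp, amp, b1map.field.shape
    )
    return B1Map(b1map.grid, b1map.field + noise, nominal_angle=b1map.nominal_angle)
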