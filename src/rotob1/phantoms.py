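"""Synthetic test objects: grids, phantoms and support masks.

The imaging grid follows an isocenter convention: the rotation pivot of the
coil sits exactly at the geometric center of the voxel lattice, so voxel
``(i, j)`` has in-plane physical coordinates

    x = (j - (n_cols - 1)/2) * voxel_size        (columns, to the right)
    y = -(i - (n_rows - 1)/2) * voxel_size       (rows, +y up)

and positive rotation angles are counterclockwise in the (x, y) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

__all__ = [
    "GridSpec",
    "ScalarImage",
    "Mask",
    "make_shepp_logan",
    "make_layer_phantom",
    "make_mask",
    "SHEPP_LOGAN_ELLIPSES",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the voxel lattice (isotropic in-plane resolution)."""

    n_rows: int
    n_cols: int
    n_slices: int = 1
    voxel_size: float = 5e-3  # meters per voxel edge

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_slices) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        if self.is_2d:
            return (self.n_rows, self.n_cols)
        return (self.n_rows, self.n_cols, self.n_slices)

    @property
    def is_2d(self) -> bool:
        return self.n_slices == 1

    @property
    def n_voxels(self) -> int:
        return self.n_rows * self.n_cols * self.n_slices

    def coordinates(self) -> tuple[np.ndarray, ...]:
        """Physical (x, y[, z]) coordinate arrays, one per voxel, grid-shaped."""
        i = np.arange(self.n_rows) - (self.n_rows - 1) / 2.0
        j = np.arange(self.n_cols) - (self.n_cols - 1) / 2.0
        if self.is_2d:
            y, x = np.meshgrid(-i, j, indexing="ij")
            return x * self.voxel_size, y * self.voxel_size
        k = np.arange(self.n_slices) - (self.n_slices - 1) / 2.0
        y, x, z = np.meshgrid(-i, j, k, indexing="ij")
        return x * self.voxel_size, y * self.voxel_size, z * self.voxel_size

    @property
    def extent_x(self) -> float:
        """Physical width along the column axis in meters."""
        return self.n_cols * self.voxel_size

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.voxel_size


@dataclass
class ScalarImage:
    """Real, non-negative signal intensity per voxel (arbitrary units)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")


@dataclass
class Mask:
    """Boolean support indicator on a grid; at least one voxel must be inside."""

    grid: GridSpec
    indicator: np.ndarray

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.indicator.any():
            raise ValueError("mask is empty")

    @property
    def n_inside(self) -> int:
        return int(self.indicator.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Raveled voxel indices inside the mask (C order); defines column order
        of the encoding matrix."""
        return np.flatnonzero(self.indicator.ravel())


# Matlab phantom('Shepp-Logan') ellipse table (original, non-modified intensities):
# columns are (additive intensity, semi-axis a, semi-axis b, x0, y0, tilt phi in deg),
# on the normalized [-1, 1] square with +y up.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.98, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.01, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.01, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def make_shepp_logan(grid: GridSpec) -> ScalarImage:
    """Render the Shepp-Logan head phantom on a 2D grid.

    Each voxel takes the summed intensity of every ellipse whose interior
    contains the voxel *center* (no anti-aliasing), the convention of common
    phantom generators. Output values lie in [0, 1]; the skull ring is 1.0.
    """
    if not grid.is_2d:
        raise ValueError("Shepp-Logan phantom is 2D; got a grid with n_slices > 1")
    # normalized coordinates: voxel centers span [-1, 1] corner to corner
    u = (np.arange(grid.n_cols) - (grid.n_cols - 1) / 2.0) / ((grid.n_cols - 1) / 2.0)
    v = -(np.arange(grid.n_rows) - (grid.n_rows - 1) / 2.0) / ((grid.n_rows - 1) / 2.0)
    vv, uu = np.meshgrid(v, u, indexing="ij")
    img = np.zeros(grid.shape)
    for amp, a, b, x0, y0, phi in SHEPP_LOGAN_ELLIPSES:
        c, s = np.cos(np.radians(phi)), np.sin(np.radians(phi))
        du, dv = uu - x0, vv - y0
        inside = ((du * c + dv * s) / a) ** 2 + ((-du * s + dv * c) / b) ** 2 <= 1.0
        img[inside] += amp
    # summed intensities are non-negative by construction of the table, but
    # clip roundoff just in case
    np.clip(img, 0.0, None, out=img)
    return ScalarImage(grid, img)


def layer_block_extents(grid: GridSpec) -> tuple[int, int, int]:
    """Edge lengths (rows, cols, slices) of the centered three-layer block.

    In-plane the block spans the central ceil(2n/3) voxels; along the slice
    axis it spans the largest multiple of 3 <= n_slices so the three slabs
    have equal integer thickness (a 21-voxel axis gives three 7-slice slabs).
    """
    er = ceil(2 * grid.n_rows / 3)
    ec = ceil(2 * grid.n_cols / 3)
    es = 3 * (grid.n_slices // 3)
    return er, ec, es


def make_layer_phantom(grid: GridSpec, layer_values=(1.0, 0.6, 0.3)) -> ScalarImage:
    """Three-layer rectangular phantom for 3D encoding tests.

    A rectangular block centered in the grid is split along the slice axis
    into three equal-thickness slabs carrying ``layer_values``; everything
    outside the block is zero.
    """
    if grid.is_2d:
        raise ValueError("layer phantom requires a 3D grid")
    layer_values = tuple(float(v) for v in layer_values)
    if len(layer_values) != 3:
        raise ValueError("exactly three layer intensities are required")
    er, ec, es = layer_block_extents(grid)
    if es < 3:
        raise ValueError("grid too thin: the three-slab block does not fit")
    img = np.zeros(grid.shape)
    r0 = (grid.n_rows - er) // 2
    c0 = (grid.n_cols - ec) // 2
    s0 = (grid.n_slices - es) // 2
    slab = es // 3
    for li, val in enumerate(layer_values):
        sl = slice(s0 + li * slab, s0 + (li + 1) * slab)
        img[r0 : r0 + er, c0 : c0 + ec, sl] = val
    return ScalarImage(grid, img)


def make_mask(image: ScalarImage, threshold_fraction: float = 0.0) -> Mask:
    """Threshold mask: voxel is inside iff intensity > fraction * max intensity."""
    if not 0.0 <= threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in [0, 1)")
    peak = float(image.values.max())
    if peak <= 0.0:
        raise ValueError("cannot build a mask from an all-zero image")
    return Mask(image.grid, image.values > threshold_fraction * peak)
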