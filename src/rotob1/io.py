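"""Import/export of images, maps, pulses and metrics (NIfTI / CSV / JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .coil_maps import B1Map
from .phantoms import GridSpec, ScalarImage
from .recon import DeviationMetrics, ImageEstimate

__all__ = [
    "save_nifti",
    "load_scalar_nifti",
    "save_map_nifti",
    "load_map_nifti",
    "save_csv",
    "save_pulse_csv",
    "metrics_to_dict",
    "save_json",
]


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = grid.voxel_size
    return aff


def _as_volume(values: np.ndarray) -> np.ndarray:
    return values if values.ndim == 3 else values[:, :, None]


def save_nifti(image: ScalarImage | ImageEstimate, path) -> None:
    values = image.values
    if np.iscomplexobj(values):
        values = np.abs(values)
    nib.save(nib.Nifti1Image(_as_volume(values).astype(np.float64), _affine(image.grid)), str(path))


def load_scalar_nifti(path, voxel_size: float | None = None) -> ScalarImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    vox = voxel_size if voxel_size is not None else float(img.affine[0, 0])
    n_slices = 1 if data.ndim == 2 else data.shape[2]
    grid = GridSpec(data.shape[0], data.shape[1], n_slices, vox)
    return ScalarImage(grid, data)


def save_map_nifti(b1map: B1Map, magnitude_path, phase_path) -> None:
    """Complex map as a (magnitude, phase-in-radians) NIfTI pair."""
    aff = _affine(b1map.grid)
    nib.save(nib.Nifti1Image(_as_volume(np.abs(b1map.field)), aff), str(magnitude_path))
    nib.save(nib.Nifti1Image(_as_volume(np.angle(b1map.field)), aff), str(phase_path))


def load_map_nifti(magnitude_path, phase_path, voxel_size: float | None = None) -> B1Map:
    mag = load_scalar_nifti(magnitude_path, voxel_size)
    ph = load_scalar_nifti(phase_path, voxel_size)
    return B1Map(mag.grid, mag.values * np.exp(1j * ph.values))


def save_csv(values: np.ndarray, path) -> None:
    if values.ndim != 2:
        raise ValueError("CSV export is for 2D arrays")
    np.savetxt(str(path), values, delimiter=",")


def save_pulse_csv(pulse, path) -> None:
    """Two columns: time in seconds, unit-normalized amplitude."""
    np.savetxt(
        str(path),
        np.column_stack([pulse.times, pulse.envelope]),
        delimiter=",",
        header="time_s,amplitude",
        comments="",
    )


def metrics_to_dict(metrics: DeviationMetrics) -> dict:
    return {
        "max_abs_deviation_pct": metrics.max_abs_deviation,
        "mean_deviation_pct": metrics.mean_deviation,
        "std_deviation_pct": metrics.std_deviation,
        "hist_counts": metrics.hist_counts.tolist(),
        "hist_edges": metrics.hist_edges.tolist(),
    }


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
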