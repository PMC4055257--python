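"""Inversion of the encoding system and image-deviation metrics.

The pseudo k-space data D and encoding matrix E define the linear system
D = E G over the masked voxels. Two solvers are exposed: a regularized
pseudo-inverse (truncated-SVD minimum-norm least squares) and LSQR with the
stopping rule 400 iterations / relative residual 1e-6. Deviation statistics
between a reconstruction and the ground-truth image are computed after peak
normalization of both magnitudes over the mask, in percent of full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.sparse import linalg as spla

from .phantoms import GridSpec, Mask, ScalarImage

__all__ = [
    "ImageEstimate",
    "DeviationMetrics",
    "solve_pinv",
    "solve_lsqr",
    "deviation_metrics",
]


@dataclass
class ImageEstimate:
    """Reconstructed complex intensity per voxel; zero outside the mask."""

    grid: GridSpec
    values: np.ndarray  # complex, grid-shaped
    solver: str = ""
    iterations: int | None = None
    residual: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.grid.shape:
            raise ValueError("value array shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstruction contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class DeviationMetrics:
    """Percentage-deviation statistics over the mask (signed, % of peak)."""

    deviation_map: np.ndarray  # grid-shaped, signed %, zero outside mask
    max_abs_deviation: float
    mean_deviation: float
    std_deviation: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def _embed(x: np.ndarray, mask: Mask, solver: str, iterations=None, residual=None) -> ImageEstimate:
    values = np.zeros(mask.grid.n_voxels, dtype=complex)
    values[mask.flat_indices] = x
    return ImageEstimate(
        mask.grid, values.reshape(mask.grid.shape), solver, iterations, residual
    )


def solve_pinv(
    E: np.ndarray, D: np.ndarray, mask: Mask, rel_tol: float = 1e-12
) -> ImageEstimate:
    """Minimum-norm least-squares solution via truncated SVD.

    Singular values below ``rel_tol`` times the largest are discarded — the
    "regularized pseudo-inverse" G = E+ D. The default keeps everything down
    to roughly the double-precision floor, the behavior of a stock pinv; pass
    a larger ``rel_tol`` for aggressive truncation of ill-conditioned systems.
    """
    E = np.asarray(E)
    D = np.asarray(D)
    if E.size == 0 or D.size == 0:
        raise ValueError("empty system")
    if E.shape[0] != D.shape[0]:
        raise ValueError("E and D have incompatible row counts")
    x, _, _, _ = sla.lstsq(E, D, cond=rel_tol, lapack_driver="gelsd")
    return _embed(x, mask, "pinv")


def solve_lsqr(
    E: np.ndarray,
    D: np.ndarray,
    mask: Mask,
    max_iter: int = 400,
    residual_tol: float = 1e-6,
) -> ImageEstimate:
    """Iterative least squares (LSQR), stopping at ``max_iter`` iterations or
    a relative residual of ``residual_tol`` (residual-based stopping only,
    the rule of Matlab's lsqr)."""
    E = np.asarray(E)
    D = np.asarray(D)
    if E.size == 0 or D.size == 0:
        raise ValueError("empty system")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    x, istop, itn, r1norm = spla.lsqr(
        E, D, atol=0.0, btol=residual_tol, iter_lim=max_iter
    )[:4]
    dnorm = float(np.linalg.norm(D))
    rel_res = r1norm / dnorm if dnorm > 0 else 0.0
    return _embed(x, mask, "lsqr", iterations=int(itn), residual=float(rel_res))


def deviation_metrics(
    recon: ImageEstimate,
    original: ScalarImage,
    mask: Mask,
    n_bins: int = 50,
) -> DeviationMetrics:
    """Percentage intensity deviation of |recon| from the normalized original.

    Both magnitudes are normalized to unit peak over the mask, then the
    per-voxel signed deviation is 100 (|recon| - |original|). The summary
    holds the maximum absolute deviation along with the signed mean/std and a
    histogram over the observed range.
    """
    if recon.grid != original.grid or recon.grid != mask.grid:
        raise ValueError("recon, original and mask must share a grid")
    m = mask.indicator
    rec = recon.magnitude
    org = original.values
    rec_peak = rec[m].max()
    org_peak = org[m].max()
    if org_peak <= 0:
        raise ValueError("original image is zero inside the mask")
    rec_n = rec / rec_peak if rec_peak > 0 else rec
    org_n = org / org_peak
    dev = np.zeros(recon.grid.shape)
    dev[m] = 100.0 * (rec_n[m] - org_n[m])
    inside = dev[m]
    lo, hi = float(inside.min()), float(inside.max())
    if lo == hi:  # degenerate (e.g. exact recovery): one-bin histogram
        edges = np.array([lo - 0.5, hi + 0.5])
        counts = np.array([inside.size])
    else:
        counts, edges = np.histogram(inside, bins=n_bins, range=(lo, hi))
    return DeviationMetrics(
        deviation_map=dev,
        max_abs_deviation=float(np.abs(inside).max()),
        mean_deviation=float(inside.mean()),
        std_deviation=float(inside.std()),
        hist_counts=counts,
        hist_edges=edges,
    )
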