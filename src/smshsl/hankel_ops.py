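"""Lifting between k-space grids and (block-)Hankel-structured matrices.

The lift H(·) maps a multicoil grid x ∈ C^(Nx×Ny×Nc) to a matrix of shape
(Nx−r+1)(Ny−r+1) × r²Nc by vectorizing every fully interior r×r window
across all coils and stacking the vectors row-wise. Row enumeration is the
window raster with ky outer and kx inner; columns are coil-major, with the
in-window raster (dy outer, dx inner) inside each coil block. The block
lift H_P(·) concatenates the per-contrast lifts row-wise in TI order, so
local k-space correlations shared across contrasts appear as a common
column space and the matrix becomes markedly rank-deficient.

The adjoint is the unnormalized transpose-sum (add each matrix entry back
into the grid sample it came from); dividing by :func:`multiplicity_map`
turns ``adjoint ∘ lift`` into the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_core import KSpaceVolume


class SizeError(ValueError):
    """Window or matrix dimensions inconsistent with the grid they address."""


def _as_grid(x) -> np.ndarray:
    data = x.data if isinstance(x, KSpaceVolume) else np.asarray(x)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise SizeError(f"expected (kx, ky, coil[, contrast]) grid, got shape {data.shape}")
    return data


@dataclass
class HankelMatrix:
    """A lifted (block-)Hankel matrix together with its provenance.

    ``source_shape`` is always 4-tuple (Nx, Ny, Nc, Np); single-contrast
    lifts carry Np=1. Row/column enumeration is documented in the module
    docstring and is bit-stable across calls.
    """

    matrix: np.ndarray
    r: int
    source_shape: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        nx, ny, nc, np_ = self.source_shape
        rows = (nx - self.r + 1) * (ny - self.r + 1) * np_
        cols = self.r * self.r * nc
        if self.matrix.shape != (rows, cols):
            raise SizeError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"source {self.source_shape} and r={self.r}: expected {(rows, cols)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _lift_single(data: np.ndarray, r: int) -> np.ndarray:
    """Lift one contrast: data (Nx, Ny, Nc) → ((Nx−r+1)(Ny−r+1), r²Nc)."""
    nx, ny, nc = data.shape
    # windows[wx, wy, c, dx, dy]
    win = sliding_window_view(data, (r, r), axis=(0, 1))
    # → (wy, wx, c, dy, dx), then flatten rows (wy outer, wx inner)
    # and columns (coil outer, dy, dx inner)
    win = win.transpose(1, 0, 2, 4, 3)
    return win.reshape((ny - r + 1) * (nx - r + 1), nc * r * r)


def hankel_lift(k, r: int) -> HankelMatrix:
    """Lift a single-contrast grid to its Hankel-structured matrix.

    Entry (p, q) is the k-space sample at in-window offset (dx, dy) of coil c
    for window position p, with q = c·r² + dy·r + dx and p = wy·(Nx−r+1) + wx.
    """
    data = _as_grid(k)
    if data.shape[3] != 1:
        raise SizeError("hankel_lift takes a single contrast; use block_hankel_lift")
    data = data[..., 0]
    nx, ny, _ = data.shape
    if r < 1 or r > min(nx, ny):
        raise SizeError(f"window r={r} exceeds grid extents {(nx, ny)}")
    mat = _lift_single(data, r)
    return HankelMatrix(np.ascontiguousarray(mat), r, (nx, ny, data.shape[2], 1))


def block_hankel_lift(k, r: int) -> HankelMatrix:
    """Row-wise concatenation of per-contrast lifts in TI order (contrast-major rows)."""
    data = _as_grid(k)
    nx, ny, nc, np_ = data.shape
    if r < 1 or r > min(nx, ny):
        raise SizeError(f"window r={r} exceeds grid extents {(nx, ny)}")
    blocks = [_lift_single(data[..., p], r) for p in range(np_)]
    return HankelMatrix(np.ascontiguousarray(np.concatenate(blocks, axis=0)), r, (nx, ny, nc, np_))


def _adjoint_single(mat: np.ndarray, shape: tuple[int, int, int], r: int) -> np.ndarray:
    """Adjoint of _lift_single: scatter-add matrix entries back onto the grid."""
    nx, ny, nc = shape
    wx_n, wy_n = nx - r + 1, ny - r + 1
    win = mat.reshape(wy_n, wx_n, nc, r, r)  # (wy, wx, c, dy, dx)
    out = np.zeros((nx, ny, nc), dtype=mat.dtype)
    for dy in range(r):
        for dx in range(r):
            out[dx:dx + wx_n, dy:dy + wy_n, :] += win[:, :, :, dy, dx].transpose(1, 0, 2)
    return out


def hankel_adjoint(H: HankelMatrix) -> np.ndarray:
    """Exact adjoint of the (block) lift under the complex inner product.

    Satisfies ⟨lift(x), Y⟩ = ⟨x, adjoint(Y)⟩ for every grid x and matrix Y.
    No normalization is applied: ``adjoint(lift(x)) = multiplicity_map ⊙ x``.
    Returns a (Nx, Ny, Nc, Np) array (last axis length 1 for single-contrast).
    """
    nx, ny, nc, np_ = H.source_shape
    rows_per = (nx - H.r + 1) * (ny - H.r + 1)
    if H.matrix.shape != (rows_per * np_, H.r * H.r * nc):
        raise SizeError("matrix/source_shape mismatch")
    out = np.empty((nx, ny, nc, np_), dtype=H.matrix.dtype)
    for p in range(np_):
        out[..., p] = _adjoint_single(H.matrix[p * rows_per:(p + 1) * rows_per], (nx, ny, nc), H.r)
    return out


def multiplicity_map(shape: tuple[int, int], r: int) -> np.ndarray:
    """Number of interior r×r windows covering each (kx, ky) sample.

    Interior samples are covered by r² windows, corners by 1; the map is
    the outer product of two 1-D covering counts and is positive everywhere.
    """
    nx, ny = shape
    if r < 1 or r > min(nx, ny):
        raise SizeError(f"window r={r} exceeds grid extents {(nx, ny)}")

    def count_1d(n: int) -> np.ndarray:
        i = np.arange(n)
        return np.minimum(i, n - r) - np.maximum(0, i - r + 1) + 1

    return np.asarray(count_1d(nx)[:, None] * count_1d(ny)[None, :], dtype=np.float64)


def normalized_adjoint(H: HankelMatrix) -> np.ndarray:
    """Count-normalized adjoint: the generalized inverse of the lift on its range."""
    grid = hankel_adjoint(H)
    m = multiplicity_map(H.source_shape[:2], H.r)
    return grid / m[:, :, None, None]


def singular_spectrum(H: HankelMatrix, k: int | None = None) -> np.ndarray:
    """Top-k singular values of the lifted matrix, normalized by the largest.

    The decay of this spectrum is the rank-deficiency diagnostic: block
    lifts over many contrasts decay faster than single-contrast lifts.
    """
    if H.matrix.size == 0:
        raise SizeError("cannot take the spectrum of an empty matrix")
    s = np.linalg.svd(H.matrix, compute_uv=False)
    if k is not None:
        if k < 1 or k > s.size:
            raise SizeError(f"k={k} outside [1, {s.size}]")
        s = s[:k]
    return s / s[0]
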