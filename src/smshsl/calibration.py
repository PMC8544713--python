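"""Coil compression and complementary-slice null-space estimation.

For a slice of interest s in an SMS group, the complement x_s^c is the
CAIPI-modulated sum of all other simultaneously excited slices. Its
(block-)Hankel lift is rank-deficient, so the right singular vectors with
small singular values span an annihilating subspace N_s^c: multiplying any
lift of the complement by N_s^c gives (nearly) zero, while the slice of
interest passes. The cutoff is relative to the largest singular value
(default 0.05); singular values exactly at the threshold are excluded.

Calibration lifting uses only the acquired central-ky band (valid windows
within the strip) — zero-filled borders would inject spurious null vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .hankel_ops import block_hankel_lift
from .io_core import KSpaceVolume
from .simulation import CAIPISchedule, caipi_modulate

logger = logging.getLogger("smshsl")


class EstimationError(RuntimeError):
    """Null-space estimation could not produce any basis vector."""


@dataclass
class NullSpaceBasis:
    """Orthonormal columns spanning the complement's annihilating subspace.

    ``basis`` is r²Nc × K; ``singular_values`` is the full calibration
    spectrum the basis was cut from, descending.
    """

    basis: np.ndarray
    cutoff_used: float
    singular_values: np.ndarray
    slice_of_interest: int | None = None
    r: int | None = None
    signal_basis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.basis.ndim != 2 or self.basis.shape[1] < 1:
            raise ValueError("basis must be a matrix with at least one column")
        gram = self.basis.conj().T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-10):
            raise ValueError("basis columns are not orthonormal to 1e-10")

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    @property
    def signal_dim(self) -> int:
        """Dimension of the complement's retained (signal) subspace."""
        return self.basis.shape[0] - self.basis.shape[1]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("basis", data=self.basis)
            f.create_dataset("singular_values", data=self.singular_values)
            if self.signal_basis is not None:
                f.create_dataset("signal_basis", data=self.signal_basis)
            f.attrs["cutoff_used"] = self.cutoff_used
            f.attrs["slice_of_interest"] = -1 if self.slice_of_interest is None else self.slice_of_interest
            f.attrs["r"] = -1 if self.r is None else self.r
        return path

    @classmethod
    def load(cls, path: str | Path) -> "NullSpaceBasis":
        with h5py.File(path, "r") as f:
            sl = int(f.attrs["slice_of_interest"])
            r = int(f.attrs["r"])
            sig = np.asarray(f["signal_basis"]) if "signal_basis" in f else None
            return cls(np.asarray(f["basis"]), float(f.attrs["cutoff_used"]),
                       np.asarray(f["singular_values"]),
                       slice_of_interest=None if sl < 0 else sl,
                       r=None if r < 0 else r, signal_basis=sig)


@dataclass
class CalibrationSet:
    """Per-slice low-resolution k-space (central ky lines, all kx and coils)."""

    volumes: list[KSpaceVolume]
    n_lines: int

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("calibration set is empty")
        nc = {v.data.shape[2] for v in self.volumes}
        if len(nc) != 1:
            raise ValueError(f"inconsistent coil counts {nc}")
        for v in self.volumes:
            if v.data.shape[1] != self.n_lines:
                raise ValueError(
                    f"volume has {v.data.shape[1]} ky lines, expected {self.n_lines}")

    @property
    def n_slices(self) -> int:
        return len(self.volumes)


def coil_compress(k: KSpaceVolume, n_out: int) -> tuple[KSpaceVolume, np.ndarray]:
    """SVD coil compression onto ``n_out`` virtual channels.

    The (samples × coils) data matrix is factored A = UΣVᴴ and projected
    onto the leading right singular vectors: compressed = A·V[:, :n_out].
    The Nc × n_out compression matrix is returned so the identical
    projection can be applied to calibration data.
    """
    nc = k.data.shape[2]
    if n_out <= 0:
        raise ValueError(f"n_out must be positive, got {n_out}")
    if n_out > nc:
        raise ValueError(f"n_out={n_out} exceeds coil count {nc}")
    # samples × coils, contrasts treated as extra samples
    moved = np.moveaxis(k.data, 2, -1)
    a = moved.reshape(-1, nc)
    _, s, vh = np.linalg.svd(a, full_matrices=False)
    comp = vh.conj().T[:, :n_out]
    retained = float(np.sum(s[:n_out] ** 2) / np.sum(s ** 2)) if s.size else 1.0
    logger.info("coil_compress: %d → %d channels, retained energy %.6f", nc, n_out, retained)
    out = np.moveaxis((a @ comp).reshape(moved.shape[:-1] + (n_out,)), -1, 2)
    return k.with_data(out), comp


def apply_compression(k: KSpaceVolume, comp: np.ndarray) -> KSpaceVolume:
    """Apply a previously computed coil-compression matrix to another volume."""
    nc = k.data.shape[2]
    if comp.shape[0] != nc:
        raise ValueError(f"compression matrix expects {comp.shape[0]} coils, data has {nc}")
    moved = np.moveaxis(k.data, 2, -1)
    out = np.moveaxis(moved @ comp, -1, 2)
    return k.with_data(out)


def build_complement(calib: CalibrationSet | Sequence[KSpaceVolume],
                     slice_of_interest: int, schedule: CAIPISchedule) -> KSpaceVolume:
    """CAIPI-modulated sum of all group slices except the slice of interest.

    The phase is applied before summation so the null space annihilates the
    complement exactly as it appears in the collapsed measurement.
    """
    volumes = calib.volumes if isinstance(calib, CalibrationSet) else list(calib)
    if len(volumes) < 2:
        raise ValueError("complement empty: SMS group must contain at least 2 slices")
    if not 0 <= slice_of_interest < len(volumes):
        raise IndexError(f"slice_of_interest {slice_of_interest} outside group")
    acc = None
    for pos, vol in enumerate(volumes):
        if pos == slice_of_interest:
            continue
        mod = caipi_modulate(vol, pos, schedule)
        acc = mod.data if acc is None else acc + mod.data
    out = volumes[0].with_data(acc)
    out.slice_index = "collapsed"
    out.caipi_id = schedule.schedule_id
    return out


def estimate_nullspace(complement: KSpaceVolume, r: int, cutoff: float = 0.05,
                       slice_of_interest: int | None = None) -> NullSpaceBasis:
    """Annihilating subspace of the complement's block-Hankel lift.

    The complement volume is lifted (per contrast, concatenated row-wise),
    an SVD is taken, and the right singular vectors whose singular values
    fall strictly below cutoff × σ_max form the basis. A contrast-independent
    calibration scan may be passed as a single-contrast volume: replicating
    it along the contrast axis rescales the spectrum by √Np without changing
    the right singular vectors, so no replication is performed.
    """
    if not np.any(complement.data):
        raise EstimationError("complement volume is identically zero")
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    lifted = block_hankel_lift(complement, r)
    rows, cols = lifted.shape
    if cols > rows:
        raise ValueError(
            f"calibration region too small: lift is {rows}×{cols}; need rows >= r²Nc")
    _, s, vh = np.linalg.svd(lifted.matrix, full_matrices=False)
    keep = s < cutoff * s[0]
    k = int(np.count_nonzero(keep))
    if k == 0:
        raise EstimationError(
            f"no singular value below {cutoff} × σ_max; increase the cutoff")
    basis = np.ascontiguousarray(vh[cols - k:].conj().T)  # s is descending
    signal = np.ascontiguousarray(vh[:cols - k].conj().T)
    logger.info("estimate_nullspace: r=%d cutoff=%.3g K=%d/%d", r, cutoff, k, cols)
    return NullSpaceBasis(basis, cutoff, s, slice_of_interest=slice_of_interest,
                          r=r, signal_basis=signal)


def annihilation_score(x: KSpaceVolume, basis: NullSpaceBasis, r: int) -> float:
    """Relative annihilation residual ‖H_P(x)·N‖_F / ‖H_P(x)‖_F.

    Near zero for the complement the basis was built from; order unity for
    the slice of interest. Scale-invariant; defined as 0 for zero input.
    """
    lifted = block_hankel_lift(x, r)
    denom = np.linalg.norm(lifted.matrix)
    if denom == 0.0:
        logger.info("annihilation_score: zero input, score defined as 0")
        return 0.0
    return float(np.linalg.norm(lifted.matrix @ basis.basis) / denom)
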