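"""Data containers, file I/O, configuration and logging shared by all stages.

Conventions fixed here and relied on everywhere else:

* k-space arrays are complex and ordered ``(kx, ky, coil[, contrast])``;
  readers permute whatever axis order a file declares into this one.
* the DC sample sits at index ``(Nx // 2, Ny // 2)`` (centered grids; the
  DFT helpers in :mod:`smshsl.simulation` use matching center shifts).
* k-space containers are HDF5 (datasets ``kspace``, ``ti_ms``, ``tr_ms``,
  ``caipi``, attrs ``slice_index``, ``axis_labels``) with an NPZ dialect
  for lightweight fixtures; real-valued parameter maps go to NIfTI-1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("smshsl")

CANONICAL_AXES_3D = ("kx", "ky", "coil")
CANONICAL_AXES_4D = ("kx", "ky", "coil", "contrast")


class FormatError(ValueError):
    """A container is missing required metadata or declares an unknown layout."""


class DataError(ValueError):
    """Payload values violate an invariant (non-finite entries, bad shapes)."""


@dataclass
class KSpaceVolume:
    """A Cartesian multicoil k-space grid, optionally with a contrast (TI) axis.

    ``data`` is indexed ``(kx, ky, coil)`` or ``(kx, ky, coil, contrast)``.
    ``slice_index`` is an integer slice label or the string ``"collapsed"``
    for SMS data that is the sum of several modulated slices.
    """

    data: np.ndarray
    ti_ms: Sequence[float] | None = None
    tr_ms: float | None = None
    slice_index: int | str | None = None
    caipi_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim not in (3, 4):
            raise DataError(f"k-space payload must be 3-D or 4-D, got shape {self.data.shape}")
        if min(self.data.shape[:3]) < 1:
            raise DataError(f"empty axis in k-space shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("k-space payload contains non-finite entries")
        if self.ti_ms is not None:
            self.ti_ms = [float(t) for t in self.ti_ms]
            if self.data.ndim == 4 and len(self.ti_ms) != self.data.shape[3]:
                raise FormatError(
                    f"TI list has {len(self.ti_ms)} entries but contrast axis is {self.data.shape[3]}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_contrasts(self) -> int:
        return self.data.shape[3] if self.data.ndim == 4 else 1

    @property
    def axis_labels(self) -> tuple[str, ...]:
        return CANONICAL_AXES_4D if self.data.ndim == 4 else CANONICAL_AXES_3D

    def with_data(self, data: np.ndarray) -> "KSpaceVolume":
        """Copy of the metadata wrapped around a new payload."""
        return KSpaceVolume(data, ti_ms=self.ti_ms, tr_ms=self.tr_ms,
                            slice_index=self.slice_index, caipi_id=self.caipi_id)


@dataclass
class ImageVolume:
    """Image-domain counterpart of :class:`KSpaceVolume`.

    ``data`` is ``(x, y[, coil][, contrast][, slice])``; the exact axis set is
    recorded in ``axis_labels``. ``pixel_spacing_mm`` applies to (x, y).
    """

    data: np.ndarray
    axis_labels: tuple[str, ...]
    pixel_spacing_mm: tuple[float, float] = (2.0, 2.0)
    ti_ms: Sequence[float] | None = None
    tr_ms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != len(self.axis_labels):
            raise DataError(
                f"{self.data.ndim}-D payload with {len(self.axis_labels)} axis labels"
            )


@dataclass
class ReconConfig:
    """Solver settings for the slice-unfolding reconstruction.

    Defaults follow the reference acquisition: a 5×5 Hankel window, inner
    factorization rank 120, null-space cutoff at 0.05 of the largest
    calibration singular value, and small regularization weights
    (λℓ, α) = (1e−7, 2e−6) chosen to minimize slice leakage without
    perturbing the measured SMS data.
    """

    kernel_r: int = 5
    rank_R: int | None = 120  # None: match the calibration signal-subspace rank
    nullspace_cutoff: float = 0.05
    lambda_l: float = 1.0e-7
    alpha: float = 2.0e-6
    outer_iters: int = 50
    cg_iters: int = 30
    cg_tol: float = 1.0e-9
    stop_tol: float = 1.0e-4
    seed: int = 0
    solver_dtype: str = "complex128"  # complex64 halves time and memory

    def __post_init__(self) -> None:
        if self.kernel_r < 1:
            raise ValueError(f"kernel_r must be >= 1, got {self.kernel_r}")
        if self.kernel_r % 2 == 0:
            logger.info("config: even kernel_r=%d accepted (odd sizes are customary)", self.kernel_r)
        if not 0.0 < self.nullspace_cutoff < 1.0:
            raise ValueError(
                f"nullspace_cutoff must lie in (0, 1), got {self.nullspace_cutoff}"
            )
        if self.lambda_l <= 0:
            raise ValueError(f"lambda_l must be > 0, got {self.lambda_l}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.rank_R is not None and self.rank_R < 1:
            raise ValueError(f"rank_R must be >= 1 or None, got {self.rank_R}")
        for name in ("outer_iters", "cg_iters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cg_tol", "stop_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.solver_dtype not in ("complex128", "complex64"):
            raise ValueError(f"solver_dtype must be complex128 or complex64, "
                             f"got {self.solver_dtype!r}")

    def config_hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def effective_rank(self, hankel_cols: int, hankel_rows: int,
                       signal_dim: int | None = None) -> int:
        """Inner factorization rank for a given lifted-matrix size.

        ``rank_R=None`` ties the rank to the calibration signal-subspace
        dimension (the complement's retained rank), which scales the
        low-rank constraint with the problem instead of fixing it.
        """
        r = self.rank_R
        if r is None:
            if signal_dim is None:
                raise ValueError("rank_R=None needs the calibration signal dimension")
            r = signal_dim
        return max(1, min(r, hankel_cols, hankel_rows))


# ---------------------------------------------------------------------------
# k-space container I/O


def _permute_to_canonical(data: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    labels = [str(x) for x in labels]
    want = list(CANONICAL_AXES_4D[: data.ndim])
    if sorted(labels) != sorted(want):
        raise FormatError(f"axis labels {labels} cannot be normalized to {want}")
    return np.transpose(data, [labels.index(ax) for ax in want])


def write_kspace(vol: KSpaceVolume, path: str | Path, dialect: str = "hdf5") -> Path:
    """Write a k-space volume to the HDF5 container (or the NPZ dialect)."""
    path = Path(path)
    labels = ",".join(vol.axis_labels)
    slice_index = "none" if vol.slice_index is None else str(vol.slice_index)
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace", data=vol.data)
            f.create_dataset("ti_ms", data=np.asarray(vol.ti_ms if vol.ti_ms is not None else []))
            f.create_dataset("tr_ms", data=float(vol.tr_ms) if vol.tr_ms is not None else np.nan)
            f.create_dataset("caipi", data=np.bytes_(vol.caipi_id or "none"))
            f.attrs["axis_labels"] = labels
            f.attrs["slice_index"] = slice_index
    elif dialect == "npz":
        np.savez(path, kspace=vol.data,
                 ti_ms=np.asarray(vol.ti_ms if vol.ti_ms is not None else []),
                 tr_ms=np.float64(vol.tr_ms if vol.tr_ms is not None else np.nan),
                 caipi=np.bytes_(vol.caipi_id or "none"),
                 axis_labels=np.bytes_(labels), slice_index=np.bytes_(slice_index))
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return path


def _decode(x) -> str:
    raw = x[()] if hasattr(x, "shape") else x
    return raw.decode() if isinstance(raw, bytes) else str(raw)


def read_kspace(path: str | Path, dialect: str = "hdf5") -> KSpaceVolume:
    """Read a k-space volume, normalizing axis order to (kx, ky, coil[, contrast])."""
    path = Path(path)
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("kspace", "ti_ms", "tr_ms", "caipi"):
                if key not in f:
                    raise FormatError(f"container {path} is missing dataset {key!r}")
            if "axis_labels" not in f.attrs:
                raise FormatError(f"container {path} is missing attribute 'axis_labels'")
            data = np.asarray(f["kspace"])
            ti = np.asarray(f["ti_ms"]).tolist()
            tr = float(np.asarray(f["tr_ms"]))
            caipi = _decode(f["caipi"])
            labels = str(f.attrs["axis_labels"]).split(",")
            slice_index = str(f.attrs.get("slice_index", "none"))
    elif dialect == "npz":
        with np.load(path) as f:
            for key in ("kspace", "ti_ms", "tr_ms", "caipi", "axis_labels"):
                if key not in f:
                    raise FormatError(f"container {path} is missing array {key!r}")
            data = f["kspace"]
            ti = f["ti_ms"].tolist()
            tr = float(f["tr_ms"])
            caipi = _decode(f["caipi"])
            labels = _decode(f["axis_labels"]).split(",")
            slice_index = _decode(f["slice_index"]) if "slice_index" in f else "none"
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    if not np.all(np.isfinite(data)):
        raise DataError(f"container {path} holds non-finite k-space samples")
    data = _permute_to_canonical(data, labels)
    sl: int | str | None
    if slice_index == "none":
        sl = None
    elif slice_index == "collapsed":
        sl = "collapsed"
    else:
        sl = int(slice_index)
    vol = KSpaceVolume(data, ti_ms=ti or None, tr_ms=None if np.isnan(tr) else tr,
                       slice_index=sl, caipi_id=None if caipi == "none" else caipi)
    logger.info("read_kspace: %s shape=%s dialect=%s", path.name, data.shape, dialect)
    return vol


# ---------------------------------------------------------------------------
# parameter-map I/O


def write_map(map2d: np.ndarray, path: str | Path,
              pixel_spacing_mm: tuple[float, float] = (2.0, 2.0)) -> Path:
    """Write a real 2-D (or stacked 3-D) map as NIfTI-1, float32, spacing in header."""
    arr = np.asarray(map2d)
    if np.iscomplexobj(arr):
        raise DataError("maps must be real-valued; take magnitude or a component first")
    if not np.all(np.isfinite(arr)):
        raise DataError("map contains non-finite pixels")
    path = Path(path)
    affine = np.diag([pixel_spacing_mm[0], pixel_spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    img.header.set_zooms((pixel_spacing_mm[0], pixel_spacing_mm[1]) + (1.0,) * (arr.ndim - 2))
    nib.save(img, str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path | None) -> ReconConfig:
    """Load a YAML config; keys absent from the file keep their defaults.

    Loading a fully-specified config is idempotent; an empty or missing file
    yields all defaults. Unknown keys raise, so typos do not pass silently.
    """
    if path is None:
        return ReconConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping, got {type(raw).__name__}")
    fields = {f.name: f for f in dataclasses.fields(ReconConfig)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise FormatError(f"config {path} has unknown keys: {sorted(unknown)}")
    coerced = {}
    for key, val in raw.items():
        if val is None:
            coerced[key] = None
        elif fields[key].type in ("float", float):
            coerced[key] = float(val)  # YAML reads "1e-07" as a string
        elif fields[key].type in ("int", int):
            coerced[key] = int(val)
        else:
            coerced[key] = val
    cfg = ReconConfig(**coerced)
    logger.info("load_config: %s hash=%s", path, cfg.config_hash())
    return cfg
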