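"""Pixelwise T1 estimation from multi-TI images and image-quality metrics.

T1 and the equilibrium signal SI0 are fit per pixel by nonlinear least
squares of the inversion-recovery model
SI(TI) = SI0·(1 − 2e^(−TI/T1) + e^(−TR/T1)); the TR recovery term is kept
because TR > 5·T1 does not hold for brain at 3 T. Magnitude images (the
default after root-sum-of-squares coil combination) lose the inversion
sign, so polarity is restored before fitting by flipping the sign of all
samples before a candidate null crossing and keeping the crossing with the
smallest residual. For fixed T1 the model is linear in SI0, so each
candidate is scored by the exact variable-projection residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .simulation import ir_signal

T1_BOUNDS_MS = (50.0, 6000.0)
T1_STARTS_MS = (500.0, 1000.0, 2000.0)


@dataclass
class T1FitResult:
    """Maps produced by :func:`fit_t1_map`.

    Non-converged pixels keep ``converged == False`` and NaN in the maps;
    they are never silently filled.
    """

    t1_ms: np.ndarray
    si0: np.ndarray
    residual: np.ndarray
    fit_mask: np.ndarray
    converged: np.ndarray

    @property
    def converged_fraction(self) -> float:
        n = int(self.fit_mask.sum())
        return float(self.converged[self.fit_mask].sum() / n) if n else 0.0


def _model(t1: float, si0: float, tis: np.ndarray, tr: float) -> np.ndarray:
    return si0 * (1.0 - 2.0 * np.exp(-tis / t1) + np.exp(-tr / t1))


def _varpro_residual(signal: np.ndarray, t1: float, tis: np.ndarray, tr: float) -> tuple[float, float]:
    """Best SI0 (linear) and the residual norm for a fixed T1."""
    f = _model(t1, 1.0, tis, tr)
    denom = float(f @ f)
    si0 = float(signal @ f) / denom if denom > 0 else 0.0
    return si0, float(np.linalg.norm(signal - si0 * f))


def _fit_signed(signal: np.ndarray, tis: np.ndarray, tr: float) -> tuple[float, float, float, bool]:
    """Bounded Levenberg–Marquardt-type fit with a fixed multi-start grid."""
    best = (np.nan, np.nan, np.inf, False)
    for t1_start in T1_STARTS_MS:
        si0_start, _ = _varpro_residual(signal, t1_start, tis, tr)
        if si0_start == 0.0:
            si0_start = float(np.max(np.abs(signal))) or 1.0
        try:
            sol = least_squares(
                lambda th: _model(th[0], th[1], tis, tr) - signal,
                x0=[t1_start, si0_start],
                bounds=([T1_BOUNDS_MS[0], -np.inf], [T1_BOUNDS_MS[1], np.inf]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        res = float(np.linalg.norm(sol.fun))
        if sol.success and res < best[2]:
            best = (float(sol.x[0]), float(sol.x[1]), res, True)
    return best


def fit_t1_pixel(signal: np.ndarray, tis_ms, tr_ms: float,
                 mode: str = "signed") -> tuple[float, float, float]:
    """Fit (T1, SI0) for one pixel's TI curve; returns (T1_ms, SI0, residual).

    ``mode='signed'`` fits the signal as given. ``mode='magnitude'`` fits
    |signal| with polarity restoration: for every candidate null-crossing
    index k the first k samples are negated, the candidate is scored by the
    exact best-SI0 residual on a T1 grid, and the winning sign pattern is
    refit with the full nonlinear search. All-zero input and optimizer
    failure return NaNs (flagged, not filled).
    """
    tis = np.asarray(tis_ms, dtype=np.float64)
    signal = np.asarray(signal, dtype=np.float64)
    if signal.shape != tis.shape:
        raise ValueError(f"signal has {signal.shape}, TI list {tis.shape}")
    if tis.size < 3:
        raise ValueError("need at least 3 TIs to fit (T1, SI0)")
    if not np.any(signal):
        return (np.nan, np.nan, np.nan)
    if mode == "signed":
        t1, si0, res, ok = _fit_signed(signal, tis, tr_ms)
    elif mode == "magnitude":
        mag = np.abs(signal)
        t1_grid = np.geomspace(T1_BOUNDS_MS[0], T1_BOUNDS_MS[1], 60)
        best_k, best_res = 0, np.inf
        for k in range(tis.size + 1):
            signed = mag.copy()
            signed[:k] *= -1.0
            res_k = min(_varpro_residual(signed, t1, tis, tr_ms)[1] for t1 in t1_grid)
            if res_k < best_res:
                best_k, best_res = k, res_k
        signed = mag.copy()
        signed[:best_k] *= -1.0
        t1, si0, res, ok = _fit_signed(signed, tis, tr_ms)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not ok:
        return (np.nan, np.nan, np.nan)
    return (t1, si0, res)


def fit_t1_map(images: np.ndarray, tis_ms, tr_ms: float,
               mask: np.ndarray | None = None, mode: str = "magnitude") -> T1FitResult:
    """Apply :func:`fit_t1_pixel` within a mask over an (x, y, TI) stack.

    Deterministic (fixed multi-start order); reports the converged fraction
    through the result object.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ValueError(f"expected (x, y, TI) stack, got shape {images.shape}")
    tis = np.asarray(tis_ms, dtype=np.float64)
    if images.shape[2] != tis.size:
        raise ValueError(f"stack has {images.shape[2]} contrasts, TI list {tis.size}")
    if mask is None:
        mask = np.any(images != 0, axis=2)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != images.shape[:2]:
        raise ValueError("mask shape does not match the image grid")
    if not mask.any():
        raise ValueError("empty fit mask")

    nx, ny = mask.shape
    t1 = np.full((nx, ny), np.nan)
    si0 = np.full((nx, ny), np.nan)
    res = np.full((nx, ny), np.nan)
    conv = np.zeros((nx, ny), dtype=bool)
    for ix, iy in zip(*np.nonzero(mask)):
        t1_px, si0_px, res_px = fit_t1_pixel(images[ix, iy], tis, tr_ms, mode=mode)
        if np.isfinite(t1_px):
            t1[ix, iy], si0[ix, iy], res[ix, iy] = t1_px, si0_px, res_px
            conv[ix, iy] = True
    return T1FitResult(t1, si0, res, mask, conv)


def nrmse(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Root-mean-square error normalized by the reference maximum.

    (1/max(ref)) · sqrt(mean((ref − est)²)) over all compared pixels.
    """
    ref = np.asarray(reference, dtype=np.float64)
    est = np.asarray(estimate, dtype=np.float64)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {est.shape}")
    if not np.any(ref):
        raise ValueError("nRMSE undefined for an all-zero reference")
    return float(np.sqrt(np.mean((ref - est) ** 2)) / ref.max())


def roi_signal_curve(images: np.ndarray, roi_corner: tuple[int, int],
                     roi_size: int = 3) -> np.ndarray:
    """Mean signal over a square ROI per TI (for relaxation-curve plots)."""
    images = np.asarray(images)
    x0, y0 = roi_corner
    nx, ny = images.shape[:2]
    if x0 < 0 or y0 < 0 or x0 + roi_size > nx or y0 + roi_size > ny:
        raise IndexError(f"ROI {roi_corner}+{roi_size} outside {images.shape[:2]}")
    return images[x0:x0 + roi_size, y0:y0 + roi_size].mean(axis=(0, 1))


def write_curve_tsv(tis_ms, values, path) -> None:
    """Write a TI/value table (e.g. an ROI relaxation curve) as TSV."""
    tis = np.asarray(tis_ms, dtype=float)
    vals = np.asarray(values, dtype=float)
    if tis.shape != vals.shape:
        raise ValueError("TI list and values differ in length")
    with open(path, "w") as f:
        f.write("TI_ms\tvalue\n")
        for t, v in zip(tis, vals):
            f.write(f"{t:g}\t{v:.8g}\n")


def leakage_fraction(recon: np.ndarray, truth_own: np.ndarray,
                     truth_other: np.ndarray) -> float:
    """Fraction of a reconstruction's energy explained by another slice's truth.

    The other slice's (flattened) image is orthogonalized against the
    reconstructed slice's own truth, normalized, and the reconstruction is
    projected onto it; the squared projection over the reconstruction's
    energy is the leakage fraction.
    """
    r = np.asarray(recon, dtype=np.float64).ravel()
    a = np.asarray(truth_own, dtype=np.float64).ravel()
    b = np.asarray(truth_other, dtype=np.float64).ravel()
    a_unit = a / np.linalg.norm(a)
    b_perp = b - (b @ a_unit) * a_unit
    nb = np.linalg.norm(b_perp)
    if nb == 0:
        return 0.0
    q = b_perp / nb
    return float((r @ q) ** 2 / (r @ r))
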