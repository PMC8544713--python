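"""Per-slice joint slice-separation / low-rank recovery from collapsed SMS data.

For each slice of interest s the solver minimizes

    E(x, U, V) = ‖(H_P(y) − H_P(x))·N‖_F²
               + (λℓ/2)(‖U‖_F² + ‖V‖_F²)
               + (α/2)‖U·V − H_P(x)‖_F²

where H_P is the block-Hankel lift over the TI dimension, N the
complementary null-space basis, and U·V a rank-R factorization standing in
for the nuclear norm of H_P(x). The first term separates slices (the null
space annihilates everything except the slice of interest), the factor
penalty enforces low rank, and α couples the two. Alternating-direction
minimization cycles x → U → V: the x subproblem is a quadratic solved by
warm-started conjugate gradients on matrix-free normal equations; the U
and V subproblems are ridge systems with closed-form solutions. Each
subproblem is convex, so the objective trace is non-increasing up to CG
slack, and iteration stops when the cost stops decreasing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationSet, NullSpaceBasis, build_complement, estimate_nullspace
from .hankel_ops import HankelMatrix, block_hankel_lift, hankel_adjoint, multiplicity_map
from .io_core import ImageVolume, KSpaceVolume, ReconConfig
from .simulation import CAIPISchedule, caipi_demodulate, ifft2c

logger = logging.getLogger("smshsl")


class ConvergenceError(RuntimeError):
    """The outer objective increased beyond the allowed CG slack."""


class SolverError(RuntimeError):
    """CG breakdown (non-finite step) inside a subproblem."""


@dataclass
class FactorPair:
    """Rank-R factorization H_P(x) ≈ U·V.

    U holds the spatial coefficients (rows = lifted-window positions across
    contrasts), V the coil basis (columns = r²Nc window/coil entries).
    """

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        if self.U.shape[1] != self.V.shape[0]:
            raise ValueError(f"inner ranks differ: U is {self.U.shape}, V is {self.V.shape}")

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def product(self) -> np.ndarray:
        return self.U @ self.V


@dataclass
class ReconState:
    """Solver output: per-slice k-space estimate, factors, and cost trace."""

    x: KSpaceVolume
    factors: FactorPair
    cost_trace: list[float] = field(default_factory=list)
    converged: bool = False


# ---------------------------------------------------------------------------
# objective and subproblems


def _lift(data: np.ndarray, r: int) -> np.ndarray:
    return block_hankel_lift(data, r).matrix


def _adjoint(mat: np.ndarray, shape: tuple[int, int, int, int], r: int) -> np.ndarray:
    return hankel_adjoint(HankelMatrix(mat, r, shape))


def _norm_sq(mat: np.ndarray) -> float:
    """Squared Frobenius norm accumulated in double precision."""
    flat = mat.ravel()
    return float(np.real(np.vdot(flat, flat).astype(np.complex128))) \
        if flat.dtype == np.complex128 else float(np.sum(np.abs(flat).astype(np.float64) ** 2))


def _null_norm_sq(mat: np.ndarray, N: NullSpaceBasis) -> float:
    """‖mat·N‖_F², via the thin signal basis when that is cheaper.

    [signal | null] right singular vectors are jointly unitary, so
    ‖M·N‖² = ‖M‖² − ‖M·S‖².
    """
    if N.signal_basis is not None and N.signal_basis.shape[1] < N.dim:
        total = _norm_sq(mat)
        sig = _norm_sq(mat @ N.signal_basis)
        return max(total - sig, 0.0)
    return _norm_sq(mat @ N.basis)


def _project_null(mat: np.ndarray, N: NullSpaceBasis) -> np.ndarray:
    """mat @ N·Nᴴ, routed through whichever basis is thinner."""
    if N.signal_basis is not None and N.signal_basis.shape[1] < N.dim:
        S = N.signal_basis
        return mat - (mat @ S) @ S.conj().T
    return (mat @ N.basis) @ N.basis.conj().T


def objective(x, U: np.ndarray, V: np.ndarray, y, N: NullSpaceBasis,
              cfg: ReconConfig, hy: np.ndarray | None = None) -> float:
    """Evaluate the joint objective E(x, U, V). ``hy`` may cache H_P(y)."""
    r = cfg.kernel_r
    xd = x.data if isinstance(x, KSpaceVolume) else np.asarray(x)
    hx = _lift(xd, r)
    if hy is None:
        hy = _lift(y.data if isinstance(y, KSpaceVolume) else np.asarray(y), r)
    fid = _null_norm_sq(hy - hx, N)
    fac = 0.5 * cfg.lambda_l * (_norm_sq(U) + _norm_sq(V))
    cpl = 0.5 * cfg.alpha * _norm_sq(U @ V - hx)
    val = float(fid + fac + cpl)
    if not np.isfinite(val):
        raise FloatingPointError("objective is non-finite")
    return val


def _apply_B(mat: np.ndarray, N: NullSpaceBasis, half_alpha: float) -> np.ndarray:
    """mat @ (N·Nᴴ + (α/2)·I) through the thinnest available factor."""
    return _project_null(mat, N) + half_alpha * mat


def solve_x(y, UV: np.ndarray, N: NullSpaceBasis, cfg: ReconConfig,
            x0: np.ndarray | None = None, hy: np.ndarray | None = None,
            shape: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """Minimize the x subproblem ‖(H_P(y)−H_P(x))N‖² + (α/2)‖UV−H_P(x)‖².

    Solved by conjugate gradients on the normal equations
    H_P*(H_P(x)(NNᴴ + (α/2)I)) = H_P*(H_P(y)NNᴴ + (α/2)UV),
    matrix-free (lift → small matmul → adjoint per application). Warm
    starting from the current iterate makes every CG step decrease the
    subproblem value, so the outer objective can never increase here.
    """
    r = cfg.kernel_r
    yd = y.data if isinstance(y, KSpaceVolume) else np.asarray(y)
    if yd.ndim == 3:
        yd = yd[..., None]
    if shape is None:
        shape = yd.shape
    if hy is None:
        hy = _lift(yd, r)
    ha = 0.5 * cfg.alpha

    b = _adjoint(_project_null(hy, N) + ha * UV, shape, r)

    def A(v: np.ndarray) -> np.ndarray:
        return _adjoint(_apply_B(_lift(v, r), N, ha), shape, r)

    x = np.zeros(shape, dtype=yd.dtype) if x0 is None else x0.astype(yd.dtype, copy=True)
    rres = b - A(x)
    p = rres.copy()
    rs = float(np.real(np.vdot(rres, rres)))
    b_norm = float(np.real(np.vdot(b, b)))
    tol2 = (cfg.cg_tol ** 2) * max(b_norm, 1e-300)
    for it in range(cfg.cg_iters):
        if rs <= tol2:
            break
        Ap = A(p)
        denom = float(np.real(np.vdot(p, Ap)))
        if not np.isfinite(denom) or denom <= 0:
            raise SolverError(f"CG breakdown at iteration {it}: curvature {denom}")
        alpha_k = rs / denom
        x = x + alpha_k * p
        rres = rres - alpha_k * Ap
        rs_new = float(np.real(np.vdot(rres, rres)))
        if not np.isfinite(rs_new):
            raise SolverError(f"CG breakdown at iteration {it}: residual non-finite")
        p = rres + (rs_new / rs) * p
        rs = rs_new
    return x


def solve_U(hx: np.ndarray, V: np.ndarray, cfg: ReconConfig) -> np.ndarray:
    """Closed-form ridge update U = α·H·Vᴴ·(α·V·Vᴴ + λℓ·I)⁻¹ (an R×R system)."""
    R = V.shape[0]
    G = cfg.alpha * (V @ V.conj().T)
    G.flat[::R + 1] += cfg.lambda_l  # ridge without dtype promotion
    rhs = cfg.alpha * (hx @ V.conj().T)
    try:
        cond = np.linalg.cond(G)
        if cond > 1.0 / np.finfo(np.float64).eps:
            logger.warning("solve_U: R×R system condition %.3g, using pseudo-inverse", cond)
            return rhs @ np.linalg.pinv(G)
        return np.linalg.solve(G.conj().T, rhs.conj().T).conj().T
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(G)


def solve_V(hx: np.ndarray, U: np.ndarray, cfg: ReconConfig) -> np.ndarray:
    """Closed-form ridge update V = (α·Uᴴ·U + λℓ·I)⁻¹·α·Uᴴ·H (mirror of solve_U)."""
    R = U.shape[1]
    G = cfg.alpha * (U.conj().T @ U)
    G.flat[::R + 1] += cfg.lambda_l  # ridge without dtype promotion
    rhs = cfg.alpha * (U.conj().T @ hx)
    try:
        cond = np.linalg.cond(G)
        if cond > 1.0 / np.finfo(np.float64).eps:
            logger.warning("solve_V: R×R system condition %.3g, using pseudo-inverse", cond)
            return np.linalg.pinv(G) @ rhs
        return np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(G) @ rhs


def _cast_basis(N: NullSpaceBasis, dtype: np.dtype) -> NullSpaceBasis:
    """Shallow copy of the basis in the solver's working precision."""
    if N.basis.dtype == dtype:
        return N
    cast = dataclasses.replace(N)
    cast.basis = N.basis.astype(dtype)
    if N.signal_basis is not None:
        cast.signal_basis = N.signal_basis.astype(dtype)
    return cast


def _init_factors(hx: np.ndarray, rank: int, seed: int) -> FactorPair:
    """Randomized range finder of H_P(x⁰) at the target rank (seeded)."""
    rng = np.random.default_rng(seed)
    rows, cols = hx.shape
    rank = max(1, min(rank, rows, cols))
    G = (rng.standard_normal((cols, rank))
         + 1j * rng.standard_normal((cols, rank))).astype(hx.dtype)
    Q, _ = np.linalg.qr(hx @ G)
    return FactorPair(Q, Q.conj().T @ hx)


def _initial_x(hy: np.ndarray, N: NullSpaceBasis,
               shape: tuple[int, int, int, int], r: int) -> np.ndarray:
    """Slice-passing seed: count-normalized adjoint of H_P(y)·N·Nᴴ.

    Projecting the measured lift onto the annihilating directions keeps
    only content the complement cannot produce — a rough but leakage-free
    first estimate of the slice of interest.
    """
    grid = _adjoint(_project_null(hy, N), shape, r)
    m = multiplicity_map(shape[:2], r)
    return grid / m[:, :, None, None]


def reconstruct_slice(y: KSpaceVolume, N: NullSpaceBasis, cfg: ReconConfig) -> ReconState:
    """Alternating minimization x → U → V until the cost stops decreasing.

    Terminates when the relative objective decrease drops below
    ``cfg.stop_tol`` or ``cfg.outer_iters`` is reached; raises
    :class:`ConvergenceError` if the trace rises beyond 10× the CG slack.
    """
    r = cfg.kernel_r
    dtype = np.dtype(cfg.solver_dtype)
    yd = y.data if y.data.ndim == 4 else y.data[..., None]
    yd = yd.astype(dtype, copy=False)
    shape = yd.shape
    N = _cast_basis(N, dtype)
    hy = _lift(yd, r)
    rows, cols = hy.shape
    rank = cfg.effective_rank(cols, rows, signal_dim=N.signal_dim)

    x = _initial_x(hy, N, shape, r).astype(dtype, copy=False)
    hx = _lift(x, r)
    fac = _init_factors(hx, rank, cfg.seed)
    trace = [objective(x, fac.U, fac.V, yd, N, cfg, hy=hy)]
    converged = False
    # single precision leaves ~1e-6 relative jitter on the cost trace
    slack = max(10.0 * cfg.cg_tol, 1e3 * float(np.finfo(dtype).eps))
    for it in range(cfg.outer_iters):
        x = solve_x(yd, fac.product(), N, cfg, x0=x, hy=hy, shape=shape)
        hx = _lift(x, r)
        U = solve_U(hx, fac.V, cfg)
        V = solve_V(hx, U, cfg)
        fac = FactorPair(U, V)
        cost = objective(x, U, V, yd, N, cfg, hy=hy)
        prev = trace[-1]
        trace.append(cost)
        logger.info("reconstruct_slice[%s]: outer %d cost %.6e", y.slice_index, it, cost)
        if cost > prev * (1.0 + slack) and cost - prev > slack:
            raise ConvergenceError(
                f"objective increased at outer iteration {it}: trace={trace}")
        if prev > 0 and (prev - cost) / prev < cfg.stop_tol:
            converged = True
            break
    x = x.astype(np.complex128, copy=False)
    vol = KSpaceVolume(x if y.data.ndim == 4 else x[..., 0],
                       ti_ms=y.ti_ms, tr_ms=y.tr_ms,
                       slice_index=N.slice_of_interest, caipi_id=y.caipi_id)
    return ReconState(vol, fac, trace, converged)


# ---------------------------------------------------------------------------
# group orchestration


def rss_combine(coil_images: np.ndarray, axis: int = 2) -> np.ndarray:
    """Root-sum-of-squares magnitude combination across the coil axis."""
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=axis))


def phase_sensitive_combine(coil_images: np.ndarray, ref_contrast: int = -1) -> np.ndarray:
    """Signed (PSIR-style) coil combination of an (x, y, coil, contrast) stack.

    Uses the longest-TI image as phase reference (fully recovered, hence
    positive), projecting every contrast onto it:
    Re[Σ_c img_p,c · conj(img_ref,c)] / ‖img_ref‖. Recovers the inversion
    sign that root-sum-of-squares combination discards, so T1 can be fit
    in signed mode without polarity restoration. Scale matches RSS.
    """
    if coil_images.ndim != 4:
        raise ValueError(f"expected (x, y, coil, contrast), got {coil_images.shape}")
    ref = coil_images[:, :, :, ref_contrast]
    norm = np.sqrt(np.sum(np.abs(ref) ** 2, axis=2))
    norm = np.where(norm > 0, norm, 1.0)
    num = np.real(np.sum(coil_images * ref.conj()[:, :, :, None], axis=2))
    return num / norm[:, :, None]


def own_signal_rank(calib: KSpaceVolume, r: int, cutoff: float) -> int:
    """Rank of a slice's own calibration lift at the relative cutoff.

    This is the natural inner rank for the factorization: the lifted matrix
    of the slice of interest carries this many significant directions.
    """
    s = np.linalg.svd(block_hankel_lift(calib, r).matrix, compute_uv=False)
    return max(1, int(np.count_nonzero(s >= cutoff * s[0])))


def reconstruct_group(y: KSpaceVolume, calib: CalibrationSet | list[KSpaceVolume],
                      schedule: CAIPISchedule, cfg: ReconConfig,
                      return_complex: bool = False):
    """Unfold every slice of an SMS group from the collapsed measurement.

    Per slice: build the CAIPI-modulated complement from calibration data,
    estimate its null space, run :func:`reconstruct_slice`, undo the CAIPI
    phase, inverse-DFT to image space and coil-combine (root sum of
    squares) per TI. Returns an :class:`ImageVolume` with axes
    (x, y, contrast, slice) — slice order follows the schedule — plus the
    per-slice :class:`ReconState` list (and complex coil images on request).
    """
    volumes = calib.volumes if isinstance(calib, CalibrationSet) else list(calib)
    ns = schedule.sms_factor
    if len(volumes) != ns:
        raise ValueError(f"calibration covers {len(volumes)} slices, schedule expects {ns}")
    yd = y.data if y.data.ndim == 4 else y.data[..., None]
    nx, ny_, _, np_ = yd.shape

    mags = np.empty((nx, ny_, np_, ns), dtype=np.float64)
    states: list[ReconState] = []
    complex_out = []
    for pos in range(ns):
        comp = build_complement(volumes, pos, schedule)
        N = estimate_nullspace(comp, cfg.kernel_r, cfg.nullspace_cutoff,
                               slice_of_interest=pos)
        slice_cfg = cfg
        if cfg.rank_R is None:
            # tie the factorization rank to the slice of interest's own
            # calibration rank at the null-space cutoff
            rank = own_signal_rank(volumes[pos], cfg.kernel_r, cfg.nullspace_cutoff)
            slice_cfg = dataclasses.replace(cfg, rank_R=rank)
        state = reconstruct_slice(y, N, slice_cfg)
        demod = caipi_demodulate(state.x, pos, schedule)
        imgs = ifft2c(demod.data if demod.data.ndim == 4 else demod.data[..., None])
        mags[:, :, :, pos] = rss_combine(imgs, axis=2)
        states.append(state)
        if return_complex:
            complex_out.append(imgs)
    out = ImageVolume(mags, ("x", "y", "contrast", "slice"),
                      ti_ms=y.ti_ms, tr_ms=y.tr_ms)
    if return_complex:
        return out, states, complex_out
    return out, states
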