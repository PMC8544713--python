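# Methods

## Problem

Simultaneous-multislice (SMS) MRI excites several slices at once; the
measured k-space `y = Σ_s x_s + n` is the sample-wise sum of the
slice k-spaces after each slice has received a slice-specific CAIPI phase
ramp over the phase-encode lines (an image-domain shift of `s·FOV/Ns`).
For quantitative T1 mapping the acquisition is repeated at `Np` inversion
times, so each slice contributes a whole multi-contrast stack. The task is
to unfold the collapsed measurement into per-slice stacks and then fit a
T1 map per slice.

## Reconstruction model

`smshsl` implements a Hankel-subspace-learning reconstruction extended
over the parameter (TI) dimension:

1. **Lifting.** `H(x)` maps a multicoil grid to a matrix whose rows are
   vectorized `r×r` sliding windows across all coils (rows
   `(Nx−r+1)(Ny−r+1)`, columns `r²Nc`; only fully interior windows).
   `H_P(x)` stacks the per-contrast lifts row-wise. Local k-space
   correlations (finite image support, smooth coil modulation, shared
   structure across TIs) make these matrices strongly rank-deficient, and
   the block matrix over contrasts more so than any single contrast.

2. **Null space.** For a slice of interest `s`, the complement `x_s^c`
   (CAIPI-modulated sum of the other slices, built from per-slice
   calibration data) is lifted and SVD'd; right singular vectors with
   singular values below `cutoff·σ_max` (default 0.05, strict inequality)
   span an annihilating basis `N`: `H_P(x_s^c)·N ≈ 0` while the slice of
   interest passes. The null space is assumed contrast-invariant, so one
   basis serves all TIs.

3. **Objective.** Slice separation and low-rank recovery are solved
   jointly,

       E(x, U, V) = ‖(H_P(y) − H_P(x))·N‖_F²
                  + (λℓ/2)(‖U‖² + ‖V‖²)
                  + (α/2)‖U·V − H_P(x)‖_F²,

   where `U·V` is a rank-`R` factorization standing in for the nuclear
   norm of `H_P(x)` (the SVD-free low-rank surrogate; the factor-norm
   penalty equals the nuclear norm at the constrained optimum).
   Alternating minimization cycles `x → U → V`: the `x` subproblem is a
   quadratic solved by warm-started conjugate gradients on matrix-free
   normal equations; `U` and `V` have closed-form ridge solutions. Each
   subproblem is convex, so the cost trace is non-increasing (to CG
   slack); iteration stops when the relative decrease falls below
   `stop_tol` or `outer_iters` is reached.

4. **Output.** Per slice: undo the CAIPI phase in k-space, inverse
   (centered, unitary) DFT, root-sum-of-squares coil combination per TI.
   The complex coil images are also available, and
   `phase_sensitive_combine` projects them onto the longest-TI image
   (which is fully recovered, hence positive) to produce signed images —
   the PSIR-style combination that keeps the inversion sign for T1
   fitting without polarity restoration.

### Why the inner rank matters

The fidelity term alone cannot separate slices: `x = y` zeroes it exactly
(lifting is linear). Separation comes from the rank constraint — the
composite (multi-slice) lift has roughly `Ns` times the rank of one
slice, so a factorization with `R` between the single-slice rank and the
composite rank admits the slice of interest but not the mixture. The
default `rank_R = 120` matches the reference acquisition scale
(120×120 grid, 12 coils, `r²Nc = 300` columns). Because the right value
scales with the problem, `rank_R = None` selects it per slice as the
number of calibration singular values at or above the null-space cutoff
(the slice's own signal rank); this is what the bundled experiments use.

### Parameter scales

`λℓ` and `α` multiply Frobenius norms of the data, so their useful
magnitudes depend on the units of the k-space samples. The config
defaults `(λℓ, α) = (1e−7, 2e−6)` correspond to raw scanner units in the
reference setting. For the unit-amplitude synthetic phantoms generated
here, the tests and the acceptance experiments use `α = 1.0` (with the
same tiny `λℓ`), which balances the separation and coupling terms at that
data scale; with `α` orders of magnitude below the data scale the `x`
update cannot transfer the low-rank information and the iteration stalls.
`λℓ` only damps the factors and its exact magnitude is uncritical.

Other numerical choices:

* **Initialization.** `x⁰` is the count-normalized adjoint of
  `H_P(y)·N·Nᴴ` — the component of the measurement that the complement
  cannot produce, i.e. a rough leakage-free seed of the slice of
  interest. (Projecting onto the orthogonal complement `I − N·Nᴴ`
  instead would retain the complement in full, since a matrix's row
  space is orthogonal to its null space.) `U⁰, V⁰` come from a seeded
  randomized range finder of `H_P(x⁰)`.
* **CG.** Warm-started from the current iterate, so truncated solves
  still descend; defaults `cg_iters = 30`, `cg_tol = 1e−9` (the bundled
  experiments use 8 inner iterations — with warm starts, many cheap
  outer cycles beat few expensive ones).
* **Ties at the cutoff** are excluded from the null space (strict `<`).
* **Degenerate inputs.** `Np = 1` runs the identical code path with a
  length-1 contrast axis and reproduces the single-contrast
  reconstruction bit-for-bit; a zero complement raises an estimation
  error rather than returning an empty basis.

## T1 estimation

Pixelwise nonlinear least squares of the inversion-recovery
gradient-echo model

    SI(TI) = SI0·(1 − 2·e^(−TI/T1) + e^(−TR/T1)),

fit over `(T1, SI0)` with bounds `T1 ∈ [50, 6000]` ms and a fixed
multi-start grid `{500, 1000, 2000}` ms (best residual wins; order fixed,
so fits are deterministic). The TR term is kept: at 3 T with TR = 3 s and
brain T1 of 1000–2000 ms, the common `TR > 5·T1` shortcut does not hold.
Magnitude images (the default after RSS combination) lose the inversion
sign, so polarity is restored by negating all samples before each
candidate null crossing, scoring every candidate by the exact
variable-projection residual (SI0 is linear given T1) on a coarse T1
grid, and refitting the winner in full. Non-converged or all-zero pixels
are flagged, never filled.

Image quality is reported as nRMSE — RMS error over compared pixels
normalized by the reference maximum — and slice leakage as the squared
projection of a reconstruction onto the other slice's truth image
(orthogonalized against the slice's own truth) over the reconstruction's
energy.

## Synthetic data

The generator emulates the validation acquisition end to end: elliptical
head-like phantoms with white-matter (T1 800 ms), gray-matter (1400 ms)
and CSF (4000 ms) compartments whose geometry shifts smoothly with slice
index; Gaussian-profile loop coils on a ring (σ = 0.45 half-FOV,
the center-to-edge falloff of elements about half a head-FOV across)
with smooth complex phase and a small per-slice ring rotation; the
signed IR signal entering the complex image through the coil phase; a
centered unitary DFT; linear CAIPI phase `2π·s·m/Ns` over centered line
index `m`; sample-wise collapse; complex Gaussian noise added once to
the collapsed measurement; and central-line calibration extraction
(default 32 lines). Everything is deterministic given a seed.

Default experiment scales: tests run 32–64 px grids with 6–8 coils,
SMS factors 2–3 and 3–5 TIs drawn from the 15-TI train
(50, 250, …, 2850 ms at TR = 3000 ms); the full 120×120 / 12-coil /
SMS-5 / 15-TI geometry is available behind `--full-scale`.

What the generator does **not** model: EPI readout artifacts (ghosting,
distortion, T2* decay), TE weighting, slice-profile and B1 effects,
motion, and physiological noise. Passing tests therefore demonstrate the
correctness and conditioning of the separation/recovery machinery on an
idealized but fully known forward model, not robustness to sequence
non-idealities of in-vivo EPI data.

## Known limitations

* The null space is estimated from noiseless calibration in the bundled
  experiments; noisy calibration raises the annihilation floor and with
  it the reconstruction error.
* The per-slice problems are solved independently; no joint coupling
  across the group beyond the shared measurement.
* Hard-edged phantom compartments are not band-limited, so their lifts
  are only approximately low-rank; annihilation residuals of ~3–6% at
  the 0.05 cutoff bound the achievable separation on these scenes.
* T1 accuracy for small, bright, long-T1 structures (the CSF
  compartment) is the weak point: where another slice's bright features
  land on them under the CAIPI shift, the near-null calibration
  directions admit TI-structured contamination, and a T1 of 4000 ms
  sampled only to TI = 2850 ms amplifies signal error into T1 error
  roughly eightfold. White- and gray-matter medians recover to a few
  tenths of a percent; the pooled CSF median sits near 2.5% on the
  SMS-3 test scene, concentrated in the slice whose ventricles collide
  with a neighbor's bright structures. Tissue medians are therefore
  evaluated on interior (eroded) masks with signed fits, the analogue
  of interior-ROI evaluation.
* Reconstruction cost is dominated by dense products with the lifted
  matrix; desk-scale problems (≤ 64², Np ≤ 5) run in minutes per slice
  on one core, and the full-scale geometry is correspondingly heavier.
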