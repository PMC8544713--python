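# smshsl — SMS slice unfolding with block-Hankel subspace learning, and T1 mapping

Simultaneous-multislice (SMS) MRI accelerates quantitative imaging by
exciting several slices at once: the scanner records one k-space that is
the sum of all excited slices, each tagged with a slice-specific CAIPI
phase ramp. `smshsl` separates such collapsed multicoil, multi-inversion-
time measurements back into per-slice image stacks and fits T1 maps from
them. It is aimed at MR-physics researchers prototyping SMS parameter-
mapping reconstructions on simulated or retrospectively collapsed data.

## Method

Writing `H_P(x)` for the block-Hankel lifting of a multi-TI k-space stack
(vectorized r×r sliding windows across coils, concatenated over the TI
dimension), and `N` for the right singular vectors of the *complementary*
slices' lifted calibration data with singular values below 0.05·σ_max,
each slice `x_s` is recovered from the collapsed measurement `y` by

    min_{x,U,V}  ‖(H_P(y) − H_P(x))·N‖_F²
               + (λℓ/2)(‖U‖_F² + ‖V‖_F²)
               + (α/2)‖U·V − H_P(x)‖_F²

— the null-space term separates slices (`N` annihilates the complement,
passes the slice of interest, and is contrast-invariant across TIs), and
the rank-R factorization `U·V` enforces the strong low-rankness of the
multi-contrast block-Hankel matrix. The objective is minimized by
alternating directions (CG for `x`, closed-form ridge updates for `U`,
`V`). Unfolded stacks are CAIPI-demodulated, inverse-DFT'd, coil-combined
(root sum of squares), and fit pixelwise with the inversion-recovery
model `SI(TI) = SI0·(1 − 2e^(−TI/T1) + e^(−TR/T1))`, including polarity
restoration for magnitude data. See `docs/methods.md` for assumptions,
parameter scales and limitations.

## Worked example

```bash
smshsl simulate --out data --seed 5 --nx 32 --np 3 --sms 2 --coils 6
smshsl recon --collapsed data/collapsed.h5 \
             --calib data/calib00.h5 --calib data/calib01.h5 \
             --auto-rank --alpha 1.0 --out rec
smshsl fit --images rec/recon_magnitude.nii.gz --ti 50,1450,2850 --out maps
smshsl eval --reference rec/recon_magnitude.nii.gz \
            --estimate rec/recon_magnitude.nii.gz --out ev
```

`simulate` writes a two-slice 32×32 phantom dataset (per-slice k-space,
collapsed SMS measurement, 32-line calibration, ground-truth images and a
scene manifest). `recon` prints per-slice progress to stderr, e.g.

```
recon: unfolded 2 slices into rec
```

and writes the magnitude stack (x, y, TI, slice) as NIfTI, the complex
per-slice k-space as HDF5 and the objective traces as JSON — the traces
are non-increasing, and on this noiseless example both unfolded slices
match the simulated truth (`data/truth_rss.npy`) at an nRMSE of 0.004.
`fit` prints

```
fit: slice 0 converged fraction 1.000
fit: slice 1 converged fraction 1.000
```

and writes `t1_ms.nii.gz` whose compartments read back the phantom values
(white matter 800 ms, gray matter 1400 ms, CSF 4000 ms; the map's median
over tissue is 802 ms, white matter being the largest compartment).
`eval` compares two stacks, writing an error map and a per-volume nRMSE
table (all zeros when a stack is compared with itself, as above).

The same pipeline is available as a library (`smshsl.simulation`,
`smshsl.calibration`, `smshsl.recon`, `smshsl.quantify`) for scripted
experiments; `--full-scale` switches the simulator to the full
120×120 / 12-coil / SMS-5 / 15-TI geometry.

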