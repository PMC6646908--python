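# hdprost

Joint reconstruction of undersampled multi-contrast MRI by high-dimensionality
patch-based regularization (HD-PROST), with a complete 2D magnetic resonance
fingerprinting (MRF) pathway and a synthetic acquisition simulator so the whole
system runs and validates without scanner data.

## Who this is for

Researchers in quantitative MRI reconstruction who want a self-contained,
testable implementation of patch-tensor regularized reconstruction for
multi-contrast acquisitions: accelerated parameter mapping (T1/T2 via MRF) and
multi-weighted structural imaging (e.g. magnetization-transfer series).

## The method

Multi-contrast images `X ∈ C^{M×L}` (L contrasts or subspace coefficients) are
recovered from undersampled multi-coil k-space `Y` by solving

    min_X  1/2 ‖E X − Y‖_F²  +  λ Σ_p ‖T_p‖_*     s.t.   T_p = P_p X

where `E = A F S` (coil sensitivities, Fourier transform, sampling) and `P_p`
extracts, for each reference patch p, the K most similar patches across all L
contrasts into a third-order tensor `T_p ∈ C^{N×K×L}`. ADMM splits the problem
into:

1. **Data consistency** — a Tikhonov-regularized SENSE solve
   `(EᴴE + μI) X = EᴴY + μT − b` by conjugate gradient;
2. **Patch-tensor denoising** — block matching, complex higher-order SVD of
   each `T_p`, hard truncation of the multilinear singular vectors at
   `τ = 2λ/μ`, and sliding-window aggregation;
3. **Dual update** — `b ← b + μ(X − T)`.

For radial MRF the encoding operator becomes `E = A U_r F S`: the time series
is compressed onto the rank-r temporal subspace `U_r` of an extended-phase-graph
(EPG) simulated dictionary, the r subspace coefficient images are
reconstructed, and per-voxel T1/T2/M0 follow from inner-product dictionary
matching. Low-rank inversion (LRI) and locally-low-rank (LLR) comparators
share the identical data-consistency path.

## Worked example

Simulate the 9-vial T1/T2 phantom acquired with one golden-angle radial spoke
per time point, reconstruct, and match:

```python
from hdprost.experiments import run_mrf_phantom_experiment

res = run_mrf_phantom_experiment(matrix=128, n_timepoints=500, n_coils=8,
                                 snr_db=30.0, seed=1)
print("truth T1 [ms]:", res.truth_t1.round(0))
print("recon T1 [ms]:", res.mean_t1["hdprost"].round(0))
print("T1 R^2:", round(res.r_squared_t1["hdprost"], 5))
```

prints (seed 1):

```
truth T1 [ms]: [ 255.  318.  396.  494.  616.  768.  958. 1194. 1489.]
recon T1 [ms]: [ 255.  318.  397.  495.  618.  770.  962. 1198. 1497.]
T1 R^2: 1.0
```

ROI-mean T1 over the nine vials tracks the ground truth to within a few
milliseconds despite the ~251-fold undersampling per time point; the
coefficient of determination of the linear fit is ≥ 0.98.

The same stages are scriptable from the shell:

```bash
hdprost --seed 1 simulate mrf --matrix 128 --timepoints 500 --out phantom.h5
hdprost dict build --timepoints 500 --rank 10 --out dict.h5
hdprost recon hdprost phantom.h5 --dictionary dict.h5 --out recon.h5
hdprost match recon.h5 --dictionary dict.h5 --out-prefix maps
```

writing T1/T2/M0 as NIfTI volumes (milliseconds for T1/T2).

## Layout

- `hdprost.encoding` — Cartesian and radial-subspace forward/adjoint operators
  (exactly adjoint pairs; the NUFFT is a Kaiser-Bessel gridding transform with
  a sparse interpolation matrix).
- `hdprost.patch_denoise` — block matching, patch-tensor construction,
  truncated complex HOSVD, aggregation.
- `hdprost.admm` — the outer loop and CG data-consistency solve.
- `hdprost.mrf` — EPG simulation (with slice-profile correction), dictionary
  build/compression, inner-product matching.
- `hdprost.baselines` — LRI and LLR comparators.
- `hdprost.synthetic` — phantoms, coil maps, trajectories, masks, noisy
  k-space.
- `hdprost.io` / `hdprost.cli` / `hdprost.config` — HDF5 container, NIfTI
  maps, YAML configuration, command line.

See `docs/methods.md` for the model details, parameter choices and known
limitations.
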