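# Methods

## Reconstruction model

The package solves the joint multi-contrast inverse problem

    min_X 1/2 ‖E X − Y‖_F² + λ Σ_p ‖T_p‖_*   s.t.  T_p = P_p X,

by ADMM with unscaled dual `b`: a CG solve of the normal equations
`(EᴴE + μI) X = EᴴY + μT − b`, then the patch-tensor denoiser applied to
`X + b/μ`, then `b ← b + μ(X − T)`. Iteration order (X-solve, denoise, dual)
and the initialization `X⁰ = T⁰ = Eᴴ_dc Y` (density-compensated adjoint for
radial data, plain adjoint for Cartesian), `b⁰ = 0`, are fixed; CG warm-starts
from the previous outer iterate.

### Encoding operators

Both operators use the unitary FFT convention (1/√N in both directions), so
the spectrum of `EᴴE` is bounded by `max Σ_c |S_c|²` per contrast and the
penalty μ has the same meaning in Cartesian and radial modes. The radial MRF
operator is `E = A U_r F S` on r temporal-subspace coefficient images; the
non-uniform Fourier evaluation is a Kaiser-Bessel gridding transform
(oversampling 2.0, kernel width 5, Beatty shape parameter) whose interpolation
step is materialized as a sparse matrix. All linear stages therefore have
exact conjugate transposes: the forward/adjoint pair is adjoint to machine
precision, while the forward model approximates the direct Fourier sum to
about 1e-5–1e-4 relative (verified against a brute-force DFT in the tests).
Sample coordinates are in cycles/pixel within [−0.5, 0.5), voxel indices are
0-based and centered, image axes ordered (x, y, contrast, coil).

The ramp density-compensation weights (∝ |k| with a floor of an eighth of the
radial sample spacing at DC, scaled by the polar area element and the matrix
size) are used only to initialize ADMM/CG; they never enter the
adjoint-consistent operators.

### Patch-tensor denoiser

For each reference patch corner on a stride-`patch_offset` grid (final
row/column shifted so patches touch the image boundary), the K−1 most similar
patches inside a Chebyshev window of radius `search_radius` are selected by
squared l2 distance on the **complex** values summed over all contrasts —
phase structure participates in matching, consistent with enforcing low rank
in the complex domain. Ties are broken by row-major corner index; the
reference is always first; windows are clipped at boundaries, and tiny images
shrink K with a warning. The N×K×L group tensor is denoised by truncated
HOSVD: per mode, left singular vectors of the mode unfolding with singular
values ≥ τ = 2λ/μ are kept (minimum one, so no group is annihilated), the
tensor is projected and reconstructed — hard truncation only, no core
shrinkage. Voxel estimates are averaged with uniform weights over all covering
groups; with τ = 0 the whole pipeline is an exact identity (partition of
unity), which the tests assert to 1e-10.

τ is interpreted as an **absolute** threshold after normalizing the working
image to unit maximum magnitude (scale restored afterwards). This makes the
published λ/μ pairs meaningful across datasets of arbitrary scanner scale.

### Default parameters

| parameter | 2D radial MRF | 3D/2D Cartesian multi-contrast |
|---|---|---|
| patch edge | 7 | 7 |
| K (similar patches) | 20 | 30 |
| search radius [vox] | 20 | 20 |
| patch offset [vox] | 3 | 3 |
| μ | 5e-3 | 5e-3 |
| ADMM iterations | 5 | 5 |
| CG tolerance / max iters | 1e-4 / 15 | 1e-7 / 10 |
| subspace rank r | 10 | — |
| λ | max(1e-3, −1e-3·n + 0.4) | 0.1 |

The MRF λ rule is an affine function of the spoke count n taken verbatim from
its source; it is non-positive for n ≥ 400, so the implementation floors it at
1e-3 and logs both values, and every entry point accepts an explicit λ
override. Consequence at n = 500: τ = 2λ/μ = 0.4 on a unit-normalized image,
which sits near the noise floor of the patch-group singular values — the
patch prior is then mild, and the reconstruction behaves close to CG-SENSE
with many iterations. Accuracy (ROI means, R²) is excellent in this regime;
per-vial standard deviations are comparable to, not uniformly better than,
the early-stopped LRI baseline. Users reproducing strong-denoising behaviour
should pass a larger λ (τ of order 10–40 is effective on unit-normalized
images).

## MRF engine

EPG variant: gradient-dephased (unbalanced, FISP-type) with configurable
per-pulse RF phase, 0/180° alternation by default, optional ideal inversion
(Z₀ → −Z₀). Per TR: RF rotation, record F₀·exp(−TE/T2) (receiver
demodulated), full-TR relaxation with longitudinal recovery, one unit of
gradient dephasing. Dephasing orders are truncated at min(n, 64); for the
default train the truncation error is ~1e-4 at the longest phantom T2 and
far below that elsewhere. The plain-numpy single-voxel simulator is the
reference; a numba kernel batches dictionaries and is tested to agree to
1e-12. Validation: exact closed forms (inversion recovery, single-pulse TE
decay), the Freeman–Hill steady-state expression for the spoiled-FID branch,
and an independent 200-isochromat Bloch simulation (max deviation < 1e-3).

The exact published flip-angle train is not available, so the default is a
smooth repeating-lobe pattern fa(i) = 70°·|sin(π·i/250)|, i = 1..n, after one
inversion, TR 4.4 ms, TE 2 ms; any train can be supplied as a CSV (one angle
per line, degrees). Simulator and dictionary always share one sequence model,
which is what matching requires.

Slice-profile correction averages 51 isochromats whose flip angles are scaled
by the small-tip Fourier response of a Hann-windowed three-lobe sinc,
evaluated uniformly across the main lobe (profile 1 at center, ~0.5 at the
edges), uniform isochromat weighting; 51 isochromats agree with a 501-point
reference to < 1% relative L2. Dictionary grids default to
T1 ∈ {50:10:1400, 1430:30:1600, 1700:100:2200, 2400:200:3000} ms (152 values)
and T2 ∈ {5:2:80, 85:5:150, 160:10:300, 330:30:600} ms (77 values), 11 704
atoms; combinations with T2 > T1 are retained, duplicates are not removed.
Compression takes the leading r = 10 left singular vectors of the atom matrix;
matching maximizes |⟨atom, x⟩| with M0 recovered from the winning projection
divided by the atom's pre-normalization norm.

## Baselines

LRI solves the unregularized least-squares problem with a fixed CG iteration
count (default 10, zero initialization) — early stopping is its only
regularization. LLR replaces the patch denoiser by per-block Casorati
(voxels × contrasts) singular-value thresholding at 5% of each block's largest
singular value, block edge 8, with a seeded random cyclic block shift per
ADMM iteration (cycle spinning); everything else, including the
data-consistency path, is shared code with the patch-tensor reconstruction.

## Synthetic data

The generator emulates the two study set-ups:

* **Radial MRF phantom** — nine disjoint circular vials in a background disc
  (T1 log-spaced 255–1489 ms, T2 log-spaced 44–243 ms, paired by sorted index;
  background 300/50 ms), unit-magnitude proton density with a smooth phase
  ramp; smooth Gaussian-lobe coil maps with linear phase, normalized to
  root-sum-of-squares one; golden-angle (111.246°) spokes, one per time point,
  2× readout oversampling, samples through DC. One spoke per time point at a
  160 matrix corresponds to round(π/2·160) = 251-fold undersampling relative
  to the fully sampled spoke count.
* **Cartesian multi-contrast stack** — a surrogate magnetization-transfer
  weighting exp(−k_tissue·α_MT/800°) over α_MT = 0…800° (six contrasts).
  This is deliberately not a physical two-pool MT model; it exists to give the
  stack the shared-structure/varying-contrast statistics the joint
  reconstruction exploits. Sampling masks are variable-density spiral arms on
  the Cartesian grid (radial density ∝ 1/r, golden-ratio rotation between
  arms, golden-angle offset between contrasts, fully sampled 8% center disc),
  with the final arm truncated so the achieved acceleration matches the
  target (6.5× by default).

Noise is complex Gaussian with `noise_sigma` the per-complex-sample standard
deviation (σ/√2 per real and imaginary channel); experiment drivers calibrate
σ from the clean k-space to a requested SNR in dB. All generators are pure
functions of their parameters and a seed.

What the synthetic data does **not** model: anatomy, B0/B1 inhomogeneity,
gradient delays and eddy currents, physical magnetization transfer and
diffusion confounds, motion. Passing tests therefore demonstrate correctness
of the algorithmic chain under a matched signal model (simulation and
reconstruction share the EPG model and the encoding operator), not robustness
to the model mismatch present in scanner data.

## Problem sizes and numerical choices

The validation experiments run the fingerprinting study at a 128×128 matrix
with 500 time points, 8 coils and ~30 dB SNR, and the multi-contrast stack at
64×64 with 6 contrasts at 6.5× — sizes chosen so the full pipeline, including
the 11 704-atom slice-corrected dictionary, completes in a few minutes on one
CPU. ROI statistics use vial masks eroded by one voxel to exclude
partial-volume edges. CG stops on relative residual (`cg_eps`) or the
iteration cap; zero-signal voxels match with M0 = 0 and index −1; rank-
deficient dictionaries compress to the achievable rank with a warning.

## Known limitations

* ADMM with a hard-truncation, block-matched prior is not a firmly
  nonexpansive splitting: the dual residual can plateau in a small limit
  cycle rather than vanish. With moderate μ and τ on structured data it
  converges to an exact fixpoint; the default 5 iterations are a practical
  stopping rule, not a convergence guarantee.
* The gridding NUFFT favors an exact adjoint pair over spectral accuracy;
  kernel width 5 gives ~1e-5 forward accuracy, adequate for the matched-model
  experiments here but below dedicated NUFFT libraries.
* 3D patches (7³) are supported by the denoiser, but the bundled experiments
  exercise the 2D path; the MT study here is single-slice.
* Dictionary matching is exhaustive (no fast group matching or dictionary
  interpolation); T1/T2 estimates are quantized to the grid.
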