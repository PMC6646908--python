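"""Comparator reconstructions: low-rank inversion (LRI) and locally low-rank (LLR).

LRI is the unregularized CG least-squares solve of the subspace-encoded MRF
problem with a fixed iteration count.  LLR reuses the identical ADMM loop as
the patch-tensor reconstruction but swaps the denoiser for singular-value
thresholding of per-block Casorati matrices (voxels x contrasts), with a
seeded random block shift per iteration for cycle spinning.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .admm import hd_prost_recon


@dataclass
class LLRParams:
    """Block size, relative singular-value threshold and ADMM settings."""

    block_edge: int = 8
    threshold_frac: float = 0.05
    admm_iters: int = 5
    mu: float = 5e-3
    cg_eps: float = 1e-7
    cg_iters: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must lie in (0, 1)")
        if self.block_edge < 2:
            raise ValueError("block_edge must be >= 2")


def lri_recon(y, op, cg_iters: int = 10, cg_eps: float = 0.0, x0=None):
    """Fixed-iteration CG solve of min ||E X - Y||^2 (no regularization)."""
    shape = op.image_shape
    n = int(np.prod(shape))

    def normal(v):
        return op.adjoint(op.forward(v.reshape(shape))).reshape(-1)

    rhs = op.adjoint(y).reshape(-1)
    A = LinearOperator((n, n), matvec=normal, dtype=np.complex128)
    x0v = None if x0 is None else np.asarray(x0).reshape(-1)
    sol, _ = cg(A, rhs, x0=x0v, rtol=max(cg_eps, 1e-300), atol=0.0, maxiter=cg_iters)
    return sol.reshape(shape)


def block_svt(x: np.ndarray, block_edge: int = 8, threshold_frac: float = 0.05,
              shift=None) -> np.ndarray:
    """Per-block Casorati singular-value thresholding over the contrast axis.

    The image is tiled into non-overlapping spatial blocks (edge blocks may be
    smaller); each block's (voxels x L) Casorati matrix keeps only singular
    values >= threshold_frac * sigma_1.  ``shift`` cyclically rolls the tiling
    for cycle spinning.
    """

    x = np.asarray(x, dtype=np.complex128)
    spatial = x.shape[:-1]
    L = x.shape[-1]
    if L < 2:
        raise ValueError("block_svt needs at least 2 contrasts")
    if shift is not None:
        x = np.roll(x, shift=tuple(-s for s in shift), axis=tuple(range(len(spatial))))

    out = np.empty_like(x)
    ranges = [range(0, s, block_edge) for s in spatial]
    for corner in product(*ranges):
        sl = tuple(slice(c, min(c + block_edge, s)) for c, s in zip(corner, spatial))
        block = x[sl]
        cas = block.reshape(-1, L)
        u, s, vh = np.linalg.svd(cas, full_matrices=False)
        s = np.where(s >= threshold_frac * s[0], s, 0.0) if s[0] > 0 else s
        out[sl] = ((u * s) @ vh).reshape(block.shape)
    if shift is not None:
        out = np.roll(out, shift=shift, axis=tuple(range(len(spatial))))
    return out


def llr_recon(y, op, params: LLRParams | None = None, x0=None):
    """Locally-low-rank reconstruction via the shared ADMM loop.

    Identical data-consistency path to the patch-tensor reconstruction; only
    the denoising step differs.
    """

    if params is None:
        params = LLRParams()
    rng = np.random.default_rng(params.seed)
    ndim = len(op.image_shape) - 1

    def denoiser(img, iteration):
        shift = tuple(rng.integers(0, params.block_edge, size=ndim))
        return block_svt(img, params.block_edge, params.threshold_frac, shift=shift)

    return hd_prost_recon(
        y, op, lam=0.0, mu=params.mu, admm_iters=params.admm_iters,
        cg_eps=params.cg_eps, cg_iters=params.cg_iters, denoiser=denoiser, x0=x0,
    )
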