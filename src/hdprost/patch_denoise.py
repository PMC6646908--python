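"""Patch-tensor denoising: block matching, complex HOSVD truncation, aggregation.

For every reference patch on a sliding grid, the K most similar patches inside
a local search window are stacked into a third-order complex tensor of shape
N x K x L (patch voxels x similar patches x contrasts).  The tensor is
denoised by a truncated higher-order SVD: per mode, only left singular vectors
whose mode singular values reach the threshold tau = 2*lambda/mu are kept
(hard truncation of the factor matrices, no shrinkage of the core).  Denoised
patches are scattered back and voxel-wise averaged over all groups covering
them.

Patch similarity is the squared l2 distance on the complex values across all
contrasts, so phase structure participates in the matching.  Ties are broken
by row-major corner index, with the reference patch always first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class DenoiseParams:
    """Block-matching and truncation parameters.

    ``patch_edge`` voxels per patch side (odd), ``n_similar`` patches per group
    (K), Chebyshev ``search_radius`` in voxels around the reference corner,
    ``patch_offset`` stride of the reference grid, and absolute singular-value
    threshold ``tau`` (= 2*lambda/mu), applied after the working image has been
    normalized to unit maximum magnitude.
    """

    patch_edge: int = 7
    n_similar: int = 20
    search_radius: int = 20
    patch_offset: int = 3
    tau: float = 0.0

    def __post_init__(self):
        if self.patch_edge < 1 or self.patch_edge % 2 == 0:
            raise ValueError("patch_edge must be odd and >= 1")
        if self.n_similar < 1:
            raise ValueError("n_similar (K) must be >= 1")
        if self.search_radius < self.patch_edge:
            raise ValueError("search_radius must be >= patch_edge")
        if self.patch_offset < 1:
            raise ValueError("patch_offset must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")


@dataclass
class PatchTensor:
    """Third-order tensor of K matched patches across L contrasts."""

    data: np.ndarray                 # (N, K, L) complex
    member_coords: np.ndarray        # (K, d) patch corner coordinates
    reference_coord: tuple = field(default=None)

    def __post_init__(self):
        self.member_coords = np.asarray(self.member_coords)
        if self.reference_coord is None:
            self.reference_coord = tuple(self.member_coords[0])


# ---------------------------------------------------------------------------
# block matching
# ---------------------------------------------------------------------------

def _spatial_shape(x: np.ndarray) -> tuple:
    return x.shape[:-1]


def _window_corners(ref, spatial, edge, radius):
    """Slices of valid candidate corners within Chebyshev ``radius`` of ``ref``."""
    return tuple(
        slice(max(0, r - radius), min(s - edge, r + radius) + 1)
        for r, s in zip(ref, spatial)
    )


def block_match(x: np.ndarray, ref_coord, params: DenoiseParams) -> np.ndarray:
    """Return the corners of the K best-matching patches (reference first).

    ``x`` is a multi-contrast image (..spatial.., L); ``ref_coord`` is the
    patch corner (0-based).  Distance is the summed squared modulus of the
    complex difference over all patch voxels and contrasts; candidates are
    returned in ascending distance order with ties resolved by row-major
    corner index.  If the window holds fewer than K candidates the group
    shrinks with a warning.
    """

    x = np.asarray(x)
    spatial = _spatial_shape(x)
    edge = params.patch_edge
    ref = tuple(int(c) for c in ref_coord)
    if any(r < 0 or r + edge > s for r, s in zip(ref, spatial)):
        raise IndexError(f"reference patch at {ref} does not fit in image {spatial}")

    patch_shape = (edge,) * len(spatial)
    views = sliding_window_view(x, patch_shape, axis=tuple(range(len(spatial))))
    win = _window_corners(ref, spatial, edge, params.search_radius)
    cand = views[win]                                   # (..win.., L, edge, edge[,edge])
    ref_patch = views[ref]
    diff = cand - ref_patch
    d = np.sum(np.abs(diff) ** 2, axis=tuple(range(len(spatial), diff.ndim)))

    win_shape = d.shape
    order = np.argsort(d.reshape(-1), kind="stable")    # stable => row-major tie-break
    starts = np.array([s.start for s in win])
    coords = np.stack(np.unravel_index(order, win_shape), axis=1) + starts

    ref_arr = np.array(ref)
    keep = ~np.all(coords == ref_arr, axis=1)           # drop reference; re-prepended
    coords = coords[keep]
    k_others = params.n_similar - 1
    if coords.shape[0] < k_others:
        warnings.warn(
            f"search window holds only {coords.shape[0] + 1} patches; "
            f"group shrinks below K={params.n_similar}",
            stacklevel=2,
        )
        k_others = coords.shape[0]
    return np.vstack([ref_arr[None, :], coords[:k_others]])


def build_patch_tensor(x: np.ndarray, coords, params: DenoiseParams) -> PatchTensor:
    """Stack the patches at ``coords`` into an (N, K, L) tensor.

    Voxels are ordered row-major within the patch; the first member is the
    reference patch.
    """

    x = np.asarray(x)
    spatial = _spatial_shape(x)
    edge = params.patch_edge
    coords = np.asarray(coords, dtype=np.int64)
    if np.any(coords < 0) or np.any(coords + edge > np.array(spatial)):
        raise IndexError("patch corner out of image bounds")
    n_voxels = edge ** len(spatial)
    L = x.shape[-1]
    data = np.empty((n_voxels, coords.shape[0], L), dtype=np.complex128)
    for k, c in enumerate(coords):
        sl = tuple(slice(ci, ci + edge) for ci in c)
        data[:, k, :] = x[sl].reshape(n_voxels, L)
    return PatchTensor(data=data, member_coords=coords)


# ---------------------------------------------------------------------------
# truncated HOSVD
# ---------------------------------------------------------------------------

def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding: rows index the mode, columns the rest (row-major)."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def fold(mat: np.ndarray, mode: int, shape) -> np.ndarray:
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(mat.reshape(full), 0, mode)


def mode_singular_values(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Singular values of the mode unfolding (the multilinear singular values)."""
    return np.linalg.svd(unfold(tensor, mode), compute_uv=False)


def hosvd_truncate(t3, tau: float):
    """Hard-truncated complex HOSVD of a third-order tensor.

    Per mode, keeps the left singular vectors of the mode unfolding whose
    singular values are >= ``tau`` (at least one per mode), projects onto the
    retained subspaces and reconstructs.  Accepts a :class:`PatchTensor` or a
    bare array and returns the same kind.
    """

    wrap = isinstance(t3, PatchTensor)
    data = t3.data if wrap else np.asarray(t3)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in patch tensor")
    if tau < 0:
        raise ValueError("tau must be nonnegative")

    out = data
    factors = []
    for mode in range(data.ndim):
        u, s, _ = np.linalg.svd(unfold(data, mode), full_matrices=False)
        keep = max(1, int(np.sum(s >= tau)))
        factors.append(u[:, :keep])
    # project then reconstruct: X x_i (U_i U_i^H)
    for mode, u in enumerate(factors):
        m = unfold(out, mode)
        out = fold(u @ (u.conj().T @ m), mode, out.shape)
    if wrap:
        return PatchTensor(out, t3.member_coords, t3.reference_coord)
    return out


# ---------------------------------------------------------------------------
# aggregation and the full sliding-window denoiser
# ---------------------------------------------------------------------------

def reference_grid(spatial, edge: int, offset: int):
    """Reference corners with stride ``offset``, final position shifted to the border."""
    axes = []
    for s in spatial:
        last = s - edge
        if last < 0:
            raise ValueError(f"patch edge {edge} exceeds image extent {s}")
        pos = list(range(0, last + 1, offset))
        if pos[-1] != last:
            pos.append(last)
        axes.append(pos)
    return list(product(*axes))


def aggregate(groups, image_shape) -> np.ndarray:
    """Average all patch estimates into an image; every voxel must be covered."""
    acc = np.zeros(image_shape, dtype=np.complex128)
    hits = np.zeros(image_shape[:-1], dtype=np.int64)
    L = image_shape[-1]
    for g in groups:
        edge = int(round(g.data.shape[0] ** (1.0 / len(image_shape[:-1]))))
        patch_shape = (edge,) * len(image_shape[:-1])
        for k, c in enumerate(g.member_coords):
            sl = tuple(slice(ci, ci + edge) for ci in c)
            acc[sl] += g.data[:, k, :].reshape(patch_shape + (L,))
            hits[sl] += 1
    if np.any(hits == 0):
        raise RuntimeError("aggregation left uncovered voxels (reference-grid bug)")
    return acc / hits[..., None]


def denoise_multicontrast(x: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Full sliding-window patch-tensor denoiser.

    The image magnitude is pre-normalized to a maximum of one so that ``tau``
    is an absolute threshold comparable across datasets; the scale is restored
    on output.
    """

    x = np.asarray(x, dtype=np.complex128)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in image")
    scale = np.max(np.abs(x))
    if scale == 0:
        return np.zeros_like(x)
    xn = x / scale

    spatial = _spatial_shape(xn)
    groups = []
    for ref in reference_grid(spatial, params.patch_edge, params.patch_offset):
        coords = block_match(xn, ref, params)
        tensor = build_patch_tensor(xn, coords, params)
        groups.append(hosvd_truncate(tensor, params.tau))
    return aggregate(groups, xn.shape) * scale
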