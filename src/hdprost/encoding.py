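"""Multi-coil encoding operators for Cartesian and radial-subspace acquisitions.

Two operator families are provided, each with a verified forward/adjoint pair:

* ``CartesianEncoding`` — E = A F S: coil-weight the multi-contrast image,
  apply a unitary centered FFT per contrast and coil, and keep the k-space
  locations selected by a per-contrast binary mask.
* ``RadialSubspaceEncoding`` — E = A U_r F S: the MRF pathway.  The unknowns
  are r temporal-subspace coefficient images; each k-space sample at time
  point t sees the subspace images combined with the t-th row of the temporal
  basis U_r, evaluated at its spoke location by the NUFFT.

All FFTs use the unitary convention (1/sqrt(N) both directions) so that
E^H E has spectrum bounded by max_r sum_c |S_c|^2 per contrast and the ADMM
penalty mu means the same thing in both sampling modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nufft import NufftPlan


# ---------------------------------------------------------------------------
# sampling descriptions
# ---------------------------------------------------------------------------

@dataclass
class CartesianSampling:
    """Per-contrast binary undersampling masks on the image grid.

    ``masks`` has shape (Mx, My, L) (or (Mx, My, Mz, L) for 3D) with entries
    in {0, 1}; k-space is stored on the same centered grid.
    """

    masks: np.ndarray

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        vals = np.unique(self.masks)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask entries must be 0 or 1")

    @property
    def n_contrasts(self) -> int:
        return self.masks.shape[-1]

    def acceleration(self) -> np.ndarray:
        """Per-contrast acceleration = grid points / sampled points."""
        total = np.prod(self.masks.shape[:-1])
        sampled = self.masks.reshape(-1, self.n_contrasts).sum(axis=0)
        return total / sampled


@dataclass
class RadialSampling:
    """Non-Cartesian sample locations with spoke and time-point bookkeeping.

    ``coords`` are in cycles/pixel within [-0.5, 0.5); ``time_point`` maps each
    sample to the acquisition time point that owns its spoke.
    """

    coords: np.ndarray
    spoke_of_sample: np.ndarray
    time_point: np.ndarray
    samples_per_spoke: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.spoke_of_sample = np.asarray(self.spoke_of_sample, dtype=np.int64)
        self.time_point = np.asarray(self.time_point, dtype=np.int64)
        if np.any(np.abs(self.coords) > 0.5):
            raise ValueError("radial coordinates must lie in [-0.5, 0.5]")
        n_tp = self.time_point.max() + 1 if self.time_point.size else 0
        owned = np.bincount(self.time_point, minlength=n_tp)
        if np.any(owned == 0):
            raise ValueError("every time point must own at least one spoke")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def n_timepoints(self) -> int:
        return int(self.time_point.max()) + 1


@dataclass
class SubspaceBasis:
    """Orthonormal temporal basis U_r (n_timepoints x r) from dictionary compression."""

    ur: np.ndarray

    def __post_init__(self):
        self.ur = np.asarray(self.ur, dtype=np.complex128)
        if self.ur.ndim != 2:
            raise ValueError("basis must be a 2D matrix")
        gram = self.ur.conj().T @ self.ur
        if not np.allclose(gram, np.eye(self.rank), atol=1e-10):
            raise ValueError("basis columns must be orthonormal")

    @property
    def n_timepoints(self) -> int:
        return self.ur.shape[0]

    @property
    def rank(self) -> int:
        return self.ur.shape[1]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def _check_sens(sens: np.ndarray, spatial: tuple) -> np.ndarray:
    sens = np.asarray(sens, dtype=np.complex128)
    if sens.shape[:-1] != spatial:
        raise ValueError(f"sensitivity shape {sens.shape} does not match image {spatial}")
    return sens


def _ufft(x, axes):
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def _uifft(x, axes):
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


class CartesianEncoding:
    """E = A F S on multi-contrast images X (..spatial.., L).

    K-space is stored on the full centered grid with zeros at unsampled
    locations, shape (..spatial.., L, Nc).
    """

    def __init__(self, sens: np.ndarray, sampling: CartesianSampling):
        self.sampling = sampling
        self.spatial = sampling.masks.shape[:-1]
        self.ndim = len(self.spatial)
        self.sens = _check_sens(sens, self.spatial)
        self.n_coils = self.sens.shape[-1]
        self.n_contrasts = sampling.n_contrasts
        self._axes = tuple(range(self.ndim))

    @property
    def image_shape(self):
        return self.spatial + (self.n_contrasts,)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.shape != self.image_shape:
            raise ValueError(f"image shape {x.shape} != {self.image_shape}")
        sx = x[..., :, None] * self.sens[..., None, :]
        y = _ufft(sx, self._axes)
        return y * self.sampling.masks[..., :, None]

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        expect = self.spatial + (self.n_contrasts, self.n_coils)
        if y.shape != expect:
            raise ValueError(f"k-space shape {y.shape} != {expect}")
        ym = y * self.sampling.masks[..., :, None]
        img = _uifft(ym, self._axes)
        return np.sum(img * np.conj(self.sens)[..., None, :], axis=-1)


class RadialSubspaceEncoding:
    """E = A U_r F S mapping r subspace images (Mx, My, r) to samples (Z, Nc)."""

    def __init__(self, sens, sampling: RadialSampling, basis: SubspaceBasis,
                 shape=None, nufft_width: int = 5):
        self.sampling = sampling
        self.basis = basis
        if basis.n_timepoints != sampling.n_timepoints:
            raise ValueError("basis time points must match the trajectory")
        sens = np.asarray(sens, dtype=np.complex128)
        if shape is None:
            shape = sens.shape[:-1]
        self.spatial = tuple(shape)
        self.sens = _check_sens(sens, self.spatial)
        self.n_coils = self.sens.shape[-1]
        self.plan = NufftPlan(sampling.coords, self.spatial, width=nufft_width)
        # per-sample basis rows: (Z, r)
        self._urs = basis.ur[sampling.time_point, :]

    @property
    def rank(self) -> int:
        return self.basis.rank

    @property
    def image_shape(self):
        return self.spatial + (self.rank,)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.shape != self.image_shape:
            raise ValueError(f"image shape {x.shape} != {self.image_shape}")
        sx = x[..., :, None] * self.sens[..., None, :]          # (Mx,My,r,Nc)
        batch = np.moveaxis(sx, (-2, -1), (0, 1))               # (r,Nc,Mx,My)
        g = self.plan.forward(batch)                            # (r,Nc,Z)
        return np.einsum("rcz,zr->zc", g, self._urs)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        expect = (self.sampling.n_samples, self.n_coils)
        if y.shape != expect:
            raise ValueError(f"sample array shape {y.shape} != {expect}")
        g = np.einsum("zc,zr->rcz", y, np.conj(self._urs))
        imgs = self.plan.adjoint(g)                             # (r,Nc,Mx,My)
        imgs = np.moveaxis(imgs, (0, 1), (-2, -1))              # (Mx,My,r,Nc)
        return np.sum(imgs * np.conj(self.sens)[..., None, :], axis=-1)


def radial_density_weights(sampling: RadialSampling, spatial) -> np.ndarray:
    """Ramp density-compensation weights for the density-compensated adjoint.

    Weight proportional to |k| (area element of radial sampling) with a finite
    floor at DC, scaled so the weighted adjoint approximates the inverse
    transform under the package's unitary convention.  Used only for
    initialization, never inside the adjoint-consistent operators.
    """

    radius = np.hypot(sampling.coords[:, 0], sampling.coords[:, 1])
    dr = 1.0 / sampling.samples_per_spoke
    n_spokes = int(sampling.spoke_of_sample.max()) + 1
    w = np.maximum(radius, dr / 8.0) * dr * np.pi / n_spokes
    # polar-area Riemann sum of the inverse transform against the 1/sqrt(N)
    # forward convention: weights carry ΔA·N so adjoint(w·y) approximates x
    return w * float(np.prod(spatial))


def density_compensated_adjoint(y: np.ndarray, op: RadialSubspaceEncoding) -> np.ndarray:
    """Ramp-weighted adjoint reconstruction (gridding recon) for initialization."""
    w = radial_density_weights(op.sampling, op.spatial)
    return op.adjoint(y * w[:, None])


def adjoint_test(op, rng: np.random.Generator, n_draws: int = 1) -> float:
    """Max normalized adjointness defect |<Ex, y> - <x, E^H y>| / (||Ex|| ||y||)."""
    worst = 0.0
    for _ in range(n_draws):
        x = rng.standard_normal(op.image_shape) + 1j * rng.standard_normal(op.image_shape)
        ex = op.forward(x)
        y = rng.standard_normal(ex.shape) + 1j * rng.standard_normal(ex.shape)
        lhs = np.vdot(y, ex)              # <y, Ex>
        rhs = np.vdot(op.adjoint(y), x)   # <E^H y, x>
        worst = max(worst, abs(lhs - rhs) / (np.linalg.norm(ex) * np.linalg.norm(y)))
    return worst
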