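"""Synthetic acquisition simulator: phantoms, coils, trajectories, k-space.

Emulates the two study set-ups end to end without scanner data:

* a 9-vial T1/T2 phantom (vial T1 log-spaced 255-1489 ms, T2 log-spaced
  44-243 ms) sampled by a golden-angle single-spoke-per-time-point radial MRF
  acquisition, and
* a multi-contrast stack with a surrogate magnetization-transfer weighting,
  sampled by variable-density Cartesian masks at a target acceleration with
  golden-ratio shifts between contrasts.

All generators are pure functions of their parameters and a seed.  Complex
Gaussian noise uses the convention that ``noise_sigma`` is the standard
deviation per complex sample, i.e. sigma/sqrt(2) per real and imaginary part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import CartesianSampling, RadialSampling, _ufft
from .mrf import SequenceParams, slice_profile_correct
from .nufft import NufftPlan

GOLDEN_ANGLE_DEG = 111.246       # radial spoke increment
GOLDEN_RATIO_ANGLE_DEG = 137.507764  # 2*pi*(1 - 1/phi), arm/contrast rotation

VIAL_T1_RANGE_MS = (255.0, 1489.0)
VIAL_T2_RANGE_MS = (44.0, 243.0)


@dataclass
class DigitalPhantom:
    """Voxelwise ground-truth relaxation parameters with vial ROI bookkeeping."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray                 # complex proton density
    label: np.ndarray              # 0 air, 1 background, 2.. vials
    vial_centers: np.ndarray
    vial_radius: float
    vial_t1_ms: np.ndarray
    vial_t2_ms: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.label > 0

    def vial_mask(self, i: int, erode: int = 0) -> np.ndarray:
        """Mask of vial ``i`` (0-based); ``erode`` shrinks the radius in voxels."""
        m = self.label == (i + 2)
        if erode > 0:
            nx, ny = self.label.shape
            xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
            cx, cy = self.vial_centers[i]
            m = m & ((xx - cx) ** 2 + (yy - cy) ** 2
                     <= (self.vial_radius - erode) ** 2)
        return m


@dataclass
class MTPhantomParams:
    """Surrogate magnetization-transfer weighting of the multi-contrast stack.

    Contrast l attenuates tissue t by exp(-k_t * alpha_l / 800 deg).  This is
    not a physical two-pool MT model; it gives the stack the shared-structure,
    varying-contrast statistics that the joint reconstruction exploits.
    """

    alpha_mt_deg: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 160.0, 320.0, 480.0, 640.0, 800.0])
    )
    k_background: float = 0.5
    k_vials: np.ndarray | None = None  # per-vial attenuation rates

    def __post_init__(self):
        self.alpha_mt_deg = np.asarray(self.alpha_mt_deg, dtype=np.float64)

    @property
    def n_contrasts(self) -> int:
        return self.alpha_mt_deg.size


@dataclass
class DatasetContainer:
    """Everything a reconstruction needs, as read from / written to HDF5."""

    kspace: np.ndarray                     # radial: (Z, Nc); cartesian: (..grid.., L, Nc)
    sampling: object                       # CartesianSampling or RadialSampling
    sens: np.ndarray
    mode: str                              # "radial-mrf" or "cartesian-multicontrast"
    sequence: SequenceParams | None = None
    truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phantom and coils
# ---------------------------------------------------------------------------

def make_vial_phantom(matrix: int, n_vials: int = 9, seed: int = 0) -> DigitalPhantom:
    """Circular vials in a background disc, relaxation times log-spaced.

    Vial T1 spans 255-1489 ms and T2 spans 44-243 ms (log-spaced, paired by
    sorted index); background is T1=300 ms, T2=50 ms.  The seed rotates the
    vial ring slightly so different seeds give distinct but statistically
    identical layouts.
    """

    if matrix < 32:
        raise ValueError("matrix must be >= 32")
    rng = np.random.default_rng(seed)
    c = (matrix - 1) / 2.0
    bg_radius = 0.42 * matrix
    ring_radius = 0.27 * matrix
    vial_radius = 0.09 * matrix

    centers = [(c, c)]
    n_ring = n_vials - 1
    theta0 = rng.uniform(0, 2 * np.pi)
    for i in range(n_ring):
        th = theta0 + 2 * np.pi * i / n_ring
        centers.append((c + ring_radius * np.cos(th), c + ring_radius * np.sin(th)))
    centers = np.array(centers)
    # disjointness check
    for i in range(n_vials):
        for j in range(i + 1, n_vials):
            if np.hypot(*(centers[i] - centers[j])) < 2 * vial_radius:
                raise RuntimeError("vials cannot be placed disjointly")
        if np.hypot(centers[i, 0] - c, centers[i, 1] - c) + vial_radius > bg_radius:
            raise RuntimeError("vial extends outside the background disc")

    xx, yy = np.meshgrid(np.arange(matrix), np.arange(matrix), indexing="ij")
    label = np.zeros((matrix, matrix), dtype=np.int32)
    label[(xx - c) ** 2 + (yy - c) ** 2 <= bg_radius**2] = 1
    vial_t1 = np.geomspace(*VIAL_T1_RANGE_MS, n_vials)
    vial_t2 = np.geomspace(*VIAL_T2_RANGE_MS, n_vials)
    t1 = np.where(label > 0, 300.0, 0.0)
    t2 = np.where(label > 0, 50.0, 0.0)
    for i, (cx, cy) in enumerate(centers):
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= vial_radius**2
        label[m] = i + 2
        t1[m] = vial_t1[i]
        t2[m] = vial_t2[i]
    # mild smooth phase across the FOV, constant unit magnitude in the support
    phase = 0.3 * np.pi * (xx - c) / matrix + 0.2 * np.pi * (yy - c) / matrix
    m0 = np.where(label > 0, np.exp(1j * phase), 0.0)
    return DigitalPhantom(t1_ms=t1, t2_ms=t2, m0=m0, label=label,
                          vial_centers=centers, vial_radius=vial_radius,
                          vial_t1_ms=vial_t1, vial_t2_ms=vial_t2)


def simulate_coils(matrix: int, n_coils: int, seed: int = 0) -> np.ndarray:
    """Smooth complex coil maps with root-sum-of-squares one everywhere.

    Gaussian sensitivity lobes centered at points around the FOV with mild
    linear phase; a single coil yields the unit map.
    """

    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return np.ones((matrix, matrix, 1), dtype=np.complex128)
    rng = np.random.default_rng(seed)
    c = (matrix - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(matrix), np.arange(matrix), indexing="ij")
    sens = np.empty((matrix, matrix, n_coils), dtype=np.complex128)
    width = 0.6 * matrix
    theta0 = rng.uniform(0, 2 * np.pi)
    for k in range(n_coils):
        th = theta0 + 2 * np.pi * k / n_coils
        cx = c + 0.55 * matrix * np.cos(th)
        cy = c + 0.55 * matrix * np.sin(th)
        mag = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2))
        ph = np.pi * (np.cos(th) * (xx - c) + np.sin(th) * (yy - c)) / matrix
        sens[..., k] = mag * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(sens) ** 2, axis=-1))
    return sens / rss[..., None]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def nyquist_spokes(matrix: int) -> int:
    """Fully sampled radial spoke count round(pi/2 * matrix)."""
    return int(round(np.pi / 2.0 * matrix))


def golden_angle_trajectory(n_timepoints: int, samples_per_spoke: int,
                            spokes_per_tp: int = 1) -> RadialSampling:
    """Golden-angle radial spokes, one diameter through DC per spoke.

    Spoke i sits at angle i * 111.246 deg; samples run uniformly over
    [-0.5, 0.5) in cycles/pixel and include DC.
    """

    if samples_per_spoke % 2:
        raise ValueError("samples_per_spoke must be even")
    n_spokes = n_timepoints * spokes_per_tp
    radii = (np.arange(samples_per_spoke) - samples_per_spoke // 2) / samples_per_spoke
    angles = np.deg2rad(GOLDEN_ANGLE_DEG) * np.arange(n_spokes)
    kx = radii[None, :] * np.cos(angles)[:, None]
    ky = radii[None, :] * np.sin(angles)[:, None]
    coords = np.stack([kx.reshape(-1), ky.reshape(-1)], axis=1)
    spoke = np.repeat(np.arange(n_spokes), samples_per_spoke)
    return RadialSampling(coords=coords, spoke_of_sample=spoke,
                          time_point=spoke // spokes_per_tp,
                          samples_per_spoke=samples_per_spoke)


def vd_caspr_masks(matrix: int, n_contrasts: int, target_accel: float = 6.5,
                   center_fraction: float = 0.08, seed: int = 0) -> CartesianSampling:
    """Variable-density spiral-arm Cartesian masks with per-contrast shifts.

    Each contrast gets a fully sampled center disc plus points picked along
    spiral arms whose radial density falls off as 1/r; successive arms rotate
    by the golden-ratio angle and every contrast carries an additional global
    golden-angle offset.  Arms are added (the last one truncated) until the
    sampled fraction matches 1/target_accel.
    """

    if target_accel <= 1:
        raise ValueError("target acceleration must exceed 1")
    rng = np.random.default_rng(seed)
    c = (matrix - 1) / 2.0
    rmax = matrix / 2.0 - 0.5
    r_center = center_fraction * matrix / 2.0
    xx, yy = np.meshgrid(np.arange(matrix), np.arange(matrix), indexing="ij")
    center_disc = (xx - c) ** 2 + (yy - c) ** 2 <= r_center**2

    target_points = int(round(matrix * matrix / target_accel))
    if target_points < center_disc.sum():
        raise ValueError("target acceleration unreachable: center disc too large")

    pts_per_arm = matrix // 2
    # log-spaced radii => density dN/dr proportional to 1/r
    arm_radii = np.geomspace(max(1.0, r_center / 2), rmax, pts_per_arm)
    arm_theta = 0.75 * np.pi * (arm_radii / rmax)   # gentle spiral twist
    ga = np.deg2rad(GOLDEN_RATIO_ANGLE_DEG)
    theta_seed = rng.uniform(0, 2 * np.pi)

    masks = np.zeros((matrix, matrix, n_contrasts), dtype=np.uint8)
    for l in range(n_contrasts):
        m = center_disc.copy()
        base = theta_seed + l * np.deg2rad(GOLDEN_ANGLE_DEG)
        arm = 0
        while m.sum() < target_points:
            if arm > 50 * matrix:
                raise RuntimeError("unreachable sampling density")
            phi = base + arm * ga
            ix = np.clip(np.round(c + arm_radii * np.cos(arm_theta + phi)), 0,
                         matrix - 1).astype(int)
            iy = np.clip(np.round(c + arm_radii * np.sin(arm_theta + phi)), 0,
                         matrix - 1).astype(int)
            for px, py in zip(ix, iy):
                if not m[px, py]:
                    m[px, py] = True
                    if m.sum() >= target_points:
                        break
            arm += 1
        masks[..., l] = m
    return CartesianSampling(masks=masks)


# ---------------------------------------------------------------------------
# k-space simulation
# ---------------------------------------------------------------------------

def _complex_noise(rng, shape, sigma):
    return sigma / np.sqrt(2.0) * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )


def simulate_mrf_kspace(phantom: DigitalPhantom, seq: SequenceParams,
                        traj: RadialSampling, sens: np.ndarray,
                        noise_sigma: float = 0.0, seed: int = 0,
                        n_iso: int = 51, n_states: int | None = None,
                        nufft_width: int = 5) -> DatasetContainer:
    """Radial MRF k-space from slice-profile-corrected EPG fingerprints.

    Each unique phantom tissue contributes its fingerprint; the time-point
    image at t is sampled on the spoke(s) owned by t through the NUFFT, per
    coil, and complex Gaussian noise is added.  Ground-truth maps ride along
    in ``truth``.
    """

    matrix = phantom.t1_ms.shape[0]
    sens = np.asarray(sens, dtype=np.complex128)
    if sens.shape[:2] != phantom.t1_ms.shape:
        raise ValueError("coil maps do not match the phantom matrix")
    n_tp = traj.n_timepoints
    if seq.n_pulses != n_tp:
        raise ValueError("sequence length must equal the number of time points")

    pairs = {}
    for lbl in np.unique(phantom.label):
        if lbl == 0:
            continue
        m = phantom.label == lbl
        pairs[lbl] = (float(phantom.t1_ms[m][0]), float(phantom.t2_ms[m][0]), m)

    plan = NufftPlan(traj.coords, (matrix, matrix), width=nufft_width)
    n_coils = sens.shape[-1]
    y = np.zeros((traj.n_samples, n_coils), dtype=np.complex128)
    for lbl, (t1, t2, m) in pairs.items():
        fingerprint = slice_profile_correct(t1, t2, seq, n_iso=n_iso,
                                            n_states=n_states)
        tissue_img = phantom.m0 * m                       # (Mx, My)
        g = plan.forward(np.moveaxis(tissue_img[..., None] * sens, -1, 0))  # (Nc, Z)
        y += (g * fingerprint[traj.time_point][None, :]).T

    rng = np.random.default_rng(seed)
    y += _complex_noise(rng, y.shape, noise_sigma)
    return DatasetContainer(
        kspace=y, sampling=traj, sens=sens, mode="radial-mrf", sequence=seq,
        truth={"t1": phantom.t1_ms, "t2": phantom.t2_ms,
               "m0": phantom.m0, "label": phantom.label},
        meta={"matrix": matrix, "seed": seed, "noise_sigma": noise_sigma,
              "n_iso": n_iso},
    )


def mt_contrast_images(phantom: DigitalPhantom, mt: MTPhantomParams) -> np.ndarray:
    """Surrogate MT-weighted contrast stack (Mx, My, L)."""
    n_vials = phantom.vial_t1_ms.size
    if mt.k_vials is None:
        k_vials = np.linspace(0.2, 1.2, n_vials)
    else:
        k_vials = np.asarray(mt.k_vials, dtype=np.float64)
    k_map = np.where(phantom.label == 1, mt.k_background, 0.0)
    for i in range(n_vials):
        k_map[phantom.label == i + 2] = k_vials[i]
    atten = np.exp(-k_map[..., None] * mt.alpha_mt_deg[None, None, :] / 800.0)
    return phantom.m0[..., None] * atten


def simulate_mt_kspace(phantom: DigitalPhantom, mt: MTPhantomParams,
                       masks: CartesianSampling, sens: np.ndarray,
                       noise_sigma: float = 0.0, seed: int = 0) -> DatasetContainer:
    """Masked Cartesian k-space of the surrogate MT contrast stack."""
    imgs = mt_contrast_images(phantom, mt)
    if masks.n_contrasts != mt.n_contrasts:
        raise ValueError("mask count must equal the number of MT contrasts")
    sx = imgs[..., :, None] * np.asarray(sens, dtype=np.complex128)[..., None, :]
    y = _ufft(sx, (0, 1)) * masks.masks[..., :, None]
    rng = np.random.default_rng(seed)
    noise = _complex_noise(rng, y.shape, noise_sigma) * masks.masks[..., :, None]
    return DatasetContainer(
        kspace=y + noise, sampling=masks, sens=np.asarray(sens), mode="cartesian-multicontrast",
        truth={"images": imgs, "t1": phantom.t1_ms, "t2": phantom.t2_ms,
               "m0": phantom.m0, "label": phantom.label},
        meta={"matrix": imgs.shape[0], "seed": seed, "noise_sigma": noise_sigma,
              "alpha_mt_deg": mt.alpha_mt_deg},
    )


def sigma_for_snr(clean_kspace: np.ndarray, snr_db: float) -> float:
    """Per-complex-sample noise std giving the requested SNR over nonzero samples."""
    mags = np.abs(clean_kspace[clean_kspace != 0])
    rms = np.sqrt(np.mean(mags**2))
    return float(rms * 10.0 ** (-snr_db / 20.0))
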