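"""MRF signal engine: EPG simulation, dictionary building/compression, matching.

The signal model is a gradient-dephased (unbalanced, FISP-type) extended phase
graph: each TR applies an RF rotation (flip angle and phase from the train),
records the F0 configuration at TE with transverse decay, relaxes to the end
of the TR with longitudinal recovery, and shifts the configuration orders by
one unit of gradient dephasing.  An optional ideal inversion precedes the
train.  Slice-profile imperfection is corrected by averaging isochromats whose
flip angles are scaled by the excitation profile across the slice.

Dictionaries hold one unit-normalized fingerprint per (T1, T2) grid pair;
temporal compression takes the leading left singular vectors of the atom
matrix as the subspace basis U_r.  Matching maximizes the modulus of the
inner product between the (compressed) voxel signal and the atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .encoding import SubspaceBasis

log = logging.getLogger(__name__)

DEFAULT_N_STATES = 64


# ---------------------------------------------------------------------------
# sequence description
# ---------------------------------------------------------------------------

@dataclass
class SequenceParams:
    """Flip-angle train and timing of the fingerprinting sequence."""

    fa_deg: np.ndarray
    tr_ms: float = 4.4
    te_ms: float = 2.0
    invert: bool = True
    rf_phase_deg: np.ndarray | None = None

    def __post_init__(self):
        self.fa_deg = np.atleast_1d(np.asarray(self.fa_deg, dtype=np.float64))
        if self.fa_deg.size < 1:
            raise ValueError("flip-angle train must have at least one pulse")
        if np.any(self.fa_deg < 0) or np.any(self.fa_deg > 180):
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if not self.te_ms < self.tr_ms:
            raise ValueError("TE must be shorter than TR")
        if self.rf_phase_deg is None:
            # 0/180 phase alternation
            self.rf_phase_deg = 180.0 * (np.arange(self.fa_deg.size) % 2)
        else:
            self.rf_phase_deg = np.asarray(self.rf_phase_deg, dtype=np.float64)
            if self.rf_phase_deg.shape != self.fa_deg.shape:
                raise ValueError("rf_phase_deg must match the flip-angle train")

    @property
    def n_pulses(self) -> int:
        return self.fa_deg.size


def default_flip_angle_train(n: int, peak_deg: float = 70.0, period: int = 250):
    """Smooth repeating-lobe flip-angle train fa(i) = peak * |sin(pi*i/period)|.

    ``i`` runs from 1 to n; the train follows one ideal inversion.  Any other
    train can be supplied directly or loaded from CSV.
    """

    i = np.arange(1, n + 1, dtype=np.float64)
    return peak_deg * np.abs(np.sin(np.pi * i / period))


def default_sequence(n: int = 500, tr_ms: float = 4.4, te_ms: float = 2.0):
    return SequenceParams(default_flip_angle_train(n), tr_ms=tr_ms, te_ms=te_ms,
                          invert=True)


# ---------------------------------------------------------------------------
# EPG simulation
# ---------------------------------------------------------------------------

def epg_simulate(t1_ms, t2_ms, seq: SequenceParams, n_states: int | None = None,
                 fa_scale: float = 1.0, return_state: bool = False):
    """Single-tissue EPG simulation; returns the complex signal per TR.

    Plain-numpy reference implementation (the batched numba kernel used for
    dictionaries is tested against it).  ``fa_scale`` scales the whole train,
    which is how slice-profile isochromats are generated.  With
    ``return_state`` the final (F+, F-, Z) state arrays are returned as well.
    """

    if t1_ms <= 0 or t2_ms <= 0:
        raise ValueError("relaxation times must be positive")
    n = seq.n_pulses
    ns = min(n, DEFAULT_N_STATES) if n_states is None else int(n_states)
    fa = np.deg2rad(seq.fa_deg * fa_scale)
    ph = np.deg2rad(seq.rf_phase_deg)
    e1 = np.exp(-seq.tr_ms / t1_ms)
    e2 = np.exp(-seq.tr_ms / t2_ms)
    e2te = np.exp(-seq.te_ms / t2_ms)

    fp = np.zeros(ns, dtype=np.complex128)
    fm = np.zeros(ns, dtype=np.complex128)
    z = np.zeros(ns, dtype=np.complex128)
    z[0] = -1.0 if seq.invert else 1.0
    sig = np.empty(n, dtype=np.complex128)
    for i in range(n):
        ca, sa = np.cos(fa[i]), np.sin(fa[i])
        c2 = np.cos(fa[i] / 2.0) ** 2
        s2 = np.sin(fa[i] / 2.0) ** 2
        eip = np.exp(1j * ph[i])
        fp, fm, z = (
            c2 * fp + s2 * eip**2 * fm - 1j * eip * sa * z,
            s2 * np.conj(eip) ** 2 * fp + c2 * fm + 1j * np.conj(eip) * sa * z,
            -0.5j * np.conj(eip) * sa * fp + 0.5j * eip * sa * fm + ca * z,
        )
        sig[i] = fp[0] * e2te * np.conj(eip)  # receiver demodulated
        fp *= e2
        fm *= e2
        z *= e1
        z[0] += 1.0 - e1
        fp[1:] = fp[:-1]
        fp[0] = np.conj(fm[1]) if ns > 1 else np.conj(fm[0])
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
    if return_state:
        return sig, (fp, fm, z)
    return sig


@njit(cache=True)
def _epg_batch_kernel(fa, ph, tr, te, t1, t2, invert, ns):  # pragma: no cover
    n = fa.size
    nb = t1.size
    sig = np.empty((n, nb), dtype=np.complex128)
    fp = np.empty(ns, dtype=np.complex128)
    fm = np.empty(ns, dtype=np.complex128)
    z = np.empty(ns, dtype=np.complex128)
    for b in range(nb):
        e1 = np.exp(-tr / t1[b])
        e2 = np.exp(-tr / t2[b])
        e2te = np.exp(-te / t2[b])
        for k in range(ns):
            fp[k] = 0.0
            fm[k] = 0.0
            z[k] = 0.0
        z[0] = -1.0 if invert else 1.0
        for i in range(n):
            a = fa[i]
            ca = np.cos(a)
            sa = np.sin(a)
            c2 = np.cos(a / 2.0) ** 2
            s2 = np.sin(a / 2.0) ** 2
            eip = np.exp(1j * ph[i])
            ei2 = eip * eip
            for k in range(ns):
                fpk = fp[k]
                fmk = fm[k]
                zk = z[k]
                fp[k] = c2 * fpk + s2 * ei2 * fmk - 1j * eip * sa * zk
                fm[k] = s2 * np.conj(ei2) * fpk + c2 * fmk + 1j * np.conj(eip) * sa * zk
                z[k] = -0.5j * np.conj(eip) * sa * fpk + 0.5j * eip * sa * fmk + ca * zk
            sig[i, b] = fp[0] * e2te * np.conj(eip)
            for k in range(ns):
                fp[k] *= e2
                fm[k] *= e2
                z[k] *= e1
            z[0] += 1.0 - e1
            for k in range(ns - 1, 0, -1):
                fp[k] = fp[k - 1]
            if ns > 1:
                fp[0] = np.conj(fm[1])
            else:
                fp[0] = np.conj(fm[0])
            for k in range(ns - 1):
                fm[k] = fm[k + 1]
            fm[ns - 1] = 0.0
    return sig


def epg_simulate_batch(t1_ms, t2_ms, seq: SequenceParams, n_states: int | None = None,
                       fa_scale: float = 1.0):
    """Batched EPG over arrays of (T1, T2); returns signals (n_pulses, batch)."""
    t1 = np.ascontiguousarray(np.atleast_1d(t1_ms), dtype=np.float64)
    t2 = np.ascontiguousarray(np.atleast_1d(t2_ms), dtype=np.float64)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    ns = min(seq.n_pulses, DEFAULT_N_STATES) if n_states is None else int(n_states)
    fa = np.ascontiguousarray(np.deg2rad(seq.fa_deg * fa_scale))
    ph = np.ascontiguousarray(np.deg2rad(seq.rf_phase_deg))
    return _epg_batch_kernel(fa, ph, float(seq.tr_ms), float(seq.te_ms),
                             t1, t2, bool(seq.invert), ns)


# ---------------------------------------------------------------------------
# slice profile
# ---------------------------------------------------------------------------

def slice_profile(n_iso: int = 51):
    """Excitation profile samples p(z_i) across the slice, p(0) = 1.

    The profile is the small-tip (Fourier) response of a Hann-windowed sinc
    pulse with three lobes, evaluated at ``n_iso`` positions uniformly spanning
    the main lobe of the slice (center to the transition edges), and clipped
    at zero.  Isochromats are weighted uniformly.
    """

    if n_iso < 1 or n_iso % 2 == 0:
        raise ValueError("n_iso must be odd and >= 1")
    tau = np.linspace(-1.0, 1.0, 513)
    envelope = np.sinc(3.0 * tau) * (0.5 + 0.5 * np.cos(np.pi * tau))
    z = np.linspace(-1.5, 1.5, n_iso) if n_iso > 1 else np.zeros(1)
    # small-tip profile = Fourier transform of the (even) RF envelope
    p = np.cos(2.0 * np.pi * z[:, None] * tau[None, :]) @ envelope
    p = p / np.sum(envelope)  # normalize to 1 at slice center
    return np.clip(p, 0.0, None)


def slice_profile_correct(t1_ms, t2_ms, seq: SequenceParams, n_iso: int = 51,
                          n_states: int | None = None):
    """Mean EPG signal over slice-profile isochromats (uniform weighting)."""
    profile = slice_profile(n_iso)
    sig = np.zeros(seq.n_pulses, dtype=np.complex128)
    for p in profile:
        sig += epg_simulate(t1_ms, t2_ms, seq, n_states=n_states, fa_scale=p)
    return sig / n_iso


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def default_t1_grid_ms() -> np.ndarray:
    """Default dictionary T1 grid: 50:10:1400, 1430:30:1600, 1700:100:2200, 2400:200:3000."""
    return np.concatenate([
        np.arange(50, 1401, 10),
        np.arange(1430, 1601, 30),
        np.arange(1700, 2201, 100),
        np.arange(2400, 3001, 200),
    ]).astype(np.float64)


def default_t2_grid_ms() -> np.ndarray:
    """Default dictionary T2 grid: 5:2:80, 85:5:150, 160:10:300, 330:30:600."""
    return np.concatenate([
        np.arange(5, 81, 2),
        np.arange(85, 151, 5),
        np.arange(160, 301, 10),
        np.arange(330, 601, 30),
    ]).astype(np.float64)


@dataclass
class MRFDictionary:
    """Simulated fingerprints over the (T1, T2) grid product.

    ``atoms`` holds unit-normalized fingerprints (signal dim x D); after
    compression the signal dimension is the subspace rank and ``basis`` holds
    U_r.  ``t1_ms``/``t2_ms`` give the grid values per atom (length D) and
    ``norms`` the pre-normalization scales.
    """

    atoms: np.ndarray
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    norms: np.ndarray
    sequence: SequenceParams | None = None
    basis: SubspaceBasis | None = None

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def signal_dim(self) -> int:
        return self.atoms.shape[0]


def build_dictionary(t1_grid_ms, t2_grid_ms, seq: SequenceParams,
                     slice_correct: bool = True, n_iso: int = 51,
                     n_states: int | None = None) -> MRFDictionary:
    """Simulate one atom per (T1, T2) pair over the full Cartesian grid.

    Duplicated grid values produce duplicated atoms (no deduplication).  With
    ``slice_correct`` the atoms are isochromat-averaged; the symmetric profile
    is folded so each distinct flip-angle scale is simulated once.
    """

    t1_grid = np.atleast_1d(np.asarray(t1_grid_ms, dtype=np.float64))
    t2_grid = np.atleast_1d(np.asarray(t2_grid_ms, dtype=np.float64))
    if t1_grid.size == 0 or t2_grid.size == 0:
        raise ValueError("grids must be non-empty")
    t1, t2 = [a.reshape(-1) for a in np.meshgrid(t1_grid, t2_grid, indexing="ij")]

    if slice_correct:
        profile = slice_profile(n_iso)
        scales, counts = np.unique(profile, return_counts=True)
        weights = counts / n_iso
    else:
        scales, weights = np.array([1.0]), np.array([1.0])

    raw = np.zeros((seq.n_pulses, t1.size), dtype=np.complex128)
    for s, w in zip(scales, weights):
        raw += w * epg_simulate_batch(t1, t2, seq, n_states=n_states, fa_scale=s)

    norms = np.linalg.norm(raw, axis=0)
    atoms = raw / norms
    return MRFDictionary(atoms=atoms, t1_ms=t1, t2_ms=t2, norms=norms, sequence=seq)


def compress_dictionary(d: MRFDictionary, r: int) -> MRFDictionary:
    """Project atoms onto the rank-r temporal subspace of the atom matrix.

    U_r are the first r left singular vectors of the (signal dim x D) atom
    matrix; compressed atoms are U_r^H * atoms.  If the matrix rank falls below
    r the achievable rank is used with a warning.
    """

    if not 1 <= r <= d.signal_dim:
        raise ValueError("rank must satisfy 1 <= r <= signal dimension")
    u, s, _ = np.linalg.svd(d.atoms, full_matrices=False)
    numerical_rank = int(np.sum(s > s[0] * 1e-12))
    if numerical_rank < r:
        warnings.warn(f"atom matrix rank {numerical_rank} < requested {r}")
        r = numerical_rank
    ur = u[:, :r]
    return MRFDictionary(
        atoms=ur.conj().T @ d.atoms,
        t1_ms=d.t1_ms, t2_ms=d.t2_ms, norms=d.norms, sequence=d.sequence,
        basis=SubspaceBasis(ur),
    )


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass
class ParameterMaps:
    """Per-voxel quantitative outputs of dictionary matching."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray                      # complex proton-density scale
    match_index: np.ndarray             # -1 where unmatched (zero signal)
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.t1_ms.shape, dtype=bool)


def match_fingerprints(signals: np.ndarray, d: MRFDictionary,
                       mask: np.ndarray | None = None,
                       chunk: int = 2048) -> ParameterMaps:
    """Inner-product dictionary matching, voxel by voxel.

    ``signals`` has shape (..spatial.., signal_dim), where the signal dimension
    must match the dictionary's (compressed signals against compressed atoms).
    The winning atom maximizes |<atom_j, x>|; M0 is the complex projection
    divided by the atom's pre-normalization scale.  Zero-signal voxels inside
    the mask are flagged with match_index -1 and M0 = 0.
    """

    signals = np.asarray(signals, dtype=np.complex128)
    if signals.shape[-1] != d.signal_dim:
        raise ValueError(
            f"signal dimension {signals.shape[-1]} != dictionary {d.signal_dim}"
        )
    spatial = signals.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    flat = signals.reshape(-1, d.signal_dim)
    sel = mask.reshape(-1)

    idx = np.full(flat.shape[0], -1, dtype=np.int64)
    m0 = np.zeros(flat.shape[0], dtype=np.complex128)
    rows = np.flatnonzero(sel)
    for start in range(0, rows.size, chunk):
        r = rows[start:start + chunk]
        corr = flat[r] @ np.conj(d.atoms)          # (chunk, D): <atom_j, x>
        best = np.argmax(np.abs(corr), axis=1)
        idx[r] = best
        m0[r] = corr[np.arange(r.size), best] / d.norms[best]
    nonzero = np.linalg.norm(flat, axis=1) > 0
    idx[~nonzero] = -1
    m0[~nonzero] = 0.0

    ok = idx >= 0
    t1 = np.where(ok, d.t1_ms[np.clip(idx, 0, None)], 0.0)
    t2 = np.where(ok, d.t2_ms[np.clip(idx, 0, None)], 0.0)
    return ParameterMaps(
        t1_ms=t1.reshape(spatial), t2_ms=t2.reshape(spatial),
        m0=m0.reshape(spatial), match_index=idx.reshape(spatial),
        mask=np.asarray(mask, dtype=bool),
    )
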