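"""Independent oracles used by the test suite (never the implementation path)."""

import numpy as np


def bloch_isochromat_fisp(fa_deg, phase_deg, tr_ms, te_ms, t1_ms, t2_ms,
                          invert=False, n_iso=200):
    """Isochromat Bloch simulation of the gradient-dephased sequence.

    ``n_iso`` magnetization vectors are uniformly dephased by one gradient
    cycle per TR (applied between TE and the next pulse); the recorded signal
    is the isochromat-mean transverse magnetization at TE, receiver
    demodulated.  Matches the extended-phase-graph model up to state
    truncation for n_iso larger than the number of occupied orders.
    """

    n = len(fa_deg)
    m = np.zeros((3, n_iso))
    m[2] = -1.0 if invert else 1.0
    theta = 2 * np.pi * np.arange(n_iso) / n_iso
    e1 = np.exp(-tr_ms / t1_ms)
    e2 = np.exp(-tr_ms / t2_ms)
    e2te = np.exp(-te_ms / t2_ms)
    sig = np.empty(n, dtype=complex)
    for i in range(n):
        a = np.deg2rad(fa_deg[i])
        ph = np.deg2rad(phase_deg[i])
        ca, sa = np.cos(a), -np.sin(a)   # chirality: phase-0 pulse tips +z to -i
        cp, sp = np.cos(ph), np.sin(ph)
        rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, ca, sa], [0, -sa, ca]])
        m = (rz @ rx @ rz.T) @ m
        mxy = (m[0] + 1j * m[1]) * e2te * np.exp(-1j * ph)
        sig[i] = mxy.mean()
        m[0:2] *= e2
        spun = (m[0] + 1j * m[1]) * np.exp(1j * theta)
        m[0], m[1] = spun.real, spun.imag
        m[2] = m[2] * e1 + (1 - e1)
    return sig


def fisp_steady_state(alpha_deg, tr_ms, te_ms, t1_ms, t2_ms):
    """Closed-form steady-state FID magnitude of the gradient-dephased sequence
    (Freeman-Hill SSFP-FID expression), with T2 decay to TE."""

    e1 = np.exp(-tr_ms / t1_ms)
    e2 = np.exp(-tr_ms / t2_ms)
    a = np.deg2rad(alpha_deg)
    c = np.cos(a)
    p = 1 - e1 * c - e2**2 * (e1 - c)
    q = e2 * (1 - e1) * (1 + c)
    d = (1 - e2**2) / np.sqrt(p**2 - q**2)
    return np.tan(a / 2) * (1 - (e1 - c) * d) * np.exp(-te_ms / t2_ms)


def brute_force_block_match(x, ref, edge, radius, k):
    """Exhaustive K-smallest patch search (scan-order tie-break, reference first)."""
    spatial = x.shape[:-1]
    ref_patch = x[tuple(slice(r, r + edge) for r in ref)]
    scored = []
    ranges = [
        range(max(0, r - radius), min(s - edge, r + radius) + 1)
        for r, s in zip(ref, spatial)
    ]
    import itertools

    for corner in itertools.product(*ranges):
        if corner == tuple(ref):
            continue
        patch = x[tuple(slice(c, c + edge) for c in corner)]
        d = float(np.sum(np.abs(patch - ref_patch) ** 2))
        lin = int(np.ravel_multi_index(corner, spatial))
        scored.append((d, lin, corner))
    scored.sort()
    return [tuple(ref)] + [c for _, _, c in scored[: k - 1]]


def dense_normal_solve(op, y, t, b, mu):
    """Direct dense solve of (E^H E + mu I) x = E^H y + mu t - b."""
    shape = op.image_shape
    n = int(np.prod(shape))
    eye = np.eye(n)
    cols = [op.forward(eye[:, i].reshape(shape)).reshape(-1) for i in range(n)]
    e = np.stack(cols, axis=1)
    a = e.conj().T @ e + mu * np.eye(n)
    rhs = e.conj().T @ y.reshape(-1) + mu * t.reshape(-1) - b.reshape(-1)
    return np.linalg.solve(a, rhs).reshape(shape)
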