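"""Independent oracles used by the test suite.

These deliberately avoid the closed forms and fast algorithms they check:
the Bloch oracle iterates excitation/relaxation to the steady state, the
TFCE oracle recomputes connected components at every threshold.
"""

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


def rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def bloch_spgr(m0, t1, flip_deg, tr, n=8000):
    """Perfectly spoiled gradient echo steady state by iteration."""
    mz = m0
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr / t1)
    for _ in range(n):
        mz = mz * np.cos(a) * e1 + m0 * (1 - e1)
    return mz * np.sin(a)


def bloch_bssfp(m0, t1, t2, flip_deg, dphi_deg, tr, f0=0.0, n=8000):
    """Balanced steady state by full 3D spin iteration with per-pulse RF
    phase increment; magnitude right after excitation."""
    M = np.array([0.0, 0.0, m0])
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    a = np.deg2rad(flip_deg)
    theta = 2 * np.pi * f0 * tr * 1e-3
    phi = 0.0
    for _ in range(n):
        R = rot_z(phi) @ rot_x(a) @ rot_z(-phi)
        M = rot_z(theta) @ (R @ M)
        M[:2] *= e2
        M[2] = M[2] * e1 + m0 * (1 - e1)
        phi += np.deg2rad(dphi_deg)
    R = rot_z(phi) @ rot_x(a) @ rot_z(-phi)
    M = R @ M
    return float(np.hypot(M[0], M[1]))


def bloch_spgr_grid(t1s, flip_deg, tr, n):
    """Vectorized spoiled-echo iteration over a T1 vector (M0 = 1)."""
    t1s = np.asarray(t1s, dtype=float)
    e1 = np.exp(-tr / t1s)
    a = np.deg2rad(flip_deg)
    mz = np.ones_like(t1s)
    for _ in range(n):
        mz = mz * np.cos(a) * e1 + (1 - e1)
    return mz * np.sin(a)


def bloch_bssfp_grid(t1s, t2s, flip_deg, dphi_deg, tr, n):
    """Vectorized balanced-sequence iteration over (T1, T2) pairs (M0=1,
    on resonance).  The RF rotation is shared; relaxation is per pair."""
    t1s = np.asarray(t1s, dtype=float)
    t2s = np.asarray(t2s, dtype=float)
    e1 = np.exp(-tr / t1s)
    e2 = np.exp(-tr / t2s)
    a = np.deg2rad(flip_deg)
    M = np.zeros((len(t1s), 3))
    M[:, 2] = 1.0
    phi = 0.0
    for _ in range(n):
        R = rot_z(phi) @ rot_x(a) @ rot_z(-phi)
        M = M @ R.T
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + (1 - e1)
        phi += np.deg2rad(dphi_deg)
    R = rot_z(phi) @ rot_x(a) @ rot_z(-phi)
    M = M @ R.T
    return np.hypot(M[:, 0], M[:, 1])


def brute_force_tfce(s, graph, E=1.0, H=2.0, dh=None, n_steps=100):
    """Per-threshold connected-component recomputation."""
    out = np.zeros(graph.n_vertices)
    m = np.abs(s).max()
    if m == 0:
        return out
    dh = dh or m / n_steps
    for sign in (1, -1):
        ss = np.maximum(sign * s, 0)
        for h in np.arange(dh, ss.max() + 0.5 * dh, dh):
            act = ss >= h
            idx = np.flatnonzero(act)
            if len(idx) == 0:
                continue
            emask = act[graph.edges[:, 0]] & act[graph.edges[:, 1]]
            e = graph.edges[emask]
            remap = -np.ones(graph.n_vertices, int)
            remap[idx] = np.arange(len(idx))
            adj = coo_matrix(
                (np.ones(len(e)), (remap[e[:, 0]], remap[e[:, 1]])),
                shape=(len(idx), len(idx)),
            )
            _, lab = connected_components(adj, directed=False)
            areas = np.bincount(lab, weights=graph.vertex_areas[idx])
            out[idx] += sign * areas[lab] ** E * h**H * dh
    return out
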