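"""Independent brute-force oracles used by the acceptance checks.

These deliberately avoid every code path of the package under test:
surfaces come from explicit neighbour checks, distances from dense
all-pairs matrices, and the STAPLE EM from scalar loops.
"""

import numpy as np


def oracle_surface(mask_data: np.ndarray, spacing, origin) -> np.ndarray:
    """Boundary voxel centres via explicit 6-neighbour enumeration."""
    pts = []
    m = mask_data
    for i, j, k in np.argwhere(m):
        on_boundary = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < m.shape[0] and 0 <= nj < m.shape[1] and 0 <= nk < m.shape[2]):
                on_boundary = True
                break
            if not m[ni, nj, nk]:
                on_boundary = True
                break
        if on_boundary:
            pts.append((i, j, k))
    return np.asarray(pts, dtype=float) * np.asarray(spacing) + np.asarray(origin)


def oracle_distances(a_data, b_data, spacing, origin=(0, 0, 0)):
    """(msd, hd_directed_a_to_b, hd_symmetric) from a dense all-pairs matrix."""
    sa = oracle_surface(a_data, spacing, origin)
    sb = oracle_surface(b_data, spacing, origin)
    d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=-1)
    d = np.sqrt(d2)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    msd = 0.5 * (d_ab.mean() + d_ba.mean())
    return float(msd), float(d_ab.max()), float(max(d_ab.max(), d_ba.max()))


def oracle_dice(a_data, b_data) -> float:
    inter = 0
    na = nb = 0
    for idx in np.ndindex(*a_data.shape):
        if a_data[idx]:
            na += 1
        if b_data[idx]:
            nb += 1
        if a_data[idx] and b_data[idx]:
            inter += 1
    return 2.0 * inter / (na + nb)


def oracle_staple(D, pi0, max_iter=100, tol=1e-6, p0=0.99, q0=0.99):
    """Scalar-loop STAPLE EM on a decision matrix D[j][i] in {0, 1}."""
    J, N = len(D), len(D[0])
    p = [p0] * J
    q = [q0] * J
    W = [0.0] * N
    for _ in range(max_iter):
        for i in range(N):
            a, b = pi0, 1.0 - pi0
            for j in range(J):
                if D[j][i]:
                    a *= p[j]
                    b *= 1.0 - q[j]
                else:
                    a *= 1.0 - p[j]
                    b *= q[j]
            W[i] = a / (a + b)
        p_new, q_new = [], []
        for j in range(J):
            p_new.append(sum(W[i] for i in range(N) if D[j][i]) / sum(W))
            q_new.append(sum(1 - W[i] for i in range(N) if not D[j][i]) / sum(1 - w for w in W))
        delta = max(max(abs(x - y) for x, y in zip(p, p_new)),
                    max(abs(x - y) for x, y in zip(q, q_new)))
        p, q = p_new, q_new
        if delta < tol:
            break
    return W, p, q
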