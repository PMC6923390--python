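"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible — triple loops, explicit
enumeration — and shares no code with the package implementation beyond
numpy itself.
"""

from itertools import combinations

import numpy as np

NEIGH_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRS_13 = [d for d in NEIGH_26 if d > (0, 0, 0)]


def _inb(p, shape):
    return all(0 <= p[k] < shape[k] for k in range(3))


def glcm_counts(lev, n_g):
    """Pair enumeration over the 13 directions, symmetrized, unnormalized."""
    C = np.zeros((n_g, n_g), dtype=np.int64)
    shape = lev.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = lev[x, y, z]
                if a == 0:
                    continue
                for d in DIRS_13:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inb(q, shape) and lev[q] > 0:
                        b = lev[q]
                        C[a - 1, b - 1] += 1
                        C[b - 1, a - 1] += 1
    return C


def glrlm_counts(lev, n_g):
    """Run scanner: walk every maximal run in every direction."""
    shape = lev.shape
    max_len = max(shape)
    R = np.zeros((n_g, max_len), dtype=np.int64)
    for d in DIRS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = lev[x, y, z]
                    if a == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inb(prev, shape) and lev[prev] == a:
                        continue  # not a run start
                    length = 1
                    cur = (x + d[0], y + d[1], z + d[2])
                    while _inb(cur, shape) and lev[cur] == a:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    R[a - 1, length - 1] += 1
    return R


def glszm_counts(lev, n_g):
    """Flood-fill zones of equal level, 26-connected."""
    shape = lev.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if lev[x, y, z] == 0 or seen[x, y, z]:
                    continue
                a = lev[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGH_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inb(q, shape) and not seen[q] and lev[q] == a:
                            seen[q] = True
                            stack.append(q)
                zones.append((a, size))
    max_size = max((s for _, s in zones), default=1)
    S = np.zeros((n_g, max_size), dtype=np.int64)
    for a, s in zones:
        S[a - 1, s - 1] += 1
    return S


def ngldm_counts(lev, n_g):
    """Neighbour counting with alpha = 0 (equal level)."""
    shape = lev.shape
    D = np.zeros((n_g, 27), dtype=np.int64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = lev[x, y, z]
                if a == 0:
                    continue
                k = 0
                for d in NEIGH_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inb(q, shape) and lev[q] == a:
                        k += 1
                D[a - 1, k] += 1
    return D


def ngtdm_table(lev, n_g):
    """Per-level (s_i, n_i): deviation from the in-ROI neighbourhood mean."""
    shape = lev.shape
    T = np.zeros((n_g, 2), dtype=np.float64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = lev[x, y, z]
                if a == 0:
                    continue
                vals = []
                for d in NEIGH_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inb(q, shape) and lev[q] > 0:
                        vals.append(lev[q])
                if not vals:
                    continue
                T[a - 1, 0] += abs(a - sum(vals) / len(vals))
                T[a - 1, 1] += 1
    return T


def wmw_exact_p(g0, g1):
    """Exact two-sided Mann-Whitney p by full enumeration of group splits."""
    pooled = sorted(list(g0) + list(g1))
    n0, n1 = len(g0), len(g1)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    rank = {v: r for r, v in enumerate(pooled, start=1)}

    def ustat(group0):
        return sum(rank[v] for v in group0) - n0 * (n0 + 1) / 2

    u_obs = ustat(g0)
    mu = n0 * n1 / 2
    dev = abs(u_obs - mu)
    count = total = 0
    for combo in combinations(pooled, n0):
        total += 1
        if abs(ustat(combo) - mu) >= dev - 1e-12:
            count += 1
    return count / total


def conv3d_direct(image, kernel, center):
    """Direct 3D convolution: out[p] = sum_k kernel[k] * image[p + center - k].

    Zero padding outside; only valid for checking interior voxels.
    """
    out = np.zeros_like(image)
    kx, ky, kz = kernel.shape
    for i in range(kx):
        for j in range(ky):
            for k in range(kz):
                w = kernel[i, j, k]
                if w == 0:
                    continue
                shifted = np.zeros_like(image)
                dx, dy, dz = center[0] - i, center[1] - j, center[2] - k
                src = tuple(
                    slice(max(d, 0), image.shape[a] + min(d, 0))
                    for a, d in enumerate((dx, dy, dz))
                )
                dst = tuple(
                    slice(max(-d, 0), image.shape[a] + min(-d, 0))
                    for a, d in enumerate((dx, dy, dz))
                )
                shifted[dst] = image[src]
                out += w * shifted
    return out


def auc_pair_counting(scores, labels):
    """AUC by exhaustive pair counting, ties worth 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = wins = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                wins += 1
            elif a == b:
                wins += 0.5
    return wins / total


def random_roi(rng, n_g, max_edge=6):
    """A random quantized ROI: level array with 0 = outside."""
    shape = tuple(int(rng.integers(1, max_edge + 1)) for _ in range(3))
    lev = rng.integers(0, n_g + 1, size=shape)
    if not (lev > 0).any():
        lev.flat[rng.integers(0, lev.size)] = 1
    return lev.astype(np.int64)


def pad_cols(a, width):
    """Zero-pad a 2D count matrix on the right to the given column count."""
    import numpy as _np
    if a.shape[1] >= width:
        return a
    return _np.pad(a, ((0, 0), (0, width - a.shape[1])))
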