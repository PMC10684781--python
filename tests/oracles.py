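"""Independent brute-force oracles for the texture matrices and the AUC.

Everything here is deliberately naive (pure-Python triple loops, explicit
pair counting) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def brute_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts by scanning every voxel pair."""
    mat = np.zeros((n_levels, n_levels), dtype=np.int64)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for sign in (1, -1):
                    u, v, w = x + sign * offset[0], y + sign * offset[1], z + sign * offset[2]
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        mat[levels[x, y, z] - 1, levels[u, v, w] - 1] += 1
    return mat


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts by walking every maximal run voxel by voxel."""
    nx, ny, nz = levels.shape
    runs: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                px, py, pz = x - direction[0], y - direction[1], z - direction[2]
                prev_same = (
                    0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                    and mask[px, py, pz]
                    and levels[px, py, pz] == levels[x, y, z]
                )
                if prev_same:
                    continue  # not a run start
                length = 1
                u, v, w = x + direction[0], y + direction[1], z + direction[2]
                while (
                    0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                    and mask[u, v, w]
                    and levels[u, v, w] == levels[x, y, z]
                ):
                    length += 1
                    u, v, w = u + direction[0], v + direction[1], w + direction[2]
                runs.append((levels[x, y, z], length))
    max_len = max((l for _, l in runs), default=1)
    mat = np.zeros((n_levels, max_len), dtype=np.int64)
    for lev, length in runs:
        mat[lev - 1, length - 1] += 1
    return mat


def brute_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts by flood-filling 26-connected iso-level zones."""
    nx, ny, nz = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lev = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                            and mask[u, v, w] and not seen[u, v, w]
                            and levels[u, v, w] == lev
                        ):
                            seen[u, v, w] = True
                            stack.append((u, v, w))
                zones.append((lev, size))
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for lev, size in zones:
        mat[lev - 1, size - 1] += 1
    return mat


def brute_gldm(levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts (j = 1 + dependent 26-neighbors) voxel by voxel."""
    nx, ny, nz = levels.shape
    entries: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                dep = 0
                for dx, dy, dz in NEIGHBORS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if (
                        0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                        and mask[u, v, w]
                        and abs(int(levels[u, v, w]) - int(levels[x, y, z])) <= alpha
                    ):
                        dep += 1
                entries.append((levels[x, y, z], dep + 1))
    max_dep = max(j for _, j in entries)
    mat = np.zeros((n_levels, max_dep), dtype=np.int64)
    for lev, j in entries:
        mat[lev - 1, j - 1] += 1
    return mat


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level (n_i, s_i) sums and the valid-voxel count."""
    nx, ny, nz = levels.shape
    n_i = np.zeros(n_levels, dtype=np.int64)
    s_i = np.zeros(n_levels, dtype=float)
    nvp = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                neigh = []
                for dx, dy, dz in NEIGHBORS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        neigh.append(int(levels[u, v, w]))
                if not neigh:
                    continue
                nvp += 1
                lev = int(levels[x, y, z])
                n_i[lev - 1] += 1
                s_i[lev - 1] += abs(lev - sum(neigh) / len(neigh))
    return n_i, s_i, nvp


def allpairs_auc(y_true, scores) -> float:
    """AUC by explicit concordant / tied pair counting."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    total = len(pos) * len(neg)
    conc = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(0.5 for p in pos for n in neg if p == n)
    return (conc + ties) / total
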