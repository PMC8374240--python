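"""Independent brute-force oracles for the texture matrices.

Everything here is written as plain nested loops over voxels, deliberately
sharing no code with the package's vectorized builders.
"""

from __future__ import annotations

import numpy as np

OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_bruteforce(levels: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Symmetric pair-count matrix by enumerating every voxel pair."""
    P = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for p in np.ndindex(shape):
        a = levels[p]
        if a == 0:
            continue
        q = tuple(c + d for c, d in zip(p, offset))
        if not _inside(shape, q):
            continue
        b = levels[q]
        if b == 0:
            continue
        P[a - 1, b - 1] += 1
        P[b - 1, a - 1] += 1
    return P


def glrlm_bruteforce(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts by walking every line in the direction."""
    shape = levels.shape
    runs = []
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        prev = tuple(c - d for c, d in zip(p, direction))
        if _inside(shape, prev) and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        cur = p
        while True:
            nxt = tuple(c + d for c, d in zip(cur, direction))
            if not _inside(shape, nxt) or levels[nxt] != levels[p]:
                break
            length += 1
            cur = nxt
        runs.append((levels[p], length))
    max_len = max(l for _, l in runs)
    P = np.zeros((n_levels, max_len))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def glszm_bruteforce(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts via explicit flood fill with 26-connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in np.ndindex(shape):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                q = tuple(c + d for c, d in zip(cur, off))
                if _inside(shape, q) and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    P = np.zeros((n_levels, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def ngtdm_bruteforce(levels: np.ndarray, n_levels: int):
    """(n_i, s_i) by looping over voxels and their in-ROI neighbors."""
    shape = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for p in np.ndindex(shape):
        g = levels[p]
        if g == 0:
            continue
        neigh = []
        for off in OFFSETS_26:
            q = tuple(c + d for c, d in zip(p, off))
            if _inside(shape, q) and levels[q] > 0:
                neigh.append(levels[q])
        if not neigh:
            continue
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - float(np.mean(neigh)))
    return n_i, s_i


def gldm_bruteforce(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts (center voxel included) by direct neighbor checks."""
    shape = levels.shape
    entries = []
    for p in np.ndindex(shape):
        g = levels[p]
        if g == 0:
            continue
        dep = 1
        for off in OFFSETS_26:
            q = tuple(c + d for c, d in zip(p, off))
            if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(g)) <= alpha:
                dep += 1
        entries.append((g, dep))
    max_dep = max(d for _, d in entries)
    P = np.zeros((n_levels, max_dep))
    for g, d in entries:
        P[g - 1, d - 1] += 1
    return P


def auc_paircount(scores, y) -> float:
    """AUC by counting concordant pairs (half credit for ties)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
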