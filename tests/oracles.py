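"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: breadth-first flood fill for component labelling,
two-pass covariance for Pearson, and nothing shared with the library code
paths they verify.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """BFS connected components of a boolean mask as sets of pixel coords."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            q = deque([(r, c)])
            seen[r, c] = True
            while q:
                rr, cc = q.popleft()
                comp.add((rr, cc))
                for dr, dc in nbrs:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        q.append((nr, nc))
            comps.append(comp)
    return comps


def components_summary(
    mask: np.ndarray, min_area: int, connectivity: int
) -> list[tuple[int, float, float]]:
    """Sorted (area, centroid_row, centroid_col) of size-filtered components."""
    out = []
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) < min_area:
            continue
        rows = [p[0] for p in comp]
        cols = [p[1] for p in comp]
        out.append((len(comp), sum(rows) / len(comp), sum(cols) / len(comp)))
    return sorted(out)


def pearson_two_pass(a: np.ndarray, b: np.ndarray) -> float:
    """Direct two-pass covariance / variance computation."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ma, mb = a.mean(), b.mean()
    cov = ((a - ma) * (b - mb)).sum()
    return cov / math.sqrt(((a - ma) ** 2).sum() * ((b - mb) ** 2).sum())


def otsu_sweep(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximisation over observed levels."""
    values = np.asarray(values, dtype=float).ravel()
    best_t, best_v = None, -1.0
    for t in np.unique(values)[:-1]:
        lo = values[values <= t]
        hi = values[values > t]
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t
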