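"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, enumeration, grid
search) and shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def flood_fill(passable: np.ndarray, seeds: list[tuple[int, int]]) -> np.ndarray:
    """4-connected BFS flood fill over a boolean grid."""
    reached = np.zeros_like(passable, dtype=bool)
    q = deque()
    for r, c in seeds:
        if passable[r, c] and not reached[r, c]:
            reached[r, c] = True
            q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < passable.shape[0] and 0 <= cc < passable.shape[1]:
                if passable[rr, cc] and not reached[rr, cc]:
                    reached[rr, cc] = True
                    q.append((rr, cc))
    return reached


def fill_holes_by_flood(mask: np.ndarray) -> np.ndarray:
    """Hole filling defined via flood fill from the border background."""
    outside = np.pad(~mask, 1, constant_values=True)
    reach = flood_fill(outside, [(0, 0)])[1:-1, 1:-1]
    return mask | ~reach


def signed_rank_p_enumeration(differences) -> float:
    """Two-sided exact Wilcoxon p by literal enumeration of all 2^n sign
    assignments (zeros dropped, average ranks for ties)."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    mags = np.abs(d)
    # average ranks by explicit counting
    ranks = np.empty(n)
    for i in range(n):
        less = np.sum(mags < mags[i])
        equal = np.sum(mags == mags[i])
        ranks[i] = less + (equal + 1) / 2.0
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2.0**n


def grid_search_through_origin_slope(pairs, step: float = 1e-6) -> float:
    """One-parameter least squares by exhaustive grid refinement.

    Scans slope candidates over a broad bracket and refines to ``step``,
    minimizing sum((y - b x)^2) directly.
    """
    arr = np.asarray(pairs, dtype=float)
    x, y = arr[:, 0], arr[:, 1]

    def rss(b):
        return ((y - b * x) ** 2).sum()

    lo, hi = -10.0, 10.0
    width = 1e-2
    while True:
        grid = np.arange(lo, hi + width, width)
        losses = [rss(b) for b in grid]
        best = grid[int(np.argmin(losses))]
        if width <= step:
            return float(best)
        lo, hi = best - 2 * width, best + 2 * width
        width /= 100.0
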