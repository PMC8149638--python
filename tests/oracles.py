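"""Independent reference implementations used only by the tests.

Deliberately plain and slow: a queue-based breadth-first search on the
8-connected masked grid, a closed-form Chebyshev distance, and textbook
t-statistic formulas.  Nothing here shares code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

INF = float("inf")

_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def bfs_geodesic(mask: np.ndarray, seeds) -> np.ndarray:
    """Multi-source BFS distances on the 8-connected grid graph of True pixels."""
    mask = np.asarray(mask, dtype=bool)
    nr, nc = mask.shape
    dist = np.full((nr, nc), INF)
    q: deque[tuple[int, int]] = deque()
    for r, c in seeds:
        if mask[r, c] and dist[r, c] != 0:
            dist[r, c] = 0.0
            q.append((r, c))
    while q:
        r, c = q.popleft()
        d = dist[r, c] + 1
        for dr, dc in _STEPS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and d < dist[rr, cc]:
                dist[rr, cc] = d
                q.append((rr, cc))
    return dist


def chebyshev_to_nearest(shape, seeds) -> np.ndarray:
    """Closed form on an obstacle-free grid: min over seeds of max(|dr|,|dc|)."""
    nr, nc = shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    best = np.full(shape, INF)
    for r, c in seeds:
        best = np.minimum(best, np.maximum(np.abs(rr - r), np.abs(cc - c)))
    return best


def pooled_t(a, b) -> tuple[float, float]:
    """Textbook two-sample pooled-variance Student's t, two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), df=na + nb - 2)
    return t, p


def paired_t(x, y) -> tuple[float, float]:
    """Textbook paired Student's t on the differences, two-sided p."""
    from scipy.stats import t as tdist

    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), df=n - 1)
    return t, p


def average_ranks(v) -> list[float]:
    """Average ranks with ties, by explicit counting (no library calls)."""
    v = list(map(float, v))
    out = []
    for x in v:
        less = sum(1 for y in v if y < x)
        equal = sum(1 for y in v if y == x)
        # ranks occupied by the tie group: less+1 .. less+equal; take the mean
        out.append(less + (equal + 1) / 2.0)
    return out


def spearman_brute(x, y) -> float:
    """Pearson correlation of explicitly computed average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def random_blob_mask(rng: np.random.Generator, max_size: int = 64) -> np.ndarray:
    """Random connected-ish test mask with at least one True pixel."""
    nr = int(rng.integers(4, max_size + 1))
    nc = int(rng.integers(4, max_size + 1))
    mask = rng.random((nr, nc)) < rng.uniform(0.35, 0.85)
    if not mask.any():
        mask[nr // 2, nc // 2] = True
    return mask


def random_points_on(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    idx = rng.integers(0, rows.size, size=n)
    return np.column_stack([rows[idx], cols[idx]])
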