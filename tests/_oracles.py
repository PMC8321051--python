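"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive pure-Python / BFS implementations, sharing no code path
with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def otsu_bruteforce(values) -> tuple[float, float]:
    """Exhaustive intra-class-variance minimisation over distinct values.

    Returns (threshold, objective); ties toward the smallest candidate.
    """
    vals = [float(v) for v in np.asarray(values).ravel()]
    n = len(vals)

    def popvar(xs):
        if not xs:
            return 0.0
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    best_t, best_obj = None, None
    for t in sorted(set(vals)):
        bg = [v for v in vals if v < t]
        fg = [v for v in vals if v >= t]
        obj = (len(bg) * popvar(bg) + len(fg) * popvar(fg)) / n
        if best_obj is None or obj < best_obj - 1e-15:
            best_t, best_obj = t, obj
    return best_t, best_obj


def enclosed_background_components(mask) -> list[frozenset]:
    """4-connected background components unreachable by flood fill from the
    image border, as frozensets of (column, row) pixels."""
    mask = np.asarray(mask)
    h, w = mask.shape
    bg = mask == 0
    reachable = np.zeros((h, w), dtype=bool)
    queue: deque[tuple[int, int]] = deque()
    for x in range(w):
        for y in (0, h - 1):
            if bg[y, x] and not reachable[y, x]:
                reachable[y, x] = True
                queue.append((x, y))
    for y in range(h):
        for x in (0, w - 1):
            if bg[y, x] and not reachable[y, x]:
                reachable[y, x] = True
                queue.append((x, y))
    while queue:
        x, y = queue.popleft()
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h and bg[ny, nx] and not reachable[ny, nx]:
                reachable[ny, nx] = True
                queue.append((nx, ny))

    seen = np.zeros((h, w), dtype=bool)
    components = []
    for y0 in range(h):
        for x0 in range(w):
            if bg[y0, x0] and not reachable[y0, x0] and not seen[y0, x0]:
                comp = set()
                queue = deque([(x0, y0)])
                seen[y0, x0] = True
                while queue:
                    x, y = queue.popleft()
                    comp.add((x, y))
                    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nx, ny = x + dx, y + dy
                        if (0 <= nx < w and 0 <= ny < h and bg[ny, nx]
                                and not reachable[ny, nx] and not seen[ny, nx]):
                            seen[ny, nx] = True
                            queue.append((nx, ny))
                components.append(frozenset(comp))
    return components


def random_blob_mask(rng: np.random.Generator, shape=(24, 24)) -> np.ndarray:
    """Random foreground blobs with occasional enclosed holes."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    mask = (field > np.quantile(field, 0.45)).astype(np.uint8)
    # sprinkle extra foreground/background specks to roughen the topology
    speck = rng.random(shape)
    mask[speck < 0.04] = 1
    mask[speck > 0.97] = 0
    return mask


def threshold_scan_oracle(gray, gray_s, box, p, c, l1_init, l2_init):
    """Independent full-grid enumeration of the recursive threshold scan.

    Walks every (l1, l2) pair in nesting order (l2 inner, initial pair
    first) and returns the first pair admitting a qualifying enclosed
    region, with its decrement counts.
    """
    from mvtrack import find_enclosed_regions, qualifies

    def grid(init):
        vals, v = [], init
        while v > 0:
            vals.append(v)
            v = round(v - c, 12)
        vals.append(0.0)
        return vals

    for k1, l1 in enumerate(grid(l1_init)):
        for k2, l2 in enumerate(grid(l2_init)):
            combined = ((gray >= l1) | (gray_s >= l2)).astype(np.uint8)
            qual = [r for r in find_enclosed_regions(combined)
                    if qualifies(r, box, p)]
            if qual:
                return l1, l2, (k1, k2)
    return None


def max_distance_pair_bruteforce(centroids) -> tuple[int, int, float]:
    """O(n^2) scan for the farthest pair; lexicographically smallest ties.

    ``centroids``: list of (x, y) or None (skipped). Returns 0-based indices.
    """
    best = None
    for i in range(len(centroids)):
        if centroids[i] is None:
            continue
        for j in range(i + 1, len(centroids)):
            if centroids[j] is None:
                continue
            d = ((centroids[i][0] - centroids[j][0]) ** 2
                 + (centroids[i][1] - centroids[j][1]) ** 2) ** 0.5
            if best is None or d > best[2] + 1e-12:
                best = (i, j, d)
    return best
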