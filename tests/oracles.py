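"""Independent brute-force reference implementations used by the tests.

Each function here is deliberately naive (loops, explicit sums,
enumeration) and shares no code with the package, so agreement with the
package is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


def pearson_sums(x, y) -> float:
    """Pearson r from the raw textbook sum formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den


def gini_pairwise(values) -> float:
    """Gini index from the O(n^2) pairwise-difference definition."""
    x = np.asarray(values, float)
    n = len(x)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += abs(x[i] - x[j])
    return total / (2.0 * n * n * x.mean())


def welch_t(a, b) -> float:
    """Welch t statistic from explicit sums."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    return (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)


def mannwhitney_u(a, b) -> float:
    """Mann-Whitney U of sample a by direct pair counting (ties count 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def dilate_2d(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary dilation with the full 3x3 element by explicit neighbour OR."""
    out = mask.copy()
    for _ in range(iterations):
        padded = np.pad(out, 1)
        acc = np.zeros_like(out)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                acc |= padded[1 + dy : 1 + dy + out.shape[0],
                              1 + dx : 1 + dx + out.shape[1]]
        out = acc
    return out


def inner_boundary_2d(mask: np.ndarray) -> set[tuple[int, int]]:
    """True pixels with at least one false 8-neighbour (frame counts as
    false)."""
    h, w = mask.shape
    out = set()
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                        out.add((y, x))
    return out


def min_boundary_distance(centroid, boundary, spacing) -> float:
    """Min Euclidean centroid-boundary distance by full enumeration."""
    sp = np.asarray(spacing, float)
    c = np.asarray(centroid, float) * sp
    best = np.inf
    for b in np.asarray(boundary, float):
        d = np.sqrt((((b * sp) - c) ** 2).sum())
        best = min(best, d)
    return best


def percentile_sorted(values, q: float) -> float:
    """q-th percentile with linear interpolation between order statistics."""
    x = np.sort(np.asarray(values, float))
    pos = (len(x) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return x[lo] * (1 - frac) + x[hi] * frac


def best_shift_exhaustive(ref, moving, max_shift) -> tuple[int, int, float]:
    """Exhaustive Pearson-peak shift search using np.corrcoef directly."""
    best = (-2.0, None, None)
    h, w = ref.shape
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ry0, ry1 = max(0, dy), h + min(0, dy)
            rx0, rx1 = max(0, dx), w + min(0, dx)
            a = ref[ry0:ry1, rx0:rx1].ravel()
            b = moving[ry0 - dy : ry1 - dy, rx0 - dx : rx1 - dx].ravel()
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r > best[0] + 1e-12:
                best = (r, dy, dx)
    return best[1], best[2], best[0]


def prolate_spheroid_area(a: float, b: float) -> float:
    """Closed-form surface area of a prolate spheroid with polar semi-axis
    a > equatorial semi-axis b."""
    e = np.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * np.pi * b**2 * (1.0 + (a / (b * e)) * np.arcsin(e))
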