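"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's own code paths (and scipy's peak
machinery): peaks are found by exhaustive local-maxima scanning with
textbook topographic prominence, widths by explicit linear interpolation,
and the rank statistics by literal rank arithmetic.
"""
from __future__ import annotations

import math

import numpy as np


def local_maxima(x: np.ndarray) -> list[int]:
    """Leftmost indices of all strict local maxima (plateau-aware)."""
    out = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                out.append(i)  # leftmost sample of the plateau
            i = j + 1
        else:
            i += 1
    return out


def prominence_of(x: np.ndarray, peak: int) -> tuple[float, int, int]:
    """Topographic prominence and base indices of a local maximum.

    Walk outward from the peak until a strictly higher sample (or the
    signal edge); the base on each side is the minimum over that stretch;
    prominence is peak height minus the higher of the two bases.
    """
    h = x[peak]
    # left
    i = peak
    left_min, left_base = h, peak
    while i > 0 and x[i - 1] <= h:
        i -= 1
        if x[i] < left_min:
            left_min, left_base = x[i], i
    # right
    i = peak
    right_min, right_base = h, peak
    while i < len(x) - 1 and x[i + 1] <= h:
        i += 1
        if x[i] < right_min:
            right_min, right_base = x[i], i
    return h - max(left_min, right_min), left_base, right_base


def width_at_half_prominence(
    x: np.ndarray, peak: int, prominence: float, left_base: int, right_base: int
) -> float:
    """Linearly interpolated peak width at half prominence."""
    ref = x[peak] - prominence / 2.0
    i = peak
    while i > left_base and x[i] > ref:
        i -= 1
    left_ip = float(i)
    if x[i] < ref:
        left_ip += (ref - x[i]) / (x[i + 1] - x[i])
    i = peak
    while i < right_base and x[i] > ref:
        i += 1
    right_ip = float(i)
    if x[i] < ref:
        right_ip -= (ref - x[i]) / (x[i - 1] - x[i])
    return right_ip - left_ip


def oracle_peaks(
    x: np.ndarray, min_prominence: float, min_width: float
) -> list[int]:
    """Exhaustive peak detection with prominence and width criteria."""
    out = []
    for p in local_maxima(np.asarray(x, dtype=float)):
        prom, lb, rb = prominence_of(x, p)
        if prom < min_prominence:
            continue
        if width_at_half_prominence(x, p, prom, lb, rb) < min_width:
            continue
        out.append(p)
    return out


def rank_all(pooled: list[float]) -> list[float]:
    """Midranks computed by explicit sorting (no scipy)."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_kruskal(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H from literal rank arithmetic."""
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    ranks = rank_all(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (sum(r) / len(g)) ** 2
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    # tie correction
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (n_total**3 - n_total)
    return h / denom


def oracle_dunn_raw_p(groups: list[list[float]]) -> dict[tuple[int, int], float]:
    """Raw two-sided Dunn p-values from literal rank arithmetic."""
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    ranks = rank_all(pooled)
    means, start = [], 0
    for g in groups:
        means.append(sum(ranks[start : start + len(g)]) / len(g))
        start += len(g)
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    base = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(base * (1 / len(groups[i]) + 1 / len(groups[j])))
            z = (means[i] - means[j]) / se
            out[(i, j)] = math.erfc(abs(z) / math.sqrt(2))
    return out


def oracle_pooled_t(a: list[float], b: list[float]) -> tuple[float, float]:
    """Closed-form pooled-variance two-sample t and two-sided p."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist  # p only; statistic is closed form

    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def point_in_polygon(point, vertices) -> bool:
    """Even-odd test at one point, boundary inclusive (independent loop)."""
    py, px = point
    n = len(vertices)
    inside = False
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # on-segment check
        cross = (py - r1) * (c2 - c1) - (px - c1) * (r2 - r1)
        if abs(cross) < 1e-9:
            if min(r1, r2) - 1e-9 <= py <= max(r1, r2) + 1e-9 and \
               min(c1, c2) - 1e-9 <= px <= max(c1, c2) + 1e-9:
                return True
        if (r1 > py) != (r2 > py):
            x_int = c1 + (py - r1) * (c2 - c1) / (r2 - r1)
            if px < x_int:
                inside = not inside
    return inside
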