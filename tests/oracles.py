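"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the Voronoi oracle
builds each region by clipping the bounding rectangle against explicit
half-planes, one per competing point; the statistics oracles evaluate the
textbook formulas directly.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-9


def clip_halfplane(poly: np.ndarray, n: np.ndarray, c: float) -> np.ndarray:
    """Sutherland–Hodgman clip of polygon ``poly`` to {x : n·x <= c}."""
    out = []
    m = len(poly)
    for k in range(m):
        a, b = poly[k], poly[(k + 1) % m]
        da, db = np.dot(n, a) - c, np.dot(n, b) - c
        if da <= TOL:
            out.append(a)
        if (da < -TOL and db > TOL) or (da > TOL and db < -TOL):
            t = da / (da - db)
            out.append(a + t * (b - a))
    return np.asarray(out) if out else np.empty((0, 2))


def halfplane_voronoi(points: np.ndarray, lo: float, hi: float):
    """Rectangle-clipped Voronoi regions by half-plane intersection.

    Returns (areas, perimeters, neighbor_sets): for each point, the area and
    perimeter of its clipped region and the set of indices whose bisector
    contributes an edge of positive length.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    rect = np.array([[lo, lo], [hi, lo], [hi, hi], [lo, hi]], dtype=float)
    areas = np.zeros(n)
    perims = np.zeros(n)
    neighbors = [set() for _ in range(n)]
    for i in range(n):
        poly = rect
        for j in range(n):
            if j == i:
                continue
            # closer to i than to j:  (pj - pi) . x <= (|pj|^2 - |pi|^2)/2
            nv = points[j] - points[i]
            c = (np.dot(points[j], points[j]) - np.dot(points[i], points[i])) / 2.0
            poly = clip_halfplane(poly, nv, c)
            if len(poly) == 0:
                break
        if len(poly) < 3:
            continue
        x, y = poly[:, 0], poly[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        areas[i] = 0.5 * abs(np.sum(x * yn - xn * y))
        perims[i] = np.sum(np.hypot(xn - x, yn - y))
        # Attribute each polygon edge to the bisector it lies on.
        for k in range(len(poly)):
            a, b = poly[k], poly[(k + 1) % len(poly)]
            if np.hypot(*(b - a)) <= 1e-9:
                continue
            mid = 0.5 * (a + b)
            di = np.hypot(*(mid - points[i]))
            dj = np.hypot(points[:, 0] - mid[0], points[:, 1] - mid[1])
            dj[i] = np.inf
            jmin = int(np.argmin(np.abs(dj - di)))
            if abs(dj[jmin] - di) < 1e-7:
                neighbors[i].add(jmin)
    return areas, perims, neighbors


def pearson_formula(x, y):
    """Pearson r and two-sided p from the raw defining formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    r = np.sum((x - mx) * (y - my)) / np.sqrt(
        np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)
    )
    t = r * np.sqrt((n - 2) / (1 - r**2))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), n - 2)
    return float(r), float(p)


def icc3k_anova_table(x: np.ndarray) -> float:
    """ICC(3,k) via an explicit ANOVA table built from total sums of squares.

    Independent route: SS_error is obtained by subtraction from the total,
    not from the residual formula used by the implementation.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_total = np.sum((x - grand) ** 2)
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / msr
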