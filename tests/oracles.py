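"""Independent brute-force oracles used only by the test suite.

These deliberately use different algorithms from the package implementations
(parametric segment solves instead of orientation predicates, ray casting
instead of shapely, gift wrapping instead of library hulls, grid search
instead of Newton iterations).
"""

import numpy as np


def proper_segment_intersection(p0, p1, q0, q1) -> bool:
    """Transversal intersection strictly interior to both segments.

    Solves p0 + t*(p1-p0) = q0 + s*(q1-q0); a proper crossing requires a
    non-degenerate solve with 0 < t < 1 and 0 < s < 1.
    """
    d1 = np.asarray(p1, float) - p0
    d2 = np.asarray(q1, float) - q0
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if denom == 0:
        return False
    diff = np.asarray(q0, float) - p0
    t = (diff[0] * d2[1] - diff[1] * d2[0]) / denom
    s = (diff[0] * d1[1] - diff[1] * d1[0]) / denom
    return 0 < t < 1 and 0 < s < 1


def brute_force_crossings(path, features) -> int:
    """All-pairs enumeration of transversal segment intersections."""
    path = np.asarray(path, float)
    count = 0
    for i in range(len(path) - 1):
        for line in features:
            line = np.asarray(line, float)
            for j in range(len(line) - 1):
                if proper_segment_intersection(path[i], path[i + 1], line[j], line[j + 1]):
                    count += 1
    return count


def ray_cast_inside(point, ring) -> bool:
    """Crossing-number point-in-polygon test for a single exterior ring."""
    x, y = point
    inside = False
    n = len(ring)
    j = n - 1
    for i in range(n):
        xi, yi = ring[i]
        xj, yj = ring[j]
        if (yi > y) != (yj > y):
            x_int = xi + (y - yi) / (yj - yi) * (xj - xi)
            if x < x_int:
                inside = not inside
        j = i
    return inside


def gift_wrap_hull(points) -> set:
    """Jarvis-march convex hull; returns the set of hull vertices."""
    pts = [tuple(p) for p in np.asarray(points, float)]
    start = min(pts)
    hull = []
    current = start
    while True:
        hull.append(current)
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            if cross < 0 or (
                cross == 0
                and np.hypot(p[0] - current[0], p[1] - current[1])
                > np.hypot(candidate[0] - current[0], candidate[1] - current[1])
            ):
                candidate = p
        current = candidate
        if current == start:
            break
    return set(hull)


def grid_search_clogit(X, used, grid=None) -> float:
    """Single-covariate conditional-logistic MLE by dense grid search.

    ``X`` is (n_strata, n_alternatives); ``used`` gives the chosen column
    per stratum.
    """
    if grid is None:
        grid = np.arange(-5.0, 5.0, 1e-4)
    X = np.asarray(X, float)
    xu = X[np.arange(X.shape[0]), used]  # (S,)
    eta = X[:, :, None] * grid  # (S, J, G)
    m = eta.max(axis=1)
    lse = m + np.log(np.exp(eta - m[:, None, :]).sum(axis=1))
    ll = (xu[:, None] * grid - lse).sum(axis=0)
    return float(grid[np.argmax(ll)])
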