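"""Independent brute-force oracles for the ordering LP.

Both oracles evaluate the weighted-slack objective in closed form — for a
fixed alpha the optimal slack of each pair is max(0, margin - alpha.diff) —
and search the alpha simplex without any linear programming:

* :func:`vertex_oracle` is exact: the objective is convex piecewise-linear,
  so its minimum over the simplex is attained where three of the defining
  hyperplanes (alpha_j = 0 or alpha.diff = margin) are active together with
  the simplex equality; enumerating every such intersection point covers
  all candidate minimizers.
* :func:`grid_oracle` scans a fixed-step lattice on the simplex; it is an
  upper bound on the true minimum and matches it whenever the optimum is
  attained on the lattice (always the case when a fat zero-slack region
  exists).
"""

import itertools

import numpy as np


def objective(diffs, weights, margin, alpha):
    viol = np.clip(margin - diffs @ alpha, 0.0, None)
    return float(weights @ viol)


def vertex_oracle(diffs, weights, margin):
    """Exact minimum of the weighted slack objective over the alpha simplex."""
    planes = [np.eye(4)[j] for j in range(4)] + list(diffs)
    rhs = [0.0] * 4 + [margin] * len(diffs)
    ones = np.ones(4)
    candidates = [np.eye(4)[j] for j in range(4)]  # simplex corners
    for combo in itertools.combinations(range(len(planes)), 3):
        A = np.vstack([ones] + [planes[k] for k in combo])
        b = np.array([1.0] + [rhs[k] for k in combo])
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        x = np.linalg.solve(A, b)
        if np.all(x >= -1e-9):
            candidates.append(np.clip(x, 0.0, None))
    best = np.inf
    for x in candidates:
        x = x / x.sum()
        best = min(best, objective(diffs, weights, margin, x))
    return best


_GRID_CACHE: dict[float, np.ndarray] = {}


def simplex_grid(step=0.01):
    """All 4-part compositions of 1 with the given step."""
    if step not in _GRID_CACHE:
        m = int(round(1.0 / step))
        pts = [
            (a, b, c, m - a - b - c)
            for a in range(m + 1)
            for b in range(m + 1 - a)
            for c in range(m + 1 - a - b)
        ]
        _GRID_CACHE[step] = np.asarray(pts, dtype=float) * step
    return _GRID_CACHE[step]


def grid_oracle(diffs, weights, margin, step=0.01):
    grid = simplex_grid(step)
    viol = np.clip(margin - grid @ diffs.T, 0.0, None)
    return float((viol * weights).sum(axis=1).min())
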