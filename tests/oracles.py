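"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the rotation oracle
searches axis-angle space directly instead of using the SVD solution,
and the medoid oracle enumerates every candidate.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_min_rmsd(moving: np.ndarray, target: np.ndarray,
                  n_grid: int = 10) -> float:
    """Minimum RMSD over proper rotations by dense rotation-vector grid
    search followed by local Nelder-Mead refinement."""
    a = moving - moving.mean(axis=0)
    b = target - target.mean(axis=0)
    n = len(a)

    def rmsd_of(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((a @ R.T - b) ** 2).sum() / n)

    lin = np.linspace(-np.pi, np.pi, n_grid)
    best_val, best_rv = np.inf, np.zeros(3)
    for x in lin:
        for y in lin:
            for z in lin:
                rv = np.array([x, y, z])
                if np.linalg.norm(rv) > np.pi:
                    continue
                v = rmsd_of(rv)
                if v < best_val:
                    best_val, best_rv = v, rv
    res = minimize(rmsd_of, best_rv, method="Nelder-Mead",
                   options=dict(xatol=1e-12, fatol=1e-14, maxiter=5000))
    return float(min(best_val, res.fun))


def exhaustive_medoid(points: np.ndarray, members: np.ndarray,
                      dist) -> int:
    """Best medoid of a member set by full enumeration (lowest index on
    ties)."""
    costs = np.array([sum(dist(points[m], points[x]) for m in members)
                      for x in members])
    return int(members[np.argmin(costs)])


def brute_top_fraction(pi: np.ndarray, fraction: float) -> np.ndarray:
    """Reference implementation of the top-occupancy selection by explicit
    stable sort over (occupancy descending, index ascending)."""
    import math

    nonzero = int(np.count_nonzero(pi))
    k = math.ceil(fraction * nonzero)
    ranked = sorted(range(len(pi)), key=lambda i: (-pi[i], i))
    return np.array(ranked[:k])
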