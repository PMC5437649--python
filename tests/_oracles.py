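"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the superposition
oracle searches rotation space numerically instead of solving it by SVD.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_search_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over proper rotations + translations, by numeric search.

    Coarse Euler-angle grid followed by Nelder-Mead refinement from the best
    starting points. Independent of any closed-form superposition.
    """
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def rmsd_at(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return float(np.sqrt(np.mean(np.sum((m @ rot.T - r) ** 2, axis=1))))

    grid = np.linspace(-np.pi, np.pi, 13)[:-1]
    starts = []
    for a in grid[::2]:
        for b in grid[::2]:
            for c in grid[::2]:
                starts.append(((a, b, c), rmsd_at((a, b, c))))
    starts.sort(key=lambda t: t[1])
    best = np.inf
    for angles, _ in starts[:6]:
        res = minimize(
            rmsd_at,
            angles,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
        )
        best = min(best, float(res.fun))
    return best


def brute_force_paired_mean(frames_a: np.ndarray, frames_b: np.ndarray) -> np.ndarray:
    """Direct arithmetic for the mean index-paired distance per frame."""
    out = []
    for fa, fb in zip(frames_a, frames_b):
        out.append(np.mean([np.linalg.norm(a - b) for a, b in zip(fa, fb)]))
    return np.asarray(out)
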