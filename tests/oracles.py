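"""Independent brute-force oracles used by the fragility tests.

These deliberately avoid the closed-form solution path (no resolvent solve):
the direction-search oracle only evaluates determinants, and the feasibility
sampler only evaluates eigenvalues of explicitly perturbed matrices.
"""

from __future__ import annotations

import numpy as np


def row_energy_direction_search(
    A: np.ndarray,
    row: int,
    target_re: float,
    n_directions: int = 4000,
    n_refine: int = 8,
    seed: int = 0,
) -> float:
    """Minimum Euclidean norm of a row-``row`` (1-based) perturbation making
    ``target_re`` an eigenvalue, by random search over unit directions.

    For a fixed direction ``d`` the singularity condition
    ``det(A + t e_r d^T - target I) = 0`` is affine in ``t`` (rank-one
    update), so the root follows from two determinant evaluations; the outer
    problem minimizes ``|t|`` over directions with multiplicative refinement
    around the incumbent.
    """
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    M = A - target_re * np.eye(n)
    e = np.zeros(n)
    e[row - 1] = 1.0

    def energy(d: np.ndarray) -> float:
        P = np.outer(e, d)
        g0 = np.linalg.det(M)
        g1 = np.linalg.det(M + P)
        slope = g1 - g0
        if slope == 0.0:
            return np.inf
        t = -g0 / slope
        return abs(t)

    best_d, best = None, np.inf
    for _ in range(n_directions):
        d = rng.normal(size=n)
        d /= np.linalg.norm(d)
        val = energy(d)
        if val < best:
            best, best_d = val, d
    spread = 0.5
    for _ in range(n_refine):
        for _ in range(400):
            d = best_d + spread * rng.normal(size=n)
            d /= np.linalg.norm(d)
            val = energy(d)
            if val < best:
                best, best_d = val, d
        spread *= 0.5
    return best


def feasible_row_perturbations(
    A: np.ndarray,
    row: int,
    target_re: float,
    n_samples: int = 300,
    seed: int = 0,
) -> list[float]:
    """Norms of randomly sampled row perturbations that push the leading
    eigenvalue's real part to at least ``target_re``.

    Each random direction is scaled up until feasible (eigenvalue check
    only), then shrunk by bisection to sit just at the crossing; the returned
    norms are upper bounds on the true minimum energy.
    """
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    out: list[float] = []

    def lead(delta_row: np.ndarray) -> float:
        P = A.copy()
        P[row - 1] += delta_row
        return float(np.max(np.linalg.eigvals(P).real))

    for _ in range(n_samples):
        d = rng.normal(size=n)
        d /= np.linalg.norm(d)
        scale = 1e-3
        feasible = None
        for _ in range(40):
            if lead(scale * d) >= target_re:
                feasible = scale
                break
            scale *= 1.6
        if feasible is None:
            continue
        lo, hi = 0.0, feasible
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if lead(mid * d) >= target_re:
                hi = mid
            else:
                lo = mid
        out.append(hi)
    return out


def random_stable_matrix(
    n: int, seed: int, margin_lo: float = 0.05, margin_hi: float = 0.5
) -> np.ndarray:
    """A random matrix shifted to have its leading eigenvalue real part in
    ``[-margin_hi, -margin_lo]``."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n))
    shift = float(np.max(np.linalg.eigvals(A).real))
    margin = rng.uniform(margin_lo, margin_hi)
    return A - (shift + margin) * np.eye(n)
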