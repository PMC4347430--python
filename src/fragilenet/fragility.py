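"""Fixed point, linearization and minimum-energy destabilizing perturbations.

The mean-field activation probabilities ``r`` obey

    dr_i/dt = g_i(r) = -alpha * r_i + f(sbar_i) * (1 - r_i),
    sbar_i  = sum_j w_ij r_j + u_i.

``solve_fixed_point`` finds ``r*`` with ``g(r*) = 0``; ``linearize`` returns
the Jacobian ``A`` (functional connectivity) whose leading eigenvalue's real
part decides stability; ``input_matrix`` is the diagonal sensitivity of the
dynamics to the external input.  ``min_row_perturbation`` computes, in closed
form, the minimum-Euclidean-norm single-row perturbation ``Delta`` placing a
prescribed real part on the spectrum of ``A + Delta``, and
``fragility_ranking`` ranks nodes by that energy (the most fragile node is the
cheapest to destabilize).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import least_squares

from .network import (
    NetworkConfig,
    response_function,
    response_slope,
)

__all__ = [
    "FixedPoint",
    "FunctionalConnectivity",
    "InputMatrix",
    "PerturbationMatrix",
    "FragilityReport",
    "ModeMatrices",
    "FixedPointError",
    "PerturbationError",
    "FragilityError",
    "rate_field",
    "solve_fixed_point",
    "linearize",
    "input_matrix",
    "min_row_perturbation",
    "fragility_ranking",
    "build_mode_matrices",
    "sorted_eigenvalues",
]


class FixedPointError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, r_last: NDArray, residual_norm: float):
        super().__init__(message)
        self.r_last = r_last
        self.residual_norm = residual_norm


class PerturbationError(RuntimeError):
    """Perturbation construction failed verification; carries the achieved value."""

    def __init__(self, message: str, achieved_re: float | None = None):
        super().__init__(message)
        self.achieved_re = achieved_re


class FragilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixedPoint:
    """Steady-state activation probabilities and the residual at convergence."""

    r: NDArray[np.float64]
    residual_norm: float


@dataclass(frozen=True)
class FunctionalConnectivity:
    """Jacobian ``A`` of the mean-field dynamics at the fixed point, with its
    eigenvalues sorted by descending real part (ties: descending imaginary
    part, then original index)."""

    A: NDArray[np.float64]
    eigenvalues: NDArray[np.complex128]

    @property
    def lambda1_re(self) -> float:
        return float(self.eigenvalues[0].real)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class InputMatrix:
    """Diagonal sensitivity ``B`` of the mean-field dynamics to the input u."""

    B: NDArray[np.float64]

    @property
    def diag(self) -> NDArray[np.float64]:
        return np.diag(self.B)


@dataclass(frozen=True)
class PerturbationMatrix:
    """Single-row perturbation ``Delta`` (row ``row_index``, 1-based) with its
    Euclidean energy and the eigenvalue real-part target it was built for."""

    delta: NDArray[np.float64]
    row_index: int
    energy: float
    target_re: float

    @property
    def row(self) -> NDArray[np.float64]:
        return self.delta[self.row_index - 1]


@dataclass(frozen=True)
class FragilityReport:
    """Per-node destabilization energies; ``fragile_node`` is 1-based."""

    energies: NDArray[np.float64]
    fragile_node: int
    perturbations: list[PerturbationMatrix | None]
    target_re: float


def sorted_eigenvalues(A: NDArray) -> NDArray[np.complex128]:
    """Eigenvalues sorted by descending real part, then descending imaginary
    part, then index — a deterministic ordering."""
    lam = np.linalg.eigvals(np.asarray(A, dtype=float))
    order = np.lexsort((np.arange(lam.size), -lam.imag, -lam.real))
    return lam[order]


def rate_field(r: NDArray, cfg: NetworkConfig, u: NDArray) -> NDArray[np.float64]:
    """The mean-field vector field g(r)."""
    sbar = cfg.weights @ r + u
    return -cfg.alpha * r + response_function(sbar, cfg.f_params) * (1.0 - r)


def _jacobian(r: NDArray, cfg: NetworkConfig, u: NDArray) -> NDArray[np.float64]:
    sbar = cfg.weights @ r + u
    beta = response_slope(sbar, cfg.f_params) * (1.0 - r)
    return beta[:, None] * cfg.weights + np.diag(
        -cfg.alpha - response_function(sbar, cfg.f_params)
    )


def solve_fixed_point(
    cfg: NetworkConfig,
    u: NDArray | None = None,
    r0: NDArray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> FixedPoint:
    """Solve ``g(r) = 0`` for the steady-state activation probabilities.

    Minimizes ``||g(r)||^2`` over the box [0, 1]^N (trust-region least
    squares with the analytic Jacobian, followed by a damped-Newton polish),
    trying several starting points.  Raises :class:`FixedPointError` with the
    last iterate if the residual cannot be driven below ``tol``.
    """
    u = cfg.h if u is None else np.asarray(u, dtype=float)
    n = cfg.n_nodes
    starts = []
    if r0 is not None:
        starts.append(np.clip(np.asarray(r0, dtype=float), 0.0, 1.0))
    starts += [np.full(n, 0.5), np.full(n, 0.05), np.full(n, 0.95), np.zeros(n)]

    def _polish(r: NDArray) -> NDArray:
        """Damped Newton on g(r) = 0 with projection onto the box."""
        for _ in range(60):
            g = rate_field(r, cfg, u)
            norm = float(np.linalg.norm(g))
            if norm <= tol:
                break
            try:
                step = np.linalg.solve(_jacobian(r, cfg, u), -g)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            improved = False
            for _ in range(30):
                r_new = np.clip(r + lam * step, 0.0, 1.0)
                if np.linalg.norm(rate_field(r_new, cfg, u)) < norm:
                    r = r_new
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                break
        return r

    best_r, best_norm = None, np.inf
    for start in starts:
        # cheap path: Newton straight from the start often suffices
        r = _polish(start.copy())
        norm = float(np.linalg.norm(rate_field(r, cfg, u)))
        if norm <= tol:
            return FixedPoint(r=r, residual_norm=norm)
        res = least_squares(
            rate_field,
            start,
            jac=_jacobian,
            args=(cfg, u),
            bounds=(0.0, 1.0),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=max_iter,
        )
        # least_squares stops near machine precision of the *cost*; the
        # contract is on ||g|| itself, so polish with damped Newton
        r = _polish(res.x)
        norm = float(np.linalg.norm(rate_field(r, cfg, u)))
        if norm < best_norm:
            best_r, best_norm = r, norm
        if norm <= tol:
            return FixedPoint(r=r, residual_norm=norm)
    raise FixedPointError(
        f"fixed point did not converge: ||g|| = {best_norm:.3e} > tol = {tol:.1e}",
        r_last=best_r,
        residual_norm=best_norm,
    )


def linearize(
    cfg: NetworkConfig, fp: FixedPoint, u: NDArray | None = None
) -> FunctionalConnectivity:
    """Functional connectivity: the Jacobian of g at the fixed point."""
    u = cfg.h if u is None else np.asarray(u, dtype=float)
    A = _jacobian(fp.r, cfg, u)
    return FunctionalConnectivity(A=A, eigenvalues=sorted_eigenvalues(A))


def input_matrix(
    cfg: NetworkConfig, fp: FixedPoint, u: NDArray | None = None
) -> InputMatrix:
    """Diagonal input sensitivity ``B_ii = f'(sbar_i) * (1 - r_i)``."""
    u = cfg.h if u is None else np.asarray(u, dtype=float)
    sbar = cfg.weights @ fp.r + u
    beta = response_slope(sbar, cfg.f_params) * (1.0 - fp.r)
    return InputMatrix(B=np.diag(beta))


def min_row_perturbation(
    fc: FunctionalConnectivity | NDArray,
    row: int,
    target_re: float,
    verify_tol: float = 1e-6,
) -> PerturbationMatrix:
    """Minimum-norm single-row perturbation placing ``target_re`` on the
    spectrum.

    With ``M = A - target_re * I`` invertible and ``c = M^-1 e_row``, the
    rank-one singularity condition ``det(M + e_row delta^T) = 0`` reduces to
    ``delta^T c = -1``; its minimum-Euclidean-norm solution is
    ``delta = -c / ||c||^2`` with energy ``1 / ||c||``.  ``row`` is 1-based.

    The construction is verified with an eigen-decomposition:
    ``|Re lambda_1(A + Delta) - target_re| <= verify_tol`` or
    :class:`PerturbationError` is raised with the achieved value.  If ``M`` is
    singular the target is already an eigenvalue and ``Delta = 0`` is
    returned.
    """
    A = fc.A if isinstance(fc, FunctionalConnectivity) else np.asarray(fc, dtype=float)
    n = A.shape[0]
    if not 1 <= row <= n:
        raise ValueError(f"row must be in 1..{n}, got {row}")
    M = A - target_re * np.eye(n)
    e = np.zeros(n)
    e[row - 1] = 1.0
    # singular M <=> target already an eigenvalue
    if np.linalg.matrix_rank(M) < n:
        return PerturbationMatrix(
            delta=np.zeros((n, n)), row_index=row, energy=0.0, target_re=target_re
        )
    c = np.linalg.solve(M, e)
    delta_row = -c / float(c @ c)
    delta = np.zeros((n, n))
    delta[row - 1] = delta_row
    achieved = float(sorted_eigenvalues(A + delta)[0].real)
    if abs(achieved - target_re) > verify_tol:
        raise PerturbationError(
            f"row {row}: achieved Re lambda_1 = {achieved:.6g}, "
            f"target {target_re:.6g}",
            achieved_re=achieved,
        )
    return PerturbationMatrix(
        delta=delta,
        row_index=row,
        energy=float(np.linalg.norm(delta_row)),
        target_re=target_re,
    )


def fragility_ranking(
    fc: FunctionalConnectivity | NDArray, target_re: float
) -> FragilityReport:
    """Destabilization energy of every row; the fragile node is the argmin
    (ties broken by the lowest index).  Rows whose perturbation fails
    verification are assigned infinite energy."""
    A = fc.A if isinstance(fc, FunctionalConnectivity) else np.asarray(fc, dtype=float)
    n = A.shape[0]
    energies = np.full(n, np.inf)
    perturbations: list[PerturbationMatrix | None] = [None] * n
    for row in range(1, n + 1):
        try:
            pert = min_row_perturbation(A, row, target_re)
        except PerturbationError:
            continue
        energies[row - 1] = pert.energy
        perturbations[row - 1] = pert
    if not np.any(np.isfinite(energies)):
        raise FragilityError("no row admits a verified destabilizing perturbation")
    fragile = int(np.argmin(energies)) + 1  # argmin takes the lowest index on ties
    return FragilityReport(
        energies=energies,
        fragile_node=fragile,
        perturbations=perturbations,
        target_re=target_re,
    )


@dataclass(frozen=True)
class ModeVariant:
    """One unstable operating mode: the perturbed structural matrix and
    diagnostics of the perturbation that produced it."""

    target_re: float
    W: NDArray[np.float64]
    perturbation: PerturbationMatrix
    lambda1_functional: float
    lambda1_relinearized: float | None


@dataclass(frozen=True)
class ModeMatrices:
    """Stable structural matrix plus its destabilized variants.

    The perturbation is computed in functional space (eigenvalue targets on
    ``A``) and added directly to the structural matrix, so the functional
    shift of the re-linearized perturbed system is approximate;
    ``lambda1_relinearized`` records it (None when the perturbed fixed point
    does not converge), while ``lambda1_functional`` is exact on ``A + Delta``.
    """

    cfg: NetworkConfig
    u: NDArray[np.float64]
    fixed_point: FixedPoint
    functional: FunctionalConnectivity
    input_mat: InputMatrix
    report: FragilityReport
    fragile_node: int
    variants: dict[float, ModeVariant] = field(default_factory=dict)

    @property
    def W_s(self) -> NDArray[np.float64]:
        return self.cfg.weights

    def unstable_config(self, target_re: float) -> NetworkConfig:
        return self.cfg.with_weights(self.variants[target_re].W)


def build_mode_matrices(
    cfg: NetworkConfig,
    u: NDArray | None = None,
    targets: tuple[float, ...] = (0.0, 200.0),
    ranking_target: float = 0.0,
    fragile_node: int | None = None,
) -> ModeMatrices:
    """Assemble the stable matrix and its single-row destabilized variants.

    The fragile node is selected by :func:`fragility_ranking` at
    ``ranking_target`` (marginal stability by default) unless given
    explicitly; each entry of ``targets`` then yields a perturbed structural
    matrix ``W_s + Delta(target)`` on that node's row.
    """
    u_vec = cfg.h if u is None else np.asarray(u, dtype=float)
    fp = solve_fixed_point(cfg, u_vec)
    fc = linearize(cfg, fp, u_vec)
    B = input_matrix(cfg, fp, u_vec)
    report = fragility_ranking(fc, ranking_target)
    node = report.fragile_node if fragile_node is None else fragile_node

    variants: dict[float, ModeVariant] = {}
    for target in targets:
        pert = min_row_perturbation(fc, node, target)
        W_u = cfg.weights + pert.delta
        lam_fun = float(sorted_eigenvalues(fc.A + pert.delta)[0].real)
        lam_relin: float | None
        try:
            fp_u = solve_fixed_point(cfg.with_weights(W_u), u_vec)
            lam_relin = linearize(cfg.with_weights(W_u), fp_u, u_vec).lambda1_re
        except FixedPointError:
            lam_relin = None
        variants[target] = ModeVariant(
            target_re=target,
            W=W_u,
            perturbation=pert,
            lambda1_functional=lam_fun,
            lambda1_relinearized=lam_relin,
        )
    return ModeMatrices(
        cfg=cfg,
        u=u_vec,
        fixed_point=fp,
        functional=fc,
        input_mat=B,
        report=report,
        fragile_node=node,
        variants=variants,
    )
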