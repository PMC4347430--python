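"""Synthetic fragile-network fixtures.

Produces small directed networks (default: 6 single-neuron nodes, 14
connections, 2 inhibitory nodes) that are stable at their fixed point but
sit close to the stability boundary, with an inhibitory node as the most
fragile.  Destabilizing that node's inbound row silences it and disinhibits
the rest of the network — the seizure mechanism the closed loop is built
around.

Construction works backwards from the operating point: target activation
probabilities are drawn first and the background input ``h`` is solved from
the equilibrium condition, so the fixed point is known in closed form and
every node fires at a healthy baseline by design.  A global weight scale is
then bisected — with ``h`` re-derived at each trial so the fixed point never
moves — until the leading Jacobian eigenvalue sits in a narrow band just
below zero.  Candidates are rejected until the most fragile node is
inhibitory and (optionally) simulation confirms the disinhibition signature.
Accepted fixtures are relabeled so the fragile node is node 4 and are
reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .fragility import (
    FixedPointError,
    FragilityError,
    ModeMatrices,
    PerturbationError,
    build_mode_matrices,
    linearize,
    solve_fixed_point,
)
from .network import NetworkConfig, ResponseFunctionParams, gillespie_simulate

__all__ = [
    "GeneratorSpec",
    "GeneratedNetwork",
    "GenerationError",
    "generate_network",
    "default_network",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs of the fixture generator.

    The response gain is steeper than the simulator default so that the
    operating point has appreciable input sensitivity (``f'(sbar)(1 - r)``):
    that is what lets a single-row structural perturbation move the fragile
    node's rate far enough to be detectable.  ``r_range`` bounds the target
    activation probabilities from which ``h`` is derived; it must stay below
    ``f_max / (alpha + f_max)`` for the equilibrium condition to be solvable.
    """

    n_nodes: int = 6
    n_connections: int = 14
    n_inhibitory: int = 2
    weight_range: tuple[float, float] = (0.5, 1.5)
    r_range: tuple[float, float] = (0.15, 0.45)
    alpha: float = 0.1
    f_params: ResponseFunctionParams = field(
        default_factory=lambda: ResponseFunctionParams(f_max=0.1, gain=16.0, threshold=0.3)
    )
    allow_self_loops: bool = False
    lambda1_band: tuple[float, float] = (-0.05, -0.005)
    min_b_fragile: float = 0.05
    targets: tuple[float, ...] = (0.0, 200.0)
    fragile_position: int = 4
    behavioral_check: bool = True
    check_duration: float = 12_000.0
    min_separation_sd: float = 3.0
    max_rejections: int = 2000

    def __post_init__(self) -> None:
        n = self.n_nodes
        max_e = n * (n - 1) + (n if self.allow_self_loops else 0)
        if not 0 <= self.n_connections <= max_e:
            raise ValueError(f"n_connections must be in [0, {max_e}]")
        if not 1 <= self.n_inhibitory < n:
            raise ValueError("need 1 <= n_inhibitory < n_nodes")
        if not 1 <= self.fragile_position <= n:
            raise ValueError("fragile_position out of range")
        r_cap = self.f_params.f_max / (self.alpha + self.f_params.f_max)
        if not (0 < self.r_range[0] <= self.r_range[1] < r_cap):
            raise ValueError(f"r_range must lie inside (0, {r_cap:.3f})")


@dataclass(frozen=True)
class GeneratedNetwork:
    cfg: NetworkConfig
    modes: ModeMatrices
    inhibitory_nodes: tuple[int, ...]  # 1-based
    seed: int
    n_rejections: int


def _draw_candidate(spec: GeneratorSpec, rng: np.random.Generator):
    n = spec.n_nodes
    pairs = [
        (i, j) for i in range(n) for j in range(n) if spec.allow_self_loops or i != j
    ]
    idx = rng.choice(len(pairs), size=spec.n_connections, replace=False)
    inhibitory = np.sort(rng.choice(n, size=spec.n_inhibitory, replace=False))
    W = np.zeros((n, n))
    lo, hi = spec.weight_range
    for p in idx:
        i, j = pairs[p]
        mag = rng.uniform(lo, hi)
        W[i, j] = -mag if j in inhibitory else mag
    r_target = rng.uniform(*spec.r_range, size=n)
    return W, r_target, inhibitory


def _h_for(W: NDArray, r: NDArray, spec: GeneratorSpec) -> NDArray:
    """Background input making ``r`` an exact fixed point of the dynamics.

    Equilibrium requires ``f(sbar_i) = alpha r_i / (1 - r_i)``; inverting the
    clamped tanh on its active branch gives ``sbar`` and then
    ``h = sbar - W r``.
    """
    fp = spec.f_params
    y = spec.alpha * r / (1.0 - r)
    sbar = fp.threshold + np.arctanh(y / fp.f_max) / fp.gain
    return sbar - W @ r


def _lambda1_at_scale(
    W0: NDArray, r: NDArray, scale: float, spec: GeneratorSpec
) -> float:
    W = scale * W0
    cfg = NetworkConfig(
        weights=W, h=_h_for(W, r, spec), alpha=spec.alpha, f_params=spec.f_params
    )
    fp = solve_fixed_point(cfg, r0=r, tol=1e-11)
    return linearize(cfg, fp).lambda1_re


def _rescale_to_band(
    W0: NDArray, r: NDArray, spec: GeneratorSpec
) -> tuple[NDArray, NDArray] | None:
    """Bisect a global weight scale until lambda_1 sits in the marginal band.

    ``h`` is re-derived at every trial scale, pinning the fixed point, so
    lambda_1 varies continuously (its off-diagonal part is linear in the
    scale) and the bisection is reliable."""
    lo_band, hi_band = spec.lambda1_band
    lo, hi = 0.0, None
    s = 1.0
    for _ in range(30):
        lam = _lambda1_at_scale(W0, r, s, spec)
        if lo_band <= lam <= hi_band:
            W = s * W0
            return W, _h_for(W, r, spec)
        if lam > hi_band:
            hi = s
            break
        lo = s
        s *= 1.7
    if hi is None:
        return None
    for _ in range(100):
        s = 0.5 * (lo + hi)
        lam = _lambda1_at_scale(W0, r, s, spec)
        if lam > hi_band:
            hi = s
        elif lam < lo_band:
            lo = s
        else:
            W = s * W0
            return W, _h_for(W, r, spec)
    return None


def _behavioral_ok(
    modes: ModeMatrices, spec: GeneratorSpec, rng: np.random.Generator
) -> bool:
    """Disinhibition check on the largest destabilized variant.

    The fragile node's windowed firing rate (250 ms windows) must drop by at
    least ``min_separation_sd`` stable-mode standard deviations — the
    separation the downstream likelihood-ratio detector lives on — while the
    network-wide rate increases."""
    node0 = modes.fragile_node - 1
    T = spec.check_duration
    stable = gillespie_simulate(modes.cfg, T, rng=rng, record_states=False)
    unstable = gillespie_simulate(
        modes.unstable_config(max(modes.variants)), T, rng=rng, record_states=False
    )
    win, step = 250.0, 50.0
    times = np.arange(win, T, step)

    def _window_counts(sp):
        hi = np.searchsorted(sp, times, side="right")
        lo = np.searchsorted(sp, times - win, side="right")
        return hi - lo

    v_s = _window_counts(stable.spike_times[node0])
    v_u = _window_counts(unstable.spike_times[node0])
    mu_s, sd_s = float(np.mean(v_s)), float(np.std(v_s))
    if mu_s <= 0 or sd_s <= 0:
        return False
    net_s = sum(len(sp) for sp in stable.spike_times)
    net_u = sum(len(sp) for sp in unstable.spike_times)
    sep = (mu_s - float(np.mean(v_u))) / sd_s
    return sep >= spec.min_separation_sd and net_u > net_s


def generate_network(spec: GeneratorSpec, seed: int) -> GeneratedNetwork:
    """Rejection-sample a fixture satisfying the spec.

    Acceptance requires: the leading Jacobian eigenvalue inside the marginal
    band below zero at a healthy fixed point, the most fragile node (lowest
    destabilization energy at the marginal target) inhibitory with finite
    energy and real input authority, and — when ``behavioral_check`` is on —
    simulated disinhibition under the strongest destabilized variant.  The
    accepted network is relabeled so the fragile node sits at
    ``fragile_position``.
    """
    rng = np.random.default_rng(seed)
    failures: dict[str, int] = {}

    def _fail(reason: str) -> None:
        failures[reason] = failures.get(reason, 0) + 1

    for attempt in range(spec.max_rejections):
        W0, r_target, inhibitory = _draw_candidate(spec, rng)
        try:
            scaled = _rescale_to_band(W0, r_target, spec)
        except FixedPointError:
            scaled = None
        if scaled is None:
            _fail("rescale")
            continue
        W, h = scaled
        cfg = NetworkConfig(weights=W, h=h, alpha=spec.alpha, f_params=spec.f_params)
        try:
            modes = build_mode_matrices(cfg, targets=spec.targets)
        except (FixedPointError, FragilityError, PerturbationError):
            _fail("fragility")
            continue
        f_idx = modes.fragile_node - 1
        if f_idx not in inhibitory:
            _fail("fragile_not_inhibitory")
            continue
        if not np.isfinite(modes.report.energies[f_idx]):
            _fail("infinite_energy")
            continue
        if modes.input_mat.diag[f_idx] < spec.min_b_fragile:
            _fail("no_input_authority")
            continue
        if spec.behavioral_check and not _behavioral_ok(modes, spec, rng):
            _fail("behavior")
            continue

        # relabel so the fragile node lands at the designated position
        perm = np.arange(spec.n_nodes)
        b = spec.fragile_position - 1
        perm[f_idx], perm[b] = perm[b], perm[f_idx]
        cfg_p = NetworkConfig(
            weights=W[np.ix_(perm, perm)],
            h=h[perm],
            alpha=spec.alpha,
            f_params=spec.f_params,
        )
        modes_p = build_mode_matrices(cfg_p, targets=spec.targets)
        if modes_p.fragile_node != spec.fragile_position:
            _fail("relabel")
            continue
        inv = np.argsort(perm)
        inhib_p = tuple(sorted(int(inv[i]) + 1 for i in inhibitory))
        return GeneratedNetwork(
            cfg=cfg_p,
            modes=modes_p,
            inhibitory_nodes=inhib_p,
            seed=seed,
            n_rejections=attempt,
        )
    raise GenerationError(
        f"no acceptable network within {spec.max_rejections} attempts; "
        f"rejection causes: {failures}"
    )


def default_network(seed: int = 1, **overrides) -> GeneratedNetwork:
    """The default 6-node / 14-connection fixture used across tests and the
    acceptance report."""
    return generate_network(GeneratorSpec(**overrides), seed)
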