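"""Closed-loop orchestration: mode switching, detection, control, metrics.

The simulated network starts in the stable mode and transitions to the
unstable mode (structural matrix ``W_s + Delta``) with probability ``rho`` per
grid step.  The detector watches the fragile node's firing rate; when the
derivative of the cumulative likelihood ratio crosses the calibrated
threshold, the switch signal sigma is set to 1 and the state-feedback gain is
applied.  When the rate has sat inside the stable band for the hold period,
sigma returns to 0, ``W_s`` is restored, the mode belief is reset, and a
refractory gap (one detector fill) passes before a new onset may be
scheduled.  Episode metrics mirror the benchmark protocol: detection delay
(onset to unstable detection), stable-mode delay (unstable detection to
stable detection) and the time for the rate to first re-enter the stable band
(from unstable detection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .control import GainMatrix, linear_gain, nonlinear_gain
from .detector import (
    DetectorParams,
    EmissionModel,
    OnlineDetector,
    calibrate_max_count,
    calibrate_threshold,
    fit_emissions,
    firing_rate_series,
)
from .fragility import ModeMatrices
from .network import gillespie_simulate, response_function

__all__ = [
    "CalibratedDetector",
    "EpisodeMetrics",
    "ClosedLoopResult",
    "ExperimentReport",
    "ClosedLoopSimulator",
    "calibrate_detector",
    "run_episode",
    "run_benchmark",
]

Variant = Literal["linear", "nonlinear"]


@dataclass(frozen=True)
class CalibratedDetector:
    """Detector parameters with calibration filled in, plus the fitted
    emission model and the watched (fragile) node, 1-based."""

    params: DetectorParams
    emissions: EmissionModel
    node: int
    meta: dict = field(default_factory=dict)


def calibrate_detector(
    modes: ModeMatrices,
    params: DetectorParams,
    seed: int,
    duration: float = 100_000.0,
    threshold_duration: float = 60_000.0,
    emission_target: float | None = None,
) -> CalibratedDetector:
    """Full calibration pipeline on a set of mode matrices.

    Independent seeds (spawned from ``seed``) drive four simulations: a
    stable run for the max window count, a stable run for q1, an unstable run
    for q2, and one unstable run per variant for the threshold.  ``q2`` is
    fitted from the largest-target variant by default — the strongly
    destabilized mode whose behavioral signature (a depressed fragile-node
    rate) defines the unstable emission density.
    """
    ss = np.random.SeedSequence(seed)
    n_unstable = len(modes.variants)
    children = ss.spawn(3 + n_unstable)
    node = modes.fragile_node
    cfg = modes.cfg

    max_count = calibrate_max_count(
        cfg, params, node, duration=duration, rng=np.random.default_rng(children[0])
    )
    params_mc = replace(params, max_count=max_count)

    stable_trace = gillespie_simulate(
        cfg, duration, rng=np.random.default_rng(children[1]), record_states=False
    )
    stable_rates = firing_rate_series(
        stable_trace.spike_times, node, params_mc, duration
    ).p

    if emission_target is None:
        emission_target = max(modes.variants)
    unstable_trace = gillespie_simulate(
        modes.unstable_config(emission_target),
        duration,
        rng=np.random.default_rng(children[2]),
        record_states=False,
    )
    unstable_rates = firing_rate_series(
        unstable_trace.spike_times, node, params_mc, duration
    ).p
    # floor at the one-spike resolution of the averaged estimator so a fully
    # silenced fragile node still yields a proper (narrow) unstable density
    var_floor = (1.0 / max_count) ** 2
    em = fit_emissions(stable_rates, unstable_rates, var_floor=var_floor)

    targets = sorted(modes.variants)
    threshold = calibrate_threshold(
        [modes.unstable_config(t) for t in targets],
        em,
        params_mc,
        node,
        duration=threshold_duration,
        rng=np.random.default_rng(children[3]),
    )
    params_full = replace(params_mc, threshold=threshold)
    return CalibratedDetector(
        params=params_full,
        emissions=em,
        node=node,
        meta={
            "seed": seed,
            "duration_ms": duration,
            "threshold_duration_ms": threshold_duration,
            "emission_target": emission_target,
            "max_count": max_count,
            "threshold": threshold,
        },
    )


@dataclass
class EpisodeMetrics:
    """Timing metrics of one seizure episode (all times in ms).

    ``detection_delay`` is onset -> unstable detection; ``stable_mode_delay``
    and ``first_stable_fr_time`` are measured from the unstable detection.
    ``resolved`` is False when the episode hit the wall-time horizon before a
    stable detection; ``true_positive`` is False for detections with no onset
    since the last stable period.
    """

    index: int
    controller_variant: str
    target_re: float | None
    onset_time: float | None
    unstable_detection_time: float | None
    detection_delay: float | None
    stable_detection_time: float | None
    stable_mode_delay: float | None
    first_stable_fr_time: float | None
    resolved: bool
    true_positive: bool


@dataclass
class ClosedLoopResult:
    episodes: list[EpisodeMetrics]
    events: list[tuple[float, str]]
    sim_time: float
    n_onsets: int
    n_detections: int
    n_false_positives: int
    trace: dict[str, NDArray] | None = None

    @property
    def resolved_episodes(self) -> list[EpisodeMetrics]:
        return [e for e in self.episodes if e.resolved]


class ClosedLoopSimulator:
    """Event-driven simulation of the full feedback loop of one network.

    ``episode_targets`` selects which destabilized variant each successive
    onset uses (cycled; default: all variants of ``modes`` in ascending
    order, i.e. alternating).  ``apply_control=False`` forces sigma = 0
    forever (open-loop ablation).
    """

    def __init__(
        self,
        modes: ModeMatrices,
        calib: CalibratedDetector,
        variant: Variant = "nonlinear",
        episode_targets: Sequence[float] | None = None,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        horizon: float = 30_000.0,
        apply_control: bool = True,
        record_trace: bool = False,
    ) -> None:
        self.modes = modes
        self.calib = calib
        self.variant = variant
        self.horizon = horizon
        self.apply_control = apply_control
        self.record_trace = record_trace
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.targets = (
            list(episode_targets) if episode_targets is not None else sorted(modes.variants)
        )
        self._gains: dict[float, GainMatrix] = {}
        for t in self.targets:
            pert = modes.variants[t].perturbation
            self._gains[t] = (
                linear_gain(modes.input_mat, pert)
                if variant == "linear"
                else nonlinear_gain(pert)
            )

    def run(
        self,
        max_time: float,
        max_detections: int | None = None,
        max_episodes: int | None = None,
    ) -> ClosedLoopResult:
        modes, calib = self.modes, self.calib
        params = calib.params
        rng = self.rng
        cfg = modes.cfg
        n = cfg.n_nodes
        node0 = calib.node - 1
        alpha = cfg.alpha
        fp = cfg.f_params
        h = cfg.h
        W_s = cfg.weights
        W_u = {t: modes.variants[t].W for t in self.targets}
        dt = params.grid_dt
        rho = params.rho
        threshold = params.threshold
        hold_steps = int(round(params.stable_hold / dt)) + 1

        det = OnlineDetector(params, calib.emissions)
        x = np.zeros(n)
        W = W_s
        K: NDArray | None = None
        sigma = 0
        z = 1
        mode_unstable = False
        target_idx = 0
        cur_target: float | None = None
        onset_time: float | None = None
        udet_time: float | None = None
        first_entry: float | None = None
        band_run = 0
        refractory_until = params.burn_in

        episodes: list[EpisodeMetrics] = []
        events: list[tuple[float, str]] = []
        n_onsets = n_detections = n_fp = 0
        trace: dict[str, list] | None = (
            {"t": [], "p": [], "LR": [], "dgr": [], "z": [], "sigma": []}
            if self.record_trace
            else None
        )

        t = 0.0
        k = 1
        t_grid = dt
        need_rates = True
        next_event = math.inf
        cum = np.empty(n)

        def finalize(resolved: bool, sdet: float | None) -> None:
            nonlocal onset_time, udet_time, first_entry, band_run, cur_target
            nonlocal W, K, sigma, z, mode_unstable, refractory_until
            episodes.append(
                EpisodeMetrics(
                    index=len(episodes),
                    controller_variant=self.variant,
                    target_re=cur_target,
                    onset_time=onset_time,
                    unstable_detection_time=udet_time,
                    detection_delay=(
                        udet_time - onset_time
                        if udet_time is not None and onset_time is not None
                        else None
                    ),
                    stable_detection_time=sdet,
                    stable_mode_delay=(
                        sdet - udet_time
                        if sdet is not None and udet_time is not None
                        else None
                    ),
                    first_stable_fr_time=(
                        first_entry - udet_time
                        if first_entry is not None and udet_time is not None
                        else None
                    ),
                    resolved=resolved,
                    true_positive=onset_time is not None,
                )
            )
            onset_time = udet_time = first_entry = None
            band_run = 0
            cur_target = None
            W = W_s
            K = None
            sigma = 0
            z = 1
            mode_unstable = False
            refractory_until = t + params.burn_in

        while t_grid <= max_time + 1e-9:
            if need_rates:
                u = (K @ x + h) if (sigma and K is not None) else h
                s = W @ x + u
                tr = alpha * x + response_function(s, fp) * (1.0 - x)
                tr_net = float(tr.sum())
                if tr_net > 0.0:
                    next_event = t + rng.exponential(1.0 / tr_net)
                else:
                    next_event = math.inf
                need_rates = False

            if next_event < t_grid:
                t = next_event
                np.cumsum(tr, out=cum)
                i = int(np.searchsorted(cum, rng.random() * tr_net, side="right"))
                if i >= n:
                    i = n - 1
                x[i] = 1.0 - x[i]
                if x[i] == 1.0 and i == node0:
                    det.add_spike(t)
                need_rates = True
                continue

            t = t_grid
            det.update(t)
            if trace is not None and det.ready:
                trace["t"].append(t)
                trace["p"].append(det.p)
                trace["LR"].append(det.LR)
                trace["dgr"].append(det.dgr)
                trace["z"].append(z)
                trace["sigma"].append(sigma)

            if det.ready:
                if z == 1:
                    if det.dgr is not None and det.dgr > threshold:
                        # unstable-mode detection
                        n_detections += 1
                        if onset_time is None:
                            n_fp += 1
                            events.append((t, "false_positive_detection"))
                            if cur_target is None:
                                cur_target = self.targets[
                                    target_idx % len(self.targets)
                                ]
                        else:
                            events.append((t, "unstable_detection"))
                        udet_time = t
                        z = 2
                        if self.apply_control:
                            sigma = 1
                            K = self._gains[cur_target].K
                            need_rates = True
                else:
                    # looking for the return to stability
                    if det.in_stable_band():
                        if first_entry is None and udet_time is not None:
                            first_entry = t
                        band_run += 1
                        if band_run >= hold_steps:
                            events.append((t, "stable_detection"))
                            finalize(True, t)
                            need_rates = True
                    else:
                        band_run = 0
                # horizon guard
                if (
                    z == 2
                    and udet_time is not None
                    and t - udet_time > self.horizon
                ) or (
                    z == 1
                    and onset_time is not None
                    and t - onset_time > self.horizon
                ):
                    events.append((t, "unresolved_reset"))
                    finalize(False, None)
                    need_rates = True

            # schedule a new onset
            if (
                not mode_unstable
                and z == 1
                and t >= refractory_until
                and rng.random() < rho
            ):
                cur_target = self.targets[target_idx % len(self.targets)]
                target_idx += 1
                W = W_u[cur_target]
                mode_unstable = True
                onset_time = t
                n_onsets += 1
                events.append((t, "onset"))
                need_rates = True

            if max_detections is not None and n_detections >= max_detections and z == 1:
                break
            if max_episodes is not None and len(episodes) >= max_episodes:
                break
            k += 1
            t_grid = k * dt

        return ClosedLoopResult(
            episodes=episodes,
            events=events,
            sim_time=t,
            n_onsets=n_onsets,
            n_detections=n_detections,
            n_false_positives=n_fp,
            trace=(
                {key: np.asarray(val) for key, val in trace.items()}
                if trace is not None
                else None
            ),
        )


def run_episode(
    modes: ModeMatrices,
    calib: CalibratedDetector,
    variant: Variant = "nonlinear",
    target: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    horizon: float = 30_000.0,
    max_time: float = 600_000.0,
    apply_control: bool = True,
    record_trace: bool = False,
) -> tuple[EpisodeMetrics | None, ClosedLoopResult]:
    """Run the loop until one episode completes (or ``max_time`` elapses);
    returns that episode (None if none occurred) and the full result."""
    sim = ClosedLoopSimulator(
        modes,
        calib,
        variant=variant,
        episode_targets=None if target is None else [target],
        seed=seed,
        rng=rng,
        horizon=horizon,
        apply_control=apply_control,
        record_trace=record_trace,
    )
    result = sim.run(max_time=max_time, max_episodes=1)
    episode = result.episodes[0] if result.episodes else None
    return episode, result


@dataclass
class ExperimentReport:
    """Benchmark summary: per-episode table plus per-variant statistics."""

    episodes: list[EpisodeMetrics]
    n_false_positives: int
    n_detections: int
    n_onsets: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.episodes])

    def summary(self) -> dict:
        frame = self.to_frame()
        out: dict = {
            "n_episodes": len(self.episodes),
            "n_detections": self.n_detections,
            "n_onsets": self.n_onsets,
            "n_false_positives": self.n_false_positives,
            "n_unresolved": int((~frame["resolved"]).sum()) if len(frame) else 0,
            "variants": {},
        }
        if not len(frame):
            return out
        resolved = frame[frame["resolved"] & frame["true_positive"]]
        for variant, group in resolved.groupby("controller_variant"):
            stats = {}
            for col in (
                "detection_delay",
                "stable_mode_delay",
                "first_stable_fr_time",
            ):
                vals = group[col].dropna()
                stats[col] = {
                    "n": int(vals.size),
                    "mean_ms": float(vals.mean()) if vals.size else None,
                    "sd_ms": float(vals.std(ddof=1)) if vals.size > 1 else None,
                }
            out["variants"][variant] = stats
        return out


def run_benchmark(
    modes: ModeMatrices,
    calib: CalibratedDetector,
    detections_per_matrix: int = 100,
    variants: Iterable[Variant] = ("linear", "nonlinear"),
    targets: Sequence[float] | None = None,
    seed: int | None = None,
    horizon: float = 30_000.0,
    max_time_per_run: float | None = None,
) -> ExperimentReport:
    """Repeat closed-loop episodes until ``detections_per_matrix`` unstable
    detections have occurred for every (controller variant, unstable matrix)
    pair; summarize delays as mean +- SD with true/false-positive counts."""
    targets = sorted(modes.variants) if targets is None else list(targets)
    ss = np.random.SeedSequence(seed)
    episodes: list[EpisodeMetrics] = []
    n_fp = n_det = n_onsets = 0
    if detections_per_matrix > 0:
        for variant in variants:
            for target in targets:
                rng = np.random.default_rng(ss.spawn(1)[0])
                sim = ClosedLoopSimulator(
                    modes,
                    calib,
                    variant=variant,
                    episode_targets=[target],
                    rng=rng,
                    horizon=horizon,
                )
                cap = (
                    max_time_per_run
                    if max_time_per_run is not None
                    else detections_per_matrix
                    * (10.0 / calib.params.rho + 2 * horizon)
                )
                res = sim.run(max_time=cap, max_detections=detections_per_matrix)
                episodes.extend(res.episodes)
                n_fp += res.n_false_positives
                n_det += res.n_detections
                n_onsets += res.n_onsets
    for idx, ep in enumerate(episodes):
        ep.index = idx
    return ExperimentReport(
        episodes=episodes,
        n_false_positives=n_fp,
        n_detections=n_det,
        n_onsets=n_onsets,
    )
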