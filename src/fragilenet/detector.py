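"""Firing-rate estimation and two-mode instability detection.

The detector watches the normalized firing rate of the most fragile node: at
every step of a uniform grid it counts spikes in the trailing ``m``-ms window,
divides by the calibrated maximum count for that window size, and averages the
``n`` most recent window values.  A two-mode hidden Markov model with Gaussian
emissions (q1 stable, q2 unstable) turns the rate into a likelihood ratio
``LR_k = q2(p_k) / q1(p_k)``; the cumulative sum ``gr_k`` and its per-step
derivative ``dgr_k = LR_k / grid_dt`` are thresholded to declare a transition
to the unstable mode.  The return to stability is declared when the rate sits
inside a +-2 SD band around the stable mean for an uninterrupted hold period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from .network import NetworkConfig, NetworkTrace, gillespie_simulate

__all__ = [
    "DetectorParams",
    "Gaussian",
    "EmissionModel",
    "FiringRateSeries",
    "DetectorState",
    "CalibrationError",
    "firing_rate_series",
    "window_values",
    "calibrate_max_count",
    "fit_emissions",
    "likelihood_ratio",
    "instability_statistic",
    "calibrate_threshold",
    "detect_stability",
    "OnlineDetector",
]

# likelihood-ratio clamp keeping cumulative sums finite over long runs
_LOG_LR_CAP = math.log(1e250)


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectorParams:
    """Detector configuration.

    m: window length (ms); n: number of averaged windows; grid_dt: evaluation
    step (ms); max_count: normalization count per m-window (calibrated);
    rho: per-grid-step stable->unstable transition probability; threshold:
    detection threshold on dgr (per ms, calibrated); stable_hold: required
    in-band duration (ms); band_halfwidth_sd: half-width of the stable band
    in stable-mode standard deviations.
    """

    m: float = 250.0
    n: int = 25
    grid_dt: float = 1.0
    max_count: int | None = None
    rho: float = 2e-4
    threshold: float | None = None
    stable_hold: float = 500.0
    band_halfwidth_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.n >= 1 and self.grid_dt > 0):
            raise ValueError("require m > 0, n >= 1, grid_dt > 0")
        if not (0 <= self.rho < 1):
            # rho = 0 is allowed: it disables spontaneous onsets entirely
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.max_count is not None and self.max_count < 1:
            raise ValueError("max_count must be >= 1")

    @property
    def burn_in(self) -> float:
        """Initial fill before the rate estimate is defined (ms)."""
        return self.m + (self.n - 1) * self.grid_dt


@dataclass(frozen=True)
class Gaussian:
    mean: float
    var: float

    def __post_init__(self) -> None:
        if not (self.var > 0):
            raise ValueError(f"variance must be > 0, got {self.var}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = -0.5 * ((x - self.mean) ** 2 / self.var) - 0.5 * np.log(
            2.0 * np.pi * self.var
        )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EmissionModel:
    """Gaussian emission densities of the normalized firing rate: q1 stable
    mode, q2 unstable mode."""

    q1: Gaussian
    q2: Gaussian


@dataclass(frozen=True)
class FiringRateSeries:
    """Normalized firing rate on a uniform grid, starting after the initial
    window-averaging delay.  ``exceeded`` flags grid points whose raw window
    count exceeded the calibration maximum (values are not clipped)."""

    times: NDArray[np.float64]
    p: NDArray[np.float64]
    grid_dt: float
    exceeded: NDArray[np.bool_]


@dataclass
class DetectorState:
    """Per-grid-step detector statistics over a firing-rate series."""

    times: NDArray[np.float64]
    p: NDArray[np.float64]
    LR: NDArray[np.float64]
    gr: NDArray[np.float64]
    dgr: NDArray[np.float64]
    threshold: float | None
    unstable_detection_time: float | None


def window_values(
    spikes: NDArray[np.float64],
    times: NDArray[np.float64],
    m: float,
    max_count: int,
) -> NDArray[np.float64]:
    """Normalized spike count of the window ``(t - m, t]`` for each t."""
    sp = np.asarray(spikes, dtype=float)
    hi = np.searchsorted(sp, times, side="right")
    lo = np.searchsorted(sp, times - m, side="right")
    return (hi - lo) / float(max_count)


def firing_rate_series(
    spikes: Sequence[NDArray[np.float64]] | NDArray[np.float64],
    node: int,
    params: DetectorParams,
    duration: float,
) -> FiringRateSeries:
    """Windowed, normalized, ``n``-averaged firing rate of ``node`` (1-based).

    Defined on the grid ``t = burn_in, burn_in + grid_dt, ... <= duration``;
    earlier times fall inside the initial averaging delay and are not
    reported.  ``spikes`` may be the per-node list from a
    :class:`~fragilenet.network.NetworkTrace` or a single spike-time array.
    """
    if params.max_count is None:
        raise CalibrationError("max_count is not calibrated")
    sp = (
        np.asarray(spikes, dtype=float)
        if isinstance(spikes, np.ndarray)
        else np.asarray(spikes[node - 1], dtype=float)
    )
    dt = params.grid_dt
    # window values on the grid starting at t = m
    n_w = int(math.floor((duration - params.m) / dt)) + 1
    if n_w < params.n:
        raise ValueError(
            f"duration {duration} ms too short for burn-in {params.burn_in} ms"
        )
    w_times = params.m + dt * np.arange(n_w)
    v = window_values(sp, w_times, params.m, params.max_count)
    kernel_csum = np.concatenate(([0.0], np.cumsum(v)))
    p = (kernel_csum[params.n :] - kernel_csum[: -params.n]) / params.n
    times = w_times[params.n - 1 :]
    exc_raw = v > 1.0
    exc_csum = np.concatenate(([0], np.cumsum(exc_raw)))
    exceeded = (exc_csum[params.n :] - exc_csum[: -params.n]) > 0
    return FiringRateSeries(times=times, p=p, grid_dt=dt, exceeded=exceeded)


def calibrate_max_count(
    cfg: NetworkConfig,
    params: DetectorParams,
    node: int,
    duration: float = 100_000.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    trace: NetworkTrace | None = None,
) -> int:
    """Maximum spike count of ``node`` over grid-aligned ``m``-windows in a
    stable-mode simulation of ``duration`` ms (default 100 s).

    A pre-computed stable-mode ``trace`` may be supplied instead of running a
    fresh simulation.  Raises :class:`CalibrationError` if the node never
    spikes (degenerate network).
    """
    if trace is None:
        trace = gillespie_simulate(
            cfg, duration, seed=seed, rng=rng, record_states=False
        )
    sp = trace.spike_times[node - 1]
    if sp.size == 0:
        raise CalibrationError(f"node {node} produced no spikes during calibration")
    dt = params.grid_dt
    times = params.m + dt * np.arange(int((trace.duration - params.m) / dt) + 1)
    hi = np.searchsorted(sp, times, side="right")
    lo = np.searchsorted(sp, times - params.m, side="right")
    return int(np.max(hi - lo))


def fit_emissions(
    stable_rates: NDArray[np.float64],
    unstable_rates: NDArray[np.float64],
    var_floor: float = 0.0,
) -> EmissionModel:
    """Gaussian maximum-likelihood fit (sample mean, 1/N variance) per mode.

    ``var_floor`` guards against a degenerate mode (e.g. a completely
    silenced node whose rate is identically zero): the fitted variance is
    raised to the floor instead of erroring.  With the default floor of 0 a
    zero-variance sample raises :class:`CalibrationError`.
    """

    def _fit(x, label):
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise CalibrationError(f"{label}: need >= 2 samples, got {x.size}")
        var = max(float(np.var(x)), var_floor)  # MLE (biased) variance
        if var <= 0:
            raise CalibrationError(f"{label}: zero variance")
        return Gaussian(mean=float(np.mean(x)), var=var)

    return EmissionModel(
        q1=_fit(stable_rates, "stable rates"), q2=_fit(unstable_rates, "unstable rates")
    )


def likelihood_ratio(p, em: EmissionModel):
    """``q2(p) / q1(p)``, clamped to keep long cumulative sums finite."""
    log_lr = np.clip(em.q2.logpdf(p) - em.q1.logpdf(p), -_LOG_LR_CAP, _LOG_LR_CAP)
    out = np.exp(log_lr)
    return float(out) if np.ndim(out) == 0 else out


def instability_statistic(
    series: FiringRateSeries,
    em: EmissionModel,
    params: DetectorParams,
) -> DetectorState:
    """Likelihood ratio, its cumulative sum and per-step derivative over a
    firing-rate series; the first grid step with ``dgr > threshold`` (when a
    threshold is set) is reported as the unstable detection time."""
    LR = likelihood_ratio(series.p, em)
    gr = np.cumsum(LR)
    dgr = LR / series.grid_dt
    detection = None
    if params.threshold is not None:
        idx = np.nonzero(dgr > params.threshold)[0]
        if idx.size:
            detection = float(series.times[idx[0]])
    return DetectorState(
        times=series.times,
        p=series.p,
        LR=LR,
        gr=gr,
        dgr=dgr,
        threshold=params.threshold,
        unstable_detection_time=detection,
    )


def calibrate_threshold(
    unstable_cfgs: Sequence[NetworkConfig],
    em: EmissionModel,
    params: DetectorParams,
    node: int,
    duration: float = 60_000.0,
    seeds: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Detection threshold: the mean of ``dgr`` pooled sample-wise over
    unstable-mode simulations of every supplied matrix (default 60 s each),
    burn-in excluded."""
    if seeds is not None and len(seeds) != len(unstable_cfgs):
        raise ValueError("need one seed per unstable configuration")
    pooled = []
    for k, cfg in enumerate(unstable_cfgs):
        trace = gillespie_simulate(
            cfg,
            duration,
            seed=None if seeds is None else seeds[k],
            rng=rng,
            record_states=False,
        )
        series = firing_rate_series(trace.spike_times, node, params, duration)
        pooled.append(likelihood_ratio(series.p, em) / params.grid_dt)
    dgr = np.concatenate(pooled)
    if float(np.ptp(dgr)) == 0.0:
        raise CalibrationError("degenerate (constant) dgr during calibration")
    return float(np.mean(dgr))


def detect_stability(
    series: FiringRateSeries,
    em: EmissionModel,
    params: DetectorParams,
    start_time: float | None = None,
) -> float | None:
    """First time the rate has sat inside ``mean1 +- band_halfwidth_sd * sd1``
    (endpoints inclusive) for an uninterrupted ``stable_hold`` ms, ignoring
    grid points before ``start_time``.  Returns None if never satisfied; any
    exit from the band resets the hold timer."""
    lo = em.q1.mean - params.band_halfwidth_sd * em.q1.sd
    hi = em.q1.mean + params.band_halfwidth_sd * em.q1.sd
    mask = (series.p >= lo) & (series.p <= hi)
    if start_time is not None:
        mask &= series.times >= start_time
    need = int(round(params.stable_hold / series.grid_dt))
    run = 0
    for k, ok in enumerate(mask):
        run = run + 1 if ok else 0
        if run >= need + 1:  # in-band span of stable_hold ms (need+1 grid points)
            return float(series.times[k])
    return None


class OnlineDetector:
    """Incremental counterpart of the vectorized operations above.

    Drives the closed loop: spikes of the watched node are appended as they
    occur and :meth:`update` is called once per grid step, returning the
    current rate estimate and likelihood statistics.  The arithmetic matches
    :func:`firing_rate_series` / :func:`instability_statistic` exactly on the
    shared grid.
    """

    def __init__(self, params: DetectorParams, em: EmissionModel):
        if params.max_count is None or params.threshold is None:
            raise CalibrationError("detector requires calibrated max_count/threshold")
        self.params = params
        self.em = em
        self._spikes: list[float] = []
        self._lo = 0  # first spike strictly inside the current window
        self._hi = 0  # one past the last spike at or before now
        self._ring = [0.0] * params.n  # last n window values
        self._ring_sum = 0.0
        self._n_windows = 0
        self.gr = 0.0
        # per-update outputs
        self.p: float | None = None
        self.LR: float | None = None
        self.dgr: float | None = None

    def add_spike(self, t: float) -> None:
        self._spikes.append(t)

    @property
    def ready(self) -> bool:
        return self._n_windows >= self.params.n

    def update(self, t: float) -> None:
        """Advance to grid time ``t`` (strictly increasing across calls)."""
        params = self.params
        if t < params.m - 1e-9:
            return
        sp = self._spikes
        while self._hi < len(sp) and sp[self._hi] <= t:
            self._hi += 1
        t_lo = t - params.m
        while self._lo < self._hi and sp[self._lo] <= t_lo:
            self._lo += 1
        v = (self._hi - self._lo) / float(params.max_count)
        slot = self._n_windows % params.n
        self._ring_sum += v - self._ring[slot]
        self._ring[slot] = v
        self._n_windows += 1
        if not self.ready:
            self.p = self.LR = self.dgr = None
            return
        self.p = self._ring_sum / params.n
        log_lr = self.em.q2.logpdf(self.p) - self.em.q1.logpdf(self.p)
        log_lr = min(max(log_lr, -_LOG_LR_CAP), _LOG_LR_CAP)
        self.LR = math.exp(log_lr)
        self.gr += self.LR
        self.dgr = self.LR / params.grid_dt

    def in_stable_band(self) -> bool:
        if self.p is None:
            return False
        half = self.params.band_halfwidth_sd * self.em.q1.sd
        return self.em.q1.mean - half <= self.p <= self.em.q1.mean + half


def with_calibration(
    params: DetectorParams, max_count: int, threshold: float
) -> DetectorParams:
    """Return a copy of ``params`` with calibration results filled in."""
    return replace(params, max_count=max_count, threshold=threshold)
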