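"""Shared fixtures.

The default generated network, its calibrated detector and a benchmark run
are expensive (tens of seconds of simulated activity), so they are built once
per session and shared; everything derived from them uses fixed seeds and is
therefore deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from fragilenet.detector import DetectorParams
from fragilenet.generator import default_network
from fragilenet.loop import calibrate_detector, run_benchmark

#: seed of the shared fixture network (chosen for fast generation)
NET_SEED = 3
CALIB_SEED = 10
BENCH_SEED = 7


@pytest.fixture(scope="session")
def default_net():
    return default_network(seed=NET_SEED)


@pytest.fixture(scope="session")
def modes(default_net):
    return default_net.modes


@pytest.fixture(scope="session")
def calib(modes):
    return calibrate_detector(modes, DetectorParams(), seed=CALIB_SEED)


@pytest.fixture(scope="session")
def benchmark_report(modes, calib):
    """50 detections per controller variant on the strong unstable matrix."""
    return run_benchmark(
        modes,
        calib,
        detections_per_matrix=55,
        variants=("linear", "nonlinear"),
        targets=[200.0],
        seed=BENCH_SEED,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
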