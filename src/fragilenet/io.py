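"""Plain-text readers/writers for every artifact the pipeline produces.

CSV for matrices, spike trains, traces and episode tables; JSON for the
network descriptor, emission model, threshold, fragility report, benchmark
summary and run manifests; YAML or JSON for run configuration.  Node ids are
1-based everywhere on disk; rates appear in Hz in descriptors (``alpha_hz``)
and are converted to the internal ms^-1 convention on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detector import DetectorParams, EmissionModel, Gaussian
from .fragility import FragilityReport
from .network import NetworkConfig, NetworkTrace, ResponseFunctionParams

__all__ = [
    "SchemaError",
    "read_network",
    "write_network",
    "read_weights_csv",
    "write_weights_csv",
    "write_spikes",
    "read_spikes",
    "write_trace",
    "write_fragility_report",
    "write_emissions",
    "read_emissions",
    "write_detector_params",
    "read_detector_params",
    "write_episodes",
    "write_json",
    "read_json",
    "load_config",
    "write_manifest",
]


class SchemaError(ValueError):
    """A file violated the expected schema; lists the offending fields."""

    def __init__(self, path, fields: list[str]):
        super().__init__(f"{path}: invalid or missing fields: {', '.join(fields)}")
        self.fields = fields


def _node_labels(n: int) -> list[str]:
    return [f"node_{i}" for i in range(1, n + 1)]


def write_network(cfg: NetworkConfig, path) -> None:
    """JSON network descriptor {N, alpha_hz, weights, h, f_params}."""
    doc = {
        "N": cfg.n_nodes,
        "alpha_hz": cfg.alpha * 1000.0,
        "weights": cfg.weights.tolist(),
        "h": cfg.h.tolist(),
        "f_params": {
            "f_max_hz": cfg.f_params.f_max * 1000.0,
            "gain": cfg.f_params.gain,
            "threshold": cfg.f_params.threshold,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_network(path) -> NetworkConfig:
    """Load a JSON network descriptor; round-trips :func:`write_network`."""
    doc = json.loads(Path(path).read_text())
    bad: list[str] = []
    for key in ("N", "alpha_hz", "weights", "h", "f_params"):
        if key not in doc:
            bad.append(key)
    if bad:
        raise SchemaError(path, bad)
    n = doc["N"]
    W = np.asarray(doc["weights"], dtype=float)
    h = np.asarray(doc["h"], dtype=float)
    if W.ndim != 2 or W.shape != (n, n):
        bad.append("weights (must be N x N)")
    if h.shape != (n,):
        bad.append("h (must have length N)")
    fp = doc["f_params"]
    for key in ("f_max_hz", "gain", "threshold"):
        if key not in fp:
            bad.append(f"f_params.{key}")
    if bad:
        raise SchemaError(path, bad)
    return NetworkConfig(
        weights=W,
        h=h,
        alpha=doc["alpha_hz"] / 1000.0,
        f_params=ResponseFunctionParams(
            f_max=fp["f_max_hz"] / 1000.0,
            gain=fp["gain"],
            threshold=fp["threshold"],
        ),
    )


def write_weights_csv(W: np.ndarray, path) -> None:
    W = np.asarray(W, dtype=float)
    pd.DataFrame(W, columns=_node_labels(W.shape[1])).to_csv(path, index=False)


def read_weights_csv(path) -> np.ndarray:
    # round_trip parsing: the default fast parser can be off by one ulp
    return pd.read_csv(path, float_precision="round_trip").to_numpy(dtype=float)


def write_spikes(trace: NetworkTrace, path) -> None:
    """Two-column CSV (time_ms, node_id), time-sorted, 1-based node ids,
    microsecond-precision times."""
    rows = [
        (t, i + 1)
        for i, sp in enumerate(trace.spike_times)
        for t in sp
    ]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("time_ms,node_id\n")
        for t, node in rows:
            fh.write(f"{t:.6f},{node}\n")


def read_spikes(path, n_nodes: int) -> list[np.ndarray]:
    frame = pd.read_csv(path)
    out = []
    for node in range(1, n_nodes + 1):
        out.append(frame.loc[frame["node_id"] == node, "time_ms"].to_numpy(dtype=float))
    return out


def write_trace(trace: NetworkTrace, path) -> None:
    """Full event record: time_ms then one binary column per node."""
    if trace.states is None:
        raise ValueError("trace was recorded without states")
    times = np.concatenate(([0.0], trace.event_times))
    frame = pd.DataFrame(trace.states, columns=_node_labels(trace.n_nodes))
    frame.insert(0, "time_ms", times)
    frame.to_csv(path, index=False, float_format="%.6f")


def write_fragility_report(report: FragilityReport, path) -> None:
    doc = {
        "target_re_per_ms": report.target_re,
        "energies": [None if not np.isfinite(e) else e for e in report.energies],
        "fragile_node": report.fragile_node,
        "perturbation_rows": [
            None if p is None else {"row": p.row_index, "delta": p.row.tolist()}
            for p in report.perturbations
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_emissions(em: EmissionModel, path) -> None:
    doc = {
        "q1": {"mean": em.q1.mean, "var": em.q1.var},
        "q2": {"mean": em.q2.mean, "var": em.q2.var},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_emissions(path) -> EmissionModel:
    doc = json.loads(Path(path).read_text())
    bad = [k for k in ("q1", "q2") if k not in doc]
    if bad:
        raise SchemaError(path, bad)
    return EmissionModel(
        q1=Gaussian(**doc["q1"]),
        q2=Gaussian(**doc["q2"]),
    )


def write_detector_params(params: DetectorParams, path) -> None:
    Path(path).write_text(json.dumps(asdict(params), indent=2) + "\n")


def read_detector_params(path) -> DetectorParams:
    return DetectorParams(**json.loads(Path(path).read_text()))


def write_episodes(report_frame: pd.DataFrame, path) -> None:
    report_frame.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path) -> dict:
    """Run configuration from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def write_manifest(path, *, seed, config: dict | None = None, extra: dict | None = None) -> None:
    """Record everything needed to re-run bit-identically."""
    config = config or {}
    canonical = json.dumps(config, sort_keys=True, default=_jsonable)
    doc = {
        "fragilenet_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable) + "\n")
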