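"""File formats and run configuration.

Traces are stored as two-column delimited text (``time_s``,
``current_pA``) with a JSON metadata sidecar (``<file>.json``) carrying
sampling rate, protocol, generator parameters, and seed.  Tabular
outputs are plain CSV.  Run configurations are YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .types import CurrentTrace, MiniKernel, RateTriple, SucroseProtocol

__all__ = [
    "write_trace",
    "read_trace",
    "ConditionConfig",
    "RunConfig",
    "load_config",
]


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write a trace as delimited text plus a JSON sidecar."""
    path = Path(path)
    data = np.column_stack([trace.times, trace.samples])
    header = "time_s\tcurrent_pA"
    np.savetxt(path, data, fmt="%.6f\t%.4f", header=header, comments="")
    sidecar = dict(trace.annotations)
    sidecar["sampling_rate"] = trace.sampling_rate
    sidecar["n_samples"] = trace.n_samples
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=_jsonable)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.random.SeedSequence):
        return obj.entropy
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    data = np.loadtxt(path, skiprows=1)
    samples = data[:, 1]
    sampling_rate = float(meta.pop("sampling_rate"))
    meta.pop("n_samples", None)
    if "application_window" in meta and meta["application_window"] is not None:
        meta["application_window"] = tuple(meta["application_window"])
    return CurrentTrace(samples, sampling_rate, meta)


@dataclass
class ConditionConfig:
    """One experimental condition: rates, protocol, replicates, seed."""

    name: str
    rates: RateTriple
    seed: int
    n_cells: int = 10
    protocol: SucroseProtocol | None = None
    spont_duration: float = 60.0
    kernel: MiniKernel = field(default_factory=MiniKernel)
    noise_sd: float = 3.0
    sampling_rate: float = 20_000.0

    def cell_seeds(self) -> list[int]:
        """Deterministic per-cell seeds derived from the condition seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(self.n_cells)]


@dataclass
class RunConfig:
    conditions: list[ConditionConfig]

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Schema (per condition)::

        conditions:
          - name: WT
            rates: {k1: 385.6, k_minus1: 0.0903, kf: 0.000844}
            seed: 1
            n_cells: 10
            spont_duration: 60.0
            noise_sd: 3.0
            protocol: {onset_time: 1.0, duration: 5.0, n_suc: 5000,
                       baseline_shift: -20.0, exchange_time: 0.05}
            kernel: {unitary_charge: 0.05, rise_tau: 0.0005,
                     decay_tau: 0.003, amplitude_cv: 0.3}

    Every condition must name a seed; all nested parameters are
    validated by their type constructors at load time.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "conditions" not in raw:
        raise ValueError("config must contain a 'conditions' list")
    conditions = []
    for entry in raw["conditions"]:
        if "seed" not in entry:
            raise ValueError(
                f"condition {entry.get('name', '?')!r} is missing a seed"
            )
        if "rates" not in entry or "name" not in entry:
            raise ValueError("each condition needs 'name' and 'rates'")
        kwargs = dict(
            name=entry["name"],
            rates=RateTriple(**entry["rates"]),
            seed=int(entry["seed"]),
        )
        if "protocol" in entry and entry["protocol"] is not None:
            kwargs["protocol"] = SucroseProtocol(**entry["protocol"])
        if "kernel" in entry:
            kwargs["kernel"] = MiniKernel(**entry["kernel"])
        for key in ("n_cells", "spont_duration", "noise_sd", "sampling_rate"):
            if key in entry:
                kwargs[key] = entry[key]
        conditions.append(ConditionConfig(**kwargs))
    return RunConfig(conditions=conditions)
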