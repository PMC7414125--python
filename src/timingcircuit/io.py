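"""Configuration, event-table I/O and synthetic subject-summary fixtures.

Event tables are headered plain-text TSV; run configurations load from YAML
or JSON with unknown keys rejected, and every CLI run writes back a resolved
snapshot so it can be reproduced exactly from the snapshot plus master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .core_dynamics import CircuitParams
from .mpm import ProductionRecord
from .stimuli import StimulusTrain
from .linear_baseline import LinearParams, simulate_linear_reproduction
from .tasks import run_reproduction, run_sync_cont, bias_curve

__all__ = ["RunConfig", "read_event_table", "write_event_table",
           "read_production_record", "write_production_record",
           "generate_fixture_subject"]

_KNOWN_KEYS = {
    "task", "seed", "out", "trials", "params", "K", "I0", "alpha", "sigma_n",
    "I_levels", "duration_ms", "kind", "ts_list", "isi_grid", "n_samples",
    "n_continuation", "n_trials_per_isi", "beta_ISI", "beta_Asynch", "T0",
}


@dataclass
class RunConfig:
    """Resolved run configuration: task selector, overrides, seed, output."""

    task: str
    seed: int = 0
    out: Optional[str] = None
    trials: Optional[int] = None
    params: dict = field(default_factory=dict)  # CircuitParams overrides
    options: dict = field(default_factory=dict)  # protocol parameters

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        opts = {k: v for k, v in data.items()
                if k not in {"task", "seed", "out", "trials", "params"}}
        return cls(task=data["task"], seed=data.get("seed", 0),
                   out=data.get("out"), trials=data.get("trials"),
                   params=data.get("params", {}), options=opts)

    def circuit_params(self) -> CircuitParams:
        return CircuitParams(**self.params)

    def write_snapshot(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def write_event_table(obj, path) -> None:
    """Write a stimulus train or production record as headered TSV."""
    if isinstance(obj, StimulusTrain):
        obj.write_tsv(path)
    elif isinstance(obj, ProductionRecord):
        write_production_record(obj, path)
    else:
        raise TypeError(f"cannot write event table for {type(obj).__name__}")


def read_event_table(path):
    """Read an event table; dispatches on the header line."""
    header = Path(path).read_text().splitlines()[0]
    if header.startswith("onset_ms"):
        return StimulusTrain.read_tsv(path)
    if header.startswith("production_ms"):
        return read_production_record(path)
    raise ValueError(f"malformed event-table header: {header!r}")


def write_production_record(record: ProductionRecord, path) -> None:
    lines = ["production_ms"]
    lines += [f"{t:.6g}" for t in record.production_times]
    Path(path).write_text("\n".join(lines) + "\n")


def read_production_record(path) -> ProductionRecord:
    lines = Path(path).read_text().strip().splitlines()
    if lines[0] != "production_ms":
        raise ValueError(f"malformed event-table header: {lines[0]!r}")
    return ProductionRecord(np.asarray([float(x) for x in lines[1:]]))


def generate_fixture_subject(kind: str, true_params: dict, seed: int = 0,
                             path=None, model: str = "circuit",
                             n_trials: int = 100,
                             n_trials_per_isi: int = 21):
    """Synthetic subject summary for fitting, with recorded ground truth.

    ``kind`` is ``"reproduction"`` (10 rows of per-condition mean/SD of the
    produced interval) or ``"sync_cont"`` (one BIAS_k row per interval
    index).  The summary is produced by simulating the chosen generating
    model (``"circuit"`` or ``"linear"``, reproduction only) at
    ``true_params``.  Returns ``(summary DataFrame, ground-truth dict)``; if
    ``path`` is given the summary is written as CSV with a JSON sidecar
    holding the ground truth.
    """
    if kind == "reproduction":
        if model == "circuit":
            res = run_reproduction(K=true_params["K"], I0=true_params["I0"],
                                   sigma_n=true_params["sigma_n"],
                                   task="both", n_trials=n_trials, seed=seed)
        elif model == "linear":
            res = simulate_linear_reproduction(
                LinearParams(**true_params), task="both", n_trials=n_trials,
                seed=seed)
        else:
            raise ValueError(f"unknown generating model {model!r}")
        frame = res.frame.groupby(["task", "t_s_ms"])["t_p_ms"].agg(
            mean_tp_ms="mean",
            sd_tp_ms=lambda x: x.std(ddof=1)).reset_index()
    elif kind == "sync_cont":
        res = run_sync_cont(K=true_params["K"], I0=true_params["I0"],
                            alpha=true_params["alpha"],
                            sigma_n=true_params.get("sigma_n", 0.01),
                            n_trials_per_isi=n_trials_per_isi, seed=seed)
        frame = bias_curve(res)[["k", "bias_ms"]]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    truth = {"kind": kind, "model": model, "seed": seed,
             "true_params": dict(true_params)}
    if path is not None:
        path = Path(path)
        frame.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(truth, indent=2))
    return frame, truth
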