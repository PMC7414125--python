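"""Task harnesses: each protocol run across trials with derived seeds.

Every harness is deterministic given its configuration and master seed.
Per-trial seeds are derived with a counter-based scheme (condition index,
trial index), so adding trials or conditions never changes earlier ones.
Results come back as a :class:`TaskResult`: a tidy per-interval DataFrame
plus the raw per-trial records needed for downstream metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _engine, metrics
from .core_dynamics import CircuitParams
from .mpm import ProductionRecord
from .sam import SamConfig, reproduce_many
from .stimuli import (StimulusTrain, make_tracking_blocks, make_perturbation,
                      make_sync_cont, SYNC_CONT_ISI_GRID)

__all__ = ["TaskResult", "run_tracking", "run_perturbation", "run_sync_cont",
           "run_reproduction", "run_periodic_production"]

#: Number of interval-reproduction target intervals (ms).
REPRODUCTION_TS = (600.0, 700.0, 800.0, 900.0, 1000.0)

#: Warm-up intervals of the tracking protocol excluded from phase analysis.
TRACKING_WARMUP = 20


@dataclass
class TaskResult:
    """Trials of one protocol: tidy data plus per-trial provenance."""

    task: str
    config: dict
    seed: int
    frame: pd.DataFrame
    trials: list = field(default_factory=list)  # per-trial dicts

    @property
    def conditions(self) -> list:
        return self.config.get("conditions", [])


def _trial_seed_pair(master_seed: int, condition: int, trial: int):
    """Independent (stimulus, noise) seeds for one trial."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(condition), int(trial)))
    return ss.spawn(2)


def run_periodic_production(params: Optional[CircuitParams] = None,
                            I_levels: Sequence[float] = (0.75, 0.76, 0.77, 0.78),
                            duration: float = 40_000.0, n_trials: int = 1,
                            sigma_n: float = 0.01, seed: int = 0) -> TaskResult:
    """Periodic production: the MPM alone at each tonic input level.

    Defaults follow the reference protocol: four input levels uniformly
    spaced from 0.75 to 0.78, 40 s per level, per-step noise SD 0.01.
    """
    params = (params or CircuitParams()).with_(sigma_n=sigma_n)
    n_steps = int(duration / params.dt)
    rows = []
    trials = []
    for ci, I in enumerate(I_levels):
        seeds = _engine.derive_trial_seeds(seed, ci, n_trials)
        eta = _engine.batch_noise(params.sigma_n, n_steps, _engine.MPM_UNITS, seeds)
        prods, _ = _engine.run_mpm_batch(params, I, n_steps, eta)
        for ti, pt in enumerate(prods):
            rec = ProductionRecord(production_times=pt, trial_id=ti, seed=seed)
            if len(rec) == 0:
                rec.flags.append("no_productions")
            trials.append({"condition": {"I": I}, "trial": ti, "record": rec})
            for n, ipi in enumerate(rec.ipis):
                rows.append({"I": I, "trial": ti, "n": n, "ipi_ms": ipi})
    frame = pd.DataFrame(rows, columns=["I", "trial", "n", "ipi_ms"])
    cfg = {"I_levels": list(I_levels), "duration_ms": duration,
           "n_trials": n_trials, "sigma_n": sigma_n,
           "conditions": [{"I": I} for I in I_levels]}
    return TaskResult("periodic_production", cfg, seed, frame, trials)


def _tracking_frame(train: StimulusTrain, record: ProductionRecord,
                    trial: int) -> list[dict]:
    isis = train.isis
    ipis = record.ipis
    sync = None
    if len(record) and len(train) >= 2:
        sync = metrics.asynchrony_and_phase(record.production_times, train.onsets)
    rows = []
    for n in range(len(isis)):
        row = {
            "trial": trial, "n": n, "block": n // 20, "isi_ms": isis[n],
            "ipi_ms": ipis[n] if n < len(ipis) else np.nan,
            "asynchrony_ms": np.nan, "phase_deg": np.nan,
        }
        if sync is not None and n < len(sync.asynchronies):
            row["asynchrony_ms"] = sync.asynchronies[n]
            row["phase_deg"] = sync.phases[n]
        rows.append(row)
    return rows


def run_tracking(params: Optional[CircuitParams] = None, K: float = 2.0,
                 I0: float = 0.771, alpha: float = 0.0, sigma_n: float = 0.01,
                 n_trials: int = 50, seed: int = 0) -> TaskResult:
    """ISI tracking: coupled circuit against randomized-block metronomes.

    Each trial presents 5 blocks x 20 ISIs (block 1 fixed at 800 ms, later
    blocks drawn from {600, 700, 800, 900} ms).  The tidy frame has one row
    per stimulus interval with the index-paired IPI and the nearest-production
    asynchrony and phase.
    """
    params = (params or CircuitParams()).with_(sigma_n=sigma_n)
    dt = params.dt
    trains = []
    noise_seeds = []
    for ti in range(n_trials):
        stim_ss, noise_ss = _trial_seed_pair(seed, 0, ti)
        trains.append(make_tracking_blocks(stim_ss, start=params.run_in))
        noise_seeds.append(noise_ss)
    durations = np.array([tr.onsets[-1] + 1000.0 for tr in trains])
    n_steps = int(np.max(durations) / dt)
    gates = np.zeros((n_trials, n_steps), dtype=bool)
    for i, tr in enumerate(trains):
        gates[i] = _engine.stim_gate(tr.onsets, n_steps, params)
    eta = _engine.batch_noise(params.sigma_n, n_steps, _engine.COUPLED_UNITS,
                              noise_seeds)
    freeze = _engine.first_pulse_window(np.array([params.run_in]), params)
    prods, _, _, _ = _engine.run_coupled_batch(params, K, I0, alpha, gates,
                                               eta, freeze_window=freeze)
    rows = []
    trials = []
    for ti in range(n_trials):
        pt = prods[ti][prods[ti] <= durations[ti]]
        rec = ProductionRecord(production_times=pt, trial_id=ti, seed=seed)
        trials.append({"condition": {"alpha": alpha}, "trial": ti,
                       "train": trains[ti], "record": rec})
        rows += _tracking_frame(trains[ti], rec, ti)
    frame = pd.DataFrame(rows)
    cfg = {"K": K, "I0": I0, "alpha": alpha, "sigma_n": sigma_n,
           "n_trials": n_trials, "conditions": [{"alpha": alpha}]}
    return TaskResult("tracking", cfg, seed, frame, trials)


def tracking_phases(result: TaskResult, skip_warmup: bool = True) -> np.ndarray:
    """Pooled production phases from a tracking run.

    The fixed 800 ms warm-up block exists to initialize the circuit; by
    default phases are pooled over the randomized blocks only.
    """
    fr = result.frame
    if skip_warmup:
        fr = fr[fr["n"] >= TRACKING_WARMUP]
    return fr["phase_deg"].dropna().to_numpy()


def run_perturbation(kind: str, params: Optional[CircuitParams] = None,
                     K: float = 2.0, alpha: float = 0.1, I0: float = 0.771,
                     sigma_n: float = 0.005, n_trials: int = 1000,
                     seed: int = 0, n_post: int = 15,
                     batch_size: int = 250) -> TaskResult:
    """Metronome perturbations: step, phase shift or single-stimulus jitter.

    All trials share the deterministic perturbed train (30 pre-perturbation
    ISIs, then the perturbation).  The frame holds per-stimulus-index
    asynchronies and index-paired IPIs for every trial; use
    :func:`perturbation_summary` for trial-averaged curves.
    """
    params = (params or CircuitParams()).with_(sigma_n=sigma_n)
    train = make_perturbation(kind, start=params.run_in, n_post=n_post)
    duration = train.onsets[-1] + 2.0 * train.isis[-1]
    n_steps = int(duration / params.dt)
    gate = _engine.stim_gate(train.onsets, n_steps, params)
    freeze = _engine.first_pulse_window(train.onsets, params)
    seeds = [_trial_seed_pair(seed, 0, ti)[1] for ti in range(n_trials)]
    rows = []
    trials = []
    for lo in range(0, n_trials, batch_size):
        chunk = seeds[lo: lo + batch_size]
        eta = _engine.batch_noise(params.sigma_n, n_steps,
                                  _engine.COUPLED_UNITS, chunk)
        prods, _, _, _ = _engine.run_coupled_batch(params, K, I0, alpha, gate,
                                                   eta, freeze_window=freeze)
        for j, pt in enumerate(prods):
            ti = lo + j
            rec = ProductionRecord(production_times=pt, trial_id=ti, seed=seed)
            trials.append({"condition": {"kind": kind, "K": K, "alpha": alpha},
                           "trial": ti, "train": train, "record": rec})
            rows += _tracking_frame(train, rec, ti)
    frame = pd.DataFrame(rows)
    cfg = {"kind": kind, "K": K, "alpha": alpha, "I0": I0, "sigma_n": sigma_n,
           "n_trials": n_trials, "n_pre": 30, "n_post": n_post,
           "conditions": [{"kind": kind, "K": K, "alpha": alpha}]}
    return TaskResult(f"perturbation_{kind}", cfg, seed, frame, trials)


def perturbation_summary(result: TaskResult,
                         remove_baseline_asynchrony: bool = True) -> pd.DataFrame:
    """Trial-averaged IPI and asynchrony per stimulus index.

    Indices are aligned on the first perturbed stimulus: index 0 is the first
    displaced onset (the interval row at index -1 spans the perturbation
    itself).  For asynchrony curves the mean pre-perturbation asynchrony is
    subtracted by default, mirroring how human phase-shift responses are
    reported.
    """
    n_pre = result.config["n_pre"]
    g = result.frame.groupby("n").agg(
        mean_ipi_ms=("ipi_ms", "mean"),
        mean_asynchrony_ms=("asynchrony_ms", "mean"),
        isi_ms=("isi_ms", "first"),
    ).reset_index()
    g["index_from_perturbation"] = g["n"] - n_pre - 1
    if remove_baseline_asynchrony:
        base = g.loc[g["index_from_perturbation"] < 0, "mean_asynchrony_ms"].mean()
        g["mean_asynchrony_ms"] -= base
    return g


def run_sync_cont(params: Optional[CircuitParams] = None, K: float = 2.0,
                  I0: float = 0.771, alpha: float = 0.05,
                  sigma_n: float = 0.01, n_trials_per_isi: int = 21,
                  seed: int = 0, isi_grid=SYNC_CONT_ISI_GRID,
                  n_continuation: int = 17) -> TaskResult:
    """Synchronization/continuation: three flashes, then free tapping.

    Per trial the full circuit hears 3 flashes at one ISI from the five-point
    grid, then runs without stimuli until it has produced ``n_continuation``
    further outputs.  The frame lists per-trial IPIs indexed k = 1, 2, ...
    (diffs of the production sequence starting at the first production after
    ``first flash - ISI/2``) with the synchronization/continuation phase label
    switching after k = 3 (the first interval produced wholly without
    stimuli begins at k = 4 when productions align to the three flashes).
    """
    params = (params or CircuitParams()).with_(sigma_n=sigma_n)
    rows = []
    trials = []
    for ci, isi in enumerate(isi_grid):
        train, _ = make_sync_cont(isi=isi, start=params.run_in)
        last = train.onsets[-1]
        duration = last + (n_continuation + 3) * isi + 2000.0
        n_steps = int(duration / params.dt)
        gate = _engine.stim_gate(train.onsets, n_steps, params)
        freeze = _engine.first_pulse_window(train.onsets, params)
        seeds = [_trial_seed_pair(seed, ci, ti)[1]
                 for ti in range(n_trials_per_isi)]
        eta = _engine.batch_noise(params.sigma_n, n_steps,
                                  _engine.COUPLED_UNITS, seeds)
        prods, _, _, _ = _engine.run_coupled_batch(params, K, I0, alpha, gate,
                                                   eta, freeze_window=freeze)
        for ti, pt in enumerate(prods):
            keep = pt[pt >= train.onsets[0] - isi / 2]
            n_after = int(np.sum(keep > last))
            if n_after > n_continuation:
                # truncate to the allowed number of continuation productions
                cut = np.nonzero(keep > last)[0][n_continuation - 1]
                keep = keep[: cut + 1]
            rec = ProductionRecord(production_times=keep, trial_id=ti, seed=seed)
            if n_after < n_continuation:
                rec.flags.append("short_continuation")
            trials.append({"condition": {"isi": isi}, "trial": ti,
                           "train": train, "record": rec})
            for k, ipi in enumerate(rec.ipis, start=1):
                rows.append({"isi_ms": isi, "trial": ti, "k": k, "ipi_ms": ipi,
                             "phase": "sync" if k <= 3 else "continuation"})
    frame = pd.DataFrame(rows, columns=["isi_ms", "trial", "k", "ipi_ms", "phase"])
    cfg = {"K": K, "I0": I0, "alpha": alpha, "sigma_n": sigma_n,
           "n_trials_per_isi": n_trials_per_isi,
           "isi_grid": list(isi_grid), "n_continuation": n_continuation,
           "conditions": [{"isi": isi} for isi in isi_grid]}
    return TaskResult("sync_cont", cfg, seed, frame, trials)


def bias_curve(result: TaskResult, k_max: Optional[int] = None) -> pd.DataFrame:
    """BIAS_k (positive root of the squared bias) across interval index k."""
    fr = result.frame
    if k_max is None:
        # largest k present in every (isi, trial) combination
        k_max = int(fr.groupby(["isi_ms", "trial"])["k"].max().min())
    table = {
        isi: sub.pivot_table(index="trial", columns="k",
                             values="ipi_ms").reindex(
                                 columns=range(1, k_max + 1)).to_numpy()
        for isi, sub in fr.groupby("isi_ms")
    }
    out = []
    for k in range(1, k_max + 1):
        b2 = metrics.bias_by_index(table, k - 1)
        out.append({"k": k, "bias_ms": np.sqrt(b2), "bias_sq": b2})
    return pd.DataFrame(out)


def run_reproduction(params: Optional[CircuitParams] = None, K: float = 5.0,
                     I0: float = 0.78, sigma_n: float = 0.02,
                     task: str = "both", n_trials: int = 100, seed: int = 0,
                     ts_list=REPRODUCTION_TS) -> TaskResult:
    """1-2-Go / 1-2-3-Go interval reproduction with the SAM.

    ``task`` is ``"12go"`` (2 flashes), ``"123go"`` (3 flashes) or ``"both"``
    (10 conditions: 5 sample intervals x 2 tasks).
    """
    params = (params or CircuitParams()).with_(sigma_n=sigma_n)
    cfg_sam = SamConfig(K=K, I0=I0)
    tasks = {"12go": 2, "123go": 3}
    if task != "both":
        if task not in tasks:
            raise ValueError(f"unknown task {task!r}")
        tasks = {task: tasks[task]}
    rows = []
    conditions = []
    ci = 0
    for name, n_flashes in tasks.items():
        for ts in ts_list:
            seeds = [_trial_seed_pair(seed, ci, ti)[1] for ti in range(n_trials)]
            tp = reproduce_many(params, cfg_sam, ts, n_flashes, n_trials, seeds)
            for ti, val in enumerate(tp):
                rows.append({"task": name, "t_s_ms": ts, "trial": ti,
                             "t_p_ms": val})
            conditions.append({"task": name, "t_s_ms": ts})
            ci += 1
    frame = pd.DataFrame(rows, columns=["task", "t_s_ms", "trial", "t_p_ms"])
    cfg = {"K": K, "I0": I0, "sigma_n": sigma_n, "n_trials": n_trials,
           "ts_list": list(ts_list), "conditions": conditions}
    return TaskResult("reproduction", cfg, seed, frame)


def reproduction_summary(result: TaskResult) -> pd.DataFrame:
    """Per-condition mean/SD of t_p and the count of missing productions."""
    fr = result.frame
    g = fr.groupby(["task", "t_s_ms"])["t_p_ms"].agg(
        mean_tp_ms="mean", sd_tp_ms=lambda x: x.std(ddof=1),
        n_missing=lambda x: int(x.isna().sum()), n="count").reset_index()
    return g
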