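"""Linear error-correction algorithm used as a behavioral baseline.

The algorithm keeps a running estimate ``T_n`` of the inter-stimulus interval
and schedules the next production as::

    t_{n+1} = t_n + T_n - beta_Asynch * (t_n - m_n) - beta_ISI * (T_n - ISI_n)

with production noise added to ``t_{n+1}``.  The estimate itself tracks the
observed intervals exponentially, ``T_{n+1} = T_n - beta_ISI * (T_n -
ISI_n)``.  After the final stimulus the estimate freezes at its last value,
so — unlike the circuit model — continuation intervals have a constant mean
and the continuation bias stays flat across interval index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tasks import TaskResult
from .stimuli import SYNC_CONT_ISI_GRID

__all__ = ["LinearParams", "step_linear", "simulate_linear_reproduction",
           "simulate_linear_sync_cont"]


@dataclass(frozen=True)
class LinearParams:
    """Initial interval estimate, correction weights and production noise."""

    T0: float = 800.0
    beta_ISI: float = 0.5
    beta_Asynch: float = 0.0
    sigma_n: float = 50.0  # ms, SD of the production noise

    def __post_init__(self):
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be non-negative")


def step_linear(t_n: float, T_n: float, m_n: float, isi_n: float,
                params: LinearParams, noise_draw: float = 0.0):
    """One update of the linear algorithm; returns ``(t_{n+1}, T_{n+1})``."""
    t_next = (t_n + T_n
              - params.beta_Asynch * (t_n - m_n)
              - params.beta_ISI * (T_n - isi_n)
              + noise_draw)
    T_next = T_n - params.beta_ISI * (T_n - isi_n)
    return t_next, T_next


def simulate_linear_reproduction(params: LinearParams, task: str = "both",
                                 ts_list: Sequence[float] = (600.0, 700.0,
                                                             800.0, 900.0,
                                                             1000.0),
                                 n_trials: int = 100,
                                 seed: int = 0) -> TaskResult:
    """Interval reproduction with the linear algorithm.

    The estimate starts at ``T0`` and assimilates each demonstrated interval
    (one for 1-2-Go, two for 1-2-3-Go); the produced interval is the final
    estimate plus production noise.  With ``beta_ISI = 0`` the response is
    the pure prior ``T0``; with ``beta_ISI = 1`` it matches the sample
    exactly (up to noise).
    """
    tasks = {"12go": 1, "123go": 2}  # number of demonstrated intervals
    if task != "both":
        if task not in tasks:
            raise ValueError(f"unknown task {task!r}")
        tasks = {task: tasks[task]}
    rows = []
    conditions = []
    ci = 0
    for name, n_obs in tasks.items():
        for ts in ts_list:
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=int(seed), spawn_key=(ci,)))
            eta = rng.normal(0.0, params.sigma_n, size=n_trials) \
                if params.sigma_n > 0 else np.zeros(n_trials)
            T = params.T0
            for _ in range(n_obs):
                T = T - params.beta_ISI * (T - ts)
            for ti in range(n_trials):
                rows.append({"task": name, "t_s_ms": ts, "trial": ti,
                             "t_p_ms": T + eta[ti]})
            conditions.append({"task": name, "t_s_ms": ts})
            ci += 1
    frame = pd.DataFrame(rows, columns=["task", "t_s_ms", "trial", "t_p_ms"])
    cfg = {"params": params.__dict__, "n_trials": n_trials,
           "ts_list": list(ts_list), "conditions": conditions}
    return TaskResult("linear_reproduction", cfg, seed, frame)


def simulate_linear_sync_cont(params: LinearParams,
                              isi: Optional[float] = None,
                              isi_grid=SYNC_CONT_ISI_GRID,
                              n_flashes: int = 3, n_continuation: int = 17,
                              n_trials: int = 21, seed: int = 0,
                              start: float = 750.0) -> TaskResult:
    """Synchronization/continuation with the linear algorithm.

    During synchronization the full update runs against the flashes; after
    the final flash the estimate freezes at ``T_N`` and productions advance
    by ``T_N`` plus noise, so continuation IPIs have a constant mean.
    Runs every ISI of ``isi_grid`` unless a single ``isi`` is given.
    """
    isis = [isi] if isi is not None else list(isi_grid)
    rows = []
    trials = []
    for ci, isi_v in enumerate(isis):
        m = start + np.arange(n_flashes) * isi_v
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=int(seed), spawn_key=(ci,)))
        for ti in range(n_trials):
            t = m[0]  # first action aligned with the first flash
            T = params.T0
            prods = [t]
            for n in range(n_flashes - 1):
                eta = float(rng.normal(0.0, params.sigma_n)) \
                    if params.sigma_n > 0 else 0.0
                t, T = step_linear(t, T, m[n], isi_v, params, eta)
                prods.append(t)
            for _ in range(n_continuation):
                eta = float(rng.normal(0.0, params.sigma_n)) \
                    if params.sigma_n > 0 else 0.0
                t = t + T + eta
                prods.append(t)
            ipis = np.diff(prods)
            trials.append({"condition": {"isi": isi_v}, "trial": ti,
                           "production_times": np.asarray(prods)})
            for k, ipi in enumerate(ipis, start=1):
                rows.append({"isi_ms": isi_v, "trial": ti, "k": k,
                             "ipi_ms": ipi,
                             "phase": "sync" if k < n_flashes
                             else "continuation"})
    frame = pd.DataFrame(rows, columns=["isi_ms", "trial", "k", "ipi_ms",
                                        "phase"])
    cfg = {"params": params.__dict__, "n_trials": n_trials,
           "n_flashes": n_flashes, "n_continuation": n_continuation,
           "conditions": [{"isi": v} for v in isis]}
    return TaskResult("linear_sync_cont", cfg, seed, frame, trials)
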