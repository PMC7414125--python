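"""Motor planning module (MPM): the BCM plus a self-reset after each output.

Each threshold crossing of ``y_p`` registers a production and triggers a
transient reset pulse ``I_p`` (one pulse duration, starting the step after
the crossing) that drives ``u_p`` down and ``v_p`` up inside their sigmoid
arguments, restarting the ramp so the module can produce an arbitrary number
of timed outputs.  ``y_p`` is not reset directly; its rapid drop is emergent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .core_dynamics import CircuitParams, UnitState, SimTrace, step_bcm

__all__ = ["ProductionRecord", "step_mpm", "simulate_periodic_production"]


@dataclass
class ProductionRecord:
    """Ordered production (threshold-crossing) times and derived IPIs."""

    production_times: np.ndarray
    trial_id: int = 0
    seed: Optional[int] = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.production_times = np.asarray(self.production_times, dtype=float)
        if len(self.production_times) and np.any(np.diff(self.production_times) <= 0):
            raise ValueError("production times must be strictly increasing")

    @property
    def ipis(self) -> np.ndarray:
        """Inter-production intervals, ``IPI_n = t_{n+1} - t_n``."""
        return np.diff(self.production_times)

    def __len__(self) -> int:
        return len(self.production_times)


def step_mpm(state: UnitState, params: CircuitParams, reset_active: bool,
             noise: Sequence[float] = (0.0, 0.0, 0.0),
             shared_drive: Optional[float] = None) -> UnitState:
    """One Euler step of the MPM: ``step_bcm`` with the reset pulse applied.

    ``shared_drive`` is the total tonic input (``I``, or ``I + dI`` in the
    coupled circuit); defaults to the state's own ``I``.
    """
    if shared_drive is not None:
        state = UnitState(u=state.u, v=state.v, y=state.y, I=shared_drive)
    pulse = params.I_p if reset_active else 0.0
    return step_bcm(state, params, noise=noise, extra_u=-pulse, extra_v=+pulse)


def simulate_periodic_production(params: CircuitParams, I: float,
                                 duration: float, seed: Optional[int] = None,
                                 record_trace: bool = False):
    """Run the MPM at fixed tonic input for ``duration`` ms.

    Returns a :class:`ProductionRecord`; if ``record_trace`` is set, returns
    ``(record, SimTrace)``.  A run with zero productions carries a
    ``"no_productions"`` flag (and warns), since it usually means ``I`` is
    outside the productive regime.
    """
    n_steps = int(duration / params.dt)
    eta = _engine.batch_noise(params.sigma_n, n_steps, _engine.MPM_UNITS, [seed])
    prods, trace = _engine.run_mpm_batch(params, I, n_steps, eta,
                                         record=record_trace)
    record = ProductionRecord(production_times=prods[0], seed=seed)
    if len(record) == 0:
        record.flags.append("no_productions")
        warnings.warn(f"no productions within {duration} ms at I={I}", stacklevel=2)
    if record_trace:
        times = np.arange(n_steps + 1) * params.dt
        sim = SimTrace(
            times=times, u=trace["u"][:, 0], v=trace["v"][:, 0],
            y=trace["y"][:, 0], I=np.full(n_steps + 1, I),
            dI=np.zeros(n_steps + 1),
            events=[(t, "production") for t in record.production_times],
        )
        return record, sim
    return record
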