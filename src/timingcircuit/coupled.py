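"""Full circuit: SAM and MPM coupled through a shared input and a
phase-correction signal.

Both modules read the same tonic input ``I``, which only the SAM's gated
error-integration rule updates.  The MPM additionally receives a memoryless
phase-correction signal ``dI = alpha * (y_p - y_s)`` added to its tonic drive
(inside the input weights, i.e. the drive is ``W_uI * (I + dI)``).  Because
``y_p`` is synchronized to motor events and ``y_s`` to sensory events, their
difference is a graded relative-phase signal: when ``y_s > y_p`` the MPM is
lagging and ``dI < 0`` speeds it up; when ``y_s < y_p`` it is leading and is
slowed down.  The SAM is reset only by stimuli, the MPM only by its own
productions — the asymmetry responsible for the shortened intervals and
increased bias after the metronome stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .core_dynamics import CircuitParams, UnitState, SimTrace
from .mpm import ProductionRecord, step_mpm
from .sam import SamConfig, step_sam
from .stimuli import StimulusTrain

__all__ = ["CoupledConfig", "step_coupled", "simulate_coupled", "CoupledRun"]


@dataclass(frozen=True)
class CoupledConfig:
    """SAM parameters plus the phase-correction gain ``alpha``.

    ``alpha = 0`` removes the correction pathway exactly (frequency tracking
    without phase alignment).
    """

    sam_cfg: SamConfig
    alpha: float = 0.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def step_coupled(sam_state: UnitState, mpm_state: UnitState, I: float,
                 params: CircuitParams, cfg: CoupledConfig, s: int,
                 reset_active: bool,
                 noises: Sequence[float] = (0.0,) * 6,
                 first_stimulus: bool = False):
    """One Euler step of the full circuit.

    ``noises`` holds six independent draws ``(eta_up, eta_vp, eta_yp,
    eta_us, eta_vs, eta_ys)``.  Returns ``(sam_state, mpm_state, I, dI)``.
    """
    dI = cfg.alpha * (mpm_state.y - sam_state.y)
    mpm_new = step_mpm(mpm_state, params, reset_active,
                       noise=noises[:3], shared_drive=I + dI)
    sam_in = UnitState(u=sam_state.u, v=sam_state.v, y=sam_state.y, I=I)
    sam_new = step_sam(sam_in, params, cfg.sam_cfg, s, noise=noises[3:],
                       first_stimulus=first_stimulus)
    mpm_new.I = sam_new.I
    return sam_new, mpm_new, sam_new.I, dI


@dataclass
class CoupledRun:
    """Full-circuit run: the MPM-centric trace plus SAM activities."""

    trace: SimTrace            # u, v, y are the MPM units; I, dI shared
    sam_trace: SimTrace        # u, v, y are the SAM units
    record: ProductionRecord
    sam_crossings: np.ndarray


def simulate_coupled(params: CircuitParams, cfg: CoupledConfig,
                     stimuli: StimulusTrain, duration: float,
                     seed: Optional[int] = None) -> CoupledRun:
    """Run the full circuit against a stimulus train.

    ``I`` is initialized at ``cfg.sam_cfg.I0`` and the first stimulus leaves
    it frozen; productions, IPIs and asynchrony/phase are computable from the
    returned :class:`~timingcircuit.mpm.ProductionRecord` downstream.
    """
    n_steps = int(duration / params.dt)
    eta = _engine.batch_noise(params.sigma_n, n_steps, _engine.COUPLED_UNITS, [seed])
    gate = _engine.stim_gate(stimuli.onsets, n_steps, params)
    freeze = (_engine.first_pulse_window(stimuli.onsets, params)
              if cfg.sam_cfg.first_stim_frozen and len(stimuli) else None)
    prods, sam_x, _, tr = _engine.run_coupled_batch(
        params, cfg.sam_cfg.K, cfg.sam_cfg.I0, cfg.alpha, gate, eta,
        freeze_window=freeze, record=True)
    times = np.arange(n_steps + 1) * params.dt
    events = [(t, "stimulus") for t in stimuli.onsets if t <= duration]
    events += [(t, "production") for t in prods[0]]
    trace = SimTrace(times=times, u=tr["u_p"][:, 0], v=tr["v_p"][:, 0],
                     y=tr["y_p"][:, 0], I=tr["I"][:, 0], dI=tr["dI"][:, 0],
                     events=sorted(events))
    sam_trace = SimTrace(times=times, u=tr["u_s"][:, 0], v=tr["v_s"][:, 0],
                         y=tr["y_s"][:, 0], I=tr["I"][:, 0], dI=tr["dI"][:, 0],
                         events=[(t, "stimulus") for t in stimuli.onsets
                                 if t <= duration])
    record = ProductionRecord(production_times=prods[0], seed=seed)
    if len(record) == 0:
        record.flags.append("no_productions")
    return CoupledRun(trace=trace, sam_trace=sam_trace, record=record,
                      sam_crossings=sam_x[0])
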