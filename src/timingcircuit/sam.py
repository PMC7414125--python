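"""Sensory anticipation module (SAM): predictive interval measurement.

The SAM is a BCM that is reset by sensory stimuli instead of by its own
output.  While a stimulus is on (gate ``s = 1``) the shared input integrates
the anticipation error::

    tau dI/dt = s * K * (y_s - y0)

so that after a few stimuli ``y_s`` reaches the threshold ``y0`` at the
anticipated time of the next stimulus.  ``I`` is frozen during the first
stimulus of a trial (no interval has been demarcated yet) and is piecewise
constant between stimuli.  The same machinery implements Bayesian interval
reproduction: with a fixed initial input ``I0`` acting as the prior guess and
a finite update gain ``K``, produced intervals are pulled toward the
anticipated interval implied by ``I0`` — the central-tendency bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .core_dynamics import CircuitParams, UnitState, SimTrace, step_bcm
from .stimuli import StimulusTrain, make_isochronous

__all__ = ["SamConfig", "step_sam", "simulate_sam", "reproduce_interval",
           "reproduce_many"]


@dataclass(frozen=True)
class SamConfig:
    """Free parameters of the SAM: update gain and initial input level."""

    K: float
    I0: float
    first_stim_frozen: bool = True

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be non-negative")


def step_sam(state: UnitState, params: CircuitParams, cfg: SamConfig,
             s: int, noise: Sequence[float] = (0.0, 0.0, 0.0),
             first_stimulus: bool = False) -> UnitState:
    """One Euler step of the SAM.

    ``s`` is the binary stimulus gate.  The unit update and the gated
    ``I``-update run concurrently (both read the current ``y_s``); the
    ``I``-update has no noise term.  ``first_stimulus`` freezes the update
    (effective ``K = 0``) during the first stimulus presentation.
    """
    if s not in (0, 1):
        raise ValueError("s must be 0 or 1")
    drive = s * params.I_s
    new = step_bcm(state, params, noise=noise, extra_u=-drive, extra_v=+drive)
    K_eff = 0.0 if (first_stimulus and cfg.first_stim_frozen) else cfg.K
    new.I = state.I + (params.dt / params.tau) * s * K_eff * (state.y - params.y0)
    return new


def _freeze(params: CircuitParams, cfg: SamConfig, onsets) -> Optional[tuple[int, int]]:
    if not cfg.first_stim_frozen:
        return None
    return _engine.first_pulse_window(np.asarray(onsets), params)


def simulate_sam(params: CircuitParams, cfg: SamConfig, stimuli: StimulusTrain,
                 duration: float, seed: Optional[int] = None):
    """Run the SAM against a stimulus train for ``duration`` ms.

    Returns ``(trace, predicted_times)`` where ``predicted_times`` are all
    upward ``y_s``-crossings of ``y0``.  The SAM registers no motor output and
    is reset only by stimuli.
    """
    n_steps = int(duration / params.dt)
    eta = _engine.batch_noise(params.sigma_n, n_steps, _engine.SAM_UNITS, [seed])
    gate = _engine.stim_gate(stimuli.onsets, n_steps, params)
    crossings, I_final, tr = _engine.run_sam_batch(
        params, cfg.K, cfg.I0, gate, eta,
        freeze_window=_freeze(params, cfg, stimuli.onsets), record=True)
    times = np.arange(n_steps + 1) * params.dt
    events = [(t, "stimulus") for t in stimuli.onsets if t <= duration]
    events += [(t, "predicted") for t in crossings[0]]
    trace = SimTrace(times=times, u=tr["u"][:, 0], v=tr["v"][:, 0],
                     y=tr["y"][:, 0], I=tr["I"][:, 0],
                     dI=np.zeros(n_steps + 1), events=sorted(events))
    return trace, crossings[0]


def reproduce_many(params: CircuitParams, cfg: SamConfig, t_s: float,
                   n_flashes: int, n_trials: int,
                   seeds: Sequence) -> np.ndarray:
    """Batched interval reproduction: ``n_flashes`` flashes separated by
    ``t_s`` after the run-in; the produced interval ``t_p`` is the time from
    the final flash onset to the next upward ``y_s`` crossing of ``y0``.

    Returns an array of ``t_p`` (ms) with NaN where no crossing occurred
    within the guard window of ``3 * t_s`` after the final flash.
    """
    train = make_isochronous(t_s, n_flashes, start=params.run_in)
    last = train.onsets[-1]
    duration = last + 3.0 * t_s
    n_steps = int(duration / params.dt)
    eta = _engine.batch_noise(params.sigma_n, n_steps, _engine.SAM_UNITS, seeds)
    gate = _engine.stim_gate(train.onsets, n_steps, params)
    crossings, _, _ = _engine.run_sam_batch(
        params, cfg.K, cfg.I0, gate, eta,
        freeze_window=_freeze(params, cfg, train.onsets))
    tp = np.full(len(seeds), np.nan)
    for i, cr in enumerate(crossings):
        after = cr[cr > last]
        if len(after):
            tp[i] = after[0] - last
    return tp


def reproduce_interval(params: CircuitParams, cfg: SamConfig, t_s: float,
                       n_flashes: int, seed: Optional[int] = None) -> float:
    """Single-trial interval reproduction (see :func:`reproduce_many`).

    Returns ``t_p`` in ms, or NaN (flagged as missing) when ``y_s`` does not
    cross ``y0`` within the guard window.
    """
    if n_flashes not in (2, 3):
        raise ValueError("n_flashes must be 2 (1-2-Go) or 3 (1-2-3-Go)")
    return float(reproduce_many(params, cfg, t_s, n_flashes, 1, [seed])[0])
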