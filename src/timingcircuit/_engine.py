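"""Vectorized Euler integrators shared by the MPM, SAM and coupled circuit.

All simulators integrate batches of independent trials in lock-step on a
common time grid.  Conventions (identical to the scalar step operations):

* Step ``k`` advances the state from ``t_k = k*dt`` to ``t_{k+1}``; gating
  signals (stimulus ``s``, reset pulse) and the noise row ``k`` apply to that
  advance.  Threshold crossings are recorded at ``t_{k+1}``.
* A stimulus with onset ``m`` sets ``s = 1`` for the advances starting in
  ``[m, m + pulse_dur)``.
* A production detected on advance ``k`` activates the motor reset pulse for
  the following ``pulse_dur / dt`` advances.
* The shared input updates concurrently with the unit advance,
  ``I <- I + (dt/tau) * s * K_eff * (y_s - y0)``, reading the current ``y_s``;
  ``K_eff = 0`` during the first stimulus pulse of a trial.

Per-trial noise is pre-drawn from per-trial generators so that a trial's
realization depends only on its own seed, never on batch composition.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .core_dynamics import CircuitParams

MPM_UNITS = 3  # noise columns: u_p, v_p, y_p
SAM_UNITS = 3  # noise columns: u_s, v_s, y_s
COUPLED_UNITS = 6  # u_p, v_p, y_p, u_s, v_s, y_s


def derive_trial_seeds(master_seed: int, condition: int, n_trials: int,
                       start: int = 0) -> list[np.random.SeedSequence]:
    """Counter-based per-trial seed derivation.

    Trial ``i`` of a condition always receives the same seed sequence for a
    given master seed, so adding trials never changes earlier trials.
    """
    return [
        np.random.SeedSequence(entropy=int(master_seed),
                               spawn_key=(int(condition), start + i))
        for i in range(n_trials)
    ]


def batch_noise(sigma_n: float, n_steps: int, n_units: int,
                seeds: Sequence) -> np.ndarray:
    """Pre-drawn noise, shape ``(n_steps, n_units, n_trials)``.

    ``seeds`` is a sequence of ints or ``SeedSequence`` objects, one per
    trial; each trial's draws come from its own generator in C order
    ``(n_steps, n_units)``, matching the scalar simulators.
    """
    n_trials = len(seeds)
    if sigma_n == 0:
        return np.zeros((n_steps, n_units, n_trials))
    cols = [
        np.random.default_rng(s).normal(0.0, sigma_n, size=(n_steps, n_units))
        for s in seeds
    ]
    return np.stack(cols, axis=-1)


def stim_gate(onsets_ms: np.ndarray, n_steps: int, params: CircuitParams) -> np.ndarray:
    """Boolean gate ``s(k)`` over advances for a train of stimulus onsets."""
    gate = np.zeros(n_steps, dtype=bool)
    k0 = np.rint(np.asarray(onsets_ms, dtype=float) / params.dt).astype(int)
    for k in k0:
        gate[k: k + params.n_pulse_steps] = True
    return gate


def first_pulse_window(onsets_ms: np.ndarray, params: CircuitParams) -> tuple[int, int]:
    """Step-index window ``[lo, hi)`` of the first stimulus pulse."""
    k0 = int(round(float(np.min(onsets_ms)) / params.dt))
    return k0, k0 + params.n_pulse_steps


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise FloatingPointError("non-finite state: numerical divergence")


def run_mpm_batch(params: CircuitParams, I, n_steps: int, eta: np.ndarray,
                  record: bool = False, dI: Optional[np.ndarray] = None):
    """Motor planning module: BCM plus self-reset at each threshold crossing.

    ``I`` is a scalar or per-trial vector of tonic inputs; ``dI`` an optional
    ``(n_steps, n_trials)`` additive input (used for replaying a coupled run).
    Returns ``(productions, trace)`` where ``productions`` is a list of
    per-trial arrays of production times (ms) and ``trace`` is a dict of
    ``(n_steps + 1, n_trials)`` arrays when ``record``.
    """
    p = params
    n_trials = eta.shape[2]
    r = p.dt / p.tau
    u = np.full(n_trials, p.u_init)
    v = np.full(n_trials, p.v_init)
    y = np.full(n_trials, p.y_init)
    I = np.broadcast_to(np.asarray(I, dtype=float), (n_trials,)).copy()
    reset = np.zeros(n_trials, dtype=int)
    prods = [[] for _ in range(n_trials)]
    trace = None
    if record:
        trace = {nm: np.empty((n_steps + 1, n_trials)) for nm in ("u", "v", "y")}
        trace["u"][0], trace["v"][0], trace["y"][0] = u, v, y
    for k in range(n_steps):
        active = reset > 0
        pulse = np.where(active, p.I_p, 0.0)
        reset[active] -= 1
        Itot = I if dI is None else I + dI[k]
        arg_u = p.W_uI * Itot - p.W_uv * v + eta[k, 0] - pulse
        arg_v = p.W_vI * Itot - p.W_vu * u + eta[k, 1] + pulse
        u_new = u + r * (-u + expit(arg_u))
        v_new = v + r * (-v + expit(arg_v))
        y_new = y + r * (-y + p.W_yu * u - p.W_yv * v + eta[k, 2])
        crossed = (y_new >= p.y0) & (y < p.y0)
        u, v, y = u_new, v_new, y_new
        if crossed.any():
            t = (k + 1) * p.dt
            for i in np.nonzero(crossed)[0]:
                prods[i].append(t)
            reset[crossed] = p.n_pulse_steps
        if record:
            trace["u"][k + 1], trace["v"][k + 1], trace["y"][k + 1] = u, v, y
    _check_finite(u, v, y)
    return [np.asarray(t) for t in prods], trace


def run_sam_batch(params: CircuitParams, K: float, I0: float,
                  stim: np.ndarray, eta: np.ndarray,
                  freeze_window: Optional[tuple[int, int]] = None,
                  record: bool = False):
    """Sensory anticipation module with gated input updating.

    ``stim`` is a boolean gate over advances, shape ``(n_steps,)`` (shared) or
    ``(n_trials, n_steps)``.  Returns ``(crossings, I_final, trace)`` where
    ``crossings`` lists, per trial, the times at which ``y_s`` crossed ``y0``
    from below.
    """
    p = params
    n_steps = eta.shape[0]
    n_trials = eta.shape[2]
    shared_stim = stim.ndim == 1
    r = p.dt / p.tau
    u = np.full(n_trials, p.u_init)
    v = np.full(n_trials, p.v_init)
    y = np.full(n_trials, p.y_init)
    I = np.full(n_trials, float(I0))
    crossings = [[] for _ in range(n_trials)]
    trace = None
    if record:
        trace = {nm: np.empty((n_steps + 1, n_trials)) for nm in ("u", "v", "y", "I")}
        for nm, a in (("u", u), ("v", v), ("y", y), ("I", I)):
            trace[nm][0] = a
    for k in range(n_steps):
        s = (1.0 if stim[k] else 0.0) if shared_stim else stim[:, k].astype(float)
        K_eff = K
        if freeze_window is not None and freeze_window[0] <= k < freeze_window[1]:
            K_eff = 0.0
        drive = s * p.I_s
        arg_u = p.W_uI * I - p.W_uv * v + eta[k, 0] - drive
        arg_v = p.W_vI * I - p.W_vu * u + eta[k, 1] + drive
        u_new = u + r * (-u + expit(arg_u))
        v_new = v + r * (-v + expit(arg_v))
        y_new = y + r * (-y + p.W_yu * u - p.W_yv * v + eta[k, 2])
        I = I + r * s * K_eff * (y - p.y0)
        crossed = (y_new >= p.y0) & (y < p.y0)
        u, v, y = u_new, v_new, y_new
        if crossed.any():
            t = (k + 1) * p.dt
            for i in np.nonzero(crossed)[0]:
                crossings[i].append(t)
        if record:
            for nm, a in (("u", u), ("v", v), ("y", y), ("I", I)):
                trace[nm][k + 1] = a
    _check_finite(u, v, y, I)
    return [np.asarray(t) for t in crossings], I, trace


def run_coupled_batch(params: CircuitParams, K: float, I0: float, alpha: float,
                      stim: np.ndarray, eta: np.ndarray,
                      freeze_window: Optional[tuple[int, int]] = None,
                      record: bool = False):
    """Full circuit: SAM and MPM share ``I``; the MPM additionally receives
    the phase-correction signal ``dI = alpha * (y_p - y_s)``.

    The SAM is reset only by stimuli and updates ``I``; the MPM is reset only
    by its own productions.  Returns
    ``(productions, sam_crossings, I_final, trace)``.
    """
    p = params
    n_steps = eta.shape[0]
    n_trials = eta.shape[2]
    shared_stim = stim.ndim == 1
    r = p.dt / p.tau
    up = np.full(n_trials, p.u_init)
    vp = np.full(n_trials, p.v_init)
    yp = np.full(n_trials, p.y_init)
    us = np.full(n_trials, p.u_init)
    vs = np.full(n_trials, p.v_init)
    ys = np.full(n_trials, p.y_init)
    I = np.full(n_trials, float(I0))
    reset = np.zeros(n_trials, dtype=int)
    prods = [[] for _ in range(n_trials)]
    sam_x = [[] for _ in range(n_trials)]
    trace = None
    if record:
        names = ("u_p", "v_p", "y_p", "u_s", "v_s", "y_s", "I", "dI")
        trace = {nm: np.empty((n_steps + 1, n_trials)) for nm in names}
        vals = (up, vp, yp, us, vs, ys, I, alpha * (yp - ys))
        for nm, a in zip(names, vals):
            trace[nm][0] = a
    for k in range(n_steps):
        s = (1.0 if stim[k] else 0.0) if shared_stim else stim[:, k].astype(float)
        K_eff = K
        if freeze_window is not None and freeze_window[0] <= k < freeze_window[1]:
            K_eff = 0.0
        dI = alpha * (yp - ys)
        active = reset > 0
        pulse = np.where(active, p.I_p, 0.0)
        reset[active] -= 1
        Imp = I + dI
        arg_up = p.W_uI * Imp - p.W_uv * vp + eta[k, 0] - pulse
        arg_vp = p.W_vI * Imp - p.W_vu * up + eta[k, 1] + pulse
        up_new = up + r * (-up + expit(arg_up))
        vp_new = vp + r * (-vp + expit(arg_vp))
        yp_new = yp + r * (-yp + p.W_yu * up - p.W_yv * vp + eta[k, 2])
        sdrive = s * p.I_s
        arg_us = p.W_uI * I - p.W_uv * vs + eta[k, 3] - sdrive
        arg_vs = p.W_vI * I - p.W_vu * us + eta[k, 4] + sdrive
        us_new = us + r * (-us + expit(arg_us))
        vs_new = vs + r * (-vs + expit(arg_vs))
        ys_new = ys + r * (-ys + p.W_yu * us - p.W_yv * vs + eta[k, 5])
        I = I + r * s * K_eff * (ys - p.y0)
        crossed_p = (yp_new >= p.y0) & (yp < p.y0)
        crossed_s = (ys_new >= p.y0) & (ys < p.y0)
        up, vp, yp = up_new, vp_new, yp_new
        us, vs, ys = us_new, vs_new, ys_new
        t = (k + 1) * p.dt
        if crossed_p.any():
            for i in np.nonzero(crossed_p)[0]:
                prods[i].append(t)
            reset[crossed_p] = p.n_pulse_steps
        if crossed_s.any():
            for i in np.nonzero(crossed_s)[0]:
                sam_x[i].append(t)
        if record:
            vals = (up, vp, yp, us, vs, ys, I, alpha * (yp - ys))
            for nm, a in zip(("u_p", "v_p", "y_p", "u_s", "v_s", "y_s", "I", "dI"), vals):
                trace[nm][k + 1] = a
    _check_finite(up, vp, yp, us, vs, ys, I)
    return [np.asarray(t) for t in prods], [np.asarray(t) for t in sam_x], I, trace
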