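"""Shared fixtures and the independent fine-step reference integrator.

The reference integrator below is deliberately written from scratch (plain
loops, its own state handling) so it can serve as an oracle for the package's
coarse-step simulators: it integrates the same rate equations at a 100x finer
Euler step and supports reset/stimulus pulse schedules in absolute time.
"""

import math

import numpy as np
import pytest

from timingcircuit.core_dynamics import CircuitParams


@pytest.fixture
def params():
    return CircuitParams()


@pytest.fixture
def quiet(params):
    """Zero-noise parameters."""
    return params.with_(sigma_n=0.0)


def ref_sigmoid(x):
    if x > 500:
        return 1.0
    if x < -500:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def reference_bcm(I, duration, dt=0.1, tau=100.0, w=6.0, wy=1.0,
                  u0=0.7, v0=0.2, y0_init=0.5, y_thresh=0.7,
                  pulse_schedule=(), pulse_amp=50.0,
                  update_gate=(), K=0.0, y_ref=0.7):
    """Fine-step Euler reference for the three-unit module.

    ``pulse_schedule`` lists (t_on, t_off) windows (ms) during which a pulse
    of ``pulse_amp`` is subtracted from u's sigmoid argument and added to
    v's.  ``update_gate`` lists windows during which the tonic input
    integrates ``K * (y - y_ref) / tau`` (the anticipation-error update).
    Returns (times, u, v, y, I_trace, first crossing time of y >= y_thresh).
    """
    n = int(round(duration / dt))
    u, v, y = u0, v0, y0_init
    I_cur = I
    times = np.arange(n + 1) * dt
    traj = np.empty((n + 1, 4))
    traj[0] = (u, v, y, I_cur)
    crossing = None
    for k in range(n):
        t = k * dt
        pulse = pulse_amp if any(a <= t < b for a, b in pulse_schedule) else 0.0
        gated = any(a <= t < b for a, b in update_gate)
        du = (-u + ref_sigmoid(w * I_cur - w * v - pulse)) / tau
        dv = (-v + ref_sigmoid(w * I_cur - w * u + pulse)) / tau
        dy = (-y + wy * u - wy * v) / tau
        dI = (K * (y - y_ref) / tau) if gated else 0.0
        u, v, y = u + dt * du, v + dt * dv, y + dt * dy
        I_cur = I_cur + dt * dI
        if crossing is None and y >= y_thresh and traj[k, 2] < y_thresh:
            crossing = times[k + 1]
        traj[k + 1] = (u, v, y, I_cur)
    return times, traj[:, 0], traj[:, 1], traj[:, 2], traj[:, 3], crossing
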