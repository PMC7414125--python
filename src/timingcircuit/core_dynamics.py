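"""Basic circuit module (BCM): three rate units integrated with forward Euler.

The BCM is a pair of mutually inhibitory rate units, ``u`` and ``v``, that
share a tonic input ``I`` and drive an output unit ``y`` with excitatory and
inhibitory connections respectively.  With symmetric weights the system has a
saddle at ``u = v`` and two stable fixed points; started from a ``u``-dominant
state, ``y`` ramps toward the ``u``-dominant fixed point at a speed set by
``I``, and an action is triggered when ``y`` crosses a fixed threshold ``y0``.
Larger inputs place the fixed point closer to the threshold, which slows the
ramp and lengthens the produced interval.

Dynamics (all units share the time constant ``tau``)::

    tau du/dt = -u + sigmoid(W_uI*I - W_uv*v + eta_u)
    tau dv/dt = -v + sigmoid(W_vI*I - W_vu*u + eta_v)
    tau dy/dt = -y + W_yu*u - W_yv*v + eta_y

``eta_*`` are independent zero-mean Gaussian noise samples, drawn per unit at
every integration step with standard deviation ``sigma_n``.  Integration is
synchronous forward Euler with step ``dt``: all derivatives are evaluated at
the current state, then all units advance together.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CircuitParams",
    "UnitState",
    "SimTrace",
    "sigmoid",
    "draw_noise",
    "step_bcm",
    "simulate_bcm",
]


def sigmoid(x):
    """Logistic activation ``1 / (1 + exp(-x))``; saturates smoothly at 0/1."""
    return expit(x)


@dataclass(frozen=True)
class CircuitParams:
    """All weights, time constants, amplitudes and integration settings.

    Times are in milliseconds; weights, activities and noise are
    dimensionless.  Defaults are the reference values used throughout:
    symmetric input and inhibition weights of 6, unit output weights,
    ``tau`` = 100 ms, threshold ``y0`` = 0.7 and reset/stimulus pulse
    amplitudes of 50 (which saturate the sigmoid arguments).
    """

    tau: float = 100.0
    W_uI: float = 6.0
    W_vI: float = 6.0
    W_uv: float = 6.0
    W_vu: float = 6.0
    W_yu: float = 1.0
    W_yv: float = 1.0
    y0: float = 0.7
    I_p: float = 50.0
    I_s: float = 50.0
    sigma_n: float = 0.0
    dt: float = 10.0
    pulse_dur: float = 10.0
    u_init: float = 0.7
    v_init: float = 0.2
    y_init: float = 0.5
    run_in: float = 750.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.tau:
            raise ValueError("dt must not exceed tau")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be non-negative")
        if not (0.0 < self.y0 < 1.0):
            raise ValueError("y0 must lie in (0, 1)")
        if self.pulse_dur < self.dt:
            raise ValueError("pulse_dur must be at least one integration step")
        if self.sigma_n > 0 and self.dt != 10.0:
            # sigma_n is the per-step SD at the reference 10 ms step; there is
            # no sqrt(dt) rescaling, so changing dt changes the noise process.
            warnings.warn(
                "sigma_n is defined per 10 ms step; with dt = "
                f"{self.dt} ms the effective noise process differs",
                stacklevel=2,
            )

    @property
    def n_pulse_steps(self) -> int:
        return max(1, int(round(self.pulse_dur / self.dt)))

    def with_(self, **kw) -> "CircuitParams":
        return replace(self, **kw)

    def initial_state(self, I: float) -> "UnitState":
        return UnitState(u=self.u_init, v=self.v_init, y=self.y_init, I=I)


@dataclass
class UnitState:
    """Instantaneous activities of one module plus its tonic input level."""

    u: float
    v: float
    y: float
    I: float = 0.0

    def check_finite(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v) and np.isfinite(self.y)):
            raise FloatingPointError(
                f"non-finite unit state (u={self.u}, v={self.v}, y={self.y}): "
                "numerical divergence"
            )


@dataclass
class SimTrace:
    """Time-indexed record of unit activities and labelled events."""

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    y: np.ndarray
    I: np.ndarray
    dI: np.ndarray
    events: list = field(default_factory=list)  # (time_ms, label)

    def __post_init__(self):
        n = len(self.times)
        for name in ("u", "v", "y", "I", "dI"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace vector {name!r} length mismatch")

    def to_frame(self) -> pd.DataFrame:
        ev = {t: lab for t, lab in self.events}
        return pd.DataFrame(
            {
                "time_ms": self.times,
                "u": self.u,
                "v": self.v,
                "y": self.y,
                "I": self.I,
                "dI": self.dI,
                "event": [ev.get(t, "") for t in self.times],
            }
        )

    def write_csv(self, path, metadata: Optional[dict] = None) -> None:
        """Write the trace as CSV with a JSON sidecar holding run metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(metadata, indent=2, default=str))


def draw_noise(sigma_n: float, n_units: int, rng: np.random.Generator,
               n_steps: Optional[int] = None) -> np.ndarray:
    """I.i.d. Gaussian(0, sigma_n) draws, one per unit (and per step).

    Returns shape ``(n_units,)`` or ``(n_steps, n_units)``.  ``sigma_n = 0``
    returns exact zeros without consuming random state.
    """
    if sigma_n < 0:
        raise ValueError("sigma_n must be non-negative")
    shape = (n_units,) if n_steps is None else (n_steps, n_units)
    if sigma_n == 0:
        return np.zeros(shape)
    return rng.normal(0.0, sigma_n, size=shape)


def step_bcm(state: UnitState, params: CircuitParams,
             noise: Sequence[float] = (0.0, 0.0, 0.0),
             extra_u: float = 0.0, extra_v: float = 0.0) -> UnitState:
    """One synchronous Euler step of the BCM.

    ``extra_u``/``extra_v`` are signed additive drives inside the sigmoid
    arguments of ``u`` and ``v`` (used for reset and stimulus pulses; zero for
    the plain BCM).  ``noise`` is ``(eta_u, eta_v, eta_y)``: the first two
    enter inside their sigmoid arguments, the third adds linearly to the
    drive of ``y``.
    """
    state.check_finite()
    eta_u, eta_v, eta_y = noise
    p = params
    r = p.dt / p.tau
    arg_u = p.W_uI * state.I - p.W_uv * state.v + eta_u + extra_u
    arg_v = p.W_vI * state.I - p.W_vu * state.u + eta_v + extra_v
    u_new = state.u + r * (-state.u + float(expit(arg_u)))
    v_new = state.v + r * (-state.v + float(expit(arg_v)))
    y_new = state.y + r * (-state.y + p.W_yu * state.u - p.W_yv * state.v + eta_y)
    return UnitState(u=u_new, v=v_new, y=y_new, I=state.I)


def simulate_bcm(params: CircuitParams, I: float, duration: float,
                 seed: Optional[int] = None):
    """Integrate the BCM from its initial conditions for ``duration`` ms.

    Returns ``(trace, first_crossing_time)`` where the crossing is the first
    step time at which ``y >= y0`` with ``y < y0`` at the previous step, or
    ``None`` if no crossing occurs within ``duration``.
    """
    if duration < params.dt:
        raise ValueError("duration must be at least one step")
    n_steps = int(duration / params.dt)
    rng = np.random.default_rng(seed)
    eta = draw_noise(params.sigma_n, 3, rng, n_steps)
    state = params.initial_state(I)
    times = np.arange(n_steps + 1) * params.dt
    tr_u = np.empty(n_steps + 1)
    tr_v = np.empty(n_steps + 1)
    tr_y = np.empty(n_steps + 1)
    tr_u[0], tr_v[0], tr_y[0] = state.u, state.v, state.y
    first_crossing = None
    events = []
    for k in range(n_steps):
        new = step_bcm(state, params, noise=eta[k])
        if first_crossing is None and new.y >= params.y0 and state.y < params.y0:
            first_crossing = times[k + 1]
            events.append((first_crossing, "threshold"))
        state = new
        tr_u[k + 1], tr_v[k + 1], tr_y[k + 1] = state.u, state.v, state.y
    trace = SimTrace(
        times=times, u=tr_u, v=tr_v, y=tr_y,
        I=np.full(n_steps + 1, I), dI=np.zeros(n_steps + 1), events=events,
    )
    return trace, first_crossing
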