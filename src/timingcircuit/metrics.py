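"""Behavioral statistics: asynchrony/phase, RMSE, BIAS/VAR decompositions,
Pythagorean error, circular statistics and regression summaries.

Conventions
-----------
* Asynchrony ``a_n = t_n - m_n`` pairs each stimulus ``m_n`` with the
  production closest in time (ties broken toward the earlier production);
  negative values mean the action led the stimulus.
* Phase ``phi_n = 360 * a_n / ISI_n`` (degrees), wrapped to ``[-180, 180)``.
* BIAS^2 is the mean squared deviation of the per-condition mean response
  from its target; VAR is the mean per-condition variance (ddof = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pingouin as pg
from scipy import stats

__all__ = [
    "SyncMetrics",
    "asynchrony_and_phase",
    "rmse",
    "bias_var",
    "bias_by_index",
    "pythagorean_error",
    "rayleigh_test",
    "linear_fit_r2",
    "wrap_phase_deg",
    "circular_mean_deg",
    "circular_sd_deg",
]


def wrap_phase_deg(phi) -> np.ndarray:
    """Wrap phases (degrees) to the interval [-180, 180)."""
    return (np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class SyncMetrics:
    """Per-stimulus synchronization measures for one production/stimulus run."""

    asynchronies: np.ndarray      # a_n, ms
    phases: np.ndarray            # phi_n, degrees in [-180, 180)
    matched_production: np.ndarray  # index of the production matched to m_n
    n_shared_matches: int         # stimuli sharing a production (skipped beats)


def asynchrony_and_phase(production_times, stimulus_onsets) -> SyncMetrics:
    """Match each stimulus to its closest production and compute a_n, phi_n.

    Phases are defined for the stimuli that open an inter-stimulus interval
    (all but the last onset), each normalized by its own ISI.  Multiple
    stimuli may match the same production (skipped beats); the count is
    reported.
    """
    prods = np.asarray(production_times, dtype=float)
    stims = np.asarray(stimulus_onsets, dtype=float)
    if len(prods) == 0 or len(stims) < 2:
        raise ValueError("need at least one production and two stimuli")
    isis = np.diff(stims)
    m = stims[:-1]
    # nearest production per stimulus; ties toward the earlier production
    idx = np.searchsorted(prods, m)
    lo = np.clip(idx - 1, 0, len(prods) - 1)
    hi = np.clip(idx, 0, len(prods) - 1)
    pick = np.where(np.abs(prods[lo] - m) <= np.abs(prods[hi] - m), lo, hi)
    a = prods[pick] - m
    phi = wrap_phase_deg(360.0 * a / isis)
    shared = len(pick) - len(np.unique(pick))
    return SyncMetrics(asynchronies=a, phases=phi, matched_production=pick,
                       n_shared_matches=int(shared))


def rmse(ipis, isis) -> float:
    """Root-mean-squared error between produced and stimulus intervals."""
    ipis = np.asarray(ipis, dtype=float)
    isis = np.asarray(isis, dtype=float)
    if ipis.shape != isis.shape:
        raise ValueError("ipis and isis must have equal length")
    return float(np.sqrt(np.mean((ipis - isis) ** 2)))


def bias_var(tp_by_ts: Mapping[float, np.ndarray]) -> tuple[float, float]:
    """BIAS^2 and VAR of produced intervals across target conditions.

    ``tp_by_ts`` maps each target interval to its sample of productions.
    BIAS^2 averages the squared deviation of the conditional mean from the
    target; VAR averages the conditional variance (ddof = 1; conditions with
    a single sample contribute zero variance).
    """
    bias2 = 0.0
    var = 0.0
    n = len(tp_by_ts)
    if n == 0:
        raise ValueError("empty condition table")
    for ts, tp in tp_by_ts.items():
        tp = np.asarray(tp, dtype=float)
        tp = tp[~np.isnan(tp)]
        if len(tp) == 0:
            raise ValueError(f"no productions for target {ts}")
        bias2 += (tp.mean() - ts) ** 2
        var += tp.var(ddof=1) if len(tp) > 1 else 0.0
    return bias2 / n, var / n


def bias_by_index(ipis_by_isi: Mapping[float, np.ndarray], k: int) -> float:
    """Squared bias of the k-th produced interval across ISI conditions.

    ``ipis_by_isi`` maps each ISI to an array of shape ``(n_trials,
    n_intervals)`` (NaN-padded).  Returns ``BIAS_k^2``, the mean over ISIs of
    the squared deviation of the mean k-th IPI (0-based ``k``) from the ISI.
    """
    if not ipis_by_isi:
        raise ValueError("empty condition table")
    total = 0.0
    for isi, table in ipis_by_isi.items():
        table = np.atleast_2d(np.asarray(table, dtype=float))
        col = table[:, k]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            raise ValueError(f"no IPIs at index {k} for ISI {isi}")
        total += (col.mean() - isi) ** 2
    return total / len(ipis_by_isi)


def pythagorean_error(ipi_err: float, asynchrony: float) -> float:
    """Combined timing error, ``sqrt((IPI - ISI)^2 + asynchrony^2)``."""
    return float(np.hypot(ipi_err, asynchrony))


def circular_mean_deg(phases_deg) -> float:
    """Circular mean of phases (degrees), in [-180, 180)."""
    rad = np.radians(np.asarray(phases_deg, dtype=float))
    return float(wrap_phase_deg(np.degrees(
        np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))))


def circular_sd_deg(phases_deg) -> float:
    """Circular standard deviation, ``sqrt(-2 ln R)``, in degrees."""
    rad = np.radians(np.asarray(phases_deg, dtype=float))
    R = float(np.hypot(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    if R <= 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(min(R, 1.0)))))


def rayleigh_test(phases_deg):
    """Rayleigh test of circular uniformity on wrapped phases (degrees).

    Returns ``(Rbar, p, mean_deg, sd_deg)``: the mean resultant length, the
    test p-value, and the circular mean and SD used for "mean ± SD" style
    summaries.  Requires at least five phases.
    """
    phases = np.asarray(phases_deg, dtype=float)
    if len(phases) < 5:
        raise ValueError("need at least 5 phases for the Rayleigh test")
    rad = np.radians(wrap_phase_deg(phases))
    Rbar = float(pg.circ_r(rad))
    _, p = pg.circ_rayleigh(rad)
    return Rbar, float(p), circular_mean_deg(phases), circular_sd_deg(phases)


def linear_fit_r2(x, y):
    """Ordinary least-squares line fit with r^2 and the regression F test.

    Returns ``(slope, intercept, r2, F, p)``.  A constant response gives
    ``r2 = 0`` with an undefined (NaN) F.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched x/y with at least 3 points")
    if np.allclose(y, y[0]):
        slope, intercept = 0.0, float(y[0])
        return slope, intercept, 0.0, float("nan"), 1.0
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    dof = len(x) - 2
    F = r2 / (1 - r2) * dof if r2 < 1 else float("inf")
    return (float(res.slope), float(res.intercept), float(r2), float(F),
            float(res.pvalue))
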