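"""Random-search parameter fitting for the circuit model.

Three procedures:

* :func:`optimize_sam` — grid-free random search over (K, I0) minimizing the
  RMSE between the SAM's predicted interval and the stimulus ISI, repeated to
  yield a distribution of optima per noise level and stimulus count.
* :func:`fit_reproduction` — alternating fit to per-condition (mean, SD)
  summaries of produced intervals: a sigma_n step matching the SDs, then a
  joint (I0, K) step matching the means, each by uniform random sampling with
  the incumbent always included (so a step can never worsen its objective).
* :func:`fit_sync_cont` — single random search over (K, I0, alpha) minimizing
  the mean squared error between BIAS_k curves.

All searches use common random numbers across the candidates of a step:
every candidate is evaluated on the same derived trial seeds, which makes the
objective a deterministic function of the candidate within a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _engine
from .core_dynamics import CircuitParams
from .metrics import rmse
from .sam import SamConfig, reproduce_many
from .tasks import run_sync_cont, run_reproduction, reproduction_summary, bias_curve

__all__ = ["FitResult", "optimize_sam", "fit_reproduction", "fit_sync_cont",
           "anticipated_ts"]

#: Sampling ranges of the reproduction fit.
REPRO_RANGES = {"K": (1.0, 8.0), "I0": (0.77, 0.79), "sigma_n": (0.005, 0.4)}
#: Sampling ranges of the synchronization/continuation fit.
SYNC_RANGES = {"K": (0.01, 5.0), "I0": (0.76, 0.78), "alpha": (0.01, 0.1)}
#: ISI grid for SAM optimization (discrete uniform, five values).
SAM_OPT_ISIS = (600.0, 700.0, 800.0, 900.0, 1000.0)


@dataclass
class FitResult:
    """Outcome of a random search: best parameters and the full sample trace."""

    best_params: dict
    objective: float
    candidates: pd.DataFrame
    history: list = field(default_factory=list)  # (step label, best objective)
    seed: Optional[int] = None
    n_samples: int = 0


def _sam_rmse(params: CircuitParams, K: float, I0: float, isis: np.ndarray,
              n_flashes: int, trial_seeds) -> float:
    """RMSE between the predicted interval after the final flash and the ISI."""
    p = params
    errs = []
    for isi in np.unique(isis):
        idx = np.nonzero(isis == isi)[0]
        tp = reproduce_many(p, SamConfig(K=K, I0=I0), float(isi), n_flashes,
                            len(idx), [trial_seeds[i] for i in idx])
        ok = ~np.isnan(tp)
        errs.append(tp[ok] - isi)
    err = np.concatenate(errs)
    if len(err) == 0:
        return float("inf")
    return rmse(err, np.zeros_like(err))


def optimize_sam(sigma_n: float, N_stimuli: int, n_pairs: int = 100,
                 n_repeats: int = 10, n_sim: int = 500, seed: int = 0,
                 params: Optional[CircuitParams] = None,
                 isi_grid=SAM_OPT_ISIS) -> FitResult:
    """Distribution of optimal (K*, I0*) for a noise level and stimulus count.

    Per repeat, ``n_pairs`` candidates with K ~ U[1, 8] and I0 ~ U[0.77,
    0.79] are each evaluated on the same ``n_sim`` simulated runs (ISI drawn
    from the five-value 600-1000 ms grid, ``N_stimuli`` flashes) and the RMSE
    minimizer is recorded.  ``best_params`` holds the mean and SD of the
    optima across repeats.
    """
    if not (2 <= N_stimuli <= 10):
        raise ValueError("N_stimuli must be in 2..10")
    params = (params or CircuitParams()).with_(sigma_n=sigma_n)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(101,)))
    rows = []
    optima = []
    for rep in range(n_repeats):
        Ks = rng.uniform(*REPRO_RANGES["K"], size=n_pairs)
        I0s = rng.uniform(*REPRO_RANGES["I0"], size=n_pairs)
        isis = rng.choice(isi_grid, size=n_sim)
        trial_seeds = _engine.derive_trial_seeds(seed, 1000 + rep, n_sim)
        objs = np.array([
            _sam_rmse(params, Ks[i], I0s[i], isis, N_stimuli, trial_seeds)
            for i in range(n_pairs)
        ])
        best = int(np.argmin(objs))
        optima.append((Ks[best], I0s[best], objs[best]))
        for i in range(n_pairs):
            rows.append({"repeat": rep, "K": Ks[i], "I0": I0s[i],
                         "objective": objs[i]})
    optima = np.array(optima)
    best_params = {
        "K_star_mean": float(optima[:, 0].mean()),
        "K_star_sd": float(optima[:, 0].std(ddof=1)) if n_repeats > 1 else 0.0,
        "I0_star_mean": float(optima[:, 1].mean()),
        "I0_star_sd": float(optima[:, 1].std(ddof=1)) if n_repeats > 1 else 0.0,
        "sigma_n": sigma_n, "N_stimuli": N_stimuli,
    }
    return FitResult(best_params=best_params,
                     objective=float(optima[:, 2].mean()),
                     candidates=pd.DataFrame(rows),
                     history=[(f"repeat{r}", float(o)) for r, o in
                              enumerate(optima[:, 2])],
                     seed=seed, n_samples=n_pairs * n_repeats)


def _model_summary(K: float, I0: float, sigma_n: float, n_trials: int,
                   seed: int, params: Optional[CircuitParams]) -> pd.DataFrame:
    res = run_reproduction(params=params, K=K, I0=I0, sigma_n=sigma_n,
                           task="both", n_trials=n_trials, seed=seed)
    return reproduction_summary(res)


def fit_reproduction(subject_summary: pd.DataFrame, n_samples: int = 100,
                     seed: int = 0, n_alternations: int = 5,
                     n_trials_per_cond: int = 100,
                     params: Optional[CircuitParams] = None,
                     rel_tol: float = 0.01) -> FitResult:
    """Alternating random-search fit to 10 (mean, SD) reproduction conditions.

    ``subject_summary`` needs columns ``task`` (12go/123go), ``t_s_ms``,
    ``mean_tp_ms``, ``sd_tp_ms`` — one row per condition.  Each alternation
    first fits sigma_n to the SDs (means-parameters fixed), then (I0, K)
    jointly to the means (sigma_n fixed); both steps sample uniformly within
    the standard ranges and always include the incumbent.  Stops early when
    the mean-objective improves by less than ``rel_tol``.
    """
    required = {"task", "t_s_ms", "mean_tp_ms", "sd_tp_ms"}
    if not required.issubset(subject_summary.columns):
        raise ValueError(f"subject summary must have columns {sorted(required)}")
    if len(subject_summary) != 10:
        raise ValueError("expected 10 condition rows (5 t_s x 2 tasks)")
    subj = subject_summary.sort_values(["task", "t_s_ms"]).reset_index(drop=True)

    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(202,)))
    cur = {"K": 4.5, "I0": 0.78, "sigma_n": 0.1}  # range midpoints
    rows = []
    history = []
    last_mu_obj = np.inf

    def objectives(K, I0, sig, step_seed):
        mod = _model_summary(K, I0, sig, n_trials_per_cond, step_seed, params)
        mod = mod.sort_values(["task", "t_s_ms"]).reset_index(drop=True)
        d_sd = np.nansum((mod["sd_tp_ms"].to_numpy()
                          - subj["sd_tp_ms"].to_numpy()) ** 2)
        d_mu = np.nansum((mod["mean_tp_ms"].to_numpy()
                          - subj["mean_tp_ms"].to_numpy()) ** 2)
        return float(d_sd), float(d_mu)

    for it in range(n_alternations):
        # --- sigma_n step: match the SDs, (I0, K) fixed at incumbent
        sig_c = np.append(rng.uniform(*REPRO_RANGES["sigma_n"], n_samples),
                          cur["sigma_n"])
        objs = [objectives(cur["K"], cur["I0"], s, seed + 7919 * it)[0]
                for s in sig_c]
        b = int(np.argmin(objs))
        cur["sigma_n"] = float(sig_c[b])
        history.append((f"iter{it}:sigma_n", float(objs[b])))
        for s, o in zip(sig_c, objs):
            rows.append({"iter": it, "step": "sigma_n", "K": cur["K"],
                         "I0": cur["I0"], "sigma_n": s, "objective": o})
        # --- (I0, K) step: match the means, sigma_n fixed
        K_c = np.append(rng.uniform(*REPRO_RANGES["K"], n_samples), cur["K"])
        I_c = np.append(rng.uniform(*REPRO_RANGES["I0"], n_samples), cur["I0"])
        objs = [objectives(K_c[i], I_c[i], cur["sigma_n"],
                           seed + 7919 * it + 1)[1]
                for i in range(len(K_c))]
        b = int(np.argmin(objs))
        cur["K"], cur["I0"] = float(K_c[b]), float(I_c[b])
        mu_obj = float(objs[b])
        history.append((f"iter{it}:I0_K", mu_obj))
        for i in range(len(K_c)):
            rows.append({"iter": it, "step": "I0_K", "K": K_c[i], "I0": I_c[i],
                         "sigma_n": cur["sigma_n"], "objective": objs[i]})
        if last_mu_obj < np.inf and mu_obj > (1 - rel_tol) * last_mu_obj:
            break
        last_mu_obj = mu_obj

    return FitResult(best_params=dict(cur), objective=history[-1][1],
                     candidates=pd.DataFrame(rows), history=history,
                     seed=seed, n_samples=n_samples)


def fit_sync_cont(subject_bias_curve: pd.DataFrame, n_samples: int = 100,
                  seed: int = 0, n_trials_per_isi: int = 21,
                  sigma_n: float = 0.01,
                  params: Optional[CircuitParams] = None) -> FitResult:
    """Random-search fit of (K, I0, alpha) to a BIAS_k curve.

    ``subject_bias_curve`` needs columns ``k`` and ``bias_ms``.  Each of the
    ``n_samples`` candidates is evaluated by simulating the full
    synchronization/continuation protocol and comparing BIAS_k across the
    shared range of k (mean squared error).
    """
    if not {"k", "bias_ms"}.issubset(subject_bias_curve.columns):
        raise ValueError("bias curve must have columns k, bias_ms")
    subj = subject_bias_curve.sort_values("k")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(303,)))
    Ks = rng.uniform(*SYNC_RANGES["K"], size=n_samples)
    I0s = rng.uniform(*SYNC_RANGES["I0"], size=n_samples)
    alphas = rng.uniform(*SYNC_RANGES["alpha"], size=n_samples)
    rows = []
    for i in range(n_samples):
        res = run_sync_cont(params=params, K=Ks[i], I0=I0s[i], alpha=alphas[i],
                            sigma_n=sigma_n, n_trials_per_isi=n_trials_per_isi,
                            seed=seed + 4099)
        model = bias_curve(res)
        merged = subj.merge(model, on="k", suffixes=("_subj", "_model"))
        if len(merged) == 0:
            obj = float("inf")
        else:
            obj = float(np.mean((merged["bias_ms_subj"]
                                 - merged["bias_ms_model"]) ** 2))
        rows.append({"K": Ks[i], "I0": I0s[i], "alpha": alphas[i],
                     "objective": obj})
    cand = pd.DataFrame(rows)
    b = int(cand["objective"].idxmin())
    best = {"K": float(cand.loc[b, "K"]), "I0": float(cand.loc[b, "I0"]),
            "alpha": float(cand.loc[b, "alpha"]), "sigma_n": sigma_n}
    return FitResult(best_params=best,
                     objective=float(cand.loc[b, "objective"]),
                     candidates=cand, history=[("search", float(
                         cand.loc[b, "objective"]))],
                     seed=seed, n_samples=n_samples)


def anticipated_ts(I0: float, sigma_n: float = 0.0,
                   params: Optional[CircuitParams] = None,
                   seed: Optional[int] = None,
                   guard_ms: float = 3000.0) -> float:
    """Interval the SAM anticipates before any update, given ``I0``.

    A single stimulus is presented after the run-in and the interval to the
    next upward ``y_s`` crossing of ``y0`` is returned (NaN if none occurs
    within ``guard_ms``).  Slower dynamics (larger ``I0``) lengthen it.
    """
    params = (params or CircuitParams()).with_(sigma_n=sigma_n)
    cfg = SamConfig(K=0.0, I0=I0)
    tp = reproduce_many(params, cfg, guard_ms / 3.0, 1, 1, [seed])
    return float(tp[0])
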