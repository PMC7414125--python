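# Methods

This note records the modeling, numerical and analysis conventions the
package commits to, the choices that were genuinely open, and what the test
suite does and does not establish.

## Dynamics and integration

All modules integrate the three-unit rate equations with synchronous forward
Euler at `dt` = 10 ms: every derivative is evaluated at the current state,
then all units advance together.  The 10 ms step is part of the model's
definition, not an approximation to be refined — behavioral quantities are
reported at this resolution — but the test suite still checks the scheme
against an independent dt = 0.1 ms integrator: zero-noise trajectories agree
to better than 1e-3 per unit, and threshold-crossing times of the ramp
(single interval, post-reset regrow, post-stimulus regrow) agree within one
coarse step.  Quantities downstream of the gated input update inherit an
O(dt) offset (≈2e-3 on the updated input after three stimuli), which
compounds into tens of milliseconds of crossing-time difference; this is an
inherent property of the coarse scheme, so those comparisons are asserted at
the measured discretization level rather than at the fine integrator's.

Noise.  `σ_n` is the standard deviation of the Gaussian input drawn
independently per unit *per 10 ms step* (no √dt scaling).  Changing `dt`
with `σ_n > 0` therefore changes the effective noise process; the parameter
container warns when this is attempted.  `η_u`, `η_v` enter inside their
units' sigmoid arguments; `η_y` adds linearly to the output unit's drive.
The shared input `I` carries no noise of its own.

Thresholds and events.  A crossing is registered when `y ≥ y₀` with
`y < y₀` at the previous step, timestamped at the step time.  The motor
reset pulse (amplitude 50, one pulse duration) starts on the step *after*
the crossing; the production time is the crossing step itself.  `y_p` is
never reset directly — its rapid drop is emergent from the `u_p`/`v_p`
reset.  Stimulus pulses last 10 ms (one step); the input update
`I ← I + (dt/τ)·s·K·(y_s − y₀)` runs concurrently with the unit advance and
is frozen (`K_eff = 0`) during the first stimulus of a trial, since no
interval has yet been demarcated.  The phase-correction signal
`ΔI = α(y_p − y_s)` is recomputed each step from the current outputs
(memoryless) and enters the motor module's drive through the same input
weights, i.e. as `W_uI·(I + ΔI)`; its temporally integrated effect arises
through the module state.  Unit values are never clamped; non-finite states
raise instead of being silently clipped.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| τ | 100 ms | time constant of every unit |
| W_uI, W_vI, W_uv, W_vu | 6 | input and mutual-inhibition weights |
| W_yu, W_yv | 1 | output weights |
| y₀ | 0.7 | action/anticipation threshold |
| I_p, I_s | 50 | reset / stimulus pulse amplitude (saturating) |
| dt, pulse | 10 ms | Euler step and pulse duration |
| u, v, y init | 0.7, 0.2, 0.5 | u-dominant initial state |
| run-in | 750 ms | settling time before the first stimulus |

Protocol-level defaults follow the reference task battery: periodic
production at I ∈ {0.75…0.78}, σ_n = 0.01, 40 s per level; tracking with
K = 2, I₀ = 0.771, σ_n = 0.01, α ∈ {0, 0.1}, five 20-interval blocks (the
first fixed at 800 ms, later blocks drawn from {600, 700, 800, 900} ms);
perturbations with 30 pre-perturbation intervals, σ_n = 0.005, 1000 trials;
reproduction with 100 trials per sample interval in {600…1000} ms;
synchronization/continuation with three flashes on the
{550, 617, 683, 750, 817} ms grid (the evenly spaced 5-point grid between
the stated 550 ms minimum and 817 ms maximum; intermediate values are
configurable), 17 continuation productions, 21 trials per ISI.

A note on I₀ = 0.771: with these equations the isolated motor module
produces ≈730 ms intervals at that input (consistent with the four-level
periodic-production results), not 800 ms.  In the tracking tasks this is
immaterial — the anticipation module drives `I` to the ISI-appropriate value
within the warm-up block regardless of `I₀`.

## Analysis conventions

* IPI_n = t_{n+1} − t_n over production times; ISI_n likewise over onsets.
  Tracking pairs the n-th IPI with the n-th ISI (index pairing).
* Asynchrony a_n = t_n − m_n matches each stimulus to the *closest*
  production, ties toward the earlier one; several stimuli may share a
  production (skipped beats are counted).  Phase φ_n = 360·a_n/ISI_n,
  wrapped to [−180°, 180°).
* Tracking-task phase statistics are computed over the randomized blocks
  (intervals 21–100): the fixed 800 ms first block initializes the circuit
  and would otherwise imprint a common startup phase on every trial.
* The Rayleigh test assumes independent samples, but successive phases in a
  run are strongly autocorrelated (the phase performs a slow walk).  Where a
  uniformity *decision* is needed the suite tests decorrelated samples (one
  phase per randomized block per run); resultant lengths and circular means
  are reported from the full pooled set.  Circular SD is √(−2 ln R̄).
* The tracking r² is the within-run regression of IPI on ISI averaged over
  runs (each run contributes 100 interval pairs); the pooled-regression
  variant concentrates ≈0.08 higher because between-run variance partially
  averages out, and both are available from the same tidy output.
* BIAS² averages the squared deviation of the conditional mean from its
  target; VAR averages conditional variances with ddof = 1.  BIAS_k indexes
  produced intervals within synchronization/continuation runs, counting from
  the first production after (first flash − ISI/2); with three flashes,
  k ≤ 3 intervals are produced under stimulation, so synchronization bias is
  read at k = 3 and continuation bias at k = 7.
* Perturbation curves align trials on the first displaced stimulus onset and
  subtract the mean pre-perturbation asynchrony.
* Interval reproduction defines t_p as the time from the final flash onset
  to the next upward `y_s` crossing, with a guard window of 3·t_s (missing
  crossings are recorded as NaN and counted, mirroring the discard rule used
  for human responses).

## Fitting

All fits are seeded uniform random searches (the procedure the reference
protocols prescribe), with two package-level commitments: the incumbent
parameter set is always included among a step's candidates, so a step's
objective can never exceed the incumbent's; and all candidates within a step
are evaluated with common random numbers (the same derived trial seeds),
making the objective a deterministic function of the candidate within the
step.  The reproduction fit alternates a σ_n step (matching the ten
per-condition SDs) with a joint (I₀, K) step (matching the ten means),
initialized at the range midpoints, for up to five alternations or until the
mean objective improves by <1%.  The number of alternations is not
externally prescribed; five with early stopping was chosen so the
self-consistency recovery tests converge with margin.  The
synchronization/continuation fit is a single search over (K, I₀, α) against
a BIAS_k curve (mean squared error over the shared k range).  Parameter
recovery on synthetic subject summaries recovers σ_n within ±0.01, K within
±1, and (K, I₀, α) within the search resolution at 40–60 samples.

## Synthetic subjects

`io.generate_fixture_subject` creates subject summaries by running the
generating model itself (circuit or linear baseline) at known parameters —
10 (mean, SD) reproduction conditions or a BIAS_k curve — with the ground
truth stored alongside.  These fixtures emulate the *format* and statistical
character of human summary data, not human data itself: they contain no
lapse trials, no motor delay, no session drift, and their noise is exactly
the model's.  Passing recovery tests therefore demonstrates internal
consistency of the fitting machinery, not that the model fits people.

## Reference-configuration choices

Two places needed a configuration the protocols leave open.  (1) The
Bayesian-reproduction property tests use K = 5, I₀ = 0.78, σ_n = 0.02 — the
moderate-noise, moderate-gain regime in which the anticipation module's
demonstration figures operate.  At low gain/high noise (e.g. K = 2,
σ_n = 0.05) the 1-2-Go response collapses onto the prior (a flat mean-t_p
curve): a genuine model regime, but one where monotonicity cannot be
asserted.  Because the top of the 1-2-Go curve saturates (the `y_s` error
signal compresses for long intervals), monotonicity of the condition means
is tested at 1000 trials per condition.  (2) The synchronization/
continuation demonstrations use α = 0.05, the middle of the fitting range.

## Problem sizes

Test and acceptance runs use the full protocol sizes where they are cheap
(periodic production, tracking, reproduction) and scaled-down sizes chosen
for the package's CI budget elsewhere: 200 perturbation trials (vs 1000),
20 candidate pairs × 3 repeats × 100 simulations for the SAM optimization
trends (vs 100 × 10 × 500), and 40–60 random-search samples with 30–50
trials per candidate condition for the recovery tests (vs 100/100).  Each
scaled run was checked against larger runs for stability of the asserted
signs and trends.

## Known limitations

* Behavior is defined at 10 ms resolution; sub-step event times are not
  interpolated.
* No motor-execution delay between threshold crossing and overt action, no
  lapse model, no session-level nonstationarity.
* The σ_n convention ties the noise process to the 10 ms step; runs at other
  step sizes are not comparable at equal σ_n.
* The linear baseline implements the standard exponential ISI-estimate
  update; other algorithmic variants (e.g. two-level timekeeper/motor
  variance models) are out of scope.
* The alternative full-circuit implementation of single-interval
  reproduction (motor module producing the response) is not implemented; the
  anticipation module's crossing defines t_p.
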