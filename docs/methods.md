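# Methods

## Latent models

A trial is an `EventSchedule`: a time window plus ordered labeled events of
kinds `accessibility`, `gain`, `loss`, `consumption_end`, `abandon`,
`trial_start`, `trial_end`. Event kinds carry the model semantics; labels
are free text ("seeking_initiation", "food_contact", ...).

**Need** `N(t)` starts at a baseline `N0` and changes by `−R_i` at each
*step-inducing* event. Step-inducing kinds are `gain`, `loss` and
`consumption_end`; the sign convention is `R_i ≥ 0` for gain-type events
(need decreases — the future deficit is being resolved) and `R_i ≤ 0` for
loss events (need rebounds). `consumption_end` is gain-signed: it marks the
completion of the predicted gain and is the event a fitted 0–8 s delay can
shift (the observable moment — the animal turning away from food — can lag
the true end of consumption). The shifted time is capped just before the
next event so event order is preserved. An `abandon` event is a reset, not
a step: the trace returns instantaneously to the pre-trial baseline `N0`
and holds. The reset is modeled as instantaneous because nothing in the
data constrains a time course for it at the 100 Hz analysis rate.

**Motivation** `M(t)` is flat at `M0` before the accessibility moment `t0`
and accumulates `a·N(t) − Leak` per unit time afterwards. Because `N` is
piecewise constant, the integral has an exact piecewise-linear closed form;
on the sample grid this is the left-Riemann cumulative sum, which is exact
whenever event times sit on the grid (events snap to the nearest sample).
Two constraints shape the trace beyond the integral:

- accumulation **freezes at the first `loss` event** — a target that has
  become inaccessible stops driving goal-directed motivation;
- an `abandon` event **resets the trace to its pre-trial baseline** `M0`
  (a configuration switch selects a reset to zero instead; both readings
  of "abandoning induces zero motivation" vs. "return to baseline" are
  defensible, and baseline is the default because fitting operates in
  z-score space where the baseline is itself a free parameter).

Motivation is not floored at zero during fitting (z-scored targets are
routinely negative); the foraging simulator, which operates in latent
units, floors need and motivation at zero.

**Inverted-sign controls** reflect a latent about its initial value
(`2·v(0) − v(t)`). This preserves baseline semantics, is an involution, and
corresponds to the hypothesis that a population receives a sign-inverting
projection from the population encoding the direct variable.

Seven test structures are supported (`gain1`, `gain2`, `loss1`, `loss2`,
`loss3`, `multi_gain`, `multi_gain_loss`), each with an event-vocabulary
check: e.g. `loss1` contains only an inaccessibility event (its motivation
model is flat, since accumulation never starts), `loss2`/`loss3` end in an
abandon reset, and `multi_gain_loss` chains three gains, consumption end
and inaccessibility.

## Photometry forward model

Latents are convolved with a double-exponential calcium kernel
`k(t) = c·(1 − e^(−t/τr))·e^(−t/τd)` with defaults τr = 0.2 s, τd = 2.6 s,
10 s support, 100 samples/s, unit peak — representative published GCaMP6s
kinetics; all four numbers are configurable. The discrete convolution is
scaled by the sample interval so output amplitudes are rate-independent. A
free additive offset absorbs the baseline of z-scored signals and is fit
post-convolution.

Boundary handling has two modes: `pad_mean` prepends 125 samples equal to
the mean of the first 50 post-start samples (a plausible pre-trial history
instead of an artificial onset transient), and `crop_last5s` convolves
against a zero history and discards the first 5 s of output (for trials
that begin with a long inaccessibility segment whose onset is not
analyzed). Preprocessing of raw trials aligns each to a named event,
crops to a window, resamples to 100 Hz by linear interpolation, and
z-scores over the window; a numerically zero-variance window maps to zeros
with a warning. Trial averaging is pointwise, with consensus event times
(mean per label) on the averaged schedule.

## Fitting and model comparison

Every candidate model exposes `param_names`, box `bounds`, and
`predict(theta)`. `fit_model` minimizes RMSE from `n_starts` uniform-random
initial points (seeded, reproducible) with L-BFGS-B; the best restart is
returned with `AIC = N·ln(RSS/N) + 2K`, where `K` counts exactly the
parameters optimized.

The forward model is affine in the step magnitudes and baselines, so the
photometry builders precompute the kernel-convolved response of each basis
waveform (constant, unit steps truncated at abandon, unit ramps frozen at
the first loss) and evaluate predictions as small linear combinations.
This is mathematically identical to building the latent and convolving it
— padding and convolution are both linear maps — and the test suite asserts
the two routes agree to 1e−9.

Parametrization and identifiability: the need family fits
(`offset`, `N0`, one magnitude per step event), k = 2 + J. The motivation
family fits (`offset`, `M0`, a free-sign base slope `S0 = a·N0 − Leak`, one
slope magnitude `b_i = a·R_i ≥ 0` per step event before the freeze point),
k = 3 + J′. A single trace only determines these products — `a` and `Leak`
separately are scale-degenerate with the step magnitudes — so recovering
(`a`, `Leak`) in physical units uses a dedicated builder that holds the
need substrate fixed and fits (`offset`, `M0`, `a`, `Leak`) linearly.
Inverted-sign controls flip the sign constraint of every step term, which
is exactly the reflection of the latent about its initial value. Default
bounds: magnitudes [0, 10], slopes [−10, 10], baselines and offset [−5, 5],
`a`, `Leak` [0, 10] (all in z-units and seconds).

`fit_with_delay` grid-searches the consumption-end delay (default 0–8 s in
1 s steps), counts the delay as a parameter (+1 in K), and returns the
best-AIC fit. `loo_cv` fits one shared parameter vector per training fold
by minimizing the summed RSS across training trials (each trial keeps its
own schedule and hence its own basis matrix), then scores the held-out
trial's AIC. `permutation_test` splits a trace into 20 contiguous blocks,
rearranges them without replacement 1000 times (defaults), refits the model
to each surrogate, and reports the fraction of surrogates with AIC at or
below the observed — an empirical p for "does the model fit structure, or
would any rearrangement do". `friedman_on_aic` ranks models within subjects
(mid-ranks for ties, tie-corrected statistic); the p-value comes from exact
enumeration of within-subject rankings (dynamic programming over column
rank sums) when models ≤ 3 and subjects ≤ 8 with no ties, else from the
chi-square approximation.

## Behavior-probability models

Behavior rasters are binary 0.1 s bins per trial with a stimulation window
`[t_on, t_off]`. The probability curve is the across-trial mean, normalized
only if it exceeds 1, then smoothed with a centered moving average whose
window shrinks at the edges (no padding values).

The **need-activation** model ramps at rate `A` from `t_on + t_delay`,
then decays at rate `Leaky` after `t_off + t_delay`, clipped to [0, 1],
with the decay anchored at `t_on` as the piecewise form is printed (a
continuity-preserving variant anchored at `t_off` is available; the printed
form is discontinuous at the offset boundary whenever `Leaky > 0`). The
decay rate is capped at a quarter of the rise rate (`Leaky ≤ A/4`),
enforced during fitting by parametrizing `Leaky = frac·A/4`,
`frac ∈ [0, 1]`. A generated-behavior threshold gates the output (values
below it report 0; default 0). The **motivation-activation** model is a
delayed boxcar of height `A_stim`, clipped. All behavior parameters are
fit in [0, 1] bounds. k = 5 for the need model, k = 3 for the motivation
model. The models are dissociated by post-offset persistence: the
accumulation curve stays above threshold for `(value_at_off − thr)/Leaky`
seconds after the stimulus; the boxcar returns to baseline within a bin.

## Foraging simulation

One agent on a 1-D track (food at 300 steps by default; the geometry is the
simplest realization of "foraging over a distance") chooses go/stop each
step. The homeostatic deficit projects into a sum of discounted deficit
(SDD) under a constant-deficit geometric projection, normalized by
(1 − γ) so an infinite-horizon constant deficit d maps to exactly d and is
comparable to the action threshold. An active predicted gain compensates
the fraction (1 − e) of that projection, leaving the residual `e·SDD`
(e = 0.1): prediction nearly cancels the projected deficit while the
agent is on course to the food. This residual-fraction reading of the
predicted-event parameter is what produces the central dissociation — with
the stated defaults (γ 0.99, threshold 0.5, deficit 1) the direct-need
agent's need is 1.0 while stopped and 0.1 while moving, so under the
"prediction changes when the agent stops" condition its own movement keeps
cancelling the need that drives it and the policy dithers in
hold-constrained bouts (10 go / 50 stop). Under the
"prediction independent of motion" condition the same agent's need is
always sub-threshold and it never initiates. The accumulated-need agent
integrates the uncompensated need (`M += a·N − leak`, gated on
accessibility, floored at 0) and acts on `M > threshold`: it crosses once
and approaches in a single sustained bout.

Defaults: γ = 0.99, e = 0.1, a = 0.0015, leak = 0.001 (0.0008 in the
constant-deficit NID condition), threshold = 0.5, dwell holds 50 (stop) /
10 (go) steps, deficit increment 1e−5 per step (ID), eating rate 0.012 per
step, NID noise uniform ±0.001. The `with_inaccessible` condition imposes
the environment schedule — deficit 0 for 100 steps, then a linear rise to
1 over 500 inaccessible steps — which dominates the per-step increment
until food access; the episode then tracks 1000 steps past the first
consumption. Deficit, need and motivation are non-negative everywhere, and
no action bout is shorter than its dwell hold; both are asserted per
trajectory in the tests.

## Synthetic data generator

Sessions emulate z-scored GCaMP6s photometry: per-trial event times are
template times plus truncated Gaussian jitter (default sd 0.5 s; draws are
resampled until order, separation and window margins hold), the true latent
is convolved with the kernel, i.i.d. Gaussian noise is added (default sd
0.3 z-units; an AR(1) option exists, off by default), and trials are
z-scored. Default generating parameters (the study conditions of the
harness, chosen once for realistic O(1)-z-unit excursions and not tuned
thereafter): `N0 = 2`, steps (0.5, 0.5, 0.5) for the three gains, 2.5 for
consumption end (driving need negative so motivation declines sharply
after consumption), −1.5 for the loss rebound; `a = 0.25`, `Leak = 0.05`,
`M0 = 0`; 15 trials per session. Behavior rasters draw Bernoulli bins from
a model curve (defaults: 10 s stimulus, 0.1 s bins, 30 trials,
`A = 0.2/s`, `Leaky = 0.04/s`, `A_stim = 0.85`, `t_delay = 0.3 s`).

What the generator does *not* emulate: photobleaching, motion artifacts,
hemodynamic contamination, autocorrelated physiological noise (unless AR(1)
is enabled), trial-to-trial amplitude variability, or inter-trial
dependence in behavior. Passing tests therefore show that the analysis
chain is correct and well-calibrated under its own assumptions — not that
those assumptions hold for any particular recording system.

## Problem sizes and numerical choices

The verification harness (`scripts/acceptance.py`, tests) uses: 100
sessions per generator for photometry model selection (40 in the script),
50 seeds for parameter recovery at noise sd 0.1 with aligned events and no
z-scoring (20 in the script; z-scoring would rescale the units the
magnitudes are expressed in), 50 delay-recovery sessions at true delay 4 s
(25 in the script), 50 behavior sessions per generator (25), 100 foraging
seed pairs (50), and 50 permutation-calibration repeats at 200 permutations
(30). Multi-start counts are 5–20 for the linear-in-basis photometry models
(the objective is nearly convex; restarts guard the bound constraints) and
15–30 for the nonlinear behavior models.

Ties in the Friedman test take mid-ranks; an all-equal row triggers a
warning. A perfect fit (RSS = 0) yields AIC = −∞ with a warning rather
than an error. Empirical permutation p uses the ≤ convention without
smoothing; a rank-zero result should be reported as < 1/n_perm. Event
times snap to the nearest sample; generators and fitters share the same
forward path, so discretization affects both identically.

## Known limitations

- The exact supplementary state equations of the normative framework are
  reconstructed from their verbal description plus the stated parameter
  values; the foraging module is an informed reconstruction, not a
  transcription (see the predicted-gain compensation note above).
- `a` and `Leak` are reported per trial, shared across events; per-event
  accumulation parameters are out of scope.
- Motivation-family fits report slope products, not physical (`a`, `Leak`),
  unless the need substrate is pinned (see identifiability above).
- Fitting averaged traces with jittered events smears steps over ~the
  jitter sd; single-trial fitting with LOO-CV is the supported path when
  event timing varies strongly across trials.
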