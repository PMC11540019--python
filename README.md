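# needmot

Event-driven latent models that dissociate homeostatic **need** from
**motivation** in hypothalamic neural recordings and behavior.

## The problem

Need (how much an animal is lacking) and motivation (how strongly it acts to
fix that) rise and fall together in natural behavior, which makes it hard to
tell which of two candidate neuronal populations encodes which variable from
bulk calcium recordings alone. This package implements a normative modeling
framework that separates them *temporally*: the two latents make different
predictions around discrete behavioral events, and those predictions can be
fit to fiber-photometry traces and optogenetically evoked behavior.

It is written for systems-neuroscience analysts: everything is a plain
Python API over numpy/scipy/pandas, with a small CLI for batch use and a
synthetic-data generator so the whole chain is testable without recordings.

## The models

**Need** is the predicted deficit. It is piecewise constant across a trial:

    N(t) = N(t0) − R(t)

where `R(t)` accumulates one step per predicted-gain event (`R_i ≥ 0`:
seeking initiation, proximity, food contact, consumption end) or
predicted-loss event (`R_i ≤ 0`: inaccessibility). A voluntary *abandon*
event resets the trace to its pre-trial baseline.

**Motivation** is the leaky accumulation of need, gated on target
accessibility at time `t0`:

    M(t) = M(t0) + ∫[t0, t] ( a·N(s) − Leak ) ds

Because `N` is piecewise constant, `M` is continuous piecewise linear with
slope `a·N − Leak` on each interval; accumulation freezes when the target
becomes inaccessible. Behavior is produced when `M` exceeds a threshold `K`.

To compare either latent with photometry, it is convolved with a GCaMP6s
double-exponential kernel `k(t) = c·(1 − e^(−t/τr))·e^(−t/τd)`
(τr = 0.2 s, τd = 2.6 s by default) plus a free offset, and candidate
models — need, motivation, and their inverted-sign controls — are fit by
multi-start bounded RMSE minimization and ranked by

    AIC = N·ln(RSS/N) + 2K.

The package also provides leave-one-out cross-validation with shared
parameters, a 0–8 s consumption-end delay fit, Friedman rank tests on AIC
matrices, block-permutation empirical p-values, the optogenetic
behavior-probability models (accumulation-with-leak vs. delayed boxcar),
and an agent-based go/no-go foraging simulation comparing a *direct-need*
policy against an *accumulated-need* policy.

## Worked example

Generate a 15-trial synthetic session from the need model, average it, and
fit all four candidates (`examples/02_model_comparison.py`):

```text
session: 15 trials generated from the need model
model                      rmse   k        AIC
need                     0.0222   7   -30457.8
motivation               0.2874   7    -9962.0
inverted_need            0.8484   7    -1301.2
inverted_motivation      0.2692   7   -10484.5

winner: need (AIC margin 19973.3 over the runner-up)
```

The generating model wins decisively: on a multi-event trial the need
staircase, the motivation ramp, and their mirror images are no longer
interchangeable after kernel convolution. The foraging simulation
(`examples/04_foraging_simulation.py`) shows why motivation, not need,
should drive action:

```text
policy              acquired at  go bouts  go steps
direct need                1750        30       300
accumulated need           1285         1       518
```

The direct-need agent's own movement cancels the need that propels it (its
predicted gain is tied to moving), so it dithers in 30 short bouts and
reaches the food 465 steps later than the accumulated-need agent, which
crosses its threshold once and walks straight in.

Other entry points: `examples/01_latent_traces.py` (latent construction),
`examples/03_behavior_models.py` (optogenetic behavior dissociation), and
the `needmot` CLI (`generate`, `fit`, `behavior-fit`, `simulate`, `sweep`,
`compare`).

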