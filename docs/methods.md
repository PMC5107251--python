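# Methods

## Model

`condlearn` simulates an agent whose stimulus→action mapping is a small
layered network. Working-memory neurons code the current stimulus
(binary presence flags for the bell/food channels; a 1/2/3 satiety code
for the puzzle-box world). The action module is a chain of fully
connected layers, one layer per step of the action sequence, one neuron
per selectable action. Non-last-layer neurons are linear units exposing
the net input `u = wᵀx`; last-layer neurons are perceptrons firing when
`u ≥ b` (the boundary fires). In the puzzle-box runs `b = −∞`, so the
chain always executes; in the salivation runs `b` is the knob that
decides when a learned association becomes overt behaviour.

Every synapse is an evidence counter: `w = ln(nr/n̄r)` over rewarded /
unrewarded outcomes of chains through that synapse. On each trial the
executed chain's edges — every working-memory input edge of the first
chosen action plus each traversed interlayer edge — all receive the
trial's outcome. Credit is not gated by stimulus activity: in
extinction both the bell and the (silent) food channel weaken, which is
the intended reading of the two-channel salivation experiment. Dopamine
is `δ = k·(R − R′)` with `R′ = 0` and `R` the sigmoid of the
ideal-degree change; `δ > 0` counts as reward, `δ ≤ 0` (including a
flat transition) as no reward.

Winner-take-all selection uses the raw synaptic weight from the single
working-memory channel when there is one (the puzzle-box case); with
several channels the linear net input `wᵀx` is used instead. The two
rules agree whenever exactly one non-negative channel is active, which
covers every run shipped here.

## Update rule and its variants

The canonical update computes the increment
`±ln(1 + (1 + e^∓ʷ)/(nr + n̄r))` from the *pre-update* totals and then
increments the matching tally. With the +1 pseudocount start
(`nr = n̄r = 1`, `w = 0`) this is exactly equivalent to recomputing
`ln(nr/n̄r)` from the tallies — the equivalence is asserted to 1e-9
throughout the test-suite, and it is the reason the acquisition weight
is `ln(1 + t)` after `t` rewarded trials in closed form. Two variants
are available for sensitivity checks, selected by `update_mode`:

* `raw` — tallies start at 0, the tally is incremented first, and the
  denominator is clamped to ≥ 1. The count-ratio identity does not hold
  here; the mode exists because the incremental and closed forms of the
  rule disagree when a tally is 0, and it shows the qualitative results
  do not depend on which reading one takes.
* `asymptotic` — fixed learning rate `μ` (default 0.1) in
  `Δw = ±μ(1 + e^∓ʷ)`, the large-sample limit of the canonical rule.

The exact increment differs from the asymptotic form by
`x − ln(1 + x) ≤ x²/2` with `x = (1 + e^∓ʷ)/(nr + n̄r)`; the often
quoted `1/(nr + n̄r)²` bound holds only once the evidence supporting
the update direction outweighs the other tally by a factor of about
2.4, and the tests assert exactly that.

## Study conditions (defaults)

| Parameter | Default | Meaning |
|---|---|---|
| acquisition / extinction trials | 50 / 50 | paired CS+US, then CS-alone trials |
| growth budget (phase 1) | 30 trials | reward-free block before a layer is added |
| sequence-phase budget | 100 trials | hard cap for phase 2 |
| `k` (dopamine gain) | 1 | scales `δ`; does not affect the rewarded flag |
| `se_stop` | 0.3 nats | entropy convergence threshold |
| `min_trials_before_stop` | 5 | guard against a one-trial stop after reload |
| `b` sweep, acquisition | 2.5, 2.8, …, 5.5 (11 values) | salivation bias grid |
| `b` sweep, extinction | 1.0, 1.3, …, 4.3 (12 values) | the quoted interval [1, 4.5] with step 0.3 does not tile; the grid starts at 1.0 and takes 12 steps, and is configurable |
| tie break | first-index | deterministic; seeded-uniform available |
| Pavlov ΔID on food | +1 | direction is what matters; magnitude only scales `δ` |
| Rescorla–Wagner | α = 0.1; λ = 1/V₀ = 0 (acq), λ = 0/V₀ = 1 (ext) | only α is externally fixed; the asymptotes are the conventional choices |

System entropy is computed in natural log (nats) for consistency with
every other formula in the model; the 0.3 stopping value is read in
nats. Entropy statistics are kept over whole executed sequences (in a
one-layer phase a "sequence" is a single action) and the counts reset
at the start of each run, while the weights persist via long-term
memory. At trial 0 the entropy of the uniform prior `ln m` is reported
once (`TrialLog.initial_se`); from trial 1 on the empirical counts are
used, so the very first trial is always degenerate (one sequence chosen,
SE = 0) — the `min_trials_before_stop` guard exists precisely so this
artifact cannot end a run.

## Environments

The Pavlov world schedules (CS, US) flags per trial; reward follows the
US and nothing else. The puzzle-box world is a three-state machine over
satiety 1 (hungry), 2 (half-hungry), 3 (full) with actions north and
east. Single actions and the two ordered pairs are tabulated; unlisted
chains (north-north, east-east, longer chains) compose the
single-action column left to right, which is consistent with the
tabulated pairs' role as exceptions (north-east reaches the food and is
the only rewarded pair from hunger). Each trial starts hungry by
default; `persist_satiety` carries the reached state into the next
trial (a second consecutive success then moves 2 → 3). Ideal degree
equals the satiety code. Physical durations, geometry and hardware are
not modelled: a trial is one abstract chain execution, and the repeated
-run learning curve is measured in trials-to-convergence rather than
wall-clock seconds.

These worlds emulate the contingency structure of the two classic
experiments — which stimulus precedes reward, and which action chain
produces it — not their sensory richness: there is no noise in
perception, no stochasticity in reward delivery, and no timing. Passing
tests therefore show that the learning rule extracts deterministic
contingencies and converges as analysed; they do not show robustness to
noisy stimuli or probabilistic reward, beyond the Bernoulli-stream
stationarity checks on a single synapse.

## Memory

Sensory memory is a one-slot snapshot buffer (no decay dynamics).
Working memory holds the coded stimulus, the live synapse statistics,
and per-sequence reward tallies (kept alongside the per-edge counts;
the per-edge counts are what drive the weights). Long-term memory is a
single JSON document — schema-versioned, counts as integers, weights as
reals — storing network shape, every synapse's `(nr, n̄r, w)`, the
chain tallies and run metadata. Weights are recomputable from counts;
both are stored and their consistency is checked on load, so corruption
raises instead of silently re-initialising. A missing store means a
fresh, zero-weight start.

## Numerical choices and degenerate inputs

* Ties in winner-take-all are exact float equality; tied weights arise
  only from identical update histories, so no tolerance is needed.
* `ln(1 + x)` is evaluated with `log1p`; over 20 000 updates the drift
  of the incremental weight from the count ratio stays below 1e-11.
* `0·ln 0 = 0` in the entropy; distributions must sum to 1 within 1e-9
  and be non-negative, otherwise the input is rejected.
* `R(ΔID)` is strictly inside (−1, 1) for finite ΔID but rounds to ±1
  beyond |ΔID| ≈ 37 and to 0 below |ΔID| ≈ 1e-16; a sub-resolution
  improvement therefore counts as unrewarded.
* Empty weight lists, unknown states/actions/channels, invalid
  probabilities and malformed configs raise named errors.

## Problem sizes

All shipped runs are desk-scale: 50-trial conditioning phases, a
30-trial single-action phase, ≤ 100 sequence trials, 10-run persistence
series, and 20-seed × 20 000-update stationarity simulations; the whole
suite and the acceptance script each complete in a few seconds on one
CPU.

## Known limitations

Reward prediction `R′` is fixed at 0 — there is no temporal-difference
learning, so phenomena that need a learned expectation (blocking,
second-order conditioning) are out of reach. Exploration is pure
winner-take-all with tie-breaking; without optimistic initialisation or
softmax noise the agent can only discover chains that failures push it
toward, which suffices in these deterministic worlds. Layer growth only
appends (chains deepen at the end), and one working-memory bank is
assumed.
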