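# condlearn

Classical and operant conditioning in one learning rule: a small
simulator for associative learning built on neuromodulated log-odds
synaptic plasticity.

Pavlovian (classical) conditioning — a bell paired with food comes to
trigger salivation, and loses that power when food stops arriving — and
Thorndike-style operant conditioning — a cat in a puzzle box discovers
that pedal-then-latch opens the door and repeats it ever faster — are
usually modelled separately. `condlearn` implements a single network
model that reproduces both from the same plasticity mechanism, for
anyone studying associative-learning models, reward-modulated Hebbian
rules, or simple embodied agents.

## The model

A bank of working-memory neurons (stimulus channels) feeds a chain of
action layers. Each plastic synapse keeps two tallies: `nr`, the times
its action chain was followed by reward, and `n̄r`, the times it was
not. The weight is the log likelihood ratio

```
w = ln(nr / n̄r)
```

updated incrementally (with pre-update totals in the denominator):

```
reward:     w ← w + ln(1 + (1 + e⁻ʷ)/(nr + n̄r)),   nr ← nr + 1
no reward:  w ← w − ln(1 + (1 + eʷ)/(nr + n̄r)),    n̄r ← n̄r + 1
```

Reward comes from simulated VTA dopaminergic neurons. Each state has an
*ideal degree* ID; an action chain moving the agent from `s` to `s'`
yields actual reward `R = 2/(1 + e^(−ΔID)) − 1` with
`ΔID = ID(s') − ID(s)`, and phasic dopamine `δ = k·R` (no reward
expectation). A trial is rewarded iff `δ > 0`.

Actions are selected winner-take-all (maximum incoming weight per
layer). Convergence is tracked by the *system entropy*
`SE = −Σ pᵢ ln pᵢ` of the empirical sequence-choice distribution;
learning stops when SE falls below a threshold (default 0.3 nats).
If a whole block of trials at the current chain depth never pays off, a
new action layer is appended — the agent concludes single actions are
not enough and starts learning longer chains.

For large counts the update tends to `Δw = ±μ(1 + e^∓ʷ)` with
`μ = 1/(nr + n̄r)`, whose expected value vanishes exactly at
`w* = ln(p/(1−p))` — the weights are bounded estimators of the reward
log-odds. The classic Rescorla–Wagner rule `ΔV = α(λ − V)` is included
as a baseline for the conditioning curves.

## Worked example

```
$ condlearn run pavlov-acq --ltm ltm.json --out runs
acquisition: 50 trials, bell weight w1 = 3.931826
$ condlearn run pavlov-ext --ltm ltm.json --out runs
extinction: 50 trials, bell weight w1 = 0.000000
```

After 50 bell+food pairings the bell→salivation weight reaches
`ln 51 ≈ 3.9318` (counts 51 rewarded / 1 pseudocount), high enough to
fire the salivation neuron for every bias in the 2.5–5.5 sweep that it
crossed on the way up — the dog drools at the bell alone. Fifty
bell-only trials then drive it back to `ln(51/51) = 0`: extinction.

```
$ condlearn run thorndike --out runs
thorndike: 30 single-action + 29 sequence trials, final SE = 0.298758, last sequence = north|east
$ condlearn run thorndike-series --runs 5 --ltm cat.json --out runs
trials-to-stop per run: 29 5 5 5 5
```

The naive agent tries lone moves for 30 reward-free trials (weights only
weaken, choices alternate), grows a second action layer, errs twice
(`north|north`, then `east|north`), finds the rewarded chain
`north|east` on trial 3 and never leaves it; the choice entropy drops
below 0.3 nats at sequence trial 29. With its long-term memory
persisted, every later run converges in the minimum 5 trials — practice
makes fast, a trial-count learning curve.

```
$ condlearn run rw-baseline --out runs
rescorla-wagner baseline: V50(acq) = 0.994846, V50(ext) = 0.005154
```

Each run writes a per-trial CSV (chosen sequence, dopamine, every
weight, entropy, events) and a JSON long-term store.

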