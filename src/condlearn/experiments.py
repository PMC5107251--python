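"""End-to-end conditioning runs.

* ``run_acquisition`` / ``run_extinction`` — classical conditioning on a
  two-channel (bell, food) network with a single salivation neuron.  In
  acquisition CS and US are paired on every trial and both input weights
  strengthen; in extinction the bell sounds alone and they weaken.  The
  salivation response is probed against a sweep of perceptron biases
  ``b`` after every trial.
* ``run_thorndike`` — operant conditioning in the puzzle-box state
  machine: a reward-free single-action phase that triggers growth of a
  second action layer, followed by sequence learning that converges once
  the system entropy of the executed sequences falls below threshold.
* ``run_repeated_thorndike`` — successive runs with long-term-memory
  persistence; trials-to-convergence shrink with practice (the
  trial-count analogue of a learning curve).
* ``rescorla_wagner`` — the classic error-correction baseline
  ``V <- V + alpha (lambda - V)`` for side-by-side comparison with the
  log-odds weight trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .environments import (
    PavlovTrialSpec,
    THORNDIKE_ACTIONS,
    ThorndikeWorld,
    pavlov_delta_id,
)
from .memory import LongTermStore, WorkingMemoryState, load_long_term, save_long_term
from .network_core import LayeredActionNetwork, add_layer
from .neuromodulation import DopamineConfig, dopamine, is_rewarded, reward_signal
from .plasticity import update_rewarded, update_unrewarded
from .selection import (
    PolicyConfig,
    SelectionRecord,
    select_sequence,
    should_grow,
    should_stop,
    system_entropy,
    update_probabilities,
)

__all__ = [
    "RunConfig",
    "TrialLog",
    "RunResult",
    "run_acquisition",
    "run_extinction",
    "run_thorndike",
    "run_thorndike_phase2",
    "run_repeated_thorndike",
    "rescorla_wagner",
    "fresh_pavlov_network",
    "fresh_thorndike_network",
    "threshold_crossing",
]

PAVLOV_ACTION = "salivate"


def _grid(start: float, step: float, n: int) -> Tuple[float, ...]:
    return tuple(round(start + step * i, 10) for i in range(n))


@dataclass
class RunConfig:
    """Everything a run needs: environment, trial budgets, policy, gains.

    Defaults are the study conditions: 50 acquisition and 50 extinction
    trials; a 30-trial single-action phase and up to 100 sequence-learning
    trials; dopamine gain ``k = 1``; entropy stop at 0.3 nats; bias sweeps
    of 11 values from 2.5 (step 0.3) for acquisition and 12 values from
    1.0 (step 0.3) for extinction.
    """

    env: str = "pavlov"
    acquisition_trials: int = 50
    extinction_trials: int = 50
    b_grid_acquisition: Tuple[float, ...] = _grid(2.5, 0.3, 11)
    b_grid_extinction: Tuple[float, ...] = _grid(1.0, 0.3, 12)
    policy: PolicyConfig = field(default_factory=PolicyConfig)
    dopamine: DopamineConfig = field(default_factory=DopamineConfig)
    update_mode: str = "canonical"
    mu: float = 0.1  # learning rate in asymptotic update mode
    extinction_init: Optional[Tuple[int, int]] = None  # (nr, nbar) per input edge
    persist_satiety: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("acquisition_trials", "extinction_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.env not in ("pavlov", "thorndike"):
            raise ValueError(f"unknown environment {self.env!r}")


@dataclass
class TrialLog:
    """Per-trial records of one run, convertible to a tidy DataFrame."""

    rows: List[Dict] = field(default_factory=list)
    initial_se: Optional[float] = None
    meta: Dict = field(default_factory=dict)

    def append(self, **record) -> None:
        self.rows.append(record)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def column(self, name: str) -> List:
        return [row[name] for row in self.rows]


@dataclass
class RunResult:
    log: TrialLog
    net: LayeredActionNetwork
    state: WorkingMemoryState


def fresh_pavlov_network(cfg: RunConfig, threshold_b: float) -> LayeredActionNetwork:
    """Two wm channels (bell, food) fully connected to one salivation neuron."""
    return LayeredActionNetwork.create(
        n_wm=2, actions=[PAVLOV_ACTION], threshold_b=threshold_b, mode=cfg.update_mode
    )


def fresh_thorndike_network(cfg: RunConfig, layers: int = 1) -> LayeredActionNetwork:
    """One satiety channel, north/east action layer(s); biases at -inf."""
    net = LayeredActionNetwork.create(
        n_wm=1,
        actions=list(THORNDIKE_ACTIONS),
        threshold_b=-np.inf,
        mode=cfg.update_mode,
    )
    for _ in range(layers - 1):
        add_layer(net)
    return net


def _apply_outcome(net, sequence: Sequence[int], rewarded: bool, cfg: RunConfig) -> None:
    """Credit every edge along the executed chain with the trial outcome."""
    for edge in net.chain_edges(sequence):
        if rewarded:
            update_rewarded(edge, mode=cfg.update_mode, mu=cfg.mu)
        else:
            update_unrewarded(edge, mode=cfg.update_mode, mu=cfg.mu)


def _weight_snapshot(net) -> Dict[str, float]:
    return {name: e.w for name, e in net.all_edges().items()}


def _count_snapshot(net) -> Dict[str, Tuple[int, int]]:
    return {name: (e.nr, e.nbar) for name, e in net.all_edges().items()}


# ---------------------------------------------------------------------------
# Classical conditioning
# ---------------------------------------------------------------------------

def _run_pavlov_phase(
    cfg: RunConfig,
    net: LayeredActionNetwork,
    spec: PavlovTrialSpec,
    n_trials: int,
    b_grid: Sequence[float],
    state: WorkingMemoryState,
) -> TrialLog:
    log = TrialLog(meta={"b_grid": tuple(b_grid), "phase_spec": spec})
    for trial in range(1, n_trials + 1):
        delta = dopamine(reward_signal(0.0, pavlov_delta_id(spec)), cfg.dopamine)
        rewarded = is_rewarded(delta)
        _apply_outcome(net, [0], rewarded, cfg)
        state.tally(PAVLOV_ACTION, rewarded)
        # CS-alone probe: net input of the salivation neuron when only the
        # bell channel is active equals the bell weight w1.
        u_cs = net.input_weights[(0, 0)].w
        row = {
            "trial": trial,
            "cs": int(spec.cs_present),
            "us": int(spec.us_present),
            "delta": delta,
            "rewarded": int(rewarded),
            **_weight_snapshot(net),
            "u_cs": u_cs,
        }
        for b in b_grid:
            row[f"out_b{b:g}"] = 1 if u_cs >= b else 0
        log.append(**row)
    return log


def run_acquisition(cfg: RunConfig, net: LayeredActionNetwork | None = None) -> RunResult:
    """Pair CS and US on every trial; both input weights strengthen.

    The logged ``u_cs`` column is the salivation neuron's net input when
    the bell sounds alone, compared against every bias in the sweep.
    """
    if net is None:
        net = fresh_pavlov_network(cfg, threshold_b=cfg.b_grid_acquisition[0])
    state = WorkingMemoryState(net=net)
    spec = PavlovTrialSpec(cs_present=True, us_present=True)
    log = _run_pavlov_phase(cfg, net, spec, cfg.acquisition_trials, cfg.b_grid_acquisition, state)
    log.meta["phase"] = "acquisition"
    return RunResult(log=log, net=net, state=state)


def run_extinction(
    cfg: RunConfig,
    store: LongTermStore | None = None,
    net: LayeredActionNetwork | None = None,
) -> RunResult:
    """Present the bell alone; the learned weights weaken trial by trial.

    Extinction presupposes prior learning: provide a long-term store from
    an acquisition run, a live network, or configured initial counts via
    ``cfg.extinction_init``.
    """
    tallies: Dict[str, list] = {}
    if net is None:
        if store is not None:
            net, tallies = store.to_state()
        elif cfg.extinction_init is not None:
            nr, nbar = cfg.extinction_init
            net = fresh_pavlov_network(cfg, threshold_b=cfg.b_grid_extinction[0])
            for edge in net.input_weights.values():
                edge.nr, edge.nbar = int(nr), int(nbar)
                edge.w = float(np.log(nr / nbar))
        else:
            raise ValueError(
                "extinction requires prior learning: pass a long-term store, "
                "a trained network, or set extinction_init"
            )
    if net.input_weights[(0, 0)].w <= 0:
        raise ValueError("extinction requires a positive initial bell weight")
    state = WorkingMemoryState(net=net, chain_tallies=tallies)
    spec = PavlovTrialSpec(cs_present=True, us_present=False)
    log = _run_pavlov_phase(cfg, net, spec, cfg.extinction_trials, cfg.b_grid_extinction, state)
    log.meta["phase"] = "extinction"
    return RunResult(log=log, net=net, state=state)


def threshold_crossing(u_trajectory: Sequence[float], b: float, falling: bool = False) -> float:
    """First 1-based trial at which the probe crosses the bias *b*.

    Rising (acquisition): first trial with ``u >= b``.  Falling
    (extinction): first trial with ``u < b``.  ``inf`` if never crossed.
    """
    for t, u in enumerate(u_trajectory, start=1):
        if (u < b) if falling else (u >= b):
            return float(t)
    return float("inf")


# ---------------------------------------------------------------------------
# Operant conditioning
# ---------------------------------------------------------------------------

def _sequence_identity(net: LayeredActionNetwork, sequence: Sequence[int]) -> str:
    return "|".join(net.layers[layer][i] for layer, i in enumerate(sequence))


def _run_sequence_phase(
    cfg: RunConfig,
    net: LayeredActionNetwork,
    world: ThorndikeWorld,
    state: WorkingMemoryState,
    log: TrialLog,
    rng: np.random.Generator,
    max_trials: int,
    stop_on_entropy: bool,
    phase_label: str,
) -> Tuple[int, bool]:
    """Shared trial loop for both Thorndike phases.

    Returns (trials executed, whether any reward was seen this phase).
    """
    record = SelectionRecord()
    rewarded_seen = state.rewarded_seen_at_depth(net.n_layers)
    for trial in range(1, max_trials + 1):
        world.begin_trial()
        stimulus = world.observe()
        sequence = select_sequence(net, stimulus, cfg.policy, rng)
        identity = _sequence_identity(net, sequence)
        update_probabilities(record, identity)
        se = record.entropy()
        before, after, delta, rewarded = world.execute(
            [net.layers[layer][i] for layer, i in enumerate(sequence)], cfg.dopamine
        )
        rewarded_seen = rewarded_seen or rewarded
        _apply_outcome(net, sequence, rewarded, cfg)
        state.tally(identity, rewarded)
        log.append(
            trial=trial,
            phase=phase_label,
            state_before=before,
            state_after=after,
            sequence=identity,
            delta=delta,
            rewarded=int(rewarded),
            se=se,
            **_weight_snapshot(net),
            event="",
        )
        if stop_on_entropy and should_stop(se, trial, cfg.policy):
            log.rows[-1]["event"] = "stop:entropy" if se < cfg.policy.se_stop else "stop:budget"
            return trial, rewarded_seen
    return max_trials, rewarded_seen


def run_thorndike(
    cfg: RunConfig,
    store: LongTermStore | None = None,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """Full puzzle-box run: single-action phase, growth, sequence phase.

    A naive (single-layer) agent first tries lone actions for
    ``policy.growth_budget`` trials; in this world no lone action is ever
    rewarded, the weights only weaken, and a second action layer is
    added.  Sequence learning then proceeds for up to
    ``policy.max_trials`` trials or until the system entropy of the
    executed sequences drops below ``policy.se_stop``.  An experienced
    agent restored from a long-term store skips straight to sequence
    learning.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if store is not None:
        net, tallies = store.to_state()
    else:
        net, tallies = fresh_thorndike_network(cfg), {}
    state = WorkingMemoryState(net=net, chain_tallies=tallies)
    world = ThorndikeWorld(persist_state=cfg.persist_satiety)
    log = TrialLog(meta={"phase1_trials": 0, "phase2_trials": 0})
    log.initial_se = float(np.log(len(net.layers[0])))

    if net.n_layers == 1 and not state.rewarded_seen_at_depth(1):
        n1, rewarded_seen = _run_sequence_phase(
            cfg, net, world, state, log, rng,
            max_trials=cfg.policy.growth_budget,
            stop_on_entropy=False,
            phase_label="single-action",
        )
        log.meta["phase1_trials"] = n1
        if should_grow(n1, rewarded_seen, cfg.policy):
            add_layer(net)
            log.rows[-1]["event"] = "grow:add-layer"

    n2, _ = _run_sequence_phase(
        cfg, net, world, state, log, rng,
        max_trials=cfg.policy.max_trials,
        stop_on_entropy=True,
        phase_label="sequence",
    )
    log.meta["phase2_trials"] = n2
    return RunResult(log=log, net=net, state=state)


def run_thorndike_phase2(
    cfg: RunConfig,
    net: LayeredActionNetwork | None = None,
    rng: np.random.Generator | None = None,
    stop_on_entropy: bool = True,
) -> RunResult:
    """Sequence-learning phase alone, from a two-layer network.

    Defaults to a naive two-layer network (all weights zero), the state
    an agent is in immediately after layer growth if the single-action
    phase is taken as read.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = fresh_thorndike_network(cfg, layers=2)
    state = WorkingMemoryState(net=net)
    world = ThorndikeWorld(persist_state=cfg.persist_satiety)
    log = TrialLog()
    log.initial_se = float(np.log(len(ThorndikeWorld.sequences(net.n_layers))))
    n2, _ = _run_sequence_phase(
        cfg, net, world, state, log, rng,
        max_trials=cfg.policy.max_trials,
        stop_on_entropy=stop_on_entropy,
        phase_label="sequence",
    )
    log.meta["phase2_trials"] = n2
    return RunResult(log=log, net=net, state=state)


def run_repeated_thorndike(
    cfg: RunConfig,
    n_runs: int,
    ltm_path: str | None = None,
    rng: np.random.Generator | None = None,
) -> Tuple[List[int], List[RunResult]]:
    """Successive puzzle-box runs with long-term-memory persistence.

    Returns the per-run count of sequence-learning trials until the
    entropy stop fired (the trial-count analogue of escape time) and the
    individual run results.  With ``ltm_path`` the learning result is
    round-tripped through the JSON store between runs; otherwise it is
    carried in memory.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    trials_to_stop: List[int] = []
    results: List[RunResult] = []
    store: LongTermStore | None = None
    for run_index in range(n_runs):
        if ltm_path is not None:
            store = load_long_term(ltm_path)
        result = run_thorndike(cfg, store=store, rng=rng)
        trials_to_stop.append(result.log.meta["phase2_trials"])
        results.append(result)
        meta = {"seed": cfg.seed, "runs_completed": run_index + 1}
        if ltm_path is not None:
            save_long_term(result.net, result.state.chain_tallies, ltm_path, meta)
            store = None
        else:
            store = LongTermStore.from_state(result.net, result.state.chain_tallies, meta)
    return trials_to_stop, results


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def rescorla_wagner(
    trials: int, alpha: float = 0.1, lam: float = 1.0, v0: float = 0.0
) -> np.ndarray:
    """Associative-value trajectory V_0..V_T of the error-correction baseline.

    ``V_{t+1} = V_t + alpha (lambda - V_t)``; ``lambda`` is the asymptote
    supported by the US (1 during acquisition, 0 during extinction) and
    ``alpha`` the learning rate.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("learning rate alpha must lie in (0, 1]")
    if trials < 0:
        raise ValueError("trials must be non-negative")
    v = np.empty(trials + 1)
    v[0] = v0
    for t in range(trials):
        v[t + 1] = v[t] + alpha * (lam - v[t])
    return v
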