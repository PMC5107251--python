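"""The two built-in conditioning worlds.

Pavlov: a conditioned stimulus (bell) and an unconditioned stimulus
(food) are scheduled per trial; reward follows food presentation and
nothing the agent does changes that — classical conditioning.

Thorndike: a puzzle-box escape reduced to a discrete state machine.
The agent's satiety state is 1 (hungry), 2 (half-hungry) or 3 (full);
the two actions are moving north and moving east, and only the chain
north-then-east reaches the food.  State transitions for single actions
and the two ordered pairs are tabulated; longer or unlisted chains are
evaluated by composing single-action transitions left to right.  The
ideal degree of a state equals its satiety code, so reaching food (1 ->
2) yields positive dopamine and every other outcome does not — operant
conditioning, where reward hinges on the chosen actions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .memory import encode_stimulus
from .network_core import StimulusVector
from .neuromodulation import DopamineConfig, IdealDegreeMap, dopamine, is_rewarded, reward_signal

__all__ = [
    "NORTH",
    "EAST",
    "THORNDIKE_ACTIONS",
    "THORNDIKE_IDEAL_DEGREE",
    "PavlovTrialSpec",
    "ThorndikeWorld",
    "pavlov_step",
    "pavlov_delta_id",
    "thorndike_transition",
    "thorndike_reward",
]

NORTH = "north"  # press the pedal, in the original cat experiment
EAST = "east"  # lift the latch
THORNDIKE_ACTIONS: Tuple[str, str] = (NORTH, EAST)

#: Ideal degree of each satiety state: hungrier is worse.
THORNDIKE_IDEAL_DEGREE = IdealDegreeMap({1: 1.0, 2: 2.0, 3: 3.0})

# Single-action transitions (columns of the transition table): from a
# hungry or half-hungry state any lone action leaves the agent hungry;
# a full agent digests down to half-hungry.
_SINGLE = {
    NORTH: {1: 1, 2: 1, 3: 2},
    EAST: {1: 1, 2: 1, 3: 2},
}
# Explicitly tabulated ordered pairs.  north-east reaches the food and
# improves satiety; east-north does not (and costs a full agent satiety).
_PAIRS = {
    (NORTH, EAST): {1: 2, 2: 3, 3: 3},
    (EAST, NORTH): {1: 1, 2: 1, 3: 2},
}

_VALID_STATES = (1, 2, 3)


@dataclass(frozen=True)
class PavlovTrialSpec:
    """Which stimuli are scheduled on one classical-conditioning trial."""

    cs_present: bool  # bell (conditioned stimulus)
    us_present: bool  # food (unconditioned stimulus)


def pavlov_delta_id(spec: PavlovTrialSpec) -> float:
    """Ideal-degree change on a Pavlov trial: +1 when food is presented.

    Food improves the dog's state by one unit of ideal degree; the
    magnitude only scales the dopamine signal, not the rewarded flag.
    """
    return 1.0 if spec.us_present else 0.0


def pavlov_step(
    spec: PavlovTrialSpec, cfg: DopamineConfig = DopamineConfig()
) -> Tuple[StimulusVector, bool]:
    """One classical-conditioning trial: coded stimulus and rewarded flag.

    Reward does not depend on any action: it follows exactly when the
    unconditioned stimulus (food) is presented.
    """
    stim = encode_stimulus((int(spec.cs_present), int(spec.us_present)), env="pavlov")
    delta = dopamine(reward_signal(0.0, pavlov_delta_id(spec)), cfg)
    return stim, is_rewarded(delta)


def thorndike_transition(state: int, seq: Sequence[str]) -> int:
    """Resulting satiety state after executing an action chain.

    Tabulated chains (single actions and the two ordered pairs) are
    looked up directly; anything else composes single-action transitions
    left to right.
    """
    if state not in _VALID_STATES:
        raise ValueError(f"invalid state {state!r}; expected one of {_VALID_STATES}")
    actions = tuple(seq)
    for a in actions:
        if a not in THORNDIKE_ACTIONS:
            raise ValueError(f"invalid action {a!r}; expected one of {THORNDIKE_ACTIONS}")
    if not actions:
        raise ValueError("action sequence must be non-empty")
    if len(actions) == 1:
        return _SINGLE[actions[0]][state]
    if actions in _PAIRS:
        return _PAIRS[actions][state]
    s = state
    for a in actions:
        s = _SINGLE[a][s]
    return s


def thorndike_reward(
    state_before: int,
    state_after: int,
    cfg: DopamineConfig = DopamineConfig(),
) -> Tuple[float, bool]:
    """Dopamine signal and rewarded flag for a satiety transition."""
    for s in (state_before, state_after):
        if s not in _VALID_STATES:
            raise ValueError(f"invalid state {s!r}; expected one of {_VALID_STATES}")
    d_id = THORNDIKE_IDEAL_DEGREE.delta(state_before, state_after)
    delta = dopamine(reward_signal(0.0, d_id), cfg)
    return delta, is_rewarded(delta)


@dataclass
class ThorndikeWorld:
    """The puzzle-box state machine with per-trial episode handling.

    By default every trial starts hungry (state 1); with
    ``persist_state`` the satiety reached in one trial carries into the
    next, so a second success moves the agent from half-hungry to full.
    """

    state: int = 1
    persist_state: bool = False

    def begin_trial(self) -> int:
        if not self.persist_state:
            self.state = 1
        return self.state

    def execute(
        self, seq: Sequence[str], cfg: DopamineConfig = DopamineConfig()
    ) -> Tuple[int, int, float, bool]:
        """Run one trial: returns (state_before, state_after, delta, rewarded)."""
        before = self.begin_trial()
        after = thorndike_transition(before, seq)
        delta, rewarded = thorndike_reward(before, after, cfg)
        self.state = after
        return before, after, delta, rewarded

    def observe(self) -> StimulusVector:
        return encode_stimulus(self.state, env="thorndike")

    @staticmethod
    def sequences(length: int) -> List[Tuple[str, ...]]:
        """All action chains of the given length, in lexicographic order."""
        seqs: List[Tuple[str, ...]] = [()]
        for _ in range(length):
            seqs = [s + (a,) for s in seqs for a in THORNDIKE_ACTIONS]
        return seqs
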