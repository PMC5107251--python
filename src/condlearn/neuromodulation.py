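"""Simulated VTA dopaminergic reward signal.

How good an outcome is enters the model through a scalar *ideal degree*
(ID) attached to each perceivable state.  When an executed action chain
moves the agent from a state with ideal degree ``ID(s)`` to one with
``ID(s')``, the actual reward is a sigmoid of the improvement

    R = 2 / (1 + exp(-dID)) - 1,        dID = ID(s') - ID(s),

an odd, strictly increasing function with range (-1, 1).  The phasic
dopamine signal is a reward-prediction error ``delta = k (R - R')`` with
gain ``k``; the agents here hold no reward expectation, so ``R'`` is
fixed at 0 and dopamine is simply proportional to actual reward.  A trial
counts as rewarded only when dopamine is strictly positive — no change in
ideal degree (dID = 0) is treated as no reward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable

__all__ = [
    "IdealDegreeMap",
    "DopamineConfig",
    "reward_signal",
    "dopamine",
    "is_rewarded",
]


@dataclass(frozen=True)
class DopamineConfig:
    """Gain ``k`` (> 0) and fixed reward prediction ``r_prime`` (0 here)."""

    k: float = 1.0
    r_prime: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("dopamine gain k must be positive")


@dataclass
class IdealDegreeMap:
    """Total mapping state label -> ideal degree over an environment's states."""

    ids: Dict[Hashable, float] = field(default_factory=dict)

    def __getitem__(self, state: Hashable) -> float:
        try:
            return self.ids[state]
        except KeyError:
            raise KeyError(f"state {state!r} has no ideal degree") from None

    def delta(self, before: Hashable, after: Hashable) -> float:
        """Change in ideal degree across a transition."""
        return self[after] - self[before]


def reward_signal(id_before: float, id_after: float) -> float:
    """Actual reward R in (-1, 1): sigmoid of the ideal-degree change."""
    d = id_after - id_before
    return 2.0 / (1.0 + math.exp(-d)) - 1.0


def dopamine(r: float, cfg: DopamineConfig = DopamineConfig()) -> float:
    """Phasic dopamine delta = k (R - R')."""
    return cfg.k * (r - cfg.r_prime)


def is_rewarded(delta: float) -> bool:
    """True only for strictly positive dopamine; delta = 0 is unrewarded."""
    return delta > 0.0
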