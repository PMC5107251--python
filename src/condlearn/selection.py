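"""Winner-take-all selection, selection statistics, and convergence policy.

Actions are chosen greedily: at each layer the candidate with the
maximum incoming weight wins.  Ties (exact float equality — tied weights
arise only from identical update histories) are broken either by first
index (deterministic) or uniformly at random from a seeded generator.

Convergence is measured by *system entropy* (SE): the Shannon entropy,
in nats, of the empirical distribution of executed action sequences.
As one sequence comes to dominate, SE falls toward 0; learning stops
once SE drops below a threshold (after a minimum number of trials) or a
trial budget is exhausted.  A layer is added to the action chain when a
whole block of trials at the current depth has never produced reward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Sequence

import numpy as np

from .network_core import LayeredActionNetwork, StimulusVector

__all__ = [
    "PolicyConfig",
    "SelectionRecord",
    "select_action",
    "select_sequence",
    "update_probabilities",
    "system_entropy",
    "should_stop",
    "should_grow",
]

TIE_BREAKS = ("first", "random")


@dataclass
class PolicyConfig:
    """Selection and stopping policy.

    tie_break:
        "first" (deterministic first index) or "random" (seeded uniform
        choice among the maximisers).
    min_trials_before_stop:
        Entropy stopping is suppressed before this many trials, so a
        well-trained agent reloaded from long-term memory still executes
        a short run rather than stopping on its first (zero-entropy)
        choice.
    se_stop:
        Entropy threshold, in nats, below which learning has converged.
    max_trials:
        Hard trial budget for a learning phase.
    growth_budget:
        Number of consecutive reward-free trials at the current chain
        depth after which a layer is added.
    """

    tie_break: str = "first"
    seed: int = 0
    min_trials_before_stop: int = 5
    se_stop: float = 0.3
    max_trials: int = 100
    growth_budget: int = 30

    def __post_init__(self):
        if self.tie_break not in TIE_BREAKS:
            raise ValueError(f"tie_break must be one of {TIE_BREAKS}")
        if self.se_stop < 0:
            raise ValueError("se_stop must be non-negative")
        if self.max_trials < 1 or self.growth_budget < 1:
            raise ValueError("trial budgets must be at least 1")
        if self.min_trials_before_stop < 0:
            raise ValueError("min_trials_before_stop must be non-negative")


def select_action(
    layer_weights: Sequence[float],
    cfg: PolicyConfig = PolicyConfig(),
    rng: np.random.Generator | None = None,
) -> int:
    """Index of the maximum weight; ties resolved per policy."""
    weights = list(layer_weights)
    if not weights:
        raise ValueError("cannot select from an empty weight list")
    best = max(weights)
    winners = [i for i, w in enumerate(weights) if w == best]
    if len(winners) == 1 or cfg.tie_break == "first":
        return winners[0]
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return int(winners[int(rng.integers(len(winners)))])


def select_sequence(
    net: LayeredActionNetwork,
    stimulus: StimulusVector,
    cfg: PolicyConfig = PolicyConfig(),
    rng: np.random.Generator | None = None,
) -> List[int]:
    """Greedy per-layer winner-take-all: one action index per layer.

    The first layer competes on the weights from working memory; each
    subsequent layer competes on the weights out of the previously chosen
    neuron.
    """
    if net.n_layers < 1:
        raise ValueError("network has no action layers")
    sequence = [select_action(net.first_layer_candidates(stimulus), cfg, rng)]
    for layer in range(net.n_layers - 1):
        cands = net.interlayer_candidates(layer, sequence[-1])
        sequence.append(select_action(cands, cfg, rng))
    return sequence


@dataclass
class SelectionRecord:
    """Cumulative selection counts N_i and empirical probabilities p_i."""

    counts: Dict[Hashable, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def probs(self) -> Dict[Hashable, float]:
        n = self.total
        if n == 0:
            return {}
        return {k: v / n for k, v in self.counts.items()}

    def entropy(self) -> float:
        """System entropy of the current empirical distribution, in nats."""
        return system_entropy(list(self.probs.values()))


def update_probabilities(rec: SelectionRecord, chosen: Hashable) -> SelectionRecord:
    """Increment the chosen identity's count; probabilities renormalise."""
    rec.counts[chosen] = rec.counts.get(chosen, 0) + 1
    return rec


def system_entropy(probs: Sequence[float]) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 = 0."""
    p = np.asarray(list(probs), dtype=float)
    if p.size == 0:
        return 0.0
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() + 0.0)  # +0.0 normalises -0.0


def should_stop(se: float, trial: int, cfg: PolicyConfig) -> bool:
    """Stop when entropy has converged (after a minimum run) or the budget is out."""
    if trial >= cfg.max_trials:
        return True
    return trial >= cfg.min_trials_before_stop and se < cfg.se_stop


def should_grow(unrewarded_trials: int, rewarded_seen: bool, cfg: PolicyConfig) -> bool:
    """Add a layer once a full reward-free block has elapsed at this depth."""
    return (not rewarded_seen) and unrewarded_trials >= cfg.growth_budget
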