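"""Count-based log-odds synaptic plasticity and its asymptotic forms.

Each plastic synapse carries two evidence tallies: ``nr``, the number of
times the action chain through that synapse was followed by reward, and
``nbar``, the number of times it was not.  The synaptic weight is the
log likelihood ratio of those tallies,

    w = ln(nr / nbar),

so the weight grows without bound only as fast as the log of accumulated
evidence, and a single surprise late in training moves it very little.

The update is applied incrementally: on a rewarded trial the weight gains

    dw = ln(1 + (1 + e^{-w}) / (nr + nbar)),

on an unrewarded trial it loses ``ln(1 + (1 + e^{w}) / (nr + nbar))``,
with the pre-update totals in the denominator; the matching tally is then
incremented.  Under the +1 pseudocount initialisation (``nr = nbar = 1``,
``w = 0``) this incremental form and the closed count-ratio form coincide
exactly, which is the invariant the test-suite audits.

For large totals the increment is asymptotically ``mu (1 + e^{-w})`` /
``-mu (1 + e^{w})`` with learning rate ``mu = 1/(nr + nbar)``; the
expected increment under a Bernoulli(p) reward stream vanishes exactly at
the log-odds ``w* = ln(p / (1 - p))``, which bounds the weights and makes
the rule a consistent estimator of the reward log-odds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EdgeStat",
    "UPDATE_MODES",
    "update_rewarded",
    "update_unrewarded",
    "asymptotic_delta",
    "expected_delta",
    "stationary_weight",
]

#: Recognised weight-update modes.
#:
#: canonical  -- +1 pseudocounts, increment computed from pre-update totals;
#:               the incremental and count-ratio forms agree exactly.
#: raw        -- tallies start at 0; the tally is incremented first and the
#:               denominator is clamped to at least 1.  Sensitivity mode.
#: asymptotic -- fixed learning rate ``mu``; the large-sample limit of the
#:               canonical rule.
UPDATE_MODES = ("canonical", "raw", "asymptotic")


@dataclass
class EdgeStat:
    """One plastic synapse: reward/no-reward tallies and the log-odds weight.

    In canonical mode the invariant ``w == ln(nr / nbar)`` holds (to float
    round-off) at all times.
    """

    nr: int = 1
    nbar: int = 1
    w: float = 0.0

    @classmethod
    def fresh(cls, mode: str = "canonical") -> "EdgeStat":
        """A naive synapse: zero weight, pseudocounts per *mode*."""
        _check_mode(mode)
        if mode == "raw":
            return cls(nr=0, nbar=0, w=0.0)
        return cls(nr=1, nbar=1, w=0.0)

    def copy(self) -> "EdgeStat":
        return EdgeStat(self.nr, self.nbar, self.w)


def _check_mode(mode: str) -> None:
    if mode not in UPDATE_MODES:
        raise ValueError(f"unknown update mode {mode!r}; expected one of {UPDATE_MODES}")


def update_rewarded(e: EdgeStat, mode: str = "canonical", mu: float = 0.1) -> EdgeStat:
    """Apply one rewarded outcome to *e* in place and return it.

    The weight moves by ``+ln(1 + (1 + e^{-w})/(nr + nbar))`` (canonical),
    equal in value to replacing ``w`` with ``ln((nr + 1)/nbar)``.
    """
    _check_mode(mode)
    if mode == "asymptotic":
        e.w += mu * (1.0 + math.exp(-e.w))
        e.nr += 1
        return e
    if mode == "raw":
        e.nr += 1
        total = max(e.nr + e.nbar, 1)
        e.w += math.log1p((1.0 + math.exp(-e.w)) / total)
        return e
    total = e.nr + e.nbar
    e.w += math.log1p((1.0 + math.exp(-e.w)) / total)
    e.nr += 1
    return e


def update_unrewarded(e: EdgeStat, mode: str = "canonical", mu: float = 0.1) -> EdgeStat:
    """Apply one unrewarded outcome to *e* in place and return it."""
    _check_mode(mode)
    if mode == "asymptotic":
        e.w -= mu * (1.0 + math.exp(e.w))
        e.nbar += 1
        return e
    if mode == "raw":
        e.nbar += 1
        total = max(e.nr + e.nbar, 1)
        e.w -= math.log1p((1.0 + math.exp(e.w)) / total)
        return e
    total = e.nr + e.nbar
    e.w -= math.log1p((1.0 + math.exp(e.w)) / total)
    e.nbar += 1
    return e


def asymptotic_delta(w: float, mu: float, rewarded: bool) -> float:
    """Large-sample weight increment: ``mu(1+e^{-w})`` if rewarded else ``-mu(1+e^{w})``."""
    if mu <= 0:
        raise ValueError("learning rate mu must be positive")
    if rewarded:
        return mu * (1.0 + math.exp(-w))
    return -mu * (1.0 + math.exp(w))


def expected_delta(w: float, p: float, mu: float) -> float:
    """Expected asymptotic increment under a Bernoulli(*p*) reward stream.

    ``p mu (1+e^{-w}) - (1-p) mu (1+e^{w})``; zero exactly at the reward
    log-odds ``w = ln(p/(1-p))``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("reward probability p must lie strictly in (0, 1)")
    if mu <= 0:
        raise ValueError("learning rate mu must be positive")
    return p * mu * (1.0 + math.exp(-w)) - (1.0 - p) * mu * (1.0 + math.exp(w))


def stationary_weight(p: float) -> float:
    """The fixed point of the expected update: the reward log-odds ln(p/(1-p))."""
    if not 0.0 < p < 1.0:
        raise ValueError("reward probability p must lie strictly in (0, 1)")
    return math.log(p / (1.0 - p))
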