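"""Three-store memory: sensory buffer, working-memory state, long-term store.

Sensory memory is a one-slot snapshot of the latest raw observation.
Working memory holds the coded stimulus, the live synaptic statistics of
the network, and per-sequence reward tallies.  Long-term memory persists
everything learned — network shape, every synapse's (nr, nbar, w), the
chain tallies and run metadata — as a single JSON document, so that a
later run starts from experience instead of from scratch.

Weights are recomputable from the counts; both are stored and their
consistency is asserted on load (canonical mode), so a corrupted or
hand-edited store fails loudly rather than silently re-initialising.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

from .network_core import LayeredActionNetwork, StimulusVector
from .plasticity import EdgeStat

__all__ = [
    "SensoryBuffer",
    "WorkingMemoryState",
    "LongTermStore",
    "encode_stimulus",
    "save_long_term",
    "load_long_term",
]

SCHEMA_VERSION = 1
#: Tolerance for the w == ln(nr/nbar) consistency assertion on load.
_W_TOL = 1e-9

PAVLOV_CHANNELS = ("bell", "food")
THORNDIKE_STATES = (1, 2, 3)


@dataclass
class SensoryBuffer:
    """One-slot sensory snapshot, overwritten each trial."""

    latest: Any = None
    trial_stamp: int = 0

    def store(self, raw: Any, trial: int) -> None:
        self.latest = raw
        self.trial_stamp = trial


def encode_stimulus(raw: Any, env: str) -> StimulusVector:
    """Memory coding: raw observation -> working-memory output vector.

    Pavlov: ``raw`` is a (bell, food) pair of presence flags, coded as a
    binary vector — one channel per stimulus.  Thorndike: ``raw`` is the
    satiety state code 1 (hungry), 2 (half-hungry) or 3 (full), passed
    through as a single integer-valued channel.
    """
    if env == "pavlov":
        if isinstance(raw, dict):
            unknown = set(raw) - set(PAVLOV_CHANNELS)
            if unknown:
                raise ValueError(f"unknown stimulus channel(s): {sorted(unknown)}")
            values = [raw.get(ch, 0) for ch in PAVLOV_CHANNELS]
        else:
            values = list(raw)
            if len(values) != len(PAVLOV_CHANNELS):
                raise ValueError("pavlov observation must have exactly 2 channels")
        if any(v not in (0, 1, True, False) for v in values):
            raise ValueError("pavlov channels are binary presence flags")
        return StimulusVector(tuple(int(bool(v)) for v in values))
    if env == "thorndike":
        if raw not in THORNDIKE_STATES:
            raise ValueError(f"unknown satiety state {raw!r}; expected one of {THORNDIKE_STATES}")
        return StimulusVector((int(raw),))
    raise ValueError(f"unknown environment {env!r}")


@dataclass
class WorkingMemoryState:
    """Live learning state: coded stimulus, synapse stats, chain tallies.

    ``chain_tallies`` maps a sequence identity (the '|'-joined action
    labels of an executed chain) to ``[rewarded, unrewarded]`` counts —
    the per-sequence bookkeeping kept alongside the per-edge counts that
    drive the weights.
    """

    coded: Optional[StimulusVector] = None
    net: Optional[LayeredActionNetwork] = None
    chain_tallies: Dict[str, list] = field(default_factory=dict)

    def tally(self, identity: str, rewarded: bool) -> None:
        r, nbar = self.chain_tallies.get(identity, [0, 0])
        if rewarded:
            r += 1
        else:
            nbar += 1
        self.chain_tallies[identity] = [r, nbar]

    def rewarded_seen_at_depth(self, depth: int) -> bool:
        """Whether any chain of the given length has ever been rewarded."""
        return any(
            r > 0
            for seq, (r, _) in self.chain_tallies.items()
            if len(seq.split("|")) == depth
        )


@dataclass
class LongTermStore:
    """Serializable learning result: shape, synapse stats, tallies, metadata."""

    n_wm: int
    layers: list
    threshold_b: float
    mode: str
    input_weights: list  # [j, i, nr, nbar, w]
    interlayer_weights: list  # [layer, i, j, nr, nbar, w]
    chain_tallies: Dict[str, list]
    meta: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_state(
        cls,
        net: LayeredActionNetwork,
        chain_tallies: Dict[str, list] | None = None,
        meta: Dict[str, Any] | None = None,
    ) -> "LongTermStore":
        return cls(
            n_wm=net.n_wm,
            layers=[list(layer) for layer in net.layers],
            threshold_b=net.threshold_b,
            mode=net.mode,
            input_weights=[
                [j, i, e.nr, e.nbar, e.w] for (j, i), e in sorted(net.input_weights.items())
            ],
            interlayer_weights=[
                [layer, i, j, e.nr, e.nbar, e.w]
                for (layer, i, j), e in sorted(net.interlayer_weights.items())
            ],
            chain_tallies={k: list(v) for k, v in (chain_tallies or {}).items()},
            meta=dict(meta or {}),
        )

    def to_state(self) -> Tuple[LayeredActionNetwork, Dict[str, list]]:
        net = LayeredActionNetwork(
            n_wm=self.n_wm,
            layers=[list(layer) for layer in self.layers],
            threshold_b=self.threshold_b,
            mode=self.mode,
        )
        for j, i, nr, nbar, w in self.input_weights:
            net.input_weights[(j, i)] = _checked_edge(nr, nbar, w, self.mode)
        for layer, i, j, nr, nbar, w in self.interlayer_weights:
            net.interlayer_weights[(layer, i, j)] = _checked_edge(nr, nbar, w, self.mode)
        return net, {k: list(v) for k, v in self.chain_tallies.items()}

    def to_json(self) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "n_wm": self.n_wm,
            "layers": self.layers,
            "threshold_b": _json_real(self.threshold_b),
            "mode": self.mode,
            "input_weights": self.input_weights,
            "interlayer_weights": self.interlayer_weights,
            "chain_tallies": self.chain_tallies,
            "meta": self.meta,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LongTermStore":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt long-term store: {exc}") from exc
        if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                "corrupt long-term store: missing or unsupported schema_version"
            )
        required = {
            "n_wm",
            "layers",
            "threshold_b",
            "mode",
            "input_weights",
            "interlayer_weights",
            "chain_tallies",
        }
        missing = required - set(doc)
        if missing:
            raise ValueError(f"corrupt long-term store: missing fields {sorted(missing)}")
        store = cls(
            n_wm=doc["n_wm"],
            layers=doc["layers"],
            threshold_b=_parse_real(doc["threshold_b"]),
            mode=doc["mode"],
            input_weights=doc["input_weights"],
            interlayer_weights=doc["interlayer_weights"],
            chain_tallies=doc["chain_tallies"],
            meta=doc.get("meta", {}),
        )
        store.to_state()  # validate counts/weights eagerly; raises on corruption
        return store


def _json_real(x: float):
    if x == -math.inf:
        return "-inf"
    if x == math.inf:
        return "inf"
    return x


def _parse_real(x) -> float:
    if isinstance(x, str):
        return float(x)
    return float(x)


def _checked_edge(nr: int, nbar: int, w: float, mode: str) -> EdgeStat:
    if nr < 0 or nbar < 0:
        raise ValueError("corrupt long-term store: negative evidence counts")
    if mode == "canonical":
        if nr < 1 or nbar < 1:
            raise ValueError("corrupt long-term store: canonical counts must be >= 1")
        if abs(w - math.log(nr / nbar)) > _W_TOL:
            raise ValueError(
                "corrupt long-term store: weight inconsistent with counts "
                f"(w={w!r}, nr={nr}, nbar={nbar})"
            )
    return EdgeStat(nr=int(nr), nbar=int(nbar), w=float(w))


def save_long_term(
    net: LayeredActionNetwork,
    chain_tallies: Dict[str, list] | None,
    path: str | os.PathLike,
    meta: Dict[str, Any] | None = None,
) -> LongTermStore:
    """Write the learning result to *path* as JSON; returns the store."""
    store = LongTermStore.from_state(net, chain_tallies, meta)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(store.to_json())
        fh.write("\n")
    return store


def load_long_term(path: str | os.PathLike) -> Optional[LongTermStore]:
    """Read a long-term store; ``None`` if the file does not exist (fresh start).

    A file that exists but cannot be parsed or fails the count/weight
    consistency check raises ``ValueError`` — never a silent re-init.
    """
    if not os.path.exists(path):
        return None
    with open(path, "r", encoding="utf-8") as fh:
        return LongTermStore.from_json(fh.read())
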