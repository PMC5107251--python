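"""Layered working-memory -> action network.

The network couples a bank of working-memory neurons to an action module
of one or more fully connected layers.  Each layer represents one step of
an action chain and each neuron one selectable action.  Non-last-layer
neurons are linear (ADALINE-style) units exposing the inner product of
their inputs; last-layer neurons are perceptron units that fire when the
net input reaches the bias ``b`` (inclusive at the boundary).

Every connection is an :class:`~condlearn.plasticity.EdgeStat`, so the
network's "weights" are the live log-odds statistics of the plasticity
rule.  When learning at the current chain depth never pays off, a new
layer is appended (``add_layer``), deepening the chain without disturbing
any learned statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .plasticity import EdgeStat

__all__ = [
    "StimulusVector",
    "LayeredActionNetwork",
    "linear_output",
    "threshold_output",
    "add_layer",
]


@dataclass(frozen=True)
class StimulusVector:
    """Ordered working-memory outputs: one real value per wm neuron.

    Binary presence codes for stimulus channels (bell/food), or a single
    integer state code for a state-observing channel.
    """

    values: Tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, i):
        return self.values[i]


def linear_output(weights: Sequence[float], inputs) -> float:
    """Inner product u = w . x of a linear neuron (pre-threshold net input)."""
    x = list(inputs)
    w = list(weights)
    if len(w) != len(x):
        raise ValueError(f"weight/input length mismatch: {len(w)} vs {len(x)}")
    return float(sum(wi * xi for wi, xi in zip(w, x)))


def threshold_output(u: float, b: float) -> int:
    """Perceptron output: 1 iff the net input reaches the bias (u >= b)."""
    return 1 if u >= b else 0


@dataclass
class LayeredActionNetwork:
    """Working memory fully connected to a chain of action layers.

    Parameters
    ----------
    n_wm:
        Number of working-memory neurons feeding the first action layer.
    layers:
        Ordered action layers; each layer is an ordered list of action
        labels.  Layer ``L`` is fully connected to layer ``L+1``.
    input_weights:
        ``(wm_index, action_index)`` -> EdgeStat for the wm -> first-layer
        connections.
    interlayer_weights:
        ``(source_layer, source_action, target_action)`` -> EdgeStat for
        layer ``L`` -> layer ``L+1`` connections.
    threshold_b:
        Bias of the last-layer perceptron neurons.  ``-inf`` makes every
        last-layer neuron fire unconditionally (pure chain execution).
    mode:
        Update mode used to initialise fresh EdgeStats (see plasticity).
    """

    n_wm: int
    layers: List[List[str]]
    input_weights: Dict[Tuple[int, int], EdgeStat] = field(default_factory=dict)
    interlayer_weights: Dict[Tuple[int, int, int], EdgeStat] = field(default_factory=dict)
    threshold_b: float = 0.0
    mode: str = "canonical"

    @classmethod
    def create(
        cls,
        n_wm: int,
        actions: Sequence[str],
        threshold_b: float = 0.0,
        mode: str = "canonical",
    ) -> "LayeredActionNetwork":
        """A single-layer network with naive (zero-weight) connections."""
        if n_wm < 1:
            raise ValueError("need at least one working-memory neuron")
        if not actions:
            raise ValueError("need at least one action")
        net = cls(
            n_wm=n_wm,
            layers=[list(actions)],
            threshold_b=threshold_b,
            mode=mode,
        )
        for j in range(n_wm):
            for i in range(len(actions)):
                net.input_weights[(j, i)] = EdgeStat.fresh(mode)
        return net

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_actions(self, layer: int) -> List[str]:
        return self.layers[layer]

    def input_weight_vector(self, action: int) -> List[float]:
        """Weights from all wm neurons into first-layer *action*."""
        return [self.input_weights[(j, action)].w for j in range(self.n_wm)]

    def first_layer_candidates(self, stimulus: StimulusVector) -> List[float]:
        """Per-action score used by winner-take-all at the first layer.

        With a single wm neuron this is the raw synaptic weight; with
        several it is the linear net input w . x (identical ordering
        whenever exactly one non-negative channel is active).
        """
        scores = []
        for i in range(len(self.layers[0])):
            if self.n_wm == 1:
                scores.append(self.input_weights[(0, i)].w)
            else:
                scores.append(linear_output(self.input_weight_vector(i), stimulus))
        return scores

    def interlayer_candidates(self, layer: int, source: int) -> List[float]:
        """Weights from *source* neuron of *layer* into every neuron of layer+1."""
        return [
            self.interlayer_weights[(layer, source, j)].w
            for j in range(len(self.layers[layer + 1]))
        ]

    def chain_edges(self, sequence: Sequence[int]) -> List[EdgeStat]:
        """All EdgeStats along an executed action chain.

        Every wm -> first-action connection participates (all stimulus
        channels share credit for the chain outcome), plus each interlayer
        edge actually traversed.
        """
        if len(sequence) != self.n_layers:
            raise ValueError("sequence length must equal the number of layers")
        edges = [self.input_weights[(j, sequence[0])] for j in range(self.n_wm)]
        for layer in range(self.n_layers - 1):
            edges.append(self.interlayer_weights[(layer, sequence[layer], sequence[layer + 1])])
        return edges

    def all_edges(self) -> Dict[str, EdgeStat]:
        """Stable name -> EdgeStat map over every connection (for logging)."""
        named: Dict[str, EdgeStat] = {}
        for (j, i), e in sorted(self.input_weights.items()):
            named[f"w_wm{j}_{self.layers[0][i]}"] = e
        for (layer, i, j), e in sorted(self.interlayer_weights.items()):
            src = self.layers[layer][i]
            dst = self.layers[layer + 1][j]
            named[f"w_L{layer + 1}{src}_L{layer + 2}{dst}"] = e
        return named


def add_layer(
    net: LayeredActionNetwork,
    n_actions: int | None = None,
    labels: Sequence[str] | None = None,
) -> LayeredActionNetwork:
    """Append a fresh action layer, deepening the learnable chain by one.

    The new layer holds one neuron per selectable action (defaulting to the
    first layer's action set) and is fully connected to the previous last
    layer with naive EdgeStats.  Existing statistics are untouched.
    """
    if labels is None:
        base = net.layers[0]
        if n_actions is None:
            n_actions = len(base)
        if n_actions == len(base):
            labels = list(base)
        else:
            labels = [f"a{i + 1}" for i in range(n_actions)]
    else:
        labels = list(labels)
        if n_actions is None:
            n_actions = len(labels)
    if n_actions < 1:
        raise ValueError("a layer needs at least one neuron")
    if len(labels) != n_actions:
        raise ValueError("label count must match n_actions")

    source_layer = net.n_layers - 1
    n_source = len(net.layers[source_layer])
    net.layers.append(labels)
    for i in range(n_source):
        for j in range(n_actions):
            net.interlayer_weights[(source_layer, i, j)] = EdgeStat.fresh(net.mode)
    return net
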