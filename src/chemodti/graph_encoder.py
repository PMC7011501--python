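"""Minimal graph neural network molecule encoder.

Node update (one message-passing layer):

    h_i^{(l+1)} = sigma( W0^{(l)} h_i^{(l)}
                         + sum_{j in N(i)} alpha_ij W1^{(l)} h_j^{(l)} )

with N(i) the one-hop neighbourhood; the self term goes through W0, so
no explicit self-loops are added.  The graph readout at every layer is
the plain node sum

    m^{(l)} = sum_{i in V} h_i^{(l)}

and the final molecule embedding is simply the last-layer readout
m = m^{(L)} (the "minimal" COMBINE).  Sum readout makes the embedding
exactly invariant under node permutation.

The coefficients alpha_ij are configurable: ``constant_one`` (default;
plain neighbour sum), ``degree_normalized`` (alpha_ij = 1/deg(i)), or
``learned_scalar_per_layer`` (one trainable scalar per layer shared by
all edges — per-edge free parameters would not transfer across
molecules).  sigma defaults to the sigmoid.  Bond attributes are
accepted by the interface but unused by this minimal encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from chemodti import _autodiff as ad
from chemodti._autodiff import Tensor
from chemodti.chem_io import MolecularGraph

__all__ = [
    "GNNParams",
    "GraphEmbedding",
    "init_node_states",
    "aggregate_node",
    "aggregate_graph",
    "encode_molecule",
]

ALPHA_POLICIES = ("constant_one", "degree_normalized", "learned_scalar_per_layer")


class GraphEncoderError(ValueError):
    pass


@dataclass
class GraphEmbedding:
    """Per-layer readouts m^{(0..L)} and the final embedding m = m^{(L)}."""

    readouts: list[Tensor]

    @property
    def m(self) -> Tensor:
        return self.readouts[-1]

    @property
    def vector(self) -> np.ndarray:
        return self.readouts[-1].data.ravel()


class GNNParams:
    """Weights of the minimal GNN: per-layer W0^{(l)}, W1^{(l)}
    (stored (in, out) so states right-multiply), optional learned
    alpha scalars, activation name, layer count."""

    def __init__(self, input_dim: int, hidden_dim: int = 100, n_layers: int = 3,
                 alpha_policy: str = "constant_one", activation: str = "sigmoid",
                 rng: Optional[np.random.Generator] = None):
        if n_layers < 1:
            raise GraphEncoderError("need at least one layer")
        if alpha_policy not in ALPHA_POLICIES:
            raise GraphEncoderError(f"unknown alpha policy {alpha_policy!r}")
        if activation not in ad.ACTIVATIONS:
            raise GraphEncoderError(f"unknown activation {activation!r}")
        if rng is None:
            rng = np.random.default_rng(0)
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.alpha_policy = alpha_policy
        self.activation = activation
        self.W0, self.W1 = [], []
        for layer in range(n_layers):
            d_in = input_dim if layer == 0 else hidden_dim
            self.W0.append(ad.parameter(ad.glorot(rng, d_in, hidden_dim)))
            self.W1.append(ad.parameter(ad.glorot(rng, d_in, hidden_dim)))
        self.alpha = (
            [ad.parameter(1.0) for _ in range(n_layers)]
            if alpha_policy == "learned_scalar_per_layer" else None
        )

    def parameters(self) -> list[Tensor]:
        out = [*self.W0, *self.W1]
        if self.alpha is not None:
            out.extend(self.alpha)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in range(self.n_layers):
            out[f"W0.{layer}"] = self.W0[layer].data.copy()
            out[f"W1.{layer}"] = self.W1[layer].data.copy()
            if self.alpha is not None:
                out[f"alpha.{layer}"] = self.alpha[layer].data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in range(self.n_layers):
            for name, params in (("W0", self.W0), ("W1", self.W1)):
                key = f"{name}.{layer}"
                if state[key].shape != params[layer].data.shape:
                    raise GraphEncoderError(
                        f"shape mismatch for {key}: checkpoint "
                        f"{state[key].shape} vs model {params[layer].data.shape}"
                    )
                params[layer].data = state[key].copy()
            if self.alpha is not None:
                self.alpha[layer].data = state[f"alpha.{layer}"].copy()

    def config_dict(self) -> dict:
        return {
            "input_dim": self.input_dim, "hidden_dim": self.hidden_dim,
            "n_layers": self.n_layers, "alpha_policy": self.alpha_policy,
            "activation": self.activation,
        }


def _adjacency(graph: MolecularGraph, policy: str) -> np.ndarray:
    a = np.zeros((graph.n_atoms, graph.n_atoms))
    for i, j in graph.edges:
        a[i, j] = a[j, i] = 1.0
    if policy == "degree_normalized":
        deg = a.sum(axis=1, keepdims=True)
        a = np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)
    return a


def init_node_states(graph: MolecularGraph, node_features) -> Tensor:
    """Layer-0 states: h_i^{(0)} = x_i."""
    feats = node_features if isinstance(node_features, Tensor) else Tensor(node_features)
    if graph.n_atoms == 0:
        raise GraphEncoderError("empty graph")
    if feats.data.ndim != 2 or feats.data.shape[0] != graph.n_atoms:
        raise GraphEncoderError(
            f"expected one feature vector per node ({graph.n_atoms}), "
            f"got array of shape {feats.data.shape}"
        )
    return feats


def aggregate_node(layer: int, graph: MolecularGraph, states: Tensor,
                   params: GNNParams) -> Tensor:
    """One node-update step: states at layer ``layer`` -> layer+1."""
    w0, w1 = params.W0[layer], params.W1[layer]
    if states.data.shape[1] != w0.data.shape[0]:
        raise GraphEncoderError(
            f"layer {layer}: state dim {states.data.shape[1]} does not match "
            f"weight input dim {w0.data.shape[0]}"
        )
    adj = Tensor(_adjacency(graph, params.alpha_policy))
    neighbour = ad.matmul(ad.matmul(adj, states), w1)
    if params.alpha is not None:
        neighbour = ad.mul(params.alpha[layer], neighbour)
    pre = ad.add(ad.matmul(states, w0), neighbour)
    return ad.ACTIVATIONS[params.activation](pre)


def aggregate_graph(states: Tensor) -> Tensor:
    """Per-layer readout m^{(l)}: sum of node representations,
    kept as a (1, d) row."""
    if states.data.shape[0] == 0:
        raise GraphEncoderError("empty graph has no readout")
    return ad.tensor_sum(states, axis=0, keepdims=True)


def encode_molecule(graph: MolecularGraph, node_features,
                    params: GNNParams) -> GraphEmbedding:
    """Run L node-update steps and return all per-layer readouts; the
    molecule embedding is the last one."""
    states = init_node_states(graph, node_features)
    readouts = [aggregate_graph(states)]
    for layer in range(params.n_layers):
        states = aggregate_node(layer, graph, states, params)
        readouts.append(aggregate_graph(states))
    return GraphEmbedding(readouts=readouts)
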