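"""Stacked 1D convolutional protein sequence encoder.

The input is the one-hot residue matrix (L x 20).  Each layer is a
strided cross-correlation along the sequence axis followed by an
elementwise nonlinearity (ReLU by default); the protein embedding
h_prot is the sum of the final-layer per-position representations, so
its dimension equals the last layer's filter count.

Defaults follow the tuned chemogenomic-network configuration: 3
layers, 100 filters per layer, filter size 8, stride 3.  Padding is
``same_zero`` by default (output length ceil(L / stride)), so short
proteins survive three strided layers; ``valid`` is available and
rejects sequences shorter than the filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from chemodti import _autodiff as ad
from chemodti._autodiff import Tensor
from chemodti.chem_io import ProteinSequence
from chemodti.featurize import aa_onehot

__all__ = ["CNNParams", "ProteinEmbedding", "conv1d_layer", "encode_protein"]


class SequenceEncoderError(ValueError):
    pass


@dataclass
class ProteinEmbedding:
    """h_prot, kept as a (1, n_filters) row tensor."""

    embedding: Tensor

    @property
    def vector(self) -> np.ndarray:
        return self.embedding.data.ravel()


class CNNParams:
    """Filter stacks of the convolutional encoder.

    Per layer: weights (n_filters, filter_size, in_channels) and a bias
    per filter.  All layers share ``n_filters``.
    """

    def __init__(self, in_channels: int = 20, n_filters: int = 100,
                 n_layers: int = 3, filter_size: int = 8, stride: int = 3,
                 padding_policy: str = "same_zero", activation: str = "relu",
                 rng: Optional[np.random.Generator] = None):
        if n_layers < 1 or filter_size < 1 or stride < 1:
            raise SequenceEncoderError("n_layers, filter_size and stride must be >= 1")
        if padding_policy not in ("same_zero", "valid"):
            raise SequenceEncoderError(f"unknown padding policy {padding_policy!r}")
        if activation not in ad.ACTIVATIONS:
            raise SequenceEncoderError(f"unknown activation {activation!r}")
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.n_layers = n_layers
        self.filter_size = filter_size
        self.stride = stride
        self.padding_policy = padding_policy
        self.activation = activation
        self.weights, self.biases = [], []
        for layer in range(n_layers):
            c_in = in_channels if layer == 0 else n_filters
            fan_in = filter_size * c_in
            self.weights.append(ad.parameter(
                ad.glorot(rng, fan_in, n_filters, shape=(n_filters, filter_size, c_in))
            ))
            self.biases.append(ad.parameter(np.zeros(n_filters)))

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in range(self.n_layers):
            out[f"weight.{layer}"] = self.weights[layer].data.copy()
            out[f"bias.{layer}"] = self.biases[layer].data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in range(self.n_layers):
            for name, params in (("weight", self.weights), ("bias", self.biases)):
                key = f"{name}.{layer}"
                if state[key].shape != params[layer].data.shape:
                    raise SequenceEncoderError(
                        f"shape mismatch for {key}: checkpoint {state[key].shape} "
                        f"vs model {params[layer].data.shape}"
                    )
                params[layer].data = state[key].copy()

    def config_dict(self) -> dict:
        return {
            "in_channels": self.in_channels, "n_filters": self.n_filters,
            "n_layers": self.n_layers, "filter_size": self.filter_size,
            "stride": self.stride, "padding_policy": self.padding_policy,
            "activation": self.activation,
        }

    def min_length(self) -> int:
        """Shortest sequence the stack accepts (valid padding needs at
        least one full filter window at every layer)."""
        if self.padding_policy == "same_zero":
            return 1
        length = 1
        for _ in range(self.n_layers):
            length = (length - 1) * self.stride + self.filter_size
        return length


def conv1d_layer(states, weight, bias, stride: int, padding_policy: str,
                 activation: str = "identity") -> Tensor:
    """One convolutional stage on per-position states (L x C_in)."""
    states = states if isinstance(states, Tensor) else Tensor(states)
    out = ad.conv1d(states, weight, bias, stride, padding_policy)
    return ad.ACTIVATIONS[activation](out)


def encode_protein(sequence: ProteinSequence, params: CNNParams,
                   onehot: Optional[np.ndarray] = None) -> ProteinEmbedding:
    """Run the filter stack and sum-pool the final residue states.

    ``onehot`` may supply a precomputed (L x in_channels) input matrix;
    otherwise the one-hot encoding is computed here.
    """
    if onehot is None:
        onehot = aa_onehot(sequence, allow_unknown=params.in_channels == 21)
    if len(sequence.residues) < params.min_length():
        raise SequenceEncoderError(
            f"protein {sequence.id!r}: length {len(sequence.residues)} below the "
            f"minimum {params.min_length()} required by {params.n_layers} valid-"
            "padding layers"
        )
    states = Tensor(onehot)
    for layer in range(params.n_layers):
        states = conv1d_layer(states, params.weights[layer], params.biases[layer],
                              params.stride, params.padding_policy, params.activation)
    pooled = ad.tensor_sum(states, axis=0, keepdims=True)
    return ProteinEmbedding(embedding=pooled)
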