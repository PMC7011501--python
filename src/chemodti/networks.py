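"""Model assembly and training: the chemogenomic network (CN), the
expert-descriptor FNN baseline, the multi-view fusions, masked
multi-task pre-training and per-block transfer learning.

The CN composes the minimal graph encoder, the convolutional sequence
encoder, concatenation of the two embeddings, and a pair-level MLP
producing an interaction score.  Training minimises binary
cross-entropy over labeled pairs with Adam, multiplies the learning
rate by a decay factor after each epoch, and stops early when the
validation AUPR has not increased for ``patience`` successive epochs,
returning the parameters of the best validation epoch.  Everything is
seeded and single-threaded, so a fixed seed reproduces the training
history bit-for-bit.

Multi-view variants:

* one-step (``CNOneStepModel``): concatenates the GNN embedding, the
  CNN embedding and descriptor-MLP outputs for molecule and protein
  into a single pair representation scored by MLP_pair;
* ``CNFeaMLPModel``: the learnt pair representation goes through
  MLP_raw-pair, the expert pair representation through MLP_fea-pair,
  and their outputs are fused by a small MLP_pair-pair (one hidden
  layer of 50 units by default).  Silencing one branch reduces the
  forward pass exactly to the CN-like (resp. FNN-like) composition of
  the remaining modules — the standard implementation sanity checks.

Transfer learning loads any subset of the named blocks
{molecule_encoder, protein_encoder, pair_mlp} from a checkpoint and
optionally freezes them (excluded from gradient updates).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from chemodti import _autodiff as ad
from chemodti._autodiff import Adam, Tensor
from chemodti.chem_io import InteractionDataset, MolecularGraph, ProteinSequence
from chemodti.evaluation import aupr, parse_ratio, roc_auc, sample_negatives
from chemodti.featurize import aa_onehot, atom_features, molecule_fingerprint, protein_descriptors
from chemodti.graph_encoder import GNNParams, encode_molecule
from chemodti.sequence_encoder import CNNParams, encode_protein
from chemodti.synthetic_data import MultiTaskLabels

logger = logging.getLogger(__name__)

__all__ = [
    "MLP",
    "CNModel",
    "FNNModel",
    "CNFeaMLPModel",
    "CNOneStepModel",
    "TrainingConfig",
    "TrainingHistory",
    "FeatureCache",
    "comb_concat",
    "mlp_forward",
    "cn_predict",
    "fnn_predict",
    "cn_feamlp_predict",
    "cn_onestep_predict",
    "train",
    "pretrain_multitask",
    "transfer_load",
    "save_checkpoint",
    "load_checkpoint",
    "build_labeled_split",
    "default_cn_model",
    "smoke_cn_model",
]

CHECKPOINT_SCHEMA_VERSION = 1


class NetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# multi-layer perceptron
# ---------------------------------------------------------------------------

class MLP:
    """Stacked fully connected layers.

    ``hidden`` lists the hidden widths; the output layer is linear
    with ``out_dim`` units (1 for pair scoring — callers apply the
    sigmoid).  Inverted dropout on hidden activations during training.
    """

    def __init__(self, in_dim: int, hidden: Sequence[int] = (100,), out_dim: int = 1,
                 activation: str = "relu", dropout: float = 0.0,
                 rng: Optional[np.random.Generator] = None):
        if not 0.0 <= dropout < 1.0:
            raise NetworkError("dropout must be in [0, 1)")
        if any(w < 1 for w in hidden) or out_dim < 1:
            raise NetworkError("layer widths must be >= 1")
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_dim = in_dim
        self.hidden = tuple(hidden)
        self.out_dim = out_dim
        self.activation = activation
        self.dropout = dropout
        widths = [in_dim, *hidden, out_dim]
        self.weights = [ad.parameter(ad.glorot(rng, a, b))
                        for a, b in zip(widths, widths[1:])]
        self.biases = [ad.parameter(np.zeros(b)) for b in widths[1:]]

    def forward(self, x: Tensor, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        """Logit output, shape (1, out_dim)."""
        if x.data.shape[1] != self.in_dim:
            raise NetworkError(
                f"MLP expects input width {self.in_dim}, got {x.data.shape[1]}"
            )
        h = x
        n_hidden = len(self.weights) - 1
        for layer in range(n_hidden):
            h = ad.add(ad.matmul(h, self.weights[layer]), self.biases[layer])
            h = ad.ACTIVATIONS[self.activation](h)
            if training and self.dropout > 0.0:
                if rng is None:
                    raise NetworkError("dropout during training needs an rng")
                keep = (rng.random(h.data.shape) >= self.dropout) / (1 - self.dropout)
                h = ad.mul(h, Tensor(keep))
        return ad.add(ad.matmul(h, self.weights[-1]), self.biases[-1])

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"weight.{layer}"] = w.data.copy()
            out[f"bias.{layer}"] = b.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            for key, param in ((f"weight.{layer}", w), (f"bias.{layer}", b)):
                if state[key].shape != param.data.shape:
                    raise NetworkError(
                        f"shape mismatch for {key}: checkpoint {state[key].shape} "
                        f"vs model {param.data.shape}"
                    )
                param.data = state[key].copy()

    def config_dict(self) -> dict:
        return {"in_dim": self.in_dim, "hidden": list(self.hidden),
                "out_dim": self.out_dim, "activation": self.activation,
                "dropout": self.dropout}


def comb_concat(m, h_prot) -> Tensor:
    """Comb block: pair representation [m ; h_prot] — molecule first,
    protein second."""
    m_t = getattr(m, "m", m)
    h_t = getattr(h_prot, "embedding", h_prot)
    if not isinstance(m_t, Tensor):
        m_t = Tensor(np.atleast_2d(m_t))
    if not isinstance(h_t, Tensor):
        h_t = Tensor(np.atleast_2d(h_t))
    return ad.concat([m_t, h_t], axis=1)


def mlp_forward(x, params: MLP) -> float:
    """Score a pair representation: sigmoid of the MLP's single logit."""
    x_t = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(np.asarray(x, dtype=float)))
    logit = params.forward(x_t)
    return float(ad.sigmoid(logit).data.ravel()[0])


# ---------------------------------------------------------------------------
# feature cache (per-entity featurization computed once per run)
# ---------------------------------------------------------------------------

class FeatureCache:
    """Lazily computed, memoised per-entity features for a dataset."""

    def __init__(self, dataset: InteractionDataset,
                 descriptor_groups=("AAC", "DC", "CTD"), fingerprint_bits: int = 1021):
        self.dataset = dataset
        self.descriptor_groups = descriptor_groups
        self.fingerprint_bits = fingerprint_bits
        self._node_feats: dict[str, np.ndarray] = {}
        self._onehots: dict[str, np.ndarray] = {}
        self._mol_desc: dict[str, np.ndarray] = {}
        self._prot_desc: dict[str, np.ndarray] = {}

    def node_features(self, mol_id: str) -> np.ndarray:
        if mol_id not in self._node_feats:
            self._node_feats[mol_id] = atom_features(self.dataset.molecule(mol_id))
        return self._node_feats[mol_id]

    def onehot(self, prot_id: str) -> np.ndarray:
        if prot_id not in self._onehots:
            self._onehots[prot_id] = aa_onehot(self.dataset.protein(prot_id))
        return self._onehots[prot_id]

    def mol_descriptor(self, mol_id: str) -> np.ndarray:
        if mol_id not in self._mol_desc:
            self._mol_desc[mol_id] = molecule_fingerprint(
                self.dataset.molecule(mol_id), n_bits=self.fingerprint_bits)
        return self._mol_desc[mol_id]

    def prot_descriptor(self, prot_id: str) -> np.ndarray:
        if prot_id not in self._prot_desc:
            self._prot_desc[prot_id] = protein_descriptors(
                self.dataset.protein(prot_id), self.descriptor_groups)
        return self._prot_desc[prot_id]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class _BlockModel:
    """Shared plumbing: named parameter blocks, freezing, checkpoints."""

    blocks: dict[str, object]

    def __init__(self):
        self.frozen: set[str] = set()

    def trainable_parameters(self) -> list[Tensor]:
        out = []
        for name, block in self.blocks.items():
            if name not in self.frozen:
                out.extend(block.parameters())
        return out

    def all_parameters(self) -> list[Tensor]:
        out = []
        for block in self.blocks.values():
            out.extend(block.parameters())
        return out

    def state_dict(self) -> dict[str, dict[str, np.ndarray]]:
        return {name: block.state_dict() for name, block in self.blocks.items()}

    def load_state_dict(self, state: dict[str, dict[str, np.ndarray]]) -> None:
        for name, block_state in state.items():
            self.blocks[name].load_state_dict(block_state)


class CNModel(_BlockModel):
    """The chemogenomic network: GNN molecule encoder + CNN protein
    encoder + concatenation + pair MLP."""

    block_names = ("molecule_encoder", "protein_encoder", "pair_mlp")

    def __init__(self, molecule_encoder: GNNParams, protein_encoder: CNNParams,
                 pair_mlp: MLP):
        super().__init__()
        expected = molecule_encoder.hidden_dim + protein_encoder.n_filters
        if pair_mlp.in_dim != expected:
            raise NetworkError(
                f"pair MLP input width {pair_mlp.in_dim} must equal molecule + "
                f"protein embedding dims ({expected})"
            )
        self.molecule_encoder = molecule_encoder
        self.protein_encoder = protein_encoder
        self.pair_mlp = pair_mlp
        self.blocks = {"molecule_encoder": molecule_encoder,
                       "protein_encoder": protein_encoder,
                       "pair_mlp": pair_mlp}

    def forward_logit(self, mol_id: str, prot_id: str, cache: FeatureCache,
                      training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> Tensor:
        graph = cache.dataset.molecule(mol_id)
        protein = cache.dataset.protein(prot_id)
        emb = encode_molecule(graph, cache.node_features(mol_id), self.molecule_encoder)
        prot = encode_protein(protein, self.protein_encoder, onehot=cache.onehot(prot_id))
        pair = comb_concat(emb, prot)
        return self.pair_mlp.forward(pair, training=training, rng=rng)


class FNNModel(_BlockModel):
    """Reference deep model: MLP on concatenated expert descriptors
    (Morgan fingerprint bits + protein composition blocks), default
    hidden widths 2000/1000/100."""

    def __init__(self, pair_mlp: MLP):
        super().__init__()
        self.pair_mlp = pair_mlp
        self.blocks = {"pair_mlp": pair_mlp}

    @classmethod
    def default(cls, mol_dim: int = 1021, prot_dim: int = 567,
                hidden: Sequence[int] = (2000, 1000, 100), dropout: float = 0.0,
                rng: Optional[np.random.Generator] = None) -> "FNNModel":
        return cls(MLP(mol_dim + prot_dim, hidden=hidden, out_dim=1,
                       dropout=dropout, rng=rng))

    def forward_logit(self, mol_id: str, prot_id: str, cache: FeatureCache,
                      training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> Tensor:
        x = Tensor(np.concatenate([cache.mol_descriptor(mol_id),
                                   cache.prot_descriptor(prot_id)])[None, :])
        return self.pair_mlp.forward(x, training=training, rng=rng)


class CNFeaMLPModel(_BlockModel):
    """Two-branch multi-view model fused by a small joint layer.

    Learnt branch: CN-style pair representation -> MLP_raw-pair.
    Expert branch: concatenated descriptors -> MLP_fea-pair.
    The two branch outputs are concatenated into MLP_pair-pair, whose
    single logit scores the pair.
    """

    def __init__(self, molecule_encoder: GNNParams, protein_encoder: CNNParams,
                 mlp_raw_pair: MLP, mlp_fea_pair: MLP, mlp_pair_pair: MLP):
        super().__init__()
        if mlp_pair_pair.in_dim != mlp_raw_pair.out_dim + mlp_fea_pair.out_dim:
            raise NetworkError("joint MLP input width must equal the sum of "
                               "branch output widths")
        self.molecule_encoder = molecule_encoder
        self.protein_encoder = protein_encoder
        self.mlp_raw_pair = mlp_raw_pair
        self.mlp_fea_pair = mlp_fea_pair
        self.mlp_pair_pair = mlp_pair_pair
        self.blocks = {
            "molecule_encoder": molecule_encoder,
            "protein_encoder": protein_encoder,
            "mlp_raw_pair": mlp_raw_pair,
            "mlp_fea_pair": mlp_fea_pair,
            "mlp_pair_pair": mlp_pair_pair,
        }

    def branch_outputs(self, mol_id: str, prot_id: str, cache: FeatureCache,
                       training: bool = False,
                       rng: Optional[np.random.Generator] = None) -> tuple[Tensor, Tensor]:
        graph = cache.dataset.molecule(mol_id)
        protein = cache.dataset.protein(prot_id)
        emb = encode_molecule(graph, cache.node_features(mol_id), self.molecule_encoder)
        prot = encode_protein(protein, self.protein_encoder, onehot=cache.onehot(prot_id))
        learnt = self.mlp_raw_pair.forward(comb_concat(emb, prot), training, rng)
        desc = Tensor(np.concatenate([cache.mol_descriptor(mol_id),
                                      cache.prot_descriptor(prot_id)])[None, :])
        expert = self.mlp_fea_pair.forward(desc, training, rng)
        return learnt, expert

    def forward_logit(self, mol_id: str, prot_id: str, cache: FeatureCache,
                      training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> Tensor:
        learnt, expert = self.branch_outputs(mol_id, prot_id, cache, training, rng)
        joint = ad.concat([ad.relu(learnt), ad.relu(expert)], axis=1)
        return self.mlp_pair_pair.forward(joint, training=training, rng=rng)

    def silence_branch(self, which: str) -> None:
        """Zero the joint MLP's first-layer weights fed by one branch
        (``expert`` or ``learnt``), making the output independent of
        it — the branch-ablation sanity check."""
        split = self.mlp_raw_pair.out_dim
        w = self.mlp_pair_pair.weights[0].data
        if which == "expert":
            w[split:, :] = 0.0
        elif which == "learnt":
            w[:split, :] = 0.0
        else:
            raise NetworkError(f"unknown branch {which!r}")


class CNOneStepModel(_BlockModel):
    """One-step multi-view model: GNN embedding, CNN embedding and the
    two descriptor-MLP outputs concatenated into a single MLP_pair."""

    def __init__(self, molecule_encoder: GNNParams, protein_encoder: CNNParams,
                 mlp_fea_mol: MLP, mlp_fea_prot: MLP, pair_mlp: MLP):
        super().__init__()
        expected = (molecule_encoder.hidden_dim + protein_encoder.n_filters
                    + mlp_fea_mol.out_dim + mlp_fea_prot.out_dim)
        if pair_mlp.in_dim != expected:
            raise NetworkError(
                f"pair MLP input width {pair_mlp.in_dim} must equal the sum of "
                f"the four representation dims ({expected})"
            )
        self.molecule_encoder = molecule_encoder
        self.protein_encoder = protein_encoder
        self.mlp_fea_mol = mlp_fea_mol
        self.mlp_fea_prot = mlp_fea_prot
        self.pair_mlp = pair_mlp
        self.blocks = {
            "molecule_encoder": molecule_encoder,
            "protein_encoder": protein_encoder,
            "mlp_fea_mol": mlp_fea_mol,
            "mlp_fea_prot": mlp_fea_prot,
            "pair_mlp": pair_mlp,
        }

    def forward_logit(self, mol_id: str, prot_id: str, cache: FeatureCache,
                      training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> Tensor:
        graph = cache.dataset.molecule(mol_id)
        protein = cache.dataset.protein(prot_id)
        emb = encode_molecule(graph, cache.node_features(mol_id), self.molecule_encoder)
        prot = encode_protein(protein, self.protein_encoder, onehot=cache.onehot(prot_id))
        fea_mol = ad.relu(self.mlp_fea_mol.forward(
            Tensor(cache.mol_descriptor(mol_id)[None, :]), training, rng))
        fea_prot = ad.relu(self.mlp_fea_prot.forward(
            Tensor(cache.prot_descriptor(prot_id)[None, :]), training, rng))
        rep = ad.concat([emb.m, prot.embedding, fea_mol, fea_prot], axis=1)
        return self.pair_mlp.forward(rep, training=training, rng=rng)


# prediction conveniences -----------------------------------------------------

def _score(logit: Tensor) -> float:
    return float(ad.sigmoid(logit).data.ravel()[0])


def cn_predict(mol_id: str, prot_id: str, model: CNModel, cache: FeatureCache) -> float:
    """Interaction score in [0, 1] for one (molecule, protein) pair."""
    return _score(model.forward_logit(mol_id, prot_id, cache))


def fnn_predict(mol_descriptors, prot_descriptors, params: MLP) -> float:
    x = np.concatenate([np.asarray(mol_descriptors, dtype=float),
                        np.asarray(prot_descriptors, dtype=float)])
    return mlp_forward(x, params)


def cn_feamlp_predict(mol_id: str, prot_id: str, model: CNFeaMLPModel,
                      cache: FeatureCache) -> float:
    return _score(model.forward_logit(mol_id, prot_id, cache))


def cn_onestep_predict(mol_id: str, prot_id: str, model: CNOneStepModel,
                       cache: FeatureCache) -> float:
    return _score(model.forward_logit(mol_id, prot_id, cache))


# default constructions -------------------------------------------------------

def default_cn_model(input_dim: int, seed: int = 0, hidden_dim: int = 100,
                     n_filters: int = 100, gnn_layers: int = 3, cnn_layers: int = 3,
                     filter_size: int = 8, stride: int = 3,
                     mlp_hidden: Sequence[int] = (100,), dropout: float = 0.0) -> CNModel:
    """CN with the tuned default hyper-parameters (100 filters, 3 conv
    layers, stride 3, filter size 8, last prediction layer of 100
    units, no dropout or weight decay)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    gnn = GNNParams(input_dim, hidden_dim=hidden_dim, n_layers=gnn_layers, rng=rng)
    cnn = CNNParams(in_channels=20, n_filters=n_filters, n_layers=cnn_layers,
                    filter_size=filter_size, stride=stride, rng=rng)
    mlp = MLP(hidden_dim + n_filters, hidden=mlp_hidden, out_dim=1,
              dropout=dropout, rng=rng)
    return CNModel(gnn, cnn, mlp)


def smoke_cn_model(input_dim: int, seed: int = 0) -> CNModel:
    """Down-scaled CN (32-dim embeddings, 2 layers per encoder, ReLU
    node updates) used by the synthetic-data learnability checks; the
    architecture is the same, only widths shrink, and the ReLU switch
    converges in far fewer epochs than the default sigmoid on the
    planted-motif task."""
    model = default_cn_model(input_dim, seed=seed, hidden_dim=32, n_filters=32,
                             gnn_layers=2, cnn_layers=2, mlp_hidden=(32,))
    model.molecule_encoder.activation = "relu"
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimisation settings.

    Defaults are the tuned values: initial learning rate 1e-3 decayed
    by 0.9 after every epoch, batch size 20 (use 100 for the FNN), at
    most 100 epochs with early stopping once the validation AUPR has
    not increased for 10 successive epochs, binary cross-entropy loss,
    Adam, and a 1:5 train positive:negative ratio.  Negatives are
    drawn once per run; ``resample_negatives_per_epoch`` redraws them
    every epoch instead.
    """

    learning_rate: float = 1e-3
    lr_decay: float = 0.9
    batch_size: int = 20
    max_epochs: int = 100
    patience: int = 10
    negative_ratio: str = "1:5"
    loss: str = "bce"
    optimizer: str = "adam"
    weight_decay: float = 0.0
    seed: int = 0
    resample_negatives_per_epoch: bool = False

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise NetworkError("patience must not exceed max_epochs")
        pos, neg = parse_ratio(self.negative_ratio)
        if neg < pos:
            raise NetworkError("negative ratio must be at least 1:1")
        if self.loss != "bce":
            raise NetworkError(f"unsupported loss {self.loss!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise NetworkError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_aupr: list[float] = field(default_factory=list)
    val_rocauc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_json_lines(self) -> str:
        lines = []
        for e, (l, a, r) in enumerate(zip(self.train_loss, self.val_aupr,
                                          self.val_rocauc), start=1):
            lines.append(json.dumps({"epoch": e, "train_loss": l,
                                     "val_aupr": a, "val_rocauc": r}))
        return "\n".join(lines)


class _SGD:
    def __init__(self, params, lr, weight_decay=0.0):
        self.params, self.lr, self.weight_decay = list(params), lr, weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            p.data -= self.lr * g


def build_labeled_split(dataset: InteractionDataset, ratio="1:5", seed: int = 0,
                        val_fraction: float = 0.2,
                        positives: Optional[list] = None):
    """Split positives into train/validation and attach sampled
    negatives at the given ratio to each part (disjoint pools)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
    pos = list(positives if positives is not None else dataset.positives)
    order = rng.permutation(len(pos))
    n_val = max(1, int(round(val_fraction * len(pos))))
    val_pos = [pos[i] for i in order[:n_val]]
    train_pos = [pos[i] for i in order[n_val:]]
    all_pairs = [(m, p) for m in dataset.molecule_ids for p in dataset.protein_ids]
    negatives = sample_negatives(dataset, all_pairs, ratio, seed,
                                 n_positives=len(pos))
    n_val_neg = max(1, int(round(val_fraction * len(negatives))))
    val = [(m, p, 1) for m, p in val_pos] + [(m, p, 0) for m, p in negatives[:n_val_neg]]
    trn = [(m, p, 1) for m, p in train_pos] + [(m, p, 0) for m, p in negatives[n_val_neg:]]
    return trn, val


def _predict_scores(model, pairs, cache) -> np.ndarray:
    return np.array([_score(model.forward_logit(m, p, cache)) for m, p in pairs])


def train(model, dataset: InteractionDataset, train_pairs, val_pairs,
          config: TrainingConfig, cache: Optional[FeatureCache] = None):
    """Train any block model on labeled (mol_id, prot_id, label) pairs.

    Returns ``(model, history)``; the model carries the parameters of
    the epoch with the best validation AUPR.
    """
    if not train_pairs or not val_pairs:
        raise NetworkError("train and validation sets must be non-empty")
    overlap = {(m, p) for m, p, _ in train_pairs} & {(m, p) for m, p, _ in val_pairs}
    if overlap:
        raise NetworkError(f"train/validation overlap on {len(overlap)} pairs")
    if cache is None:
        cache = FeatureCache(dataset)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 41)))
    params = model.trainable_parameters()
    if config.optimizer == "adam":
        opt = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    else:
        opt = _SGD(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    history = TrainingHistory()
    best_aupr, best_state, epochs_since_best = -np.inf, None, 0
    train_pos = [(m, p) for m, p, lbl in train_pairs if lbl == 1]
    current_train = list(train_pairs)
    val_label_list = [lbl for *_, lbl in val_pairs]
    val_pair_list = [(m, p) for m, p, _ in val_pairs]
    for epoch in range(1, config.max_epochs + 1):
        if config.resample_negatives_per_epoch and epoch > 1:
            all_pairs = [(m, p) for m in dataset.molecule_ids
                         for p in dataset.protein_ids]
            negs = sample_negatives(dataset, all_pairs, config.negative_ratio,
                                    config.seed + epoch, n_positives=len(train_pos))
            current_train = ([(m, p, 1) for m, p in train_pos]
                             + [(m, p, 0) for m, p in negs])
        order = rng.permutation(len(current_train))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [current_train[i] for i in order[start:start + config.batch_size]]
            logits = ad.concat(
                [model.forward_logit(m, p, cache, training=True, rng=rng)
                 for m, p, _ in batch], axis=0)
            loss = ad.bce_with_logits(logits, np.array([[lbl] for *_, lbl in batch],
                                                       dtype=float))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        scores = _predict_scores(model, val_pair_list, cache)
        epoch_aupr = aupr(scores, val_label_list)
        epoch_roc = roc_auc(scores, val_label_list)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_aupr.append(epoch_aupr)
        history.val_rocauc.append(epoch_roc)
        if epoch_aupr > best_aupr:
            best_aupr = epoch_aupr
            best_state = model.state_dict()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        history.stopped_epoch = epoch
        if epochs_since_best >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, history.best_epoch)
            break
        opt.lr *= config.lr_decay
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# masked multi-task pre-training
# ---------------------------------------------------------------------------

def multitask_loss(encoder: GNNParams, head: MLP, molecules, node_feats,
                   labels: MultiTaskLabels, indices) -> Tensor:
    """Masked multi-task BCE over a batch of molecule indices: the
    error of (molecule, task) entries labelled unknown is set to
    zero, so they contribute neither loss nor gradient."""
    logits_rows, target_rows, mask_rows = [], [], []
    targets, mask = labels.targets(), labels.mask()
    for i in indices:
        emb = encode_molecule(molecules[i], node_feats[i], encoder)
        logits_rows.append(head.forward(emb.m))
        target_rows.append(targets[i])
        mask_rows.append(mask[i])
    logits = ad.concat(logits_rows, axis=0)
    return ad.bce_with_logits(logits, np.array(target_rows), mask=np.array(mask_rows))


def pretrain_multitask(encoder: GNNParams, molecules, labels: MultiTaskLabels,
                       head: Optional[MLP] = None,
                       config: Optional[TrainingConfig] = None):
    """Pre-train a molecule encoder on bioassay-style multi-task labels.

    A sigmoid head maps molecule embeddings to per-task logits; the
    BCE of unknown entries is masked out.  Tasks whose labels are all
    unknown are skipped with a warning.  Returns
    ``(encoder_state, head, losses)`` — the encoder block checkpoint,
    the fitted head, and the per-epoch loss trace.
    """
    if config is None:
        config = TrainingConfig(max_epochs=10, patience=10)
    if labels.matrix.shape[0] != len(molecules):
        raise NetworkError("label matrix must align with the molecule list")
    observed_per_task = (labels.matrix >= 0).sum(axis=0)
    dead = np.flatnonzero(observed_per_task == 0)
    if len(dead):
        logger.warning("skipping %d all-unknown tasks: %s", len(dead), dead.tolist())
    if head is None:
        head = MLP(encoder.hidden_dim, hidden=(), out_dim=labels.n_tasks,
                   rng=np.random.default_rng(np.random.SeedSequence((config.seed, 51))))
    node_feats = [atom_features(m) for m in molecules]
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 52)))
    opt = Adam([*encoder.parameters(), *head.parameters()],
               lr=config.learning_rate, weight_decay=config.weight_decay)
    losses = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(molecules))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = multitask_loss(encoder, head, molecules, node_feats, labels, idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        opt.lr *= config.lr_decay
    return encoder.state_dict(), head, losses


# ---------------------------------------------------------------------------
# checkpoints and transfer
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: _BlockModel, config: Optional[dict] = None) -> None:
    """Versioned multi-block checkpoint (NumPy archive, one entry per
    parameter plus a JSON metadata record)."""
    arrays = {}
    block_configs = {}
    for block_name, block in model.blocks.items():
        for key, value in block.state_dict().items():
            arrays[f"{block_name}/{key}"] = value
        if hasattr(block, "config_dict"):
            block_configs[block_name] = block.config_dict()
    meta = {"schema_version": CHECKPOINT_SCHEMA_VERSION,
            "blocks": list(model.blocks), "block_configs": block_configs,
            "config": config or {}}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns ``(block_states, meta)``."""
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise NetworkError(
                f"unsupported checkpoint schema {meta.get('schema_version')!r}"
            )
        states: dict[str, dict[str, np.ndarray]] = {}
        for key in archive.files:
            if key == "__meta__":
                continue
            block_name, param_key = key.split("/", 1)
            states.setdefault(block_name, {})[param_key] = archive[key]
    return states, meta


def transfer_load(model: _BlockModel, checkpoint, blocks: Iterable[str],
                  freeze: Iterable[str] = ()) -> _BlockModel:
    """Initialise named blocks from a checkpoint; frozen blocks are
    excluded from gradient updates.  Unlisted blocks keep their
    current (seeded random) initialisation."""
    if isinstance(checkpoint, (str, bytes)) or hasattr(checkpoint, "__fspath__"):
        states, _ = load_checkpoint(checkpoint)
    else:
        states = checkpoint
    blocks = list(blocks)
    freeze = set(freeze)
    unknown = (set(blocks) | freeze) - set(model.blocks)
    if unknown:
        raise NetworkError(f"unknown blocks {sorted(unknown)}; "
                           f"model has {sorted(model.blocks)}")
    for name in blocks:
        if name not in states:
            raise NetworkError(f"checkpoint lacks block {name!r}")
        try:
            model.blocks[name].load_state_dict(states[name])
        except (KeyError, ValueError) as exc:
            raise NetworkError(f"block {name!r}: {exc}") from exc
    model.frozen |= freeze
    return model
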