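"""Synthetic molecules, proteins, interaction datasets and
partially-observed multi-task bioassay labels.

The generators emulate the statistical shape of curated DTI data:
drug-like small connected graphs, amino-acid sequences over the
20-letter alphabet, sparse positive interaction matrices in which most
entities carry only a few known interactions, and bioassay-style
active/inactive/unknown label matrices.  Two interaction rules are
available:

``motif_match``
    A pair interacts iff the protein carries planted sequence motif k
    and the molecule carries the matching planted node pattern (a
    marker element).  This plants a signal both encoders can recover,
    so end-to-end learnability is testable.

``latent_factor``
    Interaction probability is logistic(u_m . v_p + b) with i.i.d.
    normal latent vectors and b calibrated to a target positive rate.

Everything is reproducible under the config seed; per-entity RNG
streams are split so enlarging one entity set does not perturb the
draws of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from chemodti.chem_io import (
    AMINO_ACIDS,
    AtomAnnotation,
    BondAnnotation,
    InteractionDataset,
    MolecularGraph,
    ProteinSequence,
)
from chemodti.featurize import molecule_fingerprint

__all__ = [
    "GeneratorConfig",
    "MultiTaskLabels",
    "generate_molecules",
    "generate_proteins",
    "generate_interactions",
    "generate_dataset",
    "generate_multitask_bioassays",
]

#: drug-like element frequencies for non-marker atoms
_ELEMENT_POOL = ("C", "N", "O", "S", "F", "Cl")
_ELEMENT_PROBS = (0.70, 0.12, 0.12, 0.03, 0.02, 0.01)

#: default planted (protein motif, molecule marker element) pairs; the
#: marker elements are rare halogens absent from the background pool
DEFAULT_MOTIF_PAIRS = (("WHWKW", "I"), ("MCMFM", "Br"))


class SyntheticDataError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic DTI data.

    Defaults emulate a small curated interaction set: a couple hundred
    drug-sized molecules (8-18 heavy atoms), proteins of 40-80
    residues (short, so the strided convolutional encoder still sees
    several motif-scale windows), and a sparse positive matrix — with
    ``carrier_fraction`` 0.15 most entities have no known partner at
    all, mirroring the long tail of curated interaction data.

    ``max_positives_per_entity`` truncates each entity's positive list
    (per-entity sparsification).  It is off by default for the motif
    rule: motif matches form bipartite carrier blocks, so a cap would
    silently relabel most true matches as unlabelled and put a low
    ceiling on every downstream ranking metric; enable it only when
    emulating that kind of censoring is the point.
    """

    seed: int = 0
    n_molecules: int = 200
    n_proteins: int = 100
    molecule_size_range: tuple[int, int] = (8, 18)
    protein_length_range: tuple[int, int] = (40, 80)
    rule: str = "motif_match"
    target_positive_rate: float = 0.05
    latent_dim: int = 8
    motif_pairs: tuple = DEFAULT_MOTIF_PAIRS
    carrier_fraction: float = 0.15
    max_positives_per_entity: Optional[int] = None
    extra_edge_fraction: float = 0.3

    def __post_init__(self):
        lo, hi = self.molecule_size_range
        if lo < 1 or hi < lo:
            raise SyntheticDataError(f"invalid molecule size range {self.molecule_size_range}")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise SyntheticDataError(f"invalid protein length range {self.protein_length_range}")
        if not 0.0 < self.target_positive_rate < 1.0:
            raise SyntheticDataError("target_positive_rate must be in (0,1)")
        if self.rule not in ("motif_match", "latent_factor"):
            raise SyntheticDataError(f"unknown rule {self.rule!r}")

    def _rng(self, stream: str) -> np.random.Generator:
        # independent named streams derived from the one seed
        offset = {"molecules": 0, "proteins": 1, "interactions": 2, "labels": 3}[stream]
        return np.random.default_rng(np.random.SeedSequence((self.seed, offset)))


@dataclass
class MultiTaskLabels:
    """(n_molecules x n_tasks) matrix with entries +1 (active),
    0 (inactive), -1 (unknown)."""

    matrix: np.ndarray
    molecule_ids: list[str]

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.molecule_ids):
            raise SyntheticDataError("label matrix rows must match molecule list")

    @property
    def n_tasks(self) -> int:
        return self.matrix.shape[1]

    def mask(self) -> np.ndarray:
        """1 where the label is observed, 0 where unknown."""
        return (self.matrix >= 0).astype(float)

    def targets(self) -> np.ndarray:
        """0/1 targets with unknown entries zeroed (they are masked)."""
        return np.where(self.matrix > 0, 1.0, 0.0)


def _random_connected_graph(rng: np.random.Generator, n: int, extra_fraction: float):
    """Random labelled tree plus a few extra edges -> connected graph."""
    edges = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))  # random recursive tree: connected by construction
        edges.add((j, i))
    n_extra = int(round(extra_fraction * n))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.add(tuple(sorted((int(i), int(j)))))
    return sorted(edges)


def _ring_membership(n: int, edges: list) -> tuple[set, set]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    ring_nodes: set[int] = set()
    ring_edges: set[tuple[int, int]] = set()
    for cycle in nx.cycle_basis(g):
        ring_nodes.update(cycle)
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add(tuple(sorted((a, b))))
    return ring_nodes, ring_edges


def generate_molecules(config: GeneratorConfig) -> list[MolecularGraph]:
    """Connected graphs with schema-valid synthetic annotations.

    A ``carrier_fraction`` subset carries one marker atom whose element
    is the node pattern of one of the configured motif pairs.
    """
    rng = config._rng("molecules")
    lo, hi = config.molecule_size_range
    out = []
    n_pairs = len(config.motif_pairs)
    for m in range(config.n_molecules):
        n = int(rng.integers(lo, hi + 1))
        edges = _random_connected_graph(rng, n, config.extra_edge_fraction)
        ring_nodes, ring_edges = _ring_membership(n, edges)
        degree = np.zeros(n, dtype=int)
        for i, j in edges:
            degree[i] += 1
            degree[j] += 1
        elements = list(rng.choice(_ELEMENT_POOL, size=n, p=_ELEMENT_PROBS))
        if n_pairs and rng.random() < config.carrier_fraction:
            k = int(rng.integers(n_pairs))
            elements[int(rng.integers(n))] = config.motif_pairs[k][1]
        atoms = []
        for i in range(n):
            atoms.append(AtomAnnotation(
                element=str(elements[i]),
                n_hydrogens=max(0, 4 - int(degree[i]) - int(rng.integers(0, 2))),
                heavy_degree=int(degree[i]),
                formal_charge=0,
                in_ring=i in ring_nodes,
                aromatic=False,
                chirality="none",
                partial_charge=float(rng.normal(0.0, 0.1)),
                tpsa=float(abs(rng.normal(0.0, 5.0))) if elements[i] in ("N", "O") else 0.0,
            ))
        bonds = {}
        for e in edges:
            double = e not in ring_edges and rng.random() < 0.15
            bonds[e] = BondAnnotation(
                bond_type="double" if double else "single",
                in_ring=e in ring_edges,
                aromatic=False,
                conjugated=bool(double),
            )
        out.append(MolecularGraph(id=f"M{m:05d}", n_atoms=n, edges=list(edges),
                                  atoms=atoms, bonds=bonds))
    return out


def generate_proteins(config: GeneratorConfig) -> list[ProteinSequence]:
    """I.i.d. residues with motifs planted at random positions in a
    ``carrier_fraction`` subset."""
    rng = config._rng("proteins")
    lo, hi = config.protein_length_range
    aas = np.array(list(AMINO_ACIDS))
    out = []
    n_pairs = len(config.motif_pairs)
    for p in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(aas, size=length))
        if n_pairs and rng.random() < config.carrier_fraction:
            k = int(rng.integers(n_pairs))
            motif = config.motif_pairs[k][0]
            if length >= len(motif):
                start = int(rng.integers(0, length - len(motif) + 1))
                seq[start:start + len(motif)] = list(motif)
        out.append(ProteinSequence(id=f"P{p:05d}", residues="".join(seq)))
    return out


def molecule_pattern_index(graph: MolecularGraph, motif_pairs) -> Optional[int]:
    """Index of the motif pair whose marker element the molecule
    carries, or None."""
    elements = {a.element for a in graph.atoms}
    for k, (_, marker) in enumerate(motif_pairs):
        if marker in elements:
            return k
    return None


def protein_motif_index(protein: ProteinSequence, motif_pairs) -> Optional[int]:
    for k, (motif, _) in enumerate(motif_pairs):
        if motif in protein.residues:
            return k
    return None


def generate_interactions(molecules, proteins, config: GeneratorConfig):
    """Sample positive pairs under the configured rule.

    Returns ``(dataset, truth)`` where ``truth`` is the ground-truth
    interaction probability matrix (n_molecules x n_proteins), usable
    as an oracle scorer in evaluation tests.

    motif_match: the truth is the 0/1 match matrix and positives are
    the matching pairs, optionally capped at
    ``max_positives_per_entity`` per molecule and per protein (visit
    order randomised).  latent_factor: Bernoulli draws from calibrated
    logistic probabilities (never capped, so the empirical rate tracks
    the target).
    """
    rng = config._rng("interactions")
    n_mol, n_prot = len(molecules), len(proteins)
    if config.rule == "motif_match":
        mol_idx = np.array([
            -1 if (k := molecule_pattern_index(m, config.motif_pairs)) is None else k
            for m in molecules
        ])
        prot_idx = np.array([
            -1 if (k := protein_motif_index(p, config.motif_pairs)) is None else k
            for p in proteins
        ])
        truth = ((mol_idx[:, None] >= 0) & (mol_idx[:, None] == prot_idx[None, :])).astype(float)
        candidates = np.argwhere(truth > 0)
        order = rng.permutation(len(candidates))
        cap = config.max_positives_per_entity
        mol_count = np.zeros(n_mol, dtype=int)
        prot_count = np.zeros(n_prot, dtype=int)
        positives = []
        for t in order:
            i, j = candidates[t]
            if cap is not None and (mol_count[i] >= cap or prot_count[j] >= cap):
                continue
            mol_count[i] += 1
            prot_count[j] += 1
            positives.append((molecules[i].id, proteins[j].id))
        positives.sort()
    else:  # latent_factor
        u = rng.normal(size=(n_mol, config.latent_dim)) / np.sqrt(config.latent_dim)
        v = rng.normal(size=(n_prot, config.latent_dim)) / np.sqrt(config.latent_dim)
        logits = u @ v.T
        lo, hi = -30.0, 30.0  # bisect the intercept to hit the target rate
        for _ in range(80):
            b = 0.5 * (lo + hi)
            if _expit(logits + b).mean() > config.target_positive_rate:
                hi = b
            else:
                lo = b
        truth = _expit(logits + 0.5 * (lo + hi))
        draws = rng.random(truth.shape) < truth
        positives = [(molecules[i].id, proteins[j].id) for i, j in np.argwhere(draws)]
    if not positives:
        raise SyntheticDataError(
            "no positives generated; increase target_positive_rate or carrier_fraction"
        )
    dataset = InteractionDataset(list(molecules), list(proteins), positives)
    return dataset, truth


def _expit(x):
    from scipy.special import expit

    return expit(x)


def generate_dataset(config: GeneratorConfig):
    """Molecules + proteins + interactions in one call."""
    molecules = generate_molecules(config)
    proteins = generate_proteins(config)
    dataset, truth = generate_interactions(molecules, proteins, config)
    return dataset, truth


def generate_multitask_bioassays(molecules, n_tasks: int = 90,
                                 unknown_fraction: float = 0.4,
                                 seed: int = 0,
                                 config: Optional[GeneratorConfig] = None) -> MultiTaskLabels:
    """Bioassay-style multi-task labels over molecule fingerprints.

    Each task thresholds a random sparse linear score of the 1021-bit
    fingerprint at its median, so a molecule encoder can learn the
    tasks; a ``unknown_fraction`` of entries is masked as untested.
    """
    if not 0.0 <= unknown_fraction < 1.0:
        raise SyntheticDataError("unknown_fraction must be in [0, 1)")
    rng = (config._rng("labels") if config is not None
           else np.random.default_rng(np.random.SeedSequence((seed, 3))))
    fps = np.array([molecule_fingerprint(m) for m in molecules])
    n_mol, n_bits = fps.shape
    matrix = np.zeros((n_mol, n_tasks), dtype=np.int8)
    for t in range(n_tasks):
        w = rng.normal(size=n_bits) * (rng.random(n_bits) < 0.05)
        score = fps @ w
        matrix[:, t] = (score > np.median(score)).astype(np.int8)
    unknown = rng.random(matrix.shape) < unknown_fraction
    matrix[unknown] = -1
    return MultiTaskLabels(matrix=matrix, molecule_ids=[m.id for m in molecules])
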