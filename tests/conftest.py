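"""Shared fixtures: tiny hand-built and generated datasets."""

import numpy as np
import pytest

from chemodti.chem_io import (
    AtomAnnotation,
    BondAnnotation,
    InteractionDataset,
    MolecularGraph,
    ProteinSequence,
)
from chemodti.synthetic_data import GeneratorConfig, generate_dataset


def toy_molecule(mol_id: str, n_atoms: int = 3, elements=None) -> MolecularGraph:
    """Path graph with minimal schema-valid annotations."""
    elements = elements or ["C"] * n_atoms
    edges = [(i, i + 1) for i in range(n_atoms - 1)]
    return MolecularGraph(
        id=mol_id,
        n_atoms=n_atoms,
        edges=edges,
        atoms=[AtomAnnotation(element=e, heavy_degree=(1 if i in (0, n_atoms - 1) else 2)
                              if n_atoms > 1 else 0)
               for i, e in enumerate(elements)],
        bonds={e: BondAnnotation() for e in edges},
    )


def toy_protein(prot_id: str, residues: str = "ACDEFGHIKLMNPQRS") -> ProteinSequence:
    return ProteinSequence(id=prot_id, residues=residues)


def toy_dataset(n_mol: int = 8, n_prot: int = 8, positives=None) -> InteractionDataset:
    rng = np.random.default_rng(123)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    molecules = [toy_molecule(f"M{i}", n_atoms=3 + i % 4) for i in range(n_mol)]
    proteins = [
        toy_protein(f"P{j}", "".join(rng.choice(list(aas), size=24)))
        for j in range(n_prot)
    ]
    if positives is None:
        positives = [(f"M{i}", f"P{(i * 3 + 1) % n_prot}") for i in range(n_mol)]
    return InteractionDataset(molecules, proteins, positives)


@pytest.fixture(scope="session")
def tiny_generated():
    """Small generated motif-rule dataset shared across tests."""
    config = GeneratorConfig(seed=7, n_molecules=30, n_proteins=20,
                             molecule_size_range=(5, 9),
                             protein_length_range=(25, 40),
                             carrier_fraction=0.5)
    dataset, truth = generate_dataset(config)
    return config, dataset, truth


@pytest.fixture
def toy_interactions():
    return toy_dataset()
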