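"""Input featurization: atom/bond attribute vectors for the graph
encoder, one-hot residue matrices for the sequence encoder, and
expert-based descriptor vectors (circular fingerprints; AAC/DC/CTD
protein blocks) for the descriptor-driven baselines.

All featurizers are deterministic, operate purely on the annotation
records carried by :class:`~chemodti.chem_io.MolecularGraph` /
:class:`~chemodti.chem_io.ProteinSequence`, and therefore apply
unchanged to parsed and synthetic entities.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from chemodti.chem_io import (
    AMINO_ACIDS,
    BOND_TYPES,
    CHIRALITY_TAGS,
    MolecularGraph,
    ProteinSequence,
)

logger = logging.getLogger(__name__)

#: default one-hot element list for drug-like chemistry; anything else
#: maps to the trailing "other" slot
DEFAULT_ELEMENTS = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I")

#: atom attribute vector layout: element one-hot (incl. "other"),
#: scalar physicochemical entries, chirality one-hot
ATOM_FEATURE_DIM = len(DEFAULT_ELEMENTS) + 1 + 7 + len(CHIRALITY_TAGS)
BOND_FEATURE_DIM = len(BOND_TYPES) + 3


class FeaturizeError(ValueError):
    pass


def atom_features(graph: MolecularGraph, elements=DEFAULT_ELEMENTS) -> np.ndarray:
    """Per-atom attribute vectors x_i, shape (n_atoms, d).

    Layout: element one-hot (len(elements) + "other"), then scalars
    [n_hydrogens, heavy_degree, formal_charge, in_ring, aromatic,
    tpsa, partial_charge], then chirality one-hot.
    """
    n_elem = len(elements) + 1
    out = np.zeros((graph.n_atoms, n_elem + 7 + len(CHIRALITY_TAGS)))
    elem_index = {e: k for k, e in enumerate(elements)}
    for i, atom in enumerate(graph.atoms):
        k = elem_index.get(atom.element)
        if k is None:
            logger.debug("molecule %s: element %s mapped to 'other'", graph.id, atom.element)
            k = n_elem - 1
        out[i, k] = 1.0
        out[i, n_elem:n_elem + 7] = [
            atom.n_hydrogens, atom.heavy_degree, atom.formal_charge,
            float(atom.in_ring), float(atom.aromatic),
            atom.tpsa, atom.partial_charge,
        ]
        tag = atom.chirality if atom.chirality in CHIRALITY_TAGS else "other"
        out[i, n_elem + 7 + CHIRALITY_TAGS.index(tag)] = 1.0
    return out


def bond_features(graph: MolecularGraph) -> dict[tuple[int, int], np.ndarray]:
    """Per-edge attribute vectors x_ij (bond-type one-hot, ring,
    aromatic, conjugated).  Computed for completeness; the minimal
    graph encoder does not consume bond attributes."""
    out = {}
    for edge, bond in graph.bonds.items():
        v = np.zeros(BOND_FEATURE_DIM)
        v[BOND_TYPES.index(bond.bond_type)] = 1.0
        v[len(BOND_TYPES):] = [float(bond.in_ring), float(bond.aromatic),
                               float(bond.conjugated)]
        out[edge] = v
    return out


def aa_onehot(sequence: ProteinSequence, allow_unknown: bool = False) -> np.ndarray:
    """One-hot residue matrix, shape (L, 20): each row has a single 1
    and 19 zeros.  With ``allow_unknown`` the matrix gains a 21st
    column for 'X'."""
    alphabet = AMINO_ACIDS + ("X" if allow_unknown else "")
    index = {aa: k for k, aa in enumerate(alphabet)}
    out = np.zeros((len(sequence.residues), len(alphabet)))
    for i, aa in enumerate(sequence.residues):
        if aa not in index:
            raise FeaturizeError(
                f"protein {sequence.id!r}: residue {aa!r} outside the 20-letter "
                "alphabet (enable allow_unknown for an X channel)"
            )
        out[i, index[aa]] = 1.0
    return out


# ---------------------------------------------------------------------------
# circular (ECFP-style) molecule fingerprint
# ---------------------------------------------------------------------------

_FNV_OFFSET = 1469598103934665603
_FNV_PRIME = 1099511628211
_MASK64 = (1 << 64) - 1


def _mix(values) -> int:
    """Deterministic 64-bit FNV-1a style hash of an integer sequence."""
    h = _FNV_OFFSET
    for v in values:
        h = ((h ^ (int(v) & _MASK64)) * _FNV_PRIME) & _MASK64
    return h


def molecule_fingerprint(graph: MolecularGraph, n_bits: int = 1021,
                         radius: int = 2) -> np.ndarray:
    """Folded binary circular-substructure fingerprint.

    Initial atom invariants hash (element, heavy_degree, n_hydrogens,
    formal_charge, in_ring, aromatic); at each iteration up to
    ``radius`` the invariant is re-hashed together with the sorted
    (bond-type, neighbour-invariant) list, so each invariant identifies
    a rooted neighbourhood.  All invariants from all radii are folded
    modulo ``n_bits``.  Bit positions are implementation-defined but
    deterministic.
    """
    if n_bits < 1:
        raise FeaturizeError(f"n_bits must be >= 1, got {n_bits}")
    bond_code = {t: k for k, t in enumerate(BOND_TYPES)}
    inv = []
    for atom in graph.atoms:
        elem = sum((k + 1) * b for k, b in enumerate(atom.element.encode()))
        inv.append(_mix([elem, atom.heavy_degree, atom.n_hydrogens,
                         atom.formal_charge, int(atom.in_ring), int(atom.aromatic)]))
    neighbors = graph.neighbors
    bits = set(inv)
    for layer in range(1, radius + 1):
        new_inv = []
        for i in range(graph.n_atoms):
            env = sorted(
                (bond_code[graph.bonds[tuple(sorted((i, j)))].bond_type], inv[j])
                for j in neighbors[i]
            )
            flat = [layer, inv[i]]
            for b, v in env:
                flat.extend((b, v))
            new_inv.append(_mix(flat))
        inv = new_inv
        bits.update(inv)
    fp = np.zeros(n_bits)
    for b in bits:
        fp[b % n_bits] = 1.0
    return fp


# ---------------------------------------------------------------------------
# protein sequence descriptors: AAC / DC / CTD
# ---------------------------------------------------------------------------

# Three-class groupings of the 20 amino acids under seven
# physicochemical properties (the standard composition/transition/
# distribution scheme).
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

AAC_DIM = 20
DC_DIM = 400
CTD_DIM = 7 * (3 + 3 + 15)  # composition + transition + distribution = 147

DESCRIPTOR_GROUPS = ("AAC", "DC", "CTD")


def _aac(seq: str) -> np.ndarray:
    counts = np.array([seq.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return counts / len(seq)


def _dc(seq: str) -> np.ndarray:
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        counts[index[a], index[b]] += 1
    total = max(len(seq) - 1, 1)
    return counts.ravel() / total


def _ctd(seq: str) -> np.ndarray:
    out = []
    n = len(seq)
    for groups in CTD_PROPERTIES.values():
        cls = np.array([next(k for k, g in enumerate(groups) if aa in g) for aa in seq])
        # composition: fraction of residues per class
        comp = [(cls == k).mean() for k in range(3)]
        # transition: frequency of adjacent class changes (1<->2, 1<->3, 2<->3)
        pairs = list(zip(cls, cls[1:]))
        denom = max(n - 1, 1)
        trans = [
            sum(1 for a, b in pairs if {a, b} == {0, 1}) / denom,
            sum(1 for a, b in pairs if {a, b} == {0, 2}) / denom,
            sum(1 for a, b in pairs if {a, b} == {1, 2}) / denom,
        ]
        # distribution: relative position of the first, 25/50/75% and
        # last occurrence of each class (0 when the class is absent)
        dist = []
        for k in range(3):
            pos = np.flatnonzero(cls == k) + 1
            if len(pos) == 0:
                dist.extend([0.0] * 5)
            else:
                for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                    j = min(int(np.ceil(frac * len(pos))), len(pos)) - 1
                    dist.append(pos[max(j, 0)] / n)
        out.extend(comp + trans + dist)
    return np.array(out)


def protein_descriptors(sequence: ProteinSequence, groups=("AAC", "DC", "CTD"),
                        external: dict | None = None) -> np.ndarray:
    """Concatenate the requested descriptor blocks, in declared order.

    Implemented groups: AAC (20, frequency-normalized), DC (400,
    frequency-normalized), CTD (147).  The pseudo-group ``external``
    appends a precomputed vector looked up by sequence ID (e.g. a full
    externally computed descriptor table loaded with
    :func:`load_descriptor_table`).
    """
    blocks = []
    seq = sequence.residues.replace("X", "")
    if not seq:
        raise FeaturizeError(f"protein {sequence.id!r}: no standard residues")
    for group in groups:
        if group == "AAC":
            blocks.append(_aac(seq))
        elif group == "DC":
            blocks.append(_dc(seq))
        elif group == "CTD":
            blocks.append(_ctd(seq))
        elif group == "external":
            if external is None or sequence.id not in external:
                raise FeaturizeError(
                    f"external descriptors requested but none provided for {sequence.id!r}"
                )
            blocks.append(np.asarray(external[sequence.id], dtype=float))
        else:
            raise FeaturizeError(f"unknown descriptor group {group!r}")
    return np.concatenate(blocks)


def load_descriptor_table(path, ids) -> dict[str, np.ndarray]:
    """Load precomputed descriptor vectors from CSV (id column +
    numeric columns) for the requested IDs."""
    path = Path(path)
    table = pd.read_csv(path)
    id_col = table.columns[0]
    table[id_col] = table[id_col].astype(str)
    table = table.set_index(id_col)
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in table.columns:
            bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
            if bad.any():
                row = table.index[bad.argmax()]
                raise FeaturizeError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        raise FeaturizeError(f"{path}: non-numeric descriptor columns")
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FeaturizeError(
            f"{path}: NaN at row {table.index[r]!r}, column {table.columns[c]!r}"
        )
    out = {}
    for i in ids:
        if i not in table.index:
            raise FeaturizeError(f"{path}: requested ID {i!r} absent from table")
        out[i] = table.loc[i].to_numpy(dtype=float)
    return out


def feature_schema(elements=DEFAULT_ELEMENTS) -> dict:
    """JSON-serialisable description of the feature block layout."""
    return {
        "atom": {
            "element_onehot": list(elements) + ["other"],
            "scalars": ["n_hydrogens", "heavy_degree", "formal_charge",
                        "in_ring", "aromatic", "tpsa", "partial_charge"],
            "chirality_onehot": list(CHIRALITY_TAGS),
            "dim": len(elements) + 1 + 7 + len(CHIRALITY_TAGS),
        },
        "bond": {"type_onehot": list(BOND_TYPES),
                 "scalars": ["in_ring", "aromatic", "conjugated"],
                 "dim": BOND_FEATURE_DIM},
        "protein_groups": {"AAC": AAC_DIM, "DC": DC_DIM, "CTD": CTD_DIM},
    }


def dump_feature_schema(path, elements=DEFAULT_ELEMENTS) -> None:
    with open(path, "w") as fh:
        json.dump(feature_schema(elements), fh, indent=2)
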