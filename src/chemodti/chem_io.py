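"""Readers, writers and in-memory containers for DTI datasets.

Molecules come in as SMILES columns of TSV/CSV tables and are perceived
into annotated molecular graphs with RDKit; proteins come in as FASTA;
known interactions as two-column (molecule_id, protein_id) TSV.  Every
pair not listed as interacting is unlabelled and, by the usual
chemogenomics convention, treated as negative downstream.

Datasets round-trip through a directory layout (molecules.json,
proteins.fasta, interactions.tsv, manifest.json) so synthetic and real
data share one code path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 canonical amino acids, in the fixed column order used by the
#: one-hot encoder and all composition descriptors
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: nonstandard/ambiguous letters; policy-dependent handling
NONSTANDARD_AA = set("BJOUXZ")

BOND_TYPES = ("single", "double", "triple", "aromatic")
CHIRALITY_TAGS = ("none", "cw", "ccw", "other")


class ChemIOError(ValueError):
    """Raised for malformed molecule tables, FASTA files or pair lists."""


@dataclass
class AtomAnnotation:
    """Chemical annotation of one heavy atom."""

    element: str
    n_hydrogens: int = 0
    heavy_degree: int = 0
    formal_charge: int = 0
    in_ring: bool = False
    aromatic: bool = False
    chirality: str = "none"
    partial_charge: float = 0.0
    tpsa: float = 0.0


@dataclass
class BondAnnotation:
    bond_type: str = "single"
    in_ring: bool = False
    aromatic: bool = False
    conjugated: bool = False


@dataclass
class MolecularGraph:
    """Undirected attributed molecular graph G = (V, E).

    ``edges`` hold each undirected bond once as an (i, j) pair with
    i < j; ``neighbors`` exposes the symmetric one-hop map N(i).
    """

    id: str
    n_atoms: int
    edges: list[tuple[int, int]]
    atoms: list[AtomAnnotation]
    bonds: dict[tuple[int, int], BondAnnotation]
    smiles: Optional[str] = None

    def __post_init__(self):
        self.edges = [tuple(sorted(e)) for e in self.edges]
        self.bonds = {tuple(sorted(k)): v for k, v in self.bonds.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise ChemIOError(f"molecule {self.id!r}: empty graph")
        if len(self.atoms) != self.n_atoms:
            raise ChemIOError(f"molecule {self.id!r}: {len(self.atoms)} atom "
                              f"annotations for {self.n_atoms} atoms")
        seen = set()
        for i, j in self.edges:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms) or i == j:
                raise ChemIOError(f"molecule {self.id!r}: invalid edge ({i},{j})")
            if (i, j) in seen:
                raise ChemIOError(f"molecule {self.id!r}: duplicate edge ({i},{j})")
            seen.add((i, j))
            if (i, j) not in self.bonds:
                raise ChemIOError(f"molecule {self.id!r}: edge ({i},{j}) lacks annotation")

    @property
    def neighbors(self) -> list[list[int]]:
        nbr: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.edges:
            nbr[i].append(j)
            nbr[j].append(i)
        return nbr


@dataclass
class ProteinSequence:
    """Amino-acid sequence over the 20-letter canonical alphabet
    (plus 'X' for the optional unknown channel)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ChemIOError(f"protein {self.id!r}: empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ChemIOError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class InteractionDataset:
    """Molecule set, protein set and the known (positive) pair list.

    Unlisted pairs are unlabelled; the training code treats them as
    negatives when sampling.
    """

    molecules: list[MolecularGraph]
    proteins: list[ProteinSequence]
    positives: list[tuple[str, str]]

    def __post_init__(self):
        mol_ids = [m.id for m in self.molecules]
        prot_ids = [p.id for p in self.proteins]
        for name, ids in (("molecule", mol_ids), ("protein", prot_ids)):
            dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
            if dupes:
                raise ChemIOError(f"duplicate {name} IDs: {sorted(dupes)}")
        self._mol_index = {m.id: m for m in self.molecules}
        self._prot_index = {p.id: p for p in self.proteins}
        seen = set()
        deduped = []
        for m, p in self.positives:
            if m not in self._mol_index:
                raise ChemIOError(f"positive pair references unknown molecule {m!r}")
            if p not in self._prot_index:
                raise ChemIOError(f"positive pair references unknown protein {p!r}")
            if (m, p) not in seen:
                seen.add((m, p))
                deduped.append((m, p))
        self.positives = deduped
        if not self.positives:
            logger.warning("interaction dataset has zero positive pairs")

    def molecule(self, mol_id: str) -> MolecularGraph:
        return self._mol_index[mol_id]

    def protein(self, prot_id: str) -> ProteinSequence:
        return self._prot_index[prot_id]

    @property
    def molecule_ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    @property
    def protein_ids(self) -> list[str]:
        return [p.id for p in self.proteins]

    def positive_set(self) -> set[tuple[str, str]]:
        return set(self.positives)


# ---------------------------------------------------------------------------
# molecule perception (RDKit)
# ---------------------------------------------------------------------------

def graph_from_smiles(smiles: str, mol_id: str) -> MolecularGraph:
    """Perceive a SMILES string into an annotated molecular graph.

    Multi-fragment inputs (salts) keep the largest fragment, logged.
    Partial charges are Gasteiger charges; polar surface contributions
    are per-atom TPSA terms.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemIOError(f"unparsable structure for {mol_id!r}: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        logger.info("molecule %s: keeping largest of %d fragments", mol_id, len(frags))
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    if mol.GetNumAtoms() == 0:
        raise ChemIOError(f"structure for {mol_id!r} has no atoms")
    AllChem.ComputeGasteigerCharges(mol)
    tpsa_contribs = rdMolDescriptors._CalcTPSAContribs(mol)
    chirality_map = {
        Chem.ChiralType.CHI_UNSPECIFIED: "none",
        Chem.ChiralType.CHI_TETRAHEDRAL_CW: "cw",
        Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "ccw",
    }
    atoms = []
    for atom in mol.GetAtoms():
        charge = atom.GetDoubleProp("_GasteigerCharge")
        if not pd.notna(charge):
            charge = 0.0
        atoms.append(AtomAnnotation(
            element=atom.GetSymbol(),
            n_hydrogens=atom.GetTotalNumHs(),
            heavy_degree=atom.GetDegree(),
            formal_charge=atom.GetFormalCharge(),
            in_ring=atom.IsInRing(),
            aromatic=atom.GetIsAromatic(),
            chirality=chirality_map.get(atom.GetChiralTag(), "other"),
            partial_charge=float(charge),
            tpsa=float(tpsa_contribs[atom.GetIdx()]),
        ))
    bond_type_map = {
        Chem.BondType.SINGLE: "single",
        Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple",
        Chem.BondType.AROMATIC: "aromatic",
    }
    edges, bonds = [], {}
    for bond in mol.GetBonds():
        i, j = sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        edges.append((i, j))
        bonds[(i, j)] = BondAnnotation(
            bond_type=bond_type_map.get(bond.GetBondType(), "single"),
            in_ring=bond.IsInRing(),
            aromatic=bond.GetIsAromatic(),
            conjugated=bond.GetIsConjugated(),
        )
    return MolecularGraph(
        id=mol_id, n_atoms=mol.GetNumAtoms(), edges=edges, atoms=atoms,
        bonds=bonds, smiles=Chem.MolToSmiles(mol),
    )


def read_molecule_table(
    path,
    id_column: str = "molecule_id",
    structure_column: str = "smiles",
    strict: bool = False,
):
    """Read a TSV/CSV molecule table into annotated graphs.

    Unparsable rows are collected and logged with their row numbers
    (raised instead when ``strict``); valid rows are returned in input
    order.  Returns ``(graphs, errors)`` where ``errors`` is a list of
    (row_number, message).
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        table = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ChemIOError(f"empty molecule table: {path}") from None
    for col in (id_column, structure_column):
        if col not in table.columns:
            raise ChemIOError(f"{path}: missing column {col!r}")
    if table.empty:
        raise ChemIOError(f"molecule table has no rows: {path}")
    ids = table[id_column].astype(str)
    if ids.duplicated().any():
        raise ChemIOError(f"duplicate molecule IDs: {sorted(ids[ids.duplicated()])}")
    graphs, errors = [], []
    for row_number, (mol_id, smiles) in enumerate(zip(ids, table[structure_column]), start=1):
        try:
            graphs.append(graph_from_smiles(str(smiles), mol_id))
        except ChemIOError as exc:
            errors.append((row_number, str(exc)))
    if errors:
        msg = "; ".join(f"row {r}: {m}" for r, m in errors)
        if strict or not graphs:
            raise ChemIOError(f"{path}: {msg}")
        logger.warning("%s: skipped %d unparsable rows (%s)", path, len(errors), msg)
    return graphs, errors


def read_fasta(path, nonstandard: str = "reject") -> list[ProteinSequence]:
    """Read protein sequences from FASTA.

    IDs are the first whitespace-delimited token of each header;
    sequences are uppercased.  ``nonstandard`` controls letters outside
    the 20-letter alphabet: ``reject`` (default) raises, ``unknown``
    maps them to 'X' (routed to the optional 21st one-hot channel).
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ChemIOError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            if nonstandard == "unknown":
                seq = "".join(c if c in AMINO_ACIDS else "X" for c in seq)
            else:
                raise ChemIOError(
                    f"protein {rec.id!r}: nonstandard residues {sorted(bad)} "
                    "(pass nonstandard='unknown' to map them to an X channel)"
                )
        out.append(ProteinSequence(id=rec.id, residues=seq))
    ids = [p.id for p in out]
    if len(set(ids)) != len(ids):
        raise ChemIOError(f"duplicate protein IDs in {path}")
    return out


def read_interactions(path, molecules, proteins) -> InteractionDataset:
    """Read a two-column (molecule_id, protein_id) TSV of known
    interactions and assemble the dataset.  Duplicated pairs are
    dropped; pairs referencing unknown entities are an error."""
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    mol_ids = {m.id for m in molecules}
    prot_ids = {p.id for p in proteins}
    pairs: list[tuple[str, str]] = []
    bad_rows = []
    with open(path) as fh:
        for row_number, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                bad_rows.append((row_number, f"expected 2 columns, got {len(parts)}"))
                continue
            m, p = parts
            if m not in mol_ids:
                bad_rows.append((row_number, f"unknown molecule ID {m!r}"))
            elif p not in prot_ids:
                bad_rows.append((row_number, f"unknown protein ID {p!r}"))
            else:
                pairs.append((m, p))
    if bad_rows:
        msg = "; ".join(f"row {r}: {m}" for r, m in bad_rows)
        raise ChemIOError(f"{path}: {msg}")
    dataset = InteractionDataset(list(molecules), list(proteins), pairs)
    logger.info(
        "read %d molecules, %d proteins, %d positives from %s",
        len(dataset.molecules), len(dataset.proteins), len(dataset.positives), path,
    )
    return dataset


# ---------------------------------------------------------------------------
# dataset round-trip (JSON graphs + FASTA + TSV pairs + manifest)
# ---------------------------------------------------------------------------

def _graph_to_json(g: MolecularGraph) -> dict:
    return {
        "id": g.id,
        "n_atoms": g.n_atoms,
        "edges": [list(e) for e in g.edges],
        "atoms": [asdict(a) for a in g.atoms],
        "bonds": {f"{i},{j}": asdict(b) for (i, j), b in g.bonds.items()},
        "smiles": g.smiles,
    }


def _graph_from_json(d: dict) -> MolecularGraph:
    return MolecularGraph(
        id=d["id"],
        n_atoms=d["n_atoms"],
        edges=[tuple(e) for e in d["edges"]],
        atoms=[AtomAnnotation(**a) for a in d["atoms"]],
        bonds={tuple(int(x) for x in k.split(",")): BondAnnotation(**b)
               for k, b in d["bonds"].items()},
        smiles=d.get("smiles"),
    )


def write_dataset(dataset: InteractionDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "molecules.json", "w") as fh:
        json.dump([_graph_to_json(m) for m in dataset.molecules], fh)
    with open(directory / "proteins.fasta", "w") as fh:
        for p in dataset.proteins:
            fh.write(f">{p.id}\n{p.residues}\n")
    with open(directory / "interactions.tsv", "w") as fh:
        for m, p in dataset.positives:
            fh.write(f"{m}\t{p}\n")
    manifest = {
        "format_version": 1,
        "n_molecules": len(dataset.molecules),
        "n_proteins": len(dataset.proteins),
        "n_positives": len(dataset.positives),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_dataset(directory) -> InteractionDataset:
    directory = Path(directory)
    with open(directory / "molecules.json") as fh:
        molecules = [_graph_from_json(d) for d in json.load(fh)]
    proteins = read_fasta(directory / "proteins.fasta", nonstandard="unknown")
    positives = []
    with open(directory / "interactions.tsv") as fh:
        for line in fh:
            line = line.strip()
            if line:
                m, p = line.split("\t")
                positives.append((m, p))
    return InteractionDataset(molecules, proteins, positives)
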