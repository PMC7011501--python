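"""Shallow reference method: molecule/protein kernels and the
Kronecker pairwise-kernel SVM (kronSVM).

The pair kernel is the product of a molecule kernel and a protein
kernel, K((m,p),(m',p')) = Km(m,m') * Kp(p,p'), evaluated lazily for
the requested pair blocks — the full Kronecker matrix is never
materialised.  Molecules use the Tanimoto kernel on binary
fingerprints (intersection over union of substructure bit sets, a
valid kernel); proteins use a normalised Smith-Waterman local-
alignment score kernel projected onto the PSD cone (raw alignment
scores are not positive semidefinite in general), with the option of
loading a precomputed kernel matrix computed by external software
instead.  The SVM itself is a standard precomputed-kernel solver; the
module's content is kernel construction, lazy pairwise indexing and
nested selection of the regularisation constant C on inner-fold AUPR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KernelMatrix",
    "KronSVMConfig",
    "tanimoto_kernel",
    "sw_score",
    "sw_protein_kernel",
    "kron_pair_kernel",
    "KronSVM",
    "kronsvm_fit",
    "kronsvm_predict",
    "save_kernel",
    "load_kernel",
]


class KernelError(ValueError):
    pass


@dataclass
class KernelMatrix:
    """Square symmetric kernel over an ordered entity list."""

    matrix: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise KernelError(f"kernel shape {self.matrix.shape} does not match "
                              f"{n} entity IDs")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise KernelError("kernel matrix must be symmetric")
        self._index = {e: i for i, e in enumerate(self.ids)}

    def index(self, entity_id: str) -> int:
        if entity_id not in self._index:
            raise KernelError(f"unknown entity {entity_id!r}")
        return self._index[entity_id]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


@dataclass
class KronSVMConfig:
    C: float = 1.0
    C_grid: Optional[Sequence[float]] = None
    inner_folds: int = 5
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0 or (self.C_grid is not None and any(c <= 0 for c in self.C_grid)):
            raise KernelError("C must be positive")


def tanimoto_kernel(fingerprints, ids: Optional[list[str]] = None) -> KernelMatrix:
    """K(a,b) = |a AND b| / |a OR b| on binary fingerprint vectors.

    Convention for all-zero vectors: 1 on the diagonal, 0 elsewhere
    (an empty substructure set is similar only to itself).
    """
    fp = np.asarray(fingerprints, dtype=float)
    if fp.ndim != 2:
        raise KernelError("fingerprints must be a 2D (n, bits) array")
    if not np.isin(fp, (0.0, 1.0)).all():
        raise KernelError("Tanimoto kernel requires binary fingerprints")
    inter = fp @ fp.T
    sizes = fp.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    k = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
    np.fill_diagonal(k, 1.0)
    if ids is None:
        ids = [str(i) for i in range(fp.shape[0])]
    return KernelMatrix(matrix=k, ids=ids)


def sw_score(x: str, y: str, substitution_matrix: str = "BLOSUM62",
             gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman local alignment score with affine gaps (a gap of
    length L costs gap_open + (L-1)*gap_extend); floored at 0 by the
    local-alignment definition."""
    if not x or not y:
        raise KernelError("cannot align empty sequences")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return float(aligner.score(x, y))


def sw_protein_kernel(sequences, substitution_matrix: str = "BLOSUM62",
                      gap_open: float = 11.0, gap_extend: float = 1.0,
                      psd_tolerance: float = 1e-8) -> KernelMatrix:
    """Pairwise local-alignment score kernel.

    Raw scores are normalised K(x,y)/sqrt(K(x,x)K(y,y)), then projected
    to the PSD cone by clipping negative eigenvalues at zero, and the
    diagonal is re-normalised to 1.
    """
    seqs = [(s.id, s.residues) if hasattr(s, "residues") else (str(i), s)
            for i, s in enumerate(sequences)]
    n = len(seqs)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = sw_score(seqs[i][1], seqs[j][1],
                                             substitution_matrix, gap_open, gap_extend)
    diag = np.sqrt(np.diag(raw))
    if (diag == 0).any():
        raise KernelError("sequence with zero self-alignment score")
    k = raw / np.outer(diag, diag)
    # empirical PSD correction
    vals, vecs = np.linalg.eigh(k)
    if vals[0] < -psd_tolerance:
        vals = np.clip(vals, 0.0, None)
        k = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(k))
        k = k / np.outer(d, d)
        k = 0.5 * (k + k.T)
    return KernelMatrix(matrix=k, ids=[sid for sid, _ in seqs])


def kron_pair_kernel(km: KernelMatrix, kp: KernelMatrix,
                     pairs_a: Sequence, pairs_b: Sequence) -> np.ndarray:
    """Block of the Kronecker pair kernel for two pair lists, computed
    entrywise from the factor kernels (lazy: only the requested
    |pairs_a| x |pairs_b| block is formed)."""
    mi_a = [km.index(m) for m, _ in pairs_a]
    pi_a = [kp.index(p) for _, p in pairs_a]
    mi_b = [km.index(m) for m, _ in pairs_b]
    pi_b = [kp.index(p) for _, p in pairs_b]
    return km.matrix[np.ix_(mi_a, mi_b)] * kp.matrix[np.ix_(pi_a, pi_b)]


class KronSVM:
    """Precomputed-kernel SVM over (molecule, protein) pairs."""

    def __init__(self, km: KernelMatrix, kp: KernelMatrix,
                 config: Optional[KronSVMConfig] = None):
        self.km = km
        self.kp = kp
        self.config = config or KronSVMConfig()
        self.train_pairs: Optional[list] = None
        self._svc = None
        self.selected_C: Optional[float] = None
        #: per-C mean inner-fold AUPR recorded during nested selection
        self.selection_scores: Optional[dict[float, float]] = None

    def fit(self, train_pairs: Sequence, labels) -> "KronSVM":
        from sklearn.svm import SVC

        labels = np.asarray(labels)
        if set(np.unique(labels)) - {-1, 1}:
            raise KernelError("labels must be in {+1, -1}")
        if len(np.unique(labels)) < 2:
            raise KernelError("training labels contain a single class")
        self.train_pairs = list(train_pairs)
        c = self.config.C
        if self.config.C_grid:
            c = self._select_C(self.train_pairs, labels)
        self.selected_C = c
        gram = kron_pair_kernel(self.km, self.kp, self.train_pairs, self.train_pairs)
        self._svc = SVC(kernel="precomputed", C=c, tol=self.config.tol)
        self._svc.fit(gram, labels)
        return self

    def _select_C(self, pairs, labels) -> float:
        from chemodti.evaluation import aupr

        rng = np.random.default_rng(np.random.SeedSequence((self.config.seed, 61)))
        order = rng.permutation(len(pairs))
        chunks = np.array_split(order, self.config.inner_folds)
        self.selection_scores = {}
        best_c, best_score = self.config.C, -np.inf
        for c in self.config.C_grid:
            scores = []
            for chunk in chunks:
                test_idx = chunk.tolist()
                train_idx = [i for i in order if i not in set(test_idx)]
                y_tr, y_te = labels[train_idx], labels[test_idx]
                if len(np.unique(y_tr)) < 2 or (y_te == 1).sum() == 0:
                    continue
                sub = KronSVM(self.km, self.kp, KronSVMConfig(C=c, tol=self.config.tol))
                sub.fit([pairs[i] for i in train_idx], y_tr)
                dec = sub.decision_function([pairs[i] for i in test_idx])
                scores.append(aupr(dec, (y_te == 1).astype(int)))
            if scores:
                self.selection_scores[c] = float(np.mean(scores))
                if self.selection_scores[c] > best_score:
                    best_score, best_c = self.selection_scores[c], c
        logger.info("kronSVM selected C=%g (inner AUPR %.4f)", best_c, best_score)
        return best_c

    def decision_function(self, pairs: Sequence) -> np.ndarray:
        if self._svc is None:
            raise KernelError("fit the model first")
        block = kron_pair_kernel(self.km, self.kp, pairs, self.train_pairs)
        return self._svc.decision_function(block)

    def predict(self, pairs: Sequence) -> np.ndarray:
        return np.sign(self.decision_function(pairs))


def kronsvm_fit(train_pairs, labels, km: KernelMatrix, kp: KernelMatrix,
                config: Optional[KronSVMConfig] = None) -> KronSVM:
    return KronSVM(km, kp, config).fit(train_pairs, labels)


def kronsvm_predict(classifier: KronSVM, test_pairs) -> np.ndarray:
    """Decision values for ranking (AUPR/ROCAUC)."""
    return classifier.decision_function(test_pairs)


def save_kernel(path, kernel: KernelMatrix) -> None:
    """CSV matrix plus a JSON sidecar with the entity order."""
    path = Path(path)
    np.savetxt(path, kernel.matrix, delimiter=",")
    with open(path.with_suffix(path.suffix + ".ids.json"), "w") as fh:
        json.dump(kernel.ids, fh)


def load_kernel(path) -> KernelMatrix:
    path = Path(path)
    matrix = np.loadtxt(path, delimiter=",", ndmin=2)
    with open(path.with_suffix(path.suffix + ".ids.json")) as fh:
        ids = json.load(fh)
    return KernelMatrix(matrix=matrix, ids=ids)
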