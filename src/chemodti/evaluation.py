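"""Evaluation protocol: orphan cross-validation splits, negative
sampling, ranking metrics and the nested cross-validation harness.

Four fold-construction settings cover the regimes of specificity
prediction:

* S1 — random split of the labeled pair set,
* S2 — orphan proteins: each fold's test pairs involve proteins absent
  from its training pairs,
* S3 — orphan molecules, mirrored,
* S4 — double orphan: folds are intersections of an S2 and an S3
  partition, giving k^2 folds for k entity groups; a test pair's
  protein group and molecule group are both excluded from training.

Negatives are drawn uniformly without replacement from the unlabelled
pairs admissible for the fold (test negatives obey the fold's orphan
constraints too), at a positive:negative ratio such as 1:5.

Metrics: ROCAUC (rank statistic with midrank tie handling) and AUPR in
its average-precision form — the step-wise integral of precision over
recall.  AUPR is the primary metric: with unlabelled pairs treated as
negatives and heavy class imbalance it is more informative than
ROCAUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from chemodti.chem_io import InteractionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Fold",
    "FoldSplit",
    "MetricReport",
    "make_splits",
    "sample_negatives",
    "parse_ratio",
    "roc_auc",
    "aupr",
    "nested_cv",
]

SETTINGS = ("S1", "S2", "S3", "S4")

Pair = tuple[str, str]
LabeledPair = tuple[str, str, int]


class EvaluationError(ValueError):
    pass


@dataclass
class Fold:
    train: list[LabeledPair]
    test: list[LabeledPair]

    def train_pairs(self) -> list[Pair]:
        return [(m, p) for m, p, _ in self.train]

    def test_pairs(self) -> list[Pair]:
        return [(m, p) for m, p, _ in self.test]


@dataclass
class FoldSplit:
    setting: str
    folds: list[Fold]
    ratio: tuple[int, int]
    seed: int


@dataclass
class MetricReport:
    """Per-fold ROCAUC/AUPR with mean +/- standard deviation."""

    rocauc: list[float]
    aupr: list[float]

    @property
    def mean_rocauc(self) -> float:
        return float(np.mean(self.rocauc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.aupr))

    @property
    def std_rocauc(self) -> float:
        return float(np.std(self.rocauc))

    @property
    def std_aupr(self) -> float:
        return float(np.std(self.aupr))

    def summary(self) -> str:
        return (f"ROCAUC {self.mean_rocauc:.4f}±{self.std_rocauc:.4f}  "
                f"AUPR {self.mean_aupr:.4f}±{self.std_aupr:.4f}")


def parse_ratio(ratio) -> tuple[int, int]:
    """Accept '1:5', (1, 5) or 5 (meaning 1:5)."""
    if isinstance(ratio, str):
        pos, neg = ratio.split(":")
        return int(pos), int(neg)
    if isinstance(ratio, (tuple, list)):
        return int(ratio[0]), int(ratio[1])
    return 1, int(ratio)


def sample_negatives(dataset: InteractionDataset, pair_pool: Sequence[Pair],
                     ratio, seed: int, n_positives: Optional[int] = None,
                     ) -> list[Pair]:
    """Uniform sample, without replacement, of unlabelled pairs from
    ``pair_pool``; count = floor(neg/pos * n_positives)."""
    pos, neg = parse_ratio(ratio)
    positives = dataset.positive_set()
    pool = [p for p in pair_pool if p not in positives]
    if n_positives is None:
        n_positives = sum(1 for p in pair_pool if p in positives)
    n_wanted = (n_positives * neg) // pos
    if n_wanted > len(pool):
        achievable = len(pool) / max(n_positives, 1)
        raise EvaluationError(
            f"cannot draw {n_wanted} negatives from a pool of {len(pool)} "
            f"unlabelled pairs (achievable ratio about 1:{achievable:.1f})"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    idx = rng.choice(len(pool), size=n_wanted, replace=False)
    return [pool[i] for i in sorted(idx)]


def _label(pairs: Sequence[Pair], positives: set) -> list[LabeledPair]:
    return [(m, p, int((m, p) in positives)) for m, p in pairs]


def _partition(items: list, k: int, rng: np.random.Generator) -> list[list]:
    """Uniform random partition into k near-equal groups."""
    order = list(rng.permutation(len(items)))
    groups: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        groups[pos % k].append(items[idx])
    return groups


def make_splits(dataset: InteractionDataset, setting: str, k: int = 5,
                ratio="1:5", seed: int = 0) -> FoldSplit:
    """Build cross-validation folds under one of the S1-S4 settings.

    Negatives are sampled per fold from that fold's admissible
    unlabelled pool, so orphan constraints hold for negatives too.  S4
    returns k^2 folds (possibly with empty test sets on very sparse
    data; downstream consumers skip those).
    """
    if setting not in SETTINGS:
        raise EvaluationError(f"unknown setting {setting!r}")
    ratio_t = parse_ratio(ratio)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    positives = dataset.positive_set()
    mol_ids = dataset.molecule_ids
    prot_ids = dataset.protein_ids
    if k < 2:
        raise EvaluationError("need at least 2 folds")
    if k > len(mol_ids) or k > len(prot_ids):
        raise EvaluationError(
            f"k={k} exceeds entity count ({len(mol_ids)} molecules, "
            f"{len(prot_ids)} proteins)"
        )
    folds: list[Fold] = []
    if setting == "S1":
        all_pairs = [(m, p) for m in mol_ids for p in prot_ids]
        negs = sample_negatives(dataset, all_pairs, ratio_t, seed,
                                n_positives=len(positives))
        labeled = _label(sorted(positives) + negs, positives)
        order = rng.permutation(len(labeled))
        chunks = np.array_split(order, k)
        for c in chunks:
            c_set = set(c.tolist())
            test = [labeled[i] for i in c]
            train = [labeled[i] for i in order if i not in c_set]
            folds.append(Fold(train=train, test=test))
    elif setting in ("S2", "S3"):
        orphan_prot = setting == "S2"
        entities = prot_ids if orphan_prot else mol_ids
        groups = _partition(list(entities), k, rng)
        for g_idx, group in enumerate(groups):
            group_set = set(group)
            if orphan_prot:
                in_test = lambda m, p: p in group_set  # noqa: E731
            else:
                in_test = lambda m, p: m in group_set  # noqa: E731
            test_pos = sorted(p for p in positives if in_test(*p))
            train_pos = sorted(p for p in positives if not in_test(*p))
            test_pool = [(m, p) for m in mol_ids for p in prot_ids if in_test(m, p)]
            train_pool = [(m, p) for m in mol_ids for p in prot_ids if not in_test(m, p)]
            test_neg = sample_negatives(dataset, test_pool, ratio_t,
                                        seed + 1000 + g_idx, n_positives=len(test_pos))
            train_neg = sample_negatives(dataset, train_pool, ratio_t,
                                         seed + 2000 + g_idx, n_positives=len(train_pos))
            folds.append(Fold(
                train=_label(train_pos + train_neg, positives),
                test=_label(test_pos + test_neg, positives),
            ))
    else:  # S4: intersect an S2 and an S3 partition -> k^2 folds
        prot_groups = _partition(list(prot_ids), k, rng)
        mol_groups = _partition(list(mol_ids), k, rng)
        prot_of = {p: gi for gi, g in enumerate(prot_groups) for p in g}
        mol_of = {m: gj for gj, g in enumerate(mol_groups) for m in g}
        for i in range(k):
            for j in range(k):
                test_pos = sorted((m, p) for m, p in positives
                                  if prot_of[p] == i and mol_of[m] == j)
                train_pos = sorted((m, p) for m, p in positives
                                   if prot_of[p] != i and mol_of[m] != j)
                test_pool = [(m, p) for m in mol_groups[j] for p in prot_groups[i]]
                train_pool = [(m, p) for m in mol_ids for p in prot_ids
                              if prot_of[p] != i and mol_of[m] != j]
                test_neg = sample_negatives(dataset, test_pool, ratio_t,
                                            seed + 3000 + i * k + j,
                                            n_positives=len(test_pos))
                train_neg = sample_negatives(dataset, train_pool, ratio_t,
                                             seed + 4000 + i * k + j,
                                             n_positives=len(train_pos))
                folds.append(Fold(
                    train=_label(train_pos + train_neg, positives),
                    test=_label(test_pos + test_neg, positives),
                ))
    return FoldSplit(setting=setting, folds=folds, ratio=ratio_t, seed=seed)


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC with midrank tie handling (equivalent to the
    Mann-Whitney U statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length 1D arrays")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROCAUC needs both classes in the test set")
    from scipy.stats import rankdata

    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, average-precision form:

        AP = sum_k (R_k - R_{k-1}) * P_k

    walking thresholds down the score ranking.  Ties share a threshold
    (all tied pairs enter the ranking together).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length 1D arrays")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise EvaluationError("AUPR is undefined without positives in the test set")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # evaluate only at distinct thresholds (last index of each tie block)
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


# ---------------------------------------------------------------------------
# nested cross-validation harness
# ---------------------------------------------------------------------------

class PairScorer(Protocol):
    """Adapter contract for any model entering nested CV."""

    def fit(self, dataset: InteractionDataset, train: list[LabeledPair]) -> None: ...

    def predict(self, dataset: InteractionDataset, pairs: list[Pair]) -> np.ndarray: ...


def _inner_select(scorer_factory, grid, dataset, train, inner_k, seed):
    """Pick the grid entry with the best mean inner-fold AUPR."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    order = rng.permutation(len(train))
    chunks = np.array_split(order, inner_k)
    best_params, best_score = None, -np.inf
    for params in grid:
        fold_scores = []
        for c in chunks:
            c_set = set(c.tolist())
            inner_test = [train[i] for i in c]
            inner_train = [train[i] for i in order if i not in c_set]
            if not any(lbl for *_, lbl in inner_test) or not any(lbl for *_, lbl in inner_train):
                continue
            scorer = scorer_factory(**params)
            scorer.fit(dataset, inner_train)
            s = scorer.predict(dataset, [(m, p) for m, p, _ in inner_test])
            fold_scores.append(aupr(s, [lbl for *_, lbl in inner_test]))
        if fold_scores and np.mean(fold_scores) > best_score:
            best_score, best_params = float(np.mean(fold_scores)), params
    if best_params is None:
        raise EvaluationError("inner CV produced no usable folds")
    return best_params


def nested_cv(scorer_factory: Callable[..., PairScorer],
              dataset: InteractionDataset, setting: str = "S1", k: int = 5,
              ratio="1:5", seed: int = 0, grid: Optional[list[dict]] = None,
              inner_k: int = 5, split: Optional[FoldSplit] = None) -> MetricReport:
    """Outer folds per :func:`make_splits`; optional inner K-fold
    hyper-parameter selection on AUPR; per-fold ROCAUC/AUPR report.

    ``scorer_factory()`` must return a fresh :class:`PairScorer`;
    ``grid`` is a list of keyword dicts for the factory.  Folds whose
    test set lacks positives (possible under S4 on sparse data) are
    skipped with a warning.
    """
    if split is None:
        split = make_splits(dataset, setting, k=k, ratio=ratio, seed=seed)
    rocs, auprs = [], []
    for f_idx, fold in enumerate(split.folds):
        test_labels = [lbl for *_, lbl in fold.test]
        if not fold.test or not any(test_labels) or all(test_labels):
            logger.warning("fold %d skipped: test set lacks both classes", f_idx)
            continue
        params = {}
        if grid:
            params = _inner_select(scorer_factory, grid, dataset, fold.train,
                                   inner_k, seed + f_idx)
        scorer = scorer_factory(**params)
        scorer.fit(dataset, fold.train)
        scores = scorer.predict(dataset, fold.test_pairs())
        rocs.append(roc_auc(scores, test_labels))
        auprs.append(aupr(scores, test_labels))
    if not rocs:
        raise EvaluationError("no usable folds")
    return MetricReport(rocauc=rocs, aupr=auprs)
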