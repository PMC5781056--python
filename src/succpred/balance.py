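"""k-nearest-neighbor undersampling of the majority (negative) class.

Non-succinylated lysines vastly outnumber succinylated ones, which biases a
margin classifier toward the majority class.  The elimination rule removes
every negative sample whose k nearest neighbors (among all samples,
excluding itself) include at least one positive sample; k starts at 10 and
is increased until the class sizes are similar.  Decisions at each k are
made simultaneously against the original, unmodified dataset, so the
removal set at k is always a superset of the one at k-1 and positives are
never removed.

Distances are Euclidean on per-feature z-scored values: without scaling,
accessible surface areas (tens of square Angstroms) and backbone angles
(hundreds of degrees) would dominate the probability-scale features.
Distance ties are broken by ascending sample id for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

DEFAULT_K_START = 10
DEFAULT_RATIO_MAX = 1.10
DEFAULT_K_MAX = 200


class BalanceError(ValueError):
    pass


@dataclass
class LabeledDataset:
    """Feature matrix with labels in {+1, -1} and unique provenance ids."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n = self.X.shape[0]
        if self.y.shape[0] != n or len(self.ids) != n:
            raise BalanceError("X, y and ids must have equal length")
        if len(set(self.ids)) != n:
            raise BalanceError("sample ids must be unique")
        if n and not set(np.unique(self.y)) <= {-1, 0, 1}:
            raise BalanceError("labels must lie in {+1, -1} (0 = unlabeled)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == -1))

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(mask)
        return LabeledDataset(
            X=self.X[idx], y=self.y[idx], ids=[self.ids[i] for i in idx]
        )


@dataclass
class BalanceReport:
    """Outcome of the incremental-k elimination schedule."""

    k_start: int
    k_final: int
    n_positive: int
    initial_negatives: int
    retained_negatives: int
    removed_per_k: list[tuple[int, int]] = field(default_factory=list)
    converged: bool = True

    @property
    def ratio_final(self) -> float:
        return self.retained_negatives / self.n_positive

    def to_dict(self) -> dict:
        return {
            "k_start": self.k_start,
            "k_final": self.k_final,
            "n_positive": self.n_positive,
            "initial_negatives": self.initial_negatives,
            "retained_negatives": self.retained_negatives,
            "ratio_final": self.ratio_final,
            "removed_per_k": [list(t) for t in self.removed_per_k],
            "converged": self.converged,
        }


def _zscore(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    out = X - mean
    nonconst = sd > 0
    out[:, nonconst] /= sd[nonconst]
    out[:, ~nonconst] = 0.0
    return out


def _first_positive_rank(data: LabeledDataset, standardize: bool) -> np.ndarray:
    """For each negative sample, the neighbor rank (1-based) of the nearest
    positive sample, with ties broken by ascending sample id.

    A negative is eliminated at level k iff its rank is <= k; this encodes
    the whole incremental-k schedule in one pass.
    """
    if data.n_positive == 0:
        raise BalanceError("dataset has no positive samples")
    if data.n_negative == 0:
        raise BalanceError("dataset has no negative samples")
    X = _zscore(data.X) if standardize else data.X
    neg_idx = np.flatnonzero(data.y == -1)
    id_rank = np.empty(data.n_samples, dtype=int)
    id_rank[np.argsort(np.asarray(data.ids, dtype=object))] = np.arange(data.n_samples)

    D = cdist(X[neg_idx], X, metric="euclidean")
    ranks = np.empty(len(neg_idx), dtype=int)
    is_pos = data.y == 1
    for row, i in enumerate(neg_idx):
        d = D[row]
        order = np.lexsort((id_rank, d))
        order = order[order != i]  # exclude self
        pos_hits = np.flatnonzero(is_pos[order])
        ranks[row] = pos_hits[0] + 1 if pos_hits.size else data.n_samples
    return ranks


def knn_eliminate(
    data: LabeledDataset, k: int, standardize: bool = True
) -> set[str]:
    """Ids of negative samples whose k nearest neighbors include a positive.

    Neighbors are drawn from all original samples (both classes) excluding
    the sample itself; decisions are simultaneous against the unmodified
    dataset.
    """
    if k < 1:
        raise BalanceError(f"k must be >= 1, got {k}")
    if k >= data.n_samples:
        raise BalanceError(f"k={k} must be smaller than the sample count {data.n_samples}")
    ranks = _first_positive_rank(data, standardize)
    neg_idx = np.flatnonzero(data.y == -1)
    return {data.ids[i] for i, r in zip(neg_idx, ranks) if r <= k}


def balance(
    data: LabeledDataset,
    k_start: int = DEFAULT_K_START,
    ratio_max: float = DEFAULT_RATIO_MAX,
    k_max: int = DEFAULT_K_MAX,
    standardize: bool = True,
) -> tuple[LabeledDataset, BalanceReport]:
    """Undersample negatives by incrementing k until classes are similar.

    Runs the elimination rule at k = k_start, k_start+1, ... (each decision
    against the original dataset) and stops at the first k where the
    retained negatives are at most ``ratio_max`` times the positives, or at
    ``k_max`` (returning the best-so-far reduction with a warning).
    Positives are never removed.
    """
    if data.n_positive == 0 or data.n_negative == 0:
        raise BalanceError("balancing requires both classes")
    if k_start < 1 or k_start >= data.n_samples:
        raise BalanceError(f"k_start={k_start} must lie in [1, n_samples)")
    if k_max < k_start:
        raise BalanceError(f"k_max={k_max} must be >= k_start={k_start}")
    ranks = _first_positive_rank(data, standardize)
    neg_idx = np.flatnonzero(data.y == -1)
    n_pos, n_neg = data.n_positive, data.n_negative
    k_cap = min(k_max, data.n_samples - 1)

    removed_per_k: list[tuple[int, int]] = []
    k_final, converged = k_cap, False
    for k in range(k_start, k_cap + 1):
        removed = int(np.sum(ranks <= k))
        removed_per_k.append((k, removed))
        retained = n_neg - removed
        if retained <= ratio_max * n_pos:
            k_final, converged = k, True
            break
    if not converged:
        logger.warning(
            "balance: k_max=%d reached with %d negatives retained "
            "(> %.2f x %d positives); returning best-so-far",
            k_cap, n_neg - removed_per_k[-1][1], ratio_max, n_pos,
        )

    removed_ids = {
        data.ids[i] for i, r in zip(neg_idx, ranks) if r <= k_final
    }
    keep = np.array([sid not in removed_ids for sid in data.ids])
    balanced = data.subset(keep)
    report = BalanceReport(
        k_start=k_start,
        k_final=k_final,
        n_positive=n_pos,
        initial_negatives=n_neg,
        retained_negatives=balanced.n_negative,
        removed_per_k=removed_per_k,
        converged=converged,
    )
    logger.info(
        "balance: k=%d, negatives %d -> %d (ratio %.3f)",
        report.k_final, n_neg, report.retained_negatives, report.ratio_final,
    )
    return balanced, report
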