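"""Remote-homology benchmark statistic and embedding-based annotation transfer.

The benchmark scores ranked all-against-all hit lists the way structure-search
tools are evaluated: for each query, walk its hits best-first and count true
positives (hits sharing the query's label at the evaluated hierarchy level)
until the first false positive — a hit from a different *fold* (the coarsest
level). Hits sharing the fold but differing at the evaluated level are
neutral: they neither count nor terminate. A query's sensitivity is the
fraction of its possible true positives found before that first false
positive; the aggregate is the mean over queries, which equals the area under
the sorted per-query sensitivity curve.

EAT (embedding-based annotation transfer) labels a query with the hierarchy
label of its nearest lookup neighbour under Euclidean distance on mean-pooled
embeddings; per-level accuracy is hierarchical — a level is credited only if
all coarser levels are also correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .records import HierarchyLabel

__all__ = [
    "HitList",
    "BenchmarkResult",
    "sensitivity_first_fp",
    "benchmark",
    "eat_transfer",
    "EATResult",
    "hitlists_from_scores",
]


@dataclass
class HitList:
    """Ranked hits for one query, best score first, self-hit excluded."""

    query_id: str
    hits: List[Tuple[str, float]]

    def __post_init__(self) -> None:
        targets = [t for t, _ in self.hits]
        if self.query_id in targets:
            raise ValueError(f"hit list for {self.query_id!r} contains a self-hit")
        if len(set(targets)) != len(targets):
            raise ValueError(f"hit list for {self.query_id!r} contains duplicate targets")


@dataclass
class BenchmarkResult:
    per_query_sensitivity: Dict[int, Dict[str, float]]  # level -> query -> sens
    mean_sensitivity: Dict[int, float]
    excluded: Dict[int, List[str]]  # queries with no possible TP at a level

    def sorted_curve(self, level: int) -> Tuple[np.ndarray, np.ndarray]:
        """Cumulative sorted-sensitivity curve (x: query fraction, y: sensitivity).

        The area under this curve equals the mean sensitivity at the level.
        """
        vals = np.sort(np.array(list(self.per_query_sensitivity[level].values())))[::-1]
        x = (np.arange(len(vals)) + 0.5) / len(vals)
        return x, vals


def sensitivity_first_fp(
    hits: HitList,
    labels: Mapping[str, HierarchyLabel],
    level: int,
    n_possible: Optional[int] = None,
) -> Optional[float]:
    """Fraction of possible true positives found before the first false positive.

    A hit is a TP if it shares the query's label at ``level``; it is an FP —
    terminating the walk — if it differs at level 0 (the fold); hits sharing
    the fold but differing at ``level`` are neutral. Returns None when the
    query has no possible TP at this level (the caller excludes such queries).
    ``n_possible`` overrides the count of possible TPs (otherwise counted over
    all labelled non-query ids).
    """
    query_label = labels.get(hits.query_id)
    if query_label is None:
        raise ValueError(f"query {hits.query_id!r} is unlabeled")
    if n_possible is None:
        n_possible = sum(
            1
            for other_id, lab in labels.items()
            if other_id != hits.query_id and query_label.matches_at(lab, level)
        )
    if n_possible == 0:
        return None
    n_tp = 0
    for target_id, _score in hits.hits:
        lab = labels.get(target_id)
        if lab is None:
            raise ValueError(f"target {target_id!r} is unlabeled")
        if not query_label.matches_at(lab, 0):
            break  # first false positive: different fold
        if query_label.matches_at(lab, level):
            n_tp += 1
    return n_tp / n_possible


def benchmark(
    hitlists: Sequence[HitList],
    labels: Mapping[str, HierarchyLabel],
    levels: Optional[Sequence[int]] = None,
) -> BenchmarkResult:
    """Per-level mean sensitivity-to-first-FP over all queries."""
    if not hitlists:
        raise ValueError("no hit lists to score")
    n_levels = len(next(iter(labels.values())))
    if levels is None:
        levels = list(range(n_levels))
    per_query: Dict[int, Dict[str, float]] = {lv: {} for lv in levels}
    excluded: Dict[int, List[str]] = {lv: [] for lv in levels}
    for lv in levels:
        for hl in hitlists:
            sens = sensitivity_first_fp(hl, labels, lv)
            if sens is None:
                excluded[lv].append(hl.query_id)
            else:
                per_query[lv][hl.query_id] = sens
        if not per_query[lv]:
            raise ValueError(f"no scorable queries at level {lv}")
    means = {lv: float(np.mean(list(per_query[lv].values()))) for lv in levels}
    return BenchmarkResult(per_query, means, excluded)


def hitlists_from_scores(
    ids: Sequence[str], score_matrix: np.ndarray, higher_is_better: bool = True
) -> List[HitList]:
    """Build ranked hit lists from an all-against-all score matrix.

    Ties are broken by target order in ``ids`` for determinism; the diagonal
    (self-hit) is dropped.
    """
    n = len(ids)
    if score_matrix.shape != (n, n):
        raise ValueError("score matrix shape must match id count")
    out = []
    for i in range(n):
        scores = score_matrix[i]
        order = np.lexsort((np.arange(n), -scores if higher_is_better else scores))
        hits = [(ids[j], float(scores[j])) for j in order if j != i]
        out.append(HitList(query_id=ids[i], hits=hits))
    return out


# ---------------------------------------------------------------------------
# embedding-based annotation transfer
# ---------------------------------------------------------------------------

@dataclass
class EATResult:
    predicted: Dict[str, HierarchyLabel]
    nearest: Dict[str, str]
    per_level_accuracy: List[float]


def eat_transfer(
    query_vectors: Mapping[str, np.ndarray],
    lookup_vectors: Mapping[str, np.ndarray],
    lookup_labels: Mapping[str, HierarchyLabel],
    query_labels: Optional[Mapping[str, HierarchyLabel]] = None,
) -> EATResult:
    """Transfer each query's label from its Euclidean nearest lookup neighbour.

    Per-level accuracy (when ``query_labels`` is given) applies the
    hierarchical rule: a level is correct only if all coarser levels are also
    correct, so the accuracy vector is non-increasing from coarse to fine.
    Distance ties break towards the earlier lookup entry.
    """
    if not lookup_vectors:
        raise ValueError("lookup set is empty")
    lookup_ids = list(lookup_vectors)
    overlap = set(query_vectors) & set(lookup_vectors)
    if overlap:
        raise ValueError(f"queries must not appear in the lookup set: {sorted(overlap)[:3]}")
    L = np.stack([np.asarray(lookup_vectors[i], dtype=np.float64) for i in lookup_ids])
    query_ids = list(query_vectors)
    Q = np.stack([np.asarray(query_vectors[i], dtype=np.float64) for i in query_ids])
    if Q.shape[1] != L.shape[1]:
        raise ValueError(f"embedding width mismatch: query {Q.shape[1]} vs lookup {L.shape[1]}")
    dist = cdist(Q, L, metric="euclidean")
    nearest_idx = dist.argmin(axis=1)  # argmin breaks ties towards earlier entry

    predicted: Dict[str, HierarchyLabel] = {}
    nearest: Dict[str, str] = {}
    for qi, ni in zip(query_ids, nearest_idx):
        nid = lookup_ids[int(ni)]
        nearest[qi] = nid
        lab = lookup_labels.get(nid)
        if lab is None:
            raise ValueError(f"lookup entry {nid!r} is unlabeled")
        predicted[qi] = lab

    accuracies: List[float] = []
    if query_labels is not None:
        n_levels = len(next(iter(lookup_labels.values())))
        correct_so_far = {qi: True for qi in query_ids}
        for lv in range(n_levels):
            n_ok = 0
            for qi in query_ids:
                truth = query_labels.get(qi)
                if truth is None:
                    raise ValueError(f"query {qi!r} is unlabeled")
                level_ok = predicted[qi].levels[lv] == truth.levels[lv]
                correct_so_far[qi] = correct_so_far[qi] and level_ok
                n_ok += correct_so_far[qi]
            accuracies.append(n_ok / len(query_ids))
    return EATResult(predicted=predicted, nearest=nearest, per_level_accuracy=accuracies)


def label_frequency_baseline(
    lookup_labels: Mapping[str, HierarchyLabel],
    query_labels: Mapping[str, HierarchyLabel],
) -> List[float]:
    """Analytic baseline: always predict the most common lookup label path.

    The hierarchical accuracy of the best constant prediction — the modal
    full label — evaluated with the same prefix rule.
    """
    from collections import Counter

    paths = Counter(lab.levels for lab in lookup_labels.values())
    modal = max(paths, key=lambda p: (paths[p], p))
    n_levels = len(modal)
    out = []
    for lv in range(n_levels):
        prefix = modal[: lv + 1]
        n_ok = sum(1 for lab in query_labels.values() if lab.levels[: lv + 1] == prefix)
        out.append(n_ok / len(query_labels))
    return out
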