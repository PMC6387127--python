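"""Retrieval ranking and evaluation protocols.

Three protocols over an all-pairs distance matrix with class labels:

* bulls-eye — every shape queried against the full database (self included);
  same-class hits among the top ``top_n`` are counted and normalized by
  Nd * class_size (the maximum attainable count);
* precision at recall — query excluded; precision when the m-th correct
  neighbor is reached, averaged over queries;
* top-k hits — query excluded; per-rank counts of queries whose rank-r
  neighbor shares the query's label.

Ties in distance are broken by shape position order (stable sort), so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fmsccd.matching import DistanceMatrix

__all__ = [
    "ClassStats",
    "PrecisionRecallResult",
    "rank_neighbors",
    "bulls_eye",
    "precision_at_recall",
    "topk_hits",
    "class_stats",
]


@dataclass(frozen=True)
class ClassStats:
    """Mean distances over ordered off-diagonal pairs (self-pairs excluded)."""

    intra_mean: float
    inter_mean: float | None  # None when the database has a single class


@dataclass(frozen=True)
class PrecisionRecallResult:
    counts: tuple[int, ...]  # target correct-retrieval counts m
    recalls: tuple[float, ...]  # m / (class_size - 1) query-excluded recall
    precisions: tuple[float, ...]  # mean precision over queries at each m
    mean_precision: float
    clamped: tuple[bool, ...]  # True where m was clamped to class_size - 1


def _class_size(labels: tuple[str, ...], protocol: str = "bulls-eye") -> int:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    if counts.min() != counts.max():
        raise ValueError(f"{protocol} requires balanced classes")
    return int(counts[0])


def rank_neighbors(dm: DistanceMatrix, query: int, include_self: bool = True) -> np.ndarray:
    """Indices of database shapes by ascending distance to ``query``.

    Ties are broken by position order (stable sort).  With
    ``include_self=False`` the query itself is removed from the ranking.
    """
    order = np.argsort(dm.values[query], kind="stable")
    if not include_self:
        order = order[order != query]
    return order


def bulls_eye(dm: DistanceMatrix, top_n: int = 40) -> float:
    """Fraction of attainable same-class hits among each query's top ``top_n``.

    The query is part of the database and its self-match counts; the score
    denominator is Nd * class_size (e.g. 1400 * 20 = 28,000).
    """
    n_c = _class_size(dm.labels)
    labels = np.asarray(dm.labels)
    hits = 0
    for q in range(dm.n):
        top = rank_neighbors(dm, q, include_self=True)[:top_n]
        hits += int((labels[top] == labels[q]).sum())
    return hits / (dm.n * n_c)


def topk_hits(dm: DistanceMatrix, k: int = 10) -> np.ndarray:
    """Per-rank same-class hit counts c(1..k), query excluded from its ranking."""
    if k >= dm.n:
        raise ValueError(f"k too large: {k} (database has {dm.n} shapes)")
    labels = np.asarray(dm.labels)
    counts = np.zeros(k, dtype=int)
    for q in range(dm.n):
        ranked = rank_neighbors(dm, q, include_self=False)[:k]
        counts += labels[ranked] == labels[q]
    return counts


def precision_at_recall(
    dm: DistanceMatrix,
    recall_points: "list[int | float]",
) -> PrecisionRecallResult:
    """Mean precision when m correct shapes have been retrieved, per point.

    ``recall_points`` entries are either integer correct-retrieval counts or
    fractions f in (0, 1] of the class size (m = round(f * class_size)).
    The query is excluded from its own ranking, so at most class_size - 1
    correct retrievals are feasible; a point asking for the full class size
    is clamped to class_size - 1 and flagged.  Larger requests are errors.
    """
    n_c = _class_size(dm.labels, protocol="precision-at-recall")
    labels = np.asarray(dm.labels)

    counts: list[int] = []
    clamped: list[bool] = []
    for p in recall_points:
        m = int(round(p * n_c)) if isinstance(p, float) and p <= 1.0 else int(p)
        if m == n_c:  # 100%-recall point: self cannot be retrieved
            counts.append(n_c - 1)
            clamped.append(True)
        elif 1 <= m <= n_c - 1:
            counts.append(m)
            clamped.append(False)
        else:
            raise ValueError(
                f"infeasible recall point: {p} (feasible correct counts 1..{n_c - 1})"
            )

    per_point = np.zeros(len(counts))
    for q in range(dm.n):
        ranked = rank_neighbors(dm, q, include_self=False)
        correct = labels[ranked] == labels[q]
        # rank (1-based) at which the m-th correct hit occurs
        ranks_of_correct = np.flatnonzero(correct) + 1
        for j, m in enumerate(counts):
            per_point[j] += m / ranks_of_correct[m - 1]
    per_point /= dm.n

    return PrecisionRecallResult(
        counts=tuple(counts),
        recalls=tuple(m / (n_c - 1) for m in counts),
        precisions=tuple(per_point),
        mean_precision=float(per_point.mean()),
        clamped=tuple(clamped),
    )


def class_stats(dm: DistanceMatrix) -> ClassStats:
    """Mean intra-class and inter-class distances over ordered pairs i != j."""
    labels = np.asarray(dm.labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(dm.n, dtype=bool)
    intra_mask = same & off
    inter_mask = ~same
    intra = float(dm.values[intra_mask].mean()) if intra_mask.any() else 0.0
    inter = float(dm.values[inter_mask].mean()) if inter_mask.any() else None
    return ClassStats(intra_mean=intra, inter_mean=inter)
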