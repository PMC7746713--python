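"""Pareto frontier analysis for multi-criterion interaction ranking.

Edges carry >=2 non-negative criterion scores (all maximized; callers
pre-orient).  An edge x dominates y when x >= y in every criterion and x > y
in at least one; front 1 is the set of edges dominated by nothing, and
removing successive fronts peels the remaining maxima.  Every edge on a front
receives the same Pareto score

    score(front k) = (n_total - c_{k-1}) / n_total,

where c_{k-1} is the number of edges on strictly better fronts -- i.e. the
fraction of edges not outranked.  Front 1 always scores exactly 1; absent
pairs are defined to score 0 (no evidence).

Two objectives are stratified by an O(n log n) staircase sweep; three or more
by repeated vectorized non-dominated filtering (adequate at desk scale).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import InteractionTable

__all__ = ["ParetoRanking", "dominates", "pareto_fronts", "pareto_scores", "pareto_rank"]


@dataclass
class ParetoRanking:
    """Front assignment (and, once filled, Pareto scores) for a set of edges.

    ``edges`` columns: source_id, target_id, the criterion columns,
    front_index (1-based) and, after scoring, pareto_score.
    """

    edges: pd.DataFrame
    edge_type: str
    criteria: list[str]

    @property
    def n_total(self) -> int:
        return len(self.edges)

    @property
    def n_fronts(self) -> int:
        return int(self.edges["front_index"].max())

    def front(self, k: int) -> pd.DataFrame:
        return self.edges[self.edges["front_index"] == k]

    def score_lookup(self) -> dict[tuple[str, str], float]:
        return dict(
            zip(
                zip(self.edges["source_id"], self.edges["target_id"]),
                self.edges["pareto_score"],
            )
        )


def dominates(x: Sequence[float], y: Sequence[float]) -> bool:
    """True iff x Pareto-dominates y: x >= y componentwise and x != y."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"criterion vectors differ in dimension: {xa.shape} vs {ya.shape}")
    return bool((xa >= ya).all() and (xa > ya).any())


def _fronts_2d(points: np.ndarray) -> np.ndarray:
    """Front index per point (2 criteria) via a staircase sweep.

    Unique vectors are processed in (-c1, -c2) order; per front the last-added
    c2 is its minimum, and these tails decrease strictly across fronts, so
    the correct front is found by binary search (cf. Jensen-style
    non-dominated sorting for two objectives).
    """
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    order = np.lexsort((-uniq[:, 1], -uniq[:, 0]))
    front_of_uniq = np.empty(len(uniq), dtype=int)
    neg_tails: list[float] = []  # ascending; neg_tails[f] = -(last c2 added to front f)
    for idx in order:
        c2 = uniq[idx, 1]
        f = bisect.bisect_right(neg_tails, -c2)
        front_of_uniq[idx] = f + 1
        if f == len(neg_tails):
            neg_tails.append(-c2)
        else:
            neg_tails[f] = -c2
    return front_of_uniq[inverse]


def _nondominated_mask(points: np.ndarray) -> np.ndarray:
    """Boolean mask of points dominated by no other point (any dimension)."""
    n = len(points)
    mask = np.ones(n, dtype=bool)
    chunk = max(1, int(2e7) // max(n, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = points[lo:hi]  # (b, d)
        ge = (points[None, :, :] >= block[:, None, :]).all(axis=2)  # (b, n)
        gt = (points[None, :, :] > block[:, None, :]).any(axis=2)
        dominated = (ge & gt).any(axis=1)
        mask[lo:hi] = ~dominated
    return mask


def _fronts_nd(points: np.ndarray) -> np.ndarray:
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    front_of_uniq = np.zeros(len(uniq), dtype=int)
    remaining = np.arange(len(uniq))
    k = 0
    while remaining.size:
        k += 1
        nd = _nondominated_mask(uniq[remaining])
        front_of_uniq[remaining[nd]] = k
        remaining = remaining[~nd]
    return front_of_uniq[inverse]


def pareto_fronts(table: InteractionTable, criteria: Sequence[str] | None = None) -> ParetoRanking:
    """Stratify the edges of an interaction table into Pareto fronts.

    All named criteria are maximized.  Edges with identical criterion vectors
    land on the same front.  NaN or missing criterion values are rejected.
    """
    crit = list(criteria) if criteria is not None else table.criteria
    if len(crit) < 2:
        raise ValueError("Pareto ranking needs at least 2 criteria")
    missing = [c for c in crit if c not in table.edges.columns]
    if missing:
        raise ValueError(f"criteria {missing} not present in edge table")
    if not len(table.edges):
        raise ValueError("cannot rank an empty edge table")
    pts = table.edges[crit].to_numpy(dtype=float)
    if not np.isfinite(pts).all():
        bad = np.where(~np.isfinite(pts).all(axis=1))[0][0]
        row = table.edges.iloc[bad]
        raise ValueError(
            f"non-finite criterion for edge ({row.source_id!r}, {row.target_id!r})"
        )
    fronts = _fronts_2d(pts) if pts.shape[1] == 2 else _fronts_nd(pts)
    edges = table.edges.copy()  # keep auxiliary columns (e.g. raw counts)
    edges["front_index"] = fronts
    return ParetoRanking(edges=edges, edge_type=table.edge_type, criteria=crit)


def pareto_scores(ranking: ParetoRanking, method: str = "cumulative") -> ParetoRanking:
    """Fill in the per-front Pareto scores of a ranking.

    ``cumulative`` (default): front k scores (n_total - c_{k-1}) / n_total
    with c_{k-1} the edge count on fronts < k.  ``front_rank``: front k of K
    scores (K - k + 1) / K.  Both give front 1 exactly 1 and strictly
    decreasing scores across fronts.
    """
    if not len(ranking.edges):
        raise ValueError("empty ranking")
    fronts = ranking.edges["front_index"].to_numpy()
    n_total = len(fronts)
    if method == "cumulative":
        sizes = np.bincount(fronts)  # index 0 unused
        cum_before = np.concatenate([[0], np.cumsum(sizes[1:])])[: len(sizes)]
        score_of_front = (n_total - cum_before) / n_total  # score_of_front[k-1] for front k
        scores = score_of_front[fronts - 1]
    elif method == "front_rank":
        K = fronts.max()
        scores = (K - fronts + 1) / K
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    edges = ranking.edges.copy()
    edges["pareto_score"] = scores
    return ParetoRanking(edges=edges, edge_type=ranking.edge_type, criteria=ranking.criteria)


def pareto_rank(
    table: InteractionTable,
    criteria: Sequence[str] | None = None,
    method: str = "cumulative",
) -> ParetoRanking:
    """Fronts + scores in one call."""
    return pareto_scores(pareto_fronts(table, criteria), method=method)
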