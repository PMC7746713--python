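"""Benchmark ranking methods by precision/recall of a reference circRNA list
among the top-n interactions.

Three rankings of the same circRNA-miRNA edge table are compared: the Pareto
score, the raw site count (nMRE), and the length-normalized count (MREs/kb).
At each cutoff n the *distinct* circRNAs among the top-n edges are
intersected with the reference list; recall is the intersection over the
reference size, precision over the number of distinct top-n circRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RankingComparison", "rank_edges", "precision_recall_curves"]

_METHOD_COLUMNS = {"pareto": "pareto_score", "nMRE": "n_mre", "nMRE_per_kb": "mre_per_kb"}


@dataclass
class RankingComparison:
    """Tidy per-method, per-n precision/recall curves."""

    curves: pd.DataFrame  # columns: method, n, recall, precision
    reference: frozenset[str]

    def at(self, method: str, n: int) -> tuple[float, float]:
        row = self.curves[(self.curves["method"] == method) & (self.curves["n"] == n)]
        return float(row["recall"].iloc[0]), float(row["precision"].iloc[0])


def rank_edges(edges: pd.DataFrame, method: str) -> pd.DataFrame:
    """Order edges descending by the method's score, ties broken
    deterministically by (source_id, target_id)."""
    if method not in _METHOD_COLUMNS:
        raise ValueError(f"unknown ranking method {method!r}; choose from {sorted(_METHOD_COLUMNS)}")
    col = _METHOD_COLUMNS[method]
    if col not in edges.columns:
        raise ValueError(f"ranking by {method!r} needs column {col!r}")
    return edges.sort_values(
        [col, "source_id", "target_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def precision_recall_curves(
    rankings: dict[str, pd.DataFrame], reference, n_max: int
) -> RankingComparison:
    """Precision/recall of the reference circRNA set among top-n edges,
    for every n in 1..n_max and every named ranking."""
    ref = frozenset(reference)
    if not ref:
        raise ValueError("empty reference circRNA list")
    rows = []
    for method, ranked in rankings.items():
        circs = ranked["source_id"].to_numpy()
        limit = min(n_max, len(circs))
        seen: set[str] = set()
        n_distinct = 0
        n_hits = 0
        for n in range(1, limit + 1):
            c = circs[n - 1]
            if c not in seen:
                seen.add(c)
                n_distinct += 1
                if c in ref:
                    n_hits += 1
            rows.append((method, n, n_hits / len(ref), n_hits / n_distinct))
        # pad past the table end so curves share a common grid
        for n in range(limit + 1, n_max + 1):
            rows.append((method, n, n_hits / len(ref), n_hits / max(n_distinct, 1)))
    curves = pd.DataFrame(rows, columns=["method", "n", "recall", "precision"])
    return RankingComparison(curves=curves, reference=ref)
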