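"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results from first principles (full
pairwise dominance matrices, per-offset sequence scans, exhaustive
enumeration of miRNA draws) and share no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_pareto_fronts(points: np.ndarray) -> np.ndarray:
    """Front index per point by repeated peeling of the full O(n^2)
    dominance matrix."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    # dom[i, j] True when point j dominates point i
    ge = (pts[None, :, :] >= pts[:, None, :]).all(axis=2)
    gt = (pts[None, :, :] > pts[:, None, :]).any(axis=2)
    dom = ge & gt
    fronts = np.zeros(n, dtype=int)
    remaining = np.ones(n, dtype=bool)
    k = 0
    while remaining.any():
        k += 1
        on_front = remaining & ~(dom & remaining[None, :]).any(axis=1)
        fronts[on_front] = k
        remaining &= ~on_front
    return fronts


def brute_force_pareto_scores(fronts: np.ndarray) -> np.ndarray:
    """Score per point: fraction of points not on a strictly better front."""
    fronts = np.asarray(fronts)
    n = len(fronts)
    return np.array([(fronts >= f).sum() / n for f in fronts])


def brute_force_seed_scan(mirna: str, target: str, circular: bool) -> list[tuple[int, str]]:
    """(seed offset, site type) for every offset, checked one by one."""
    mirna = mirna.upper().replace("T", "U")
    target = target.upper().replace("T", "U")
    n = len(target)
    if n < 6:
        return []
    seed_rc = "".join(_COMP[b] for b in reversed(mirna[1:7]))
    m8_rc = _COMP[mirna[7]]
    doubled = target + target
    hits = []
    offsets = range(n) if circular else range(n - 5)
    for i in offsets:
        window = doubled[i : i + 6] if circular else target[i : i + 6]
        if window != seed_rc:
            continue
        if circular:
            m8 = n >= 7 and doubled[(i - 1) % n] == m8_rc
            a1 = n >= 7 and doubled[(i + 6) % n] == "A"
        else:
            m8 = i - 1 >= 0 and target[i - 1] == m8_rc
            a1 = i + 6 < n and target[i + 6] == "A"
        if m8 and a1:
            t = "8mer"
        elif m8:
            t = "7mer-m8"
        elif a1:
            t = "7mer-A1"
        else:
            t = "6mer"
        hits.append((i, t))
    return hits


def exhaustive_permutation_exceedance(S: np.ndarray, v: np.ndarray, observed: np.ndarray):
    """Exact exceedance probability per gene over all ordered draws of
    k = len(v) distinct columns of S."""
    n_genes, n_mir = S.shape
    k = len(v)
    arrangements = list(itertools.permutations(range(n_mir), k))
    q = np.zeros(n_genes)
    for arr in arrangements:
        null = S[:, list(arr)] @ v
        q += null >= observed
    return q / len(arrangements)


def hypergeom_tail_sum(hits: int, n_universe: int, n_set: int, n_sig: int) -> float:
    """One-sided over-representation p as a direct sum of hypergeometric
    terms, computed with exact integer binomials."""
    from math import comb

    total = comb(n_universe, n_sig)
    s = 0
    for a in range(hits, min(n_set, n_sig) + 1):
        if n_sig - a <= n_universe - n_set:
            s += comb(n_set, a) * comb(n_universe - n_set, n_sig - a)
    return s / total
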