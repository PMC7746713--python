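"""Functional annotation of a circRNA through its miRNA partners.

Given a circRNA c and the set M_k of its k positively-scored miRNAs, each
gene g receives the statistic

    S(c, g) = sum_i  S_P(c, m_i) * S_P(m_i, g),

the product of the circRNA-miRNA Pareto score vector with the (transposed)
miRNA-gene Pareto score matrix.  Its null distribution is approximated by
re-drawing k miRNAs uniformly without replacement from the full miRNA
universe N times, substituting their gene-score columns while keeping the
observed circRNA-miRNA score vector fixed, and the permutation p-value is

    p = (#{null >= observed} + 1) / (N + 1),

so p >= 1/(N+1) and a gene with observed score 0 has p = 1.  Genes passing a
raw p-value cut are then tested for over-representation in user-supplied gene
sets with a one-sided Fisher's exact test, with Benjamini-Hochberg adjusted
p-values reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .pareto import ParetoRanking

__all__ = [
    "GeneScoreVector",
    "mir_gene_score_matrix",
    "mirna_set_for_circ",
    "gene_scores",
    "permutation_pvalues",
    "significant_genes",
    "fisher_enrichment",
    "annotate_circ",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneScoreVector:
    """Per-gene association statistic for one circRNA, with permutation
    p-values once filled.  ``table`` columns: gene_id, score, and after the
    permutation step p_value and n_permutations."""

    circ_id: str
    table: pd.DataFrame


def mir_gene_score_matrix(ranking: ParetoRanking) -> pd.DataFrame:
    """Dense gene x miRNA matrix of mir-gene Pareto scores (0 = no edge)."""
    edges = ranking.edges
    return (
        edges.pivot(index="target_id", columns="source_id", values="pareto_score")
        .fillna(0.0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )


def mirna_set_for_circ(
    circ_id: str,
    circ_mir_ranking: ParetoRanking,
    top_mode: str = "all",
    top_score: float = 0.95,
    top_n: int | None = None,
) -> pd.Series:
    """The miRNA partner set M_k of a circRNA, as a Series of Pareto scores
    indexed by miRNA id.

    ``all``: every partner with positive Pareto score; ``top_score``: those
    with score >= the threshold (inclusive); ``top_n``: the n highest-scoring,
    ties broken by miRNA id.
    """
    edges = circ_mir_ranking.edges
    mine = edges[(edges["source_id"] == circ_id) & (edges["pareto_score"] > 0)]
    if mine.empty:
        raise ValueError(f"no ceRNA edges for circRNA {circ_id!r}")
    scores = pd.Series(
        mine["pareto_score"].to_numpy(), index=mine["target_id"].to_numpy(), name=circ_id
    )
    if top_mode == "all":
        chosen = scores
    elif top_mode == "top_score":
        chosen = scores[scores >= top_score]
        if chosen.empty:
            raise ValueError(
                f"no partner of {circ_id!r} reaches Pareto score {top_score}"
            )
    elif top_mode == "top_n":
        if top_n is None or top_n < 1:
            raise ValueError("top_n mode requires a positive n")
        frame = scores.rename_axis("mir_id").reset_index(name="score")
        frame = frame.sort_values(["score", "mir_id"], ascending=[False, True])
        chosen = pd.Series(
            frame["score"].to_numpy()[:top_n], index=frame["mir_id"].to_numpy()[:top_n]
        )
    else:
        raise ValueError(f"unknown top_mode {top_mode!r}")
    return chosen.sort_index()


def gene_scores(
    circ_id: str,
    mir_scores: pd.Series,
    mir_gene_matrix: pd.DataFrame,
) -> GeneScoreVector:
    """S(c, G) = circ-mir score vector x transposed mir-gene score matrix.

    miRNAs of M_k absent from the matrix contribute 0 to every gene.
    """
    if mir_scores.empty:
        raise ValueError("empty miRNA set")
    cols = mir_gene_matrix.reindex(columns=mir_scores.index, fill_value=0.0)
    scores = cols.to_numpy(dtype=float) @ mir_scores.to_numpy(dtype=float)
    table = pd.DataFrame({"gene_id": mir_gene_matrix.index, "score": scores})
    return GeneScoreVector(circ_id=circ_id, table=table.reset_index(drop=True))


def permutation_pvalues(
    observed: GeneScoreVector,
    mir_scores: pd.Series,
    full_mir_gene_matrix: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GeneScoreVector:
    """Permutation p-values for every gene's association statistic.

    Each iteration draws k distinct miRNAs uniformly from the full miRNA
    universe (the matrix columns), substitutes their gene-score columns for
    the observed partners while keeping the circRNA-miRNA score vector fixed,
    and recomputes the statistic; p = (#{null >= observed} + 1) / (N + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    k = len(mir_scores)
    universe = full_mir_gene_matrix.columns
    if k > len(universe):
        raise ValueError(f"k={k} exceeds miRNA universe size {len(universe)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    S = full_mir_gene_matrix.to_numpy(dtype=float)  # genes x n_mir
    v = mir_scores.to_numpy(dtype=float)  # k
    if set(mir_scores.index) <= set(full_mir_gene_matrix.columns):
        # recompute the observed statistic with the exact same reduction used
        # for the null draws: mixing BLAS and einsum reductions can differ in
        # the last ulp, and a null draw of the observed subset must tie exactly
        S_obs = full_mir_gene_matrix[mir_scores.index].to_numpy()
        obs = np.einsum("gk,k->g", S_obs, v)
    else:
        # partners outside the sampling universe: keep the provided statistic
        obs = observed.table["score"].to_numpy(dtype=float)
    n_genes, n_mir = S.shape
    exceed = np.zeros(n_genes, dtype=np.int64)
    # chunk iterations to bound the (genes x chunk x k) intermediate
    chunk = max(1, int(5e6) // max(n_genes * k, 1))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        # argsort of iid uniforms = uniformly random permutation; its first k
        # entries are a uniform ordered draw of k distinct miRNAs
        idx = np.argsort(rng.random((b, n_mir)), axis=1)[:, :k]
        null = np.einsum("gbk,k->gb", S[:, idx], v)
        exceed += (null >= obs[:, None]).sum(axis=1)
        done += b
    table = observed.table.copy()
    table["p_value"] = (exceed + 1) / (n_permutations + 1)
    table["n_permutations"] = n_permutations
    return GeneScoreVector(circ_id=observed.circ_id, table=table)


def significant_genes(scored: GeneScoreVector, alpha: float = 0.05) -> list[str]:
    """Genes with raw permutation p-value <= alpha (inclusive)."""
    t = scored.table
    if "p_value" not in t.columns:
        raise ValueError("run permutation_pvalues first")
    return list(t.loc[t["p_value"] <= alpha, "gene_id"])


def fisher_enrichment(
    sig_genes,
    sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation test per gene set.

    The 2x2 table per set counts (significant & in set, significant & not,
    not significant & in set, neither), with genes restricted to the
    universe.  Sets disjoint from the universe are skipped with a warning.
    Returns a frame sorted by p-value with BH-adjusted p alongside.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    sig = frozenset(sig_genes)
    if not sig <= universe:
        raise ValueError("significant genes must be a subset of the universe")
    rows = []
    for name, (_, members) in sets.sets.items():
        in_uni = members & universe
        if not in_uni:
            logger.warning("gene set %r shares no genes with the universe; skipped", name)
            continue
        hits = len(sig & in_uni)
        a = hits
        b = len(sig) - hits
        c = len(in_uni) - hits
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((name, hits, len(sig), len(in_uni), len(universe), odds, p))
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name", "n_hits", "n_sig_genes", "n_set_in_universe",
            "n_universe", "odds_ratio", "p_value",
        ],
    )
    if len(result):
        result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
    return result


def annotate_circ(
    circ_id: str,
    circ_mir_ranking: ParetoRanking,
    mir_gene_matrix: pd.DataFrame,
    gene_sets: GeneSetCollection | None = None,
    top_mode: str = "top_score",
    top_score: float = 0.95,
    top_n: int | None = None,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> tuple[GeneScoreVector, list[str], pd.DataFrame | None]:
    """Full annotation of one circRNA: gene statistics, permutation
    p-values, the significant-gene list, and (if gene sets are given)
    Fisher enrichment over them."""
    mir_scores = mirna_set_for_circ(
        circ_id, circ_mir_ranking, top_mode=top_mode, top_score=top_score, top_n=top_n
    )
    observed = gene_scores(circ_id, mir_scores, mir_gene_matrix)
    scored = permutation_pvalues(
        observed, mir_scores, mir_gene_matrix, n_permutations=n_permutations, seed=seed
    )
    sig = significant_genes(scored, alpha=alpha)
    enrichment = None
    if gene_sets is not None:
        universe = gene_sets.universe or frozenset(mir_gene_matrix.index)
        enrichment = fisher_enrichment(sig, gene_sets, universe)
    return scored, sig, enrichment
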