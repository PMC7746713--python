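"""Model/Results facade over the ceRNA prioritization pipeline.

``CeRNANetwork`` is built from tissue expression panels plus binding
evidence (sequences or precomputed site counts) and miRNA-gene evidence;
``fit()`` runs ECDF scoring, co-expression, site counting and Pareto
ranking of both edge types and returns a ``CeRNANetworkResults`` carrying
the rankings, from which individual circRNAs can be annotated (permutation
gene significance + Fisher enrichment) and rankings benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .annotation import annotate_circ, mir_gene_score_matrix
from .binding import binding_scores_from_sequences, load_mir_gene_evidence, mir_gene_evidence_table
from .evaluation import RankingComparison, precision_recall_curves, rank_edges
from .expression import TissueScoreTable, coexpression_score, tissue_ecdf_scores
from .io import ExpressionPanel, GeneSetCollection, InteractionTable, SequenceSet
from .pareto import ParetoRanking, pareto_rank

__all__ = ["CeRNANetwork", "CeRNANetworkResults", "CircAnnotation"]


@dataclass
class CircAnnotation:
    """Annotation of one circRNA: gene statistics with permutation p-values,
    the significant-gene list, and (optionally) set enrichment."""

    circ_id: str
    mirna_scores: pd.Series          # M_k, Pareto scores indexed by miRNA id
    gene_table: pd.DataFrame         # gene_id, score, p_value, n_permutations
    significant: list[str]
    enrichment: Optional[pd.DataFrame]

    def top_genes(self, n: int = 10) -> pd.DataFrame:
        return self.gene_table.sort_values(
            ["p_value", "score", "gene_id"], ascending=[True, False, True]
        ).head(n)


class CeRNANetwork:
    """Tissue-aware ceRNA interaction model.

    Parameters
    ----------
    circ_expression, mir_expression
        Per-tissue mean normalized expression panels (SRPBM / CPM).
    circ_sequences, mir_sequences
        Mature sequences for seed-site counting; alternatively pass a
        precomputed ``binding_table`` (circ_id, mir_id, n_mre,
        mature_length_nt, mre_per_kb).
    targetscan, mirtarbase
        miRNA-gene evidence tables: (mir_id, gene_id, n_sites) and
        (mir_id, gene_id, n_publications); at least one required.
    gene_sets
        Optional gene sets for enrichment in :meth:`CeRNANetworkResults.annotate`.
    circular
        Scan circRNA targets as closed circles (junction-spanning sites count).
    min_site_type
        Site-type floor in the 6mer < 7mer-A1 < 7mer-m8 < 8mer hierarchy.
    """

    def __init__(
        self,
        circ_expression: ExpressionPanel,
        mir_expression: ExpressionPanel,
        circ_sequences: Optional[SequenceSet] = None,
        mir_sequences: Optional[SequenceSet] = None,
        binding_table: Optional[pd.DataFrame] = None,
        targetscan: Optional[pd.DataFrame] = None,
        mirtarbase: Optional[pd.DataFrame] = None,
        gene_sets: Optional[GeneSetCollection] = None,
        circular: bool = True,
        min_site_type: str = "6mer",
    ) -> None:
        if binding_table is None and (circ_sequences is None or mir_sequences is None):
            raise ValueError("provide circ+mir sequences or a precomputed binding table")
        if targetscan is None and mirtarbase is None:
            raise ValueError("provide at least one miRNA-gene evidence table")
        self.circ_expression = circ_expression
        self.mir_expression = mir_expression
        self.circ_sequences = circ_sequences
        self.mir_sequences = mir_sequences
        self.binding_table = binding_table
        self.targetscan = targetscan
        self.mirtarbase = mirtarbase
        self.gene_sets = gene_sets
        self.circular = circular
        self.min_site_type = min_site_type

    @classmethod
    def from_fixture_bundle(cls, bundle) -> "CeRNANetwork":
        """Build the model straight from a synthetic fixture bundle."""
        return cls(
            circ_expression=bundle.circ_expression,
            mir_expression=bundle.mir_expression,
            circ_sequences=bundle.circ_sequences,
            mir_sequences=bundle.mir_sequences,
            targetscan=bundle.targetscan,
            mirtarbase=bundle.mirtarbase,
            gene_sets=bundle.gene_sets,
        )

    def fit(self, score_method: str = "cumulative") -> "CeRNANetworkResults":
        """Score, integrate and Pareto-rank both edge types."""
        circ_ecdf = tissue_ecdf_scores(self.circ_expression)
        mir_ecdf = tissue_ecdf_scores(self.mir_expression)
        coexp = coexpression_score(circ_ecdf, mir_ecdf)

        binding = self.binding_table
        if binding is None:
            binding = binding_scores_from_sequences(
                self.circ_sequences,
                self.mir_sequences,
                circular=self.circular,
                min_site_type=self.min_site_type,
            )
        edges = coexp.edges.merge(
            binding.rename(columns={"circ_id": "source_id", "mir_id": "target_id"}),
            on=["source_id", "target_id"],
            how="outer",
        )
        for col, fill in (("S_exp", 0.0), ("n_mre", 0), ("mre_per_kb", 0.0)):
            if col not in edges.columns:
                edges[col] = fill
            edges[col] = edges[col].fillna(fill)
        edges = edges.drop(columns=["mature_length_nt"], errors="ignore")
        # pairs with no evidence on either axis are unranked (score 0 by definition)
        edges = edges[(edges["S_exp"] > 0) | (edges["n_mre"] > 0)].reset_index(drop=True)
        edges = edges.sort_values(["source_id", "target_id"]).reset_index(drop=True)
        circ_mir_table = InteractionTable(edges=edges, edge_type="circ-mir")
        circ_mir = pareto_rank(circ_mir_table, criteria=["S_exp", "mre_per_kb"],
                               method=score_method)

        evidence = load_mir_gene_evidence(self.targetscan, self.mirtarbase)
        mir_gene = pareto_rank(
            mir_gene_evidence_table(evidence),
            criteria=["n_mre_targetscan", "n_pubs_mirtarbase"],
            method=score_method,
        )
        return CeRNANetworkResults(
            model=self,
            circ_mir=circ_mir,
            mir_gene=mir_gene,
            circ_tissue_scores=circ_ecdf,
            mir_tissue_scores=mir_ecdf,
            score_method=score_method,
        )


@dataclass
class CeRNANetworkResults:
    """Fitted rankings plus annotation and benchmarking methods."""

    model: CeRNANetwork
    circ_mir: ParetoRanking
    mir_gene: ParetoRanking
    circ_tissue_scores: TissueScoreTable
    mir_tissue_scores: TissueScoreTable
    score_method: str = "cumulative"
    _mir_gene_matrix: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def mir_gene_matrix(self) -> pd.DataFrame:
        if self._mir_gene_matrix is None:
            self._mir_gene_matrix = mir_gene_score_matrix(self.mir_gene)
        return self._mir_gene_matrix

    def annotate(
        self,
        circ_id: str,
        top_mode: str = "top_score",
        top_score: float = 0.95,
        top_n: Optional[int] = None,
        alpha: float = 0.05,
        n_permutations: int = 10_000,
        seed: Optional[int] = None,
    ) -> CircAnnotation:
        """Permutation-based gene significance and set enrichment for one circRNA."""
        from .annotation import gene_scores, mirna_set_for_circ, permutation_pvalues
        from .annotation import fisher_enrichment, significant_genes

        mir_scores = mirna_set_for_circ(
            circ_id, self.circ_mir, top_mode=top_mode, top_score=top_score, top_n=top_n
        )
        observed = gene_scores(circ_id, mir_scores, self.mir_gene_matrix)
        scored = permutation_pvalues(
            observed, mir_scores, self.mir_gene_matrix,
            n_permutations=n_permutations, seed=seed,
        )
        sig = significant_genes(scored, alpha=alpha)
        enrichment = None
        if self.model.gene_sets is not None:
            universe = self.model.gene_sets.universe or frozenset(self.mir_gene_matrix.index)
            enrichment = fisher_enrichment(sig, self.model.gene_sets, universe)
        return CircAnnotation(
            circ_id=circ_id,
            mirna_scores=mir_scores,
            gene_table=scored.table,
            significant=sig,
            enrichment=enrichment,
        )

    def compare_rankings(
        self, reference, n_max: int, methods: Sequence[str] = ("pareto", "nMRE", "nMRE_per_kb")
    ) -> RankingComparison:
        """Precision/recall of a reference circRNA list among top-n edges for
        the Pareto, raw-site-count and per-kb rankings of the same edges."""
        rankings = {m: rank_edges(self.circ_mir.edges, m) for m in methods}
        return precision_recall_curves(rankings, reference, n_max)

    def summary(self) -> str:
        """Plain-text summary of the fitted rankings."""
        cm, mg = self.circ_mir, self.mir_gene
        front1 = cm.front(1)
        lines = [
            f"ceRNA network prioritization (ceranet {_pkg_version})",
            "=" * 56,
            f"circRNA-miRNA edges ranked : {cm.n_total}",
            f"  criteria                 : {', '.join(cm.criteria)}",
            f"  Pareto fronts            : {cm.n_fronts}",
            f"  edges on front 1         : {len(front1)}",
            f"  distinct circRNAs/front 1: {front1['source_id'].nunique()}",
            f"miRNA-gene edges ranked    : {mg.n_total}",
            f"  criteria                 : {', '.join(mg.criteria)}",
            f"  Pareto fronts            : {mg.n_fronts}",
            f"  edges on front 1         : {len(mg.front(1))}",
            f"score method               : {self.score_method}",
        ]
        return "\n".join(lines)

    def plot_fronts(self, n_fronts: int = 10, ax=None):
        """Scatter the circ-mir criterion plane colored by front index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        edges = self.circ_mir.edges
        shown = edges[edges["front_index"] <= n_fronts]
        sc = ax.scatter(
            shown[self.circ_mir.criteria[0]],
            shown[self.circ_mir.criteria[1]],
            c=shown["front_index"], cmap="viridis", s=12,
        )
        ax.set_xlabel(self.circ_mir.criteria[0])
        ax.set_ylabel(self.circ_mir.criteria[1])
        ax.set_title(f"First {n_fronts} Pareto fronts")
        plt.colorbar(sc, ax=ax, label="front index")
        return ax
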