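"""Count normalization, low-expression filtering, tissue-wise ECDF scores and
the pan-tissue circRNA-miRNA co-expression score.

A feature's tissue score is its empirical-CDF quantile among the features of
its class that are expressed (value > 0) in that tissue; scores lie in (0, 1]
and the (tied-)maximal expressed feature scores exactly 1.  The co-expression
score of a (circRNA, miRNA) pair is

    S_exp = max over tissues of min(circ tissue score, miRNA tissue score),

so a high score requires both partners to sit high in the expression ranking
of at least one common tissue.  Pairs never co-expressed score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionPanel, InteractionTable

__all__ = [
    "CountPanel",
    "TissueScoreTable",
    "median_of_ratios_normalize",
    "cpm",
    "srpbm",
    "filter_low_expression",
    "tissue_ecdf_scores",
    "coexpression_score",
]

logger = logging.getLogger(__name__)


@dataclass
class CountPanel:
    """Raw integer counts per feature x sample, plus per-sample mapped-read
    totals (needed only for SRPBM)."""

    counts: pd.DataFrame
    feature_class: str
    total_mapped_reads: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids in count panel")
        if self.total_mapped_reads is not None:
            totals = self.total_mapped_reads.reindex(self.counts.columns)
            if totals.isna().any():
                missing = list(totals.index[totals.isna()])
                raise ValueError(f"missing total mapped reads for sample(s) {missing}")
            if (totals <= 0).any():
                raise ValueError("total mapped reads must be positive")
            self.total_mapped_reads = totals.astype(float)


@dataclass
class TissueScoreTable:
    """Tidy (feature_id, tissue_id, score) rows; one row per expressed
    feature-tissue pair; scores in (0, 1]."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("feature_id", "tissue_id", "score"):
            if col not in self.scores.columns:
                raise ValueError(f"score table missing column {col!r}")
        s = self.scores["score"].to_numpy(dtype=float)
        if ((s <= 0) | (s > 1)).any():
            raise ValueError("ECDF scores must lie in (0, 1]")

    def pivot(self) -> pd.DataFrame:
        """Feature x tissue matrix of scores; 0 where not expressed."""
        return self.scores.pivot(index="feature_id", columns="tissue_id", values="score").fillna(0.0)

    @property
    def tissue_ids(self) -> list[str]:
        return sorted(self.scores["tissue_id"].unique())


def median_of_ratios_normalize(counts: CountPanel) -> ExpressionPanel:
    """Median-of-ratios size-factor normalization of a count matrix.

    Each sample's size factor is the median, over features with all-positive
    counts, of the ratio of the sample's count to the feature's geometric
    mean across samples; counts are then divided by the size factor.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("median-of-ratios needs at least 2 samples")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "median-of-ratios undefined (consider CPM instead)"
        )
    ref = mat[all_pos]
    geo_mean = np.exp(np.log(ref).mean(axis=1))
    size_factors = np.median(ref / geo_mean[:, None], axis=0)
    values = pd.DataFrame(
        mat / size_factors[None, :], index=counts.counts.index, columns=counts.counts.columns
    )
    return ExpressionPanel(values=values, feature_class=counts.feature_class,
                           unit_label="median-of-ratios normalized counts")


def cpm(counts: CountPanel) -> ExpressionPanel:
    """Counts per million: count / library size x 1e6, per sample."""
    mat = counts.counts.to_numpy(dtype=float)
    colsum = mat.sum(axis=0)
    if (colsum == 0).any():
        zero = list(counts.counts.columns[colsum == 0])
        raise ValueError(f"zero total count in sample(s) {zero}; CPM undefined")
    values = pd.DataFrame(mat / colsum[None, :] * 1e6,
                          index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionPanel(values=values, feature_class=counts.feature_class, unit_label="CPM")


def srpbm(bs_junction_counts: CountPanel) -> ExpressionPanel:
    """Spliced reads per billion mapped: BS-junction count / total mapped x 1e9."""
    if bs_junction_counts.total_mapped_reads is None:
        raise ValueError("SRPBM requires per-sample total mapped reads")
    totals = bs_junction_counts.total_mapped_reads.to_numpy(dtype=float)
    mat = bs_junction_counts.counts.to_numpy(dtype=float)
    values = pd.DataFrame(mat / totals[None, :] * 1e9,
                          index=bs_junction_counts.counts.index,
                          columns=bs_junction_counts.counts.columns)
    return ExpressionPanel(values=values, feature_class=bs_junction_counts.feature_class,
                           unit_label="SRPBM")


def filter_low_expression(
    counts: CountPanel,
    normalized: ExpressionPanel,
    min_total_count: int = 10,
    min_mean_norm: float = 10.0,
) -> list[str]:
    """Ids of features passing both the raw-total and mean-normalized filters.

    A feature is retained when its total raw count is >= ``min_total_count``
    and its mean normalized value is >= ``min_mean_norm`` (both thresholds
    inclusive: the cuts drop strictly-below values).
    """
    if set(counts.counts.index) != set(normalized.values.index):
        raise ValueError("count panel and normalized panel cover different feature sets")
    totals = counts.counts.sum(axis=1)
    means = normalized.values.mean(axis=1).reindex(counts.counts.index)
    keep = (totals >= min_total_count) & (means >= min_mean_norm)
    return list(counts.counts.index[keep])


def tissue_ecdf_scores(panel: ExpressionPanel) -> TissueScoreTable:
    """Per-tissue ECDF score of each expressed feature's own expression.

    Unexpressed (value 0) features are excluded per tissue; the score of an
    expressed feature is the fraction of expressed features with value <= its
    own (right-continuous ECDF, so ties share the higher score).  A tissue
    with no expressed feature is omitted with a warning.
    """
    rows: list[tuple[str, str, float]] = []
    for tissue in panel.tissue_ids:
        col = panel.values[tissue]
        expressed = col[col > 0]
        if expressed.empty:
            logger.warning("tissue %r has no expressed %s features; omitted",
                           tissue, panel.feature_class)
            continue
        vals = expressed.to_numpy(dtype=float)
        # ECDF at own value: count of expressed values <= own, over n
        order = np.argsort(vals, kind="stable")
        ranks = np.searchsorted(vals[order], vals, side="right")
        scores = ranks / len(vals)
        rows.extend(zip(expressed.index, [tissue] * len(vals), scores))
    df = pd.DataFrame(rows, columns=["feature_id", "tissue_id", "score"])
    return TissueScoreTable(scores=df)


def coexpression_score(
    circ_scores: TissueScoreTable, mir_scores: TissueScoreTable
) -> InteractionTable:
    """Pan-tissue co-expression score for every (circRNA, miRNA) pair.

    score(c, m) = max over shared tissues of min(S_c|t, S_m|t); pairs with no
    tissue where both are expressed score 0.  Returns a circ-mir
    InteractionTable with criterion column ``S_exp`` (all pairs, zeros kept).
    """
    cmat = circ_scores.pivot()
    mmat = mir_scores.pivot()
    tissues = sorted(set(cmat.columns) & set(mmat.columns))
    circ_ids = list(cmat.index)
    mir_ids = list(mmat.index)
    if tissues:
        c = cmat[tissues].to_numpy(dtype=float)  # nc x T, 0 = not expressed
        m = mmat[tissues].to_numpy(dtype=float)  # nm x T
        # max over tissues of elementwise min; zeros (unexpressed) never win
        # unless no shared expressed tissue exists, in which case score is 0.
        pair = np.max(np.minimum(c[:, None, :], m[None, :, :]), axis=2)
    else:
        pair = np.zeros((len(circ_ids), len(mir_ids)))
    df = pd.DataFrame(
        {
            "source_id": np.repeat(circ_ids, len(mir_ids)),
            "target_id": np.tile(mir_ids, len(circ_ids)),
            "S_exp": pair.ravel(),
        }
    )
    return InteractionTable(edges=df, edge_type="circ-mir")
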