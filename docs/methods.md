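# Methods

This note records the model, the numerical conventions, and the design
choices made where more than one reasonable convention exists. Nothing here
states a result the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and assumptions

`ceranet` ranks two kinds of edges.

**circRNA–miRNA edges** carry two criteria: a pan-tissue co-expression
score and a length-normalized binding score.

*Co-expression.* Per tissue, features with zero value are excluded and each
expressed feature is scored by the right-continuous empirical CDF of the
tissue's expression values evaluated at its own value:
score = #{expressed values ≤ own}/#expressed. Scores therefore lie in
(0, 1], the (tied-)maximal feature scores exactly 1, and ties share the
higher score (the ECDF's range requirement forces the right-continuous
convention; a "<" convention would allow 0). The pair score is the maximum
over tissues of the pairwise minimum. Assumptions: expression panels hold
one mean normalized value per feature and tissue (replicates are averaged
before scoring, which discards within-tissue variance); quantile scoring
makes the method invariant to any monotone transformation of one tissue's
values, so normalization choices only matter through zero/filter decisions.

*Binding.* Canonical seed sites are counted and divided by mature-sequence
length (MREs/kb). The counter implements only the canonical seed taxonomy —
seed = miRNA positions 2–7 (5'→3'); a site is a Watson–Crick
reverse-complement match to the seed, classified 8mer / 7mer-m8 / 7mer-A1 /
6mer by the additional match opposite miRNA position 8 and/or an adenosine
opposite position 1. Context-style site scoring (conservation, local AU,
3'-pairing, accessibility) is deliberately out of scope: downstream ranking
consumes only the site count. Users with precomputed site tables can bypass
the counter entirely (`binding_table=` / load-table mode).

**miRNA–gene edges** carry the site count from a TargetScan-style table and
the publication count from a miRTarBase-style table, summed over duplicate
rows (e.g. conserved + non-conserved families), outer-joined with missing
evidence as 0; pairs with both counts 0 are dropped.

**Pareto ranking.** Dominance is "≥ everywhere, > somewhere". Fronts are
computed by a staircase sweep for two criteria (sort by (−c1, −c2); each
front's most recently added c2 is its minimum and these tails decrease
strictly across fronts, so a binary search places each point; equal vectors
are deduplicated first and share a front) and by repeated vectorized
non-dominated filtering for three or more. Both paths are checked against
an O(n²) peeling oracle in the tests. Scores: front *k* receives
(n − c_{k−1})/n where c_{k−1} counts edges on fronts < k.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_total_count` | 10 | drop features with total raw count below this (counts) |
| `min_mean_norm` | 10 | drop features with mean normalized value below this |
| `circular` | True | scan circRNA targets as closed circles |
| `min_site_type` | 6mer | site-type floor included in the MRE count |
| `top_mode` / `top_score` | top_score, 0.95 | miRNA partner set for annotation: Pareto score ≥ τ (inclusive); `all` and `top_n` available |
| `alpha` | 0.05 | raw permutation p cut for significant genes (inclusive ≤) |
| `n_permutations` | 10,000 | null draws; 1,000 is a reasonable fast mode |
| `score_method` | cumulative | per-front score; `front_rank` = (K−k+1)/K available |

Both thresholds 10 are the conventional low-expression cuts for count data;
τ = 0.95 keeps only near-front partners and keeps the permutation null
informative (with `all`, a well-connected circRNA's partner set can approach
the whole miRNA universe, making the null degenerate).

## Permutation test

The gene statistic is S(c,g) = Σᵢ S_P(c,mᵢ)·S_P(mᵢ,g) over the chosen
partner set M_k. Each null iteration draws k *distinct* miRNAs uniformly
from the full universe (the columns of the miRNA–gene score matrix),
substitutes their columns, keeps the observed circ–miR score vector fixed,
and recomputes the statistic; p = (#{null ≥ observed}+1)/(N+1), so
p ≥ 1/(N+1) and a gene with observed score 0 has p = 1. Draws are
independent across iterations and may repeat subsets; the observed subset
itself is a legal draw. Exceedance uses ≥ exactly; to make ties at the
observed subset bit-exact, the observed statistic is recomputed inside the
test with the same einsum reduction used for the null draws (mixing BLAS
and einsum reductions can differ in the last ulp and silently bias tie
counting — this was measurable as a multi-standard-error distortion at
small universes before the fix). Permutation p-values are used raw at α;
gene-set enrichment reports Benjamini–Hochberg adjusted p alongside the
one-sided Fisher p but filters on the raw value by default. The enrichment
universe defaults to all genes in the miRNA–gene matrix.

## Normalization helpers

DESeq2-style normalization is reduced to plain median-of-ratios size
factors (no shrinkage, no design): size factor = median over features with
all-positive counts of count/geometric mean across samples, with the median
taken on the ratio scale. Only the scaling matters downstream because the
ECDF scores are rank-based. CPM = count/library size × 10⁶; SRPBM =
back-splice junction count/total mapped reads × 10⁹.

## Synthetic data

The generator (`ceranet.simulate`) emulates the statistical structure the
method assumes, not biological realism. Background expression is i.i.d.
log-normal (σ = 1) with 30% dropout per feature–tissue; circRNA lengths are
log-uniform on 200–3000 nt; sequences are uniform random over {A,C,G,U};
miRNA–gene evidence is sparse (≈30 targets per miRNA, small counts). A
planted sponge raises the circRNA and its miRNAs to a chosen ECDF quantile
(default 0.95) of one shared tissue, overwrites non-overlapping stretches
of the circRNA sequence with exact 8mer sites at a chosen density (default
4 MREs/kb on a 500-nt mature sequence — moderate binding, well below a
strong sponge's tens of sites per kb), and gives its miRNAs elevated
site/publication counts against one gene set's members. The default study
conditions are 5 tissues, 200 circRNAs, 60 miRNAs, 500 genes, 20 gene sets
of 25, and 3 planted sponges with 3 miRNAs each.

What passing the planted-recovery tests shows: the pipeline separates edges
that are jointly strong on both axes from log-normal background noise and
propagates that signal through the permutation and enrichment stages. What
it does not show: robustness to correlated expression across tissues,
isoform structure, family-level miRNA redundancy, or biased gene-set
overlap — real data have all of these and the synthetic background has
none.

## Numerical choices and degenerate inputs

- TSV floats are written with `%.17g` and parsed with exact `strtod`, so
  write→read round-trips are bit-faithful and pipeline re-runs with the
  same seed are byte-identical (no timestamps in output headers).
- T/U are normalized to U at read time; site counting is encoding-invariant.
- Circular scanning reports positions modulo the mature-sequence length; a
  junction-spanning site can upgrade a boundary hit's type relative to the
  linear scan (the m8 base may wrap), so linear hits are a subset of
  circular hits by seed position, not necessarily by (position, type).
- Tissues with no expressed feature are omitted from ECDF scoring with a
  warning; pairs with no shared expressed tissue score 0; circ–miR pairs
  with no evidence on either axis are excluded from ranking (their score is
  0 by definition rather than by rescaling).
- Ranking ties in the evaluation module are broken lexicographically by
  (source, target) so all orderings are deterministic.
- Empty edge tables, empty gene universes, k exceeding the miRNA universe,
  non-finite criteria and malformed input files are rejected with located
  errors rather than silently handled.

## Open design points resolved here

- *Per-front score rescaling*: "rescaled rank" admits two readings; the
  default is the block-maximum rule (fraction of edges not on a strictly
  better front), which satisfies both fixed points (front 1 → 1, same front
  → same score); the front-index-based alternative is available as
  `score_method="front_rank"`.
- *circRNA filtering*: circRNAs are only zero-filtered per tissue; the
  count filters apply to genes/miRNAs.
- *miRNA identity*: everything is keyed by mature miRNA id; collapsing
  TargetScan families to mature ids is left to an optional user-supplied
  mapping, never guessed.
- *Gene ECDF scores*: computable but unused by default — co-expression is
  defined only for circ–miR pairs.

## Problem sizes in the shipped checks

The acceptance-style checks run at desk scale by design: Pareto oracle
equivalence on 500 random 2-D/3-D sets of up to 500 points; permutation
exactness on a 6-miRNA universe (exhaustively enumerable); Fisher
agreement on every 2×2 table from universes up to 50 genes; seed-site
agreement on 200 random 500-nt targets; and the end-to-end recovery study
over 50 seeds at the default study conditions with N = 1000 permutation
draws.

## Known limitations

- No context-style MRE scoring or RNA accessibility; counts only.
- Flat gene sets (no GO DAG awareness).
- The permutation null fixes the circ–miR score vector; only the gene-side
  columns are re-drawn.
- Within-front ordering is undefined by construction (same score); consumers
  needing a total order must use the documented lexicographic tie-break.
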