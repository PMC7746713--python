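# ceranet

Tissue-aware prioritization and functional annotation of competing
endogenous RNA (ceRNA) interactions.

Circular RNAs (circRNAs) can act as miRNA "sponges": by carrying many
miRNA response elements (MREs) they sequester a miRNA and de-repress its
other targets. Sequence-based MRE catalogues alone over-predict such
interactions badly, because a sponge is only plausible where both the
circRNA and the miRNA are actually expressed in the same tissue. `ceranet`
integrates the two kinds of evidence without choosing a trade-off between
them, ranks circRNA–miRNA and miRNA–gene interactions by Pareto optimality,
and annotates individual circRNAs with significant target genes and
enriched pathways. It is aimed at computational biologists who have
per-tissue expression tables, mature sequences (or precomputed site
counts), and miRNA–gene evidence tables, and want a ranked, testable ceRNA
network rather than a raw site catalogue.

## Method

**Expression evidence.** Within each tissue *t*, expressed features
(value > 0) of one class are scored by the empirical CDF of their mean
normalized expression evaluated at their own value, giving
S<sub>exp</sub><sup>·|t</sup> ∈ (0, 1]. The pan-tissue co-expression score
of a (circRNA *c*, miRNA *m*) pair is

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>exp</sub><sup>c|m</sup> = max<sub>t</sub> min{ S<sub>exp</sub><sup>c|t</sup>, S<sub>exp</sub><sup>m|t</sup> },

high exactly when both partners sit high in the expression ranking of at
least one common tissue. Helpers for count normalization are included
(CPM, SRPBM for back-splice junction counts, median-of-ratios size
factors) along with the standard low-expression filters (total count ≥ 10,
mean normalized value ≥ 10).

**Binding evidence.** Canonical seed sites (6mer, 7mer-A1, 7mer-m8, 8mer;
seed = miRNA positions 2–7) are counted on circRNA mature sequences —
scanned as closed circles so junction-spanning sites count — and
normalized by mature-sequence length to MREs/kb. For miRNA–gene edges, the
two criteria are the site count from a TargetScan-style table and the
publication count from a miRTarBase-style table.

**Pareto integration.** An edge *x* dominates *y* when *x* ≥ *y* in every
criterion and > in at least one. Non-dominated edges form front 1;
peeling repeats on the remainder. Every edge on front *k* receives the
Pareto score (n − c<sub>k−1</sub>)/n, the fraction of edges not on a
strictly better front; front 1 scores exactly 1 and absent pairs are
defined to score 0 (no evidence).

**Annotation.** For a circRNA *c* and its top-scoring miRNA set
**M**<sub>k</sub>, each gene *g* gets the statistic
S<sup>c|g</sup> = Σ<sub>i</sub> S<sub>P</sub><sup>c|m_i</sup> ·
S<sub>P</sub><sup>m_i|g</sup>. Its null distribution is simulated by
re-drawing k miRNAs uniformly from the full universe N times (default
10,000) with the circ–miR score vector held fixed;
p = (#{null ≥ observed} + 1)/(N + 1). Genes with p ≤ α (default 0.05) are
tested for over-representation in user-supplied gene sets (GMT) with a
one-sided Fisher's exact test, Benjamini–Hochberg adjusted p alongside.

## Worked example

Everything runs on self-contained synthetic data with a planted sponge
signal (3 sponge circRNAs among 200, each sequestering 3 miRNAs aimed at
one gene set — see `ceranet.simulate`):

```python
from ceranet import CeRNANetwork
from ceranet.simulate import default_config, generate

bundle = generate(default_config(seed=1))
results = CeRNANetwork.from_fixture_bundle(bundle).fit()
print(results.summary())
```

```
ceRNA network prioritization (ceranet 0.1.0)
========================================================
circRNA-miRNA edges ranked : 11802
  criteria                 : S_exp, mre_per_kb
  Pareto fronts            : 699
  edges on front 1         : 5
  distinct circRNAs/front 1: 5
miRNA-gene edges ranked    : 2008
  criteria                 : n_mre_targetscan, n_pubs_mirtarbase
  Pareto fronts            : 16
  edges on front 1         : 2
score method               : cumulative
```

11,802 circ–miR pairs with any evidence were stratified into 699 fronts;
the 5 edges on front 1 (score 1.0) are the strongest combined
expression+binding candidates. Annotating the first planted sponge:

```python
ann = results.annotate("circ_0001", top_score=0.95, n_permutations=1000, seed=1)
print("partners:", ", ".join(ann.mirna_scores.index))
print("significant genes:", len(ann.significant))
print(ann.enrichment.head(3).to_string(index=False))
```

```
partners: mir_0001, mir_0002, mir_0003, mir_0008, mir_0010, mir_0043
significant genes: 42
set_name  n_hits  n_set_in_universe  odds_ratio      p_value   adjusted_p
  set_01      25                 25         inf 4.094002e-31 8.188004e-30
  set_10       5                 25    2.891892 5.298541e-02 3.532361e-01
  set_13       5                 25    2.891892 5.298541e-02 3.532361e-01
```

The three planted miRNAs (mir_0001–0003) pass the 0.95 Pareto-score cut,
42 of 490 genes survive the permutation test, and the planted target set
(`set_01`, all 25 members hit) tops the enrichment ranking at
p ≈ 4×10⁻³¹ — the sponge's pathway is recovered.

The same pipeline is scriptable from the shell:

```bash
ceranet make-fixtures --seed 1 --out fixtures/
ceranet run --config config.yaml --out results/   # see docs/methods.md
```

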