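# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data design behind `cncnet`, in the order the pipeline runs.

## Random variance model (RVM) differential expression

**Model.**  For gene *g* with pooled two-group sample variance `s²_g` on
`f = n₁ + n₂ − 2` degrees of freedom, the RVM assumes the precisions are
exchangeable across genes:

    1/σ²_g ~ Gamma(a, scale = b)

Marginally `s²_g · a · b ~ F(f, 2a)`, which is how `(a, b)` is estimated:
the log-likelihood `Σ log f_F(s²·a·b; f, 2a) + log(a·b)` (the last term is
the Jacobian of the scaling) is maximized by L-BFGS-B on `(log a, log b)`
after a coarse grid initialization, with convergence tolerance 1e−12 on the
objective.  The posterior-mean variance replaces `s²`:

    s̃²_g = (f·s²_g + 2/b) / (f + 2a)

and `t = (x̄_d − x̄_c) / √(s̃²(1/n₁ + 1/n₂))` is referred to a t
distribution with `f + 2a` degrees of freedom, two-sided by tail doubling.

**Edge cases.**  Genes with `s² = 0` are excluded from the prior fit (their
density under the model is degenerate) but still tested — their moderated
variance `(2/b)/(f+2a)` is positive.  If the moderated variance is exactly
zero (possible only in pathological limits) the p-value is defined as 0
when the means differ and 1 otherwise, with a warning.  A prior fitted on
fewer than 100 genes triggers an instability warning.  `s̃²` is by
construction a convex combination of `s²` and the prior value `1/(a·b)`,
so shrinkage can never leave that interval; the vanishing-prior limit
(`a → 0`, `2/b → 0`) reproduces the ordinary pooled t-test to < 1e−6.

**Selection.**  The default gate is raw `P < 0.05` (strict inequality) with
no fold-change cutoff; BH-adjusted q-values are always reported alongside,
and both a q gate and a fold-change gate are available via
`PipelineConfig`.  This mirrors the protocol this workflow is used with,
where the published criterion is a raw p threshold; the choice of gate is
the user's.

**Clustering.**  Significant genes are clustered two-way with average
linkage on `1 − Pearson` distance (SciPy linkage; leaf order is SciPy's
deterministic order, ties resolved by input order).  Zero-variance rows
have no defined correlation and are dropped with a warning.

## Cis pairing

Intervals are 0-based half-open everywhere internally (BED convention; GTF
input is converted on read).  Classification of a (lncRNA, mRNA) pair:

* different chromosomes → no relation;
* intersecting intervals → `overlap` (same strand) or `antisense`
  (opposite strand), distance 0;
* otherwise the distance is the gap between nearest interval boundaries
  (gene-body gap, not TSS-to-TSS — the weaker, more inclusive reading);
  a gap ≥ 300,000 bases → no relation (strict `<` window);
* a surviving pair is `upstream` if the lncRNA lies entirely on the 5′ side
  of the mRNA's transcription start, `downstream` if entirely on the 3′
  side, judged by the mRNA's strand.  Anchoring on the coding gene is the
  default because the question is which coding genes a lncRNA might
  regulate in cis; `pair_anchor='lnc'` flips the reference.

Because intervals are half-open and non-intersecting, a neighbour is always
entirely on one side, so the four categories are mutually exclusive and
overlap/antisense dominate the proximity categories.  The pair finder uses
a per-chromosome sorted sweep with a window cut; it is property-tested for
exact equality against an exhaustive O(n²) scan.

## Coexpression networks and diffK

Candidate nodes are the DE lncRNAs and mRNAs of one group; every unordered
pair with `|r| ≥ 0.97` across that group's samples becomes an edge, the
sign kept as an attribute.  The absolute-value reading is the default
because negative regulatory associations are part of this analysis style
(a `corr_use_absolute=False` switch restores the literal signed reading).
Same-biotype edges are included by default (`bipartite_only=True`
restricts to lncRNA–mRNA).  With five samples per group no correlation
p-value gate is meaningful beyond the 0.97 threshold, and none is applied;
genes with constant expression in a group have no defined correlation and
are skipped with a logged count.  Zero-degree candidates are not network
members.

Per node: degree; k-core index (largest k surviving iterative pruning of
degree < k nodes, computed via networkx's core decomposition and
cross-checked in the tests against a direct pruning loop); normalized
connectivity `K = degree / max degree` of its own network (the
`n_minus_1` normalization is available as a config switch);
`diffK = K_disease − K_control` with `K = 0` for absent nodes.  The output
table is ordered by `|diffK|` descending with ties broken by node id, so
rankings are deterministic.

## Over-representation analysis

For each term in a GMT map, a 2×2 table of DE membership versus term
membership over the universe is tested with the two-sided Fisher exact
test (SciPy's hypergeometric enumeration: the mass of tables no more
probable than the observed one) and the Pearson χ² test with 1 df and no
continuity correction (a warning is raised when an expected count is
below 5; χ² is undefined and reported as NaN on a zero margin).  Both
p-values are reported; significance gating and BH adjustment use the
Fisher p, within one (mode, direction) stratum.  The universe defaults to
all mRNAs on the expression matrix — reproducible offline, unlike a
web-service background.  Pathway mode is deliberately plain
over-representation at `P < 0.05`; no topology-based impact factor is
computed, and the run-log records this simplification.

## Synthetic data generator

The generator emulates a 5-vs-5 two-group array study on a synthetic
genome, with every downstream signal planted and recorded:

* **Geometry.**  Each planted cis pair occupies one genomic block whose
  internal layout forces exactly the intended relation (overlap: same
  strand, guaranteed intersection; antisense: ditto, opposite strands;
  upstream/downstream: gap uniform on [1 kb, 250 kb] on the correct side
  of the mRNA).  Blocks — including single-feature background blocks — are
  separated by more than 300 kb plus jitter, so an exhaustive scan of the
  output recovers exactly the planted relations and nothing else.  If the
  requested features cannot fit at that spacing the generator raises
  rather than silently crowding them.  Gene lengths are uniform on
  [500, 5000] bases; strands uniform; coordinates 0-based half-open.

* **Expression.**  Baseline means uniform on log2 [6, 14] (array intensity
  range); per-gene precision `τ ~ Gamma(a=2, scale b=0.5)` by default, so
  variances follow the inverse-gamma law the RVM assumes (mean σ² = 2);
  DE genes receive ±`effect_size_log2` (default 2.5, a ~5.7-fold change,
  typical of the strong calls such studies report) in the disease group.
  Planted-pair members are always DE; the mRNA's direction matches the
  lncRNA's with probability `concordance_rate` (default 0.953).

* **Modules.**  Each module has one hub lncRNA and `module_size − 1` mRNA
  members.  Within each group the member's noise vector is built as
  `ρ·h + √(1−ρ²)·e⊥` where `h` is the hub's standardized noise and `e⊥` a
  standardized residual orthogonalized against it, so the realized
  within-group sample correlation with the hub is exactly
  `hub_corr_disease` (disease) or `hub_corr_control` (control).  Enforcing
  the correlation at the realized-sample level rather than in expectation
  makes hub recovery testable at n = 5, where population-level correlations
  would be swamped by sampling noise; member–member correlations remain
  stochastic around ρ².  Module genes are marked DE (random direction) so
  they enter the DE-restricted networks.

* **Determinism.**  All randomness flows from `SyntheticConfig.seed`
  through fixed, keyed child generators (annotation / expression / term
  map); no global random state is touched.  Identical configs give
  byte-identical outputs.

**What the generator does not emulate:** probe-level effects and
normalization artifacts, batch effects, missing values, correlated
background genes, realistic gene density (features are spaced > 300 kb
apart by design), or annotation ambiguity (one interval per gene).
Passing tests therefore demonstrate correctness of the statistics and the
geometry engine under the stated model, not robustness to real-array
artifacts upstream of a normalized matrix.

## Problem sizes used in the checks

The automated checks run at sizes where the measured properties are
statistically stable: null calibration at 2,000 genes; prior recovery at
20,000 genes over multiple seeds; pairing-oracle equivalence over hundreds
to a thousand random annotations of up to 200 features; k-core equivalence
over 100 random graphs (n = 30, p = 0.2); hub recovery over 100 replicates
of a 75-gene study with one 10-gene module; and an end-to-end run at
~1,700 genes with 400 planted pairs.  These sizes are the package's own
test design; all generator distributions are identical at larger scales.

## Known limitations

* The RVM fit assumes a common variance law across genes; strongly bimodal
  variance structure (e.g. mixed platforms) violates it.
* With five samples per group, a 0.97 correlation threshold still admits a
  ~1 % spurious edge rate per pair, so absolute network sizes are dominated
  by chance edges at realistic gene counts — diffK rankings, not edge
  counts, are the robust output at this design size.
* Enrichment treats terms independently (no GO-DAG awareness) and the
  Fisher test is conservative for small margins.
* Pairing is gene-body based; exon-level overlap and isoform structure are
  out of scope.
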