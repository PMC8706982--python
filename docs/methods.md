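# Methods

This note documents the models, the numerical choices, and what the
synthetic cohort does and does not emulate. It is the design record for the
package; empirical claims below are limited to what the test suite and
`scripts/acceptance.py` actually compute.

## Data model

All stages operate on `OmicsBlock`s: subjects × features matrices labeled
`genus`, `fecal` or `plasma`, sharing a subject index, each carrying an
ordered `transform_log`. Re-applying a preprocessing operation to a block
that already logged it raises an error, so accidental double-transformation
is impossible.

## Preprocessing

**Missingness exclusion.** A metabolite is dropped when its fraction of
missing cells exceeds `max_frac` (default 0.20, strict inequality). At
n = 47 this means 10 missing cells (21.3%) remove a feature and 9 (19.1%)
do not.

**Imputation.** Remaining missing cells are filled by iterative
random-forest imputation: features are swept in order of increasing
missingness, each regressed on all the others with a 100-tree forest using
`sqrt(p)` candidate features per split (the convention of the classical
forest imputer, which also keeps runtime tractable), starting from
feature-mean fill, until the relative squared change of the imputed values
falls below 1e-3 or 10 sweeps. Observed cells are never altered; tree seeds
derive from one generator, so results are reproducible. Imputation runs on
the raw concentration scale, before normalization (the order is a
documented choice; the transformation is rank-based, so imputing first
avoids transforming a partially observed ranking).

**Rank-based inverse normal transformation.** Per feature,
`x ↦ Φ⁻¹((r − c)/(n − 2c + 1))` with Blom's `c = 3/8` (configurable) and
average ranks for ties. The output is monotone in the input with mean ≈ 0
and SD ≈ 1; a constant feature maps to all zeros with a warning.

**Prevalence filter and CLR.** Genera with a nonzero count in fewer than
`min_prevalence · n` subjects (default 10%) are dropped. Counts then get a
pseudocount of 1 (the log of zero is undefined; 1 is the smallest count
increment and is configurable) and the centered log-ratio transform, whose
rows sum to zero and which is invariant to per-sample scaling.

## Sparse generalized CCA

The integration model maximizes
`Σ_{k<l} c_kl · g(cov(X_k a_k, X_l a_l))` subject to `‖a_k‖₂ = 1` and a
per-block sparsity constraint. Defaults, each configurable:

- **Design matrix C**: fully connected (all off-diagonal 1) — the natural
  choice when no block is privileged.
- **Scheme g**: centroid (`g = |·|`), robust to the arbitrary sign of
  correlations; horst (`g = identity`) is available.
- **Sparsity**: keep-counts (hard cardinality per block/component) or L1
  bounds. The keep-count projection retains the largest-|w| entries with
  ties resolved in feature order; the L1 projection soft-thresholds with
  the smallest λ meeting the bound, found by bisection (feasibility is
  monotone in λ).
- **Components**: default 2; each further component is fitted after
  canonical-mode deflation, `X_k ← X_k − t_k (t_kᵀt_k)⁻¹ t_kᵀ X_k`, i.e.,
  every block is deflated by its own component, keeping the blocks
  symmetric (unsupervised). Component choice is guided by the reported AVE
  (mean squared feature–component correlation per block).

**Optimization.** Cyclic block-coordinate ascent: the update for block k
linearizes the objective at the current point and maximizes the linear
minorant under the constraints, which is exactly the thresholded,
renormalized gradient — so the objective trace is monotone non-decreasing
for both sparsity types. The objective is non-convex, and single-start
ascent can stall in local optima in which different block pairs align to
different latent directions. Two measures address this: the deterministic
first start points every block at the leading shared direction of the
concatenated blocks (its top left singular vector projected into each
block), and `n_starts = 20` runs add seeded random restarts, keeping the
best final objective. On exhaustively enumerable problems (three features
per block, keep-count 1) this reaches the global support optimum in 20/20
seeded instances in the test suite; blocks are small enough that the
restarts cost fractions of a second.

Before fitting, features are standardized and each block is divided by
`sqrt(p_k)` so layers with very different widths contribute comparably.

## Network and clusters

For blocks A, B and component h, the shared variate is
`v_h = (t_A⁽ʰ⁾ + t_B⁽ʰ⁾)` scaled to unit SD; the coordinate of a feature is
its Pearson correlation with `v_h`, and the similarity of feature i (block
A) and feature j (block B) is `Σ_h coord_A(i,h)·coord_B(j,h)`, clipped to
[−1, 1] — the bisector-variate construction used by relevance networks for
multi-block latent variable models. Only features with a nonzero weight on
some component enter. Edges require |similarity| ≥ cutoff (default 0.6;
absolute value, because anti-correlation is as informative as correlation),
connect features of *different* blocks only, and exclude exact zeros.
Clusters are connected components, labeled 1..K by decreasing size with
lexicographic tie-breaks, so labeling is deterministic. Raising the cutoff
can only remove edges and split clusters (refinement), a property the test
suite asserts on random similarity matrices.

## Multi-omics scores

Within a cluster, node weights are PageRank centralities of the cluster
subgraph: the stationary distribution of a damped random walk (damping
0.85) whose transition probabilities are proportional to |similarity|,
computed by power iteration to 1e-12 and validated against a dense linear
solve. Centralities are rescaled to sum to 1.

Members of one cluster can be mutually anti-correlated (negative edges), so
each node carries an orientation sign. The default rule takes, per cluster,
the sign pattern of the leading eigenvector of the signed similarity
adjacency — for a balanced signed graph this is the exact two-coloring, and
it remains well-defined when a node's positive and negative ties nearly
cancel; the global sign is anchored by the cluster's lexicographically
smallest node. A simpler rule (sign of the summed incident similarities) is
available as `orientation="incident"` but assigns inconsistent signs in
balanced clusters, and an unsigned mode exists for comparison. The score is
the sign- and centrality-weighted sum of the members' post-transformation
values (CLR scale for genera, INT scale for metabolites), standardized to
mean 0, sample SD 1 (ddof = 1), so downstream effects are per 1-SD
increase. Raw node values rather than re-standardized ones enter the sum:
after INT/CLR all features are already on comparable scales, and the
weighted sum is then standardized anyway.

## Association stage

Each (score, outcome) pair is fitted by OLS `outcome ~ score + age + sex +
BMI` on complete cases (listwise deletion, n recorded). Outcomes are
analyzed on their raw clinical scale. Benjamini–Hochberg adjustment is
applied within each score's family of outcomes by default (configurable to
one global family). Constant outcomes are flagged, not fitted; a zero
residual SE is flagged as degenerate. Partial correlations residualize both
variables on an intercept plus the covariates, correlate the residuals, and
use `t = r·√((n − 2 − k)/(1 − r²))` with k = 3; residual vectors that are
numerically null (variable explained exactly by covariates) are treated as
zero rather than floating-point noise. The partial-correlation matrix is
BH-adjusted as one family. Sex is coded female = 1.

## Synthetic cohort generator

The generator defines the study conditions for all validation:

- **Subjects**: default 47; age ~ Normal(50.6, 7.13) truncated to [30, 65],
  BMI ~ Normal(30.5, 2.28) truncated to [25, 35], sex ~ Bernoulli(0.638)
  (female = 1) — a middle-aged, mostly female cohort with
  overweight/obesity.
- **Latent factors**: default 5, independent standard normals per subject.
- **Metabolite blocks**: 226 fecal and 378 plasma features; per factor,
  `max(2, round(0.03 · m))` features (disjoint across factors) load with
  magnitude U(0.7, 1.3) and random sign; residual noise SD 0.3. With these
  values a loaded feature correlates with its factor at roughly 0.95 while
  unloaded features are pure noise — strong but not degenerate planted
  structure.
- **Genus counts**: logistic-normal–multinomial. 180 genera, of which 151
  "core" genera get baselines ~ Normal(0, 1) on the log scale (prevalent in
  essentially every subject) and 29 rare genera get baselines ~
  Normal(−8, 0.25) (expected in < 5 of 47 subjects); factor loadings live
  on core genera; each subject's counts are one multinomial draw of library
  size 10,000 from the softmax of the log-abundances — rows are exact
  compositions of nonnegative integers.
- **Missingness**: MCAR per feature. By default 23 fecal and 5 plasma
  features get rate 0.40 — chosen among features that carry no factor
  loading, so exclusion never deletes planted signal — and the rest get
  0.05/0.03. After injection the generator asserts that every feature's
  *empirical* missingness landed on the side of the 20% threshold its rate
  intends, regenerating with an incremented seed otherwise; the analogous
  guarantee holds for genus prevalence. The preprocessing counts
  (226→203 fecal, 378→373 plasma, 180→151 genera) are therefore invariants
  of the default configuration, not properties of one lucky seed.
- **Outcomes**: the 10-column cardiometabolic panel, each outcome =
  population mean + Σ_h γ_h·factor_h + covariate effects + Normal noise
  with the panel's observed SD. Default γ: factor 1 → cholesterol and LDL,
  factor 5 → cholesterol, VLDL and triglycerides; other outcomes are null.

What the generator does **not** emulate: metabolite–metabolite covariance
beyond the factor model, informative (non-MCAR) missingness,
detection-limit censoring, sequencing batch effects, overdispersion beyond
the logistic-normal, or any dietary-intervention structure. Passing the
planted-recovery tests therefore shows the pipeline recovers factor-driven
cross-block structure under compositional counts, missingness and noise —
not that it is robust to every pathology of real cohort data.

## Problem sizes used in validation

Unit tests run on blocks of ≤ 30 features. The end-to-end recovery check
uses 200 subjects, the full-width default panels, noise SD 0.3, keep-counts
equal to the per-factor loading counts, and no missingness (random-forest
imputation of ~580 features is minutes of compute and orthogonal to what
that check measures; imputation is validated separately on small blocks,
where a masked value of a perfectly correlated feature pair is recovered
within 10%). The type-I-error simulation uses 1000 null replicates at
n = 200. Full-scale imputation of the default 47-subject cohort (203 + 373
features) takes a few minutes per block and is exercised in the examples,
not the test suite.

## Known limitations

- The SGCCA objective is non-convex; multi-start ascent gives no global
  guarantee beyond the enumerable cases where it is tested.
- Connected components are a deliberately simple clustering; a single
  spurious edge above the cutoff merges two clusters. The cutoff (0.6) is
  the only defense, and cluster counts should be read alongside the edge
  list.
- P-values assume homoskedastic Gaussian errors; at n = 47 the FDR
  adjustment is over a family of only 10 tests per score.
- The bisector-variate similarity is a model-based reconstruction of
  feature relations, not the empirical feature–feature correlation; its
  values depend on the number of components kept.
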