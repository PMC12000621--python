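# Methods

## Model overview

`coregmap` treats a bulk expression cohort as observations of a latent
regulatory layer: each regulator (TF/co-TF) has a per-sample activity,
and each target gene is driven up by a small set of co-activators and
down by a small set of co-inhibitors. The package's job is (i) to
recover those per-target programs from expression alone, (ii) to turn
the recovered network into per-sample regulator activity estimates
("influence"), and (iii) to organize samples in influence space —
clustering, embedding, classification of new cohorts, and per-class
marker discovery.

## Program inference

**Discretization.** Each gene is ternarized against its own
distribution: +1 at or above `center + threshold_sd·sd`, −1 at or below
the mirror cut, 0 in between. Defaults: median center, `threshold_sd =
1`, sample sd (ddof = 1). The rule is location/scale free per gene, so
it is invariant to per-gene additive shifts; genes whose non-zero
fraction falls below `min_gene_support = 0.1` are dropped. Rows that are
numerically constant (sd below a relative 1e-12 tolerance) discretize to
all zeros, and missing cells discretize to 0.

**Co-regulator mining.** Candidate co-activator sets are regulator sets
simultaneously +1 in at least `min_support = 0.1` of samples (mirror
for co-inhibitors at −1), up to `max_set_size = 4` members. Because the
unanimity condition is anti-monotone, a levelwise Apriori search is
exhaustive; it is implemented in-package on boolean indicator arrays
(the output is oracle-checked against brute-force subset enumeration in
the tests). Mining joint over-expression is the reason the model can
only discover co-activator complexes that are actually co-active in a
fraction of samples — a co-regulation assumption, not an implementation
accident.

**Rule scoring.** The collective state of a set in a sample is +1/−1
when *all* members agree, else 0. A program (A, I) predicts the target
state as −1 whenever s(I) = +1 (inhibition dominant), otherwise s(A).
The rule score is the fraction of samples with non-zero target state
where the prediction matches; zero-state samples are uninformative for a
ternary rule and are excluded. All admissible pairs (disjoint, not both
empty, target excluded) are ranked; the top `num_candidates = 2000` go
to regression. The pool is deliberately deep: on realistic instances
the truth's rule-score rank can sit in the hundreds to low thousands
among ~10⁴ admissible pairs, and the regression stage — not the ternary
rule — is what separates it from near-misses. A closed-form batched R²
(precomputed covariate second moments; the two-covariate R² follows
from the centered Gram entries) keeps the deep pool cheap; the plain
`lstsq` scorer is kept as the reference implementation and the two are
asserted equal in tests.

**Regression and selection.** Each candidate is scored by the R² of
`target ~ 1 + meanExpr(A) + meanExpr(I)` (a covariate omitted when its
set is empty; degenerate fits — under 3 samples, constant target or
covariate — score 0). The top 10 candidates per target by R² are
retained; the final program maximizes the merged score
`(w_r2·R² + w_reg·f_reg + w_coop·f_coop)/Σw`, where `f_reg` is the
fraction of the program's regulator→target edges present in a
regulation-evidence table and `f_coop` the fraction of within-set
regulator pairs present in a cooperation-evidence table (defined as 1
when a program has no within-set pair). A weight is dropped when its
evidence table is absent or empty, so evidence-free selection reduces to
argmax R². Ties break by R², then rule score, then program size, then
lexicographic members. The rule score is in the tie chain for a
structural reason: a program and its sign mirror (A and I swapped) have
*identical* OLS R² — the regression has free coefficients, so the
design is symmetric — and only the ternary rule semantics distinguish
activation from repression in that case.

## Cooperativity network

Each regulator's regulon is the union of targets it activates or
represses in the selected programs. A pair is connected when it shares
at least `min_shared = 5` targets and the overlap is significant at
`alpha = 0.01` under a one-sided hypergeometric test whose universe is
the set of distinct targets in the network; the edge weight is the
Jaccard coefficient of the two regulons. Raw p-values are used by
default (the `alpha` cut mirrors a fixed significance convention); no
multiple-testing correction is applied, and the threshold is exposed.
Edges can be annotated against evidence tables with the precedence
protein–protein cooperation > directed regulation > inferred-only.

## Influence

The influence of regulator *r* in one sample is the Welch two-sample
*t* statistic contrasting the expression of its activated targets
against its repressed targets (sample variances, ddof = 1). Positive
influence means the regulator's program is engaged as the network
expects. Because the statistic is a *within-sample* contrast of two
gene sets, any sample-wide shift cancels exactly, and per-gene cohort
offsets enter only through set means (attenuated by set size) — the
mechanism behind the batch-robustness of influence space.

Practical rules: influence is computed only when both sides have at
least `min_genes = 5` members; a smaller side is padded with the
targets for which the regulator has the highest R² among the retained
top-10 candidate programs; regulators that still fall short are flagged
and excluded from direct computation. If a cell is incomputable (e.g.
all of one side missing in one sample), it takes the median of the
regulator's computed influences and is flagged `median-fallback`; a
regulator with no computable cell is dropped with a warning. When both
variances are zero the statistic is undefined; equal means give 0 and
unequal means a signed cap of ±1e6 to keep downstream numerics finite.

Missing regulon genes can be imputed from a reference expression
matrix: the missing gene's values are transferred from the
reference gene with the highest absolute correlation to it that is
present in the query, re-standardized to the missing gene's reference
location and scale (sign-corrected). This is a deliberately simple
nearest-correlated-gene transfer; it preserves the pipeline contract
when query platforms lack genes, not a latent-variable reconstruction.

## Reference map

Influences are z-scored per regulator (clipped at ±10; constant rows
map to 0), reduced with full-SVD PCA (20 components by default —
deterministic, scikit-learn sign convention), and connected in a shared
nearest-neighbor graph: neighborhoods are the k = 20 nearest samples
(Euclidean in PC space, self included), edge weights are neighborhood
Jaccard overlaps, and edges at or below `prune = 1/15` are removed.
Clusters come from the Leiden algorithm at resolution 0.8 (seeded;
Leiden is used as the modularity-family optimizer and guarantees
connected clusters). The 2-D view is UMAP (n_neighbors = 30, min_dist
= 0.3, seeded, hence single-threaded layout). Scaling parameters, the
PCA basis, reference scores, labels, and the embedding are frozen in a
bundle that serializes to a directory of TSVs plus a JSON manifest
(fitted UMAP/classifier objects are pickled alongside when kept).
Cluster quality is reported as per-class mean silhouette (Euclidean on
PC scores; singleton classes score 0) and the modularity of the
partition.

## Query mapping

Queries are pushed through the *reference* network, scaling, and PCA —
never re-fit — so train and test live in one space. Classification uses
a one-vs-rest RBF SVM; posteriors come from sigmoid (Platt) calibration
with a deterministic internal cross-validation, normalized across the
per-class estimators, and a call is *confident* above 0.75. Training
sorts samples by identifier first, so the model is invariant to input
ordering. Embedding coordinates are the 1/(d+1e-8)-weighted average of
the `k_project = 10` nearest reference samples' coordinates (Euclidean
in PC space); with k = 1 this is exactly the nearest sample's position,
and a query equal to a reference sample reproduces its embedding. A
transform through the fitted UMAP model is available when the model is
kept in the bundle; the explicit weighted-neighbor rule is the default
because it is directly checkable against hand-computed cases.

## Markers and dependencies

Differentially influencing regulators are found per (regulator, class)
with a two-sided one-vs-rest Wilcoxon rank-sum test. Because influence
is signed and roughly t-scaled, a log-fold-change is ill-defined; the
effect size is the difference of class means with threshold 0.20, and
"detected" means |influence| > 0.25 (both exposed). Records need
detection fraction ≥ 0.25 in-class and Bonferroni-adjusted p < 0.05;
the Bonferroni factor is global (regulators × classes tested) by
default, per-class optionally. Classes under 3 samples are skipped with
a warning. CERES dependency tables are contrasted in-class vs rest per
regulator with the same test; a regulator is flagged essential for a
class when its in-class mean CERES is strictly below the viability
threshold (−0.5 by default; CERES is negative when knockout reduces
viability).

## Synthetic data

The generator plants exactly the structure the model assumes, so every
pipeline stage has checkable ground truth:

- regulators are assigned round-robin to `n_classes = 3` modules; a
  regulator's latent activity is Normal(mean, 1) with mean
  `+class_effect` in its own class, `−class_effect` in the next class,
  and 0 elsewhere (`class_effect = 3`, chosen so that joint
  over-expression of a planted pair clears the default mining support);
- within each module, regulators are partitioned into recurring
  co-activator groups of size `activators_per_target` (regulatory
  complexes); each target adopts one group of its class as activators
  and draws inhibitors from the other modules. Recurring groups are
  what concentrates shared targets onto planted pairs — fully random
  per-target draws would spread overlaps so thin that no pair could
  pass the ≥5-shared + p<0.01 edge rule even in principle;
- regulator expression = activity + Normal(0, σ²); target expression =
  mean activator activity − mean inhibitor activity + Normal(0, σ²)
  (σ = 0.25 default; σ = 0 gives exact closed forms used in tests);
- optional per-gene additive batch offsets ~ Normal(0, 2²), shared by
  all samples of a batch, with samples split across batches evenly
  within each class so class and batch are not confounded.

Everything flows from one seeded generator: equal seeds give bitwise
identical outputs.

What the generator does **not** emulate: count noise and library-size
effects, platform-specific intensity distributions, correlated
measurement error, tumor purity/microenvironment mixtures, regulator
post-translational control (activity is assumed visible in expression),
and overlapping or hierarchical programs. Passing the planted-recovery
benchmarks therefore shows the pipeline is correct and well-conditioned
under its own model assumptions — not that real cohorts, where those
assumptions are degraded, will reach the same accuracies.

## Benchmarks and problem sizes

The test suite and `scripts/acceptance.py` run at desk scale, chosen as
the package's own benchmark sizes: program recovery on 20 regulators ×
200 targets × 120 samples (mean per-target F1 against the planted
regulator sets, at σ = 0 and σ = 0.25, plus cooperative-edge precision
and recall against the network built from the planted programs); batch
attenuation and cross-batch classification on ten seeded two-batch
cohorts; map recovery and confident self-mapping on a 150-sample
three-class cohort; marker recovery with five regulators shifted +3σ in
their class (50 samples per class). Statistical primitives are compared
with independent oracles: the Welch statistic against
`scipy.stats.ttest_ind(equal_var=False)` over 1000 random draws, the
overlap p-value against an exact `math.comb` tail sum for all
configurations with universe ≤ 25, and itemset mining against
brute-force subset enumeration on 50 random ternary instances.
Determinism is asserted byte-for-byte on the files written by two
identically seeded end-to-end runs.

## Numerical choices and degenerate inputs

- Ties everywhere break by score (desc), then program size (asc), then
  lexicographic member order — all orderings are total, making the
  pipeline deterministic for fixed inputs and seeds.
- Discretization uses ≥/≤ at the cut (boundary values are called).
- R² is clipped to [0, 1]; near-collinear two-covariate designs fall
  back to the better single-covariate R².
- The two-sided rank-sum test uses scipy's exact method for small
  tie-free groups, the normal approximation otherwise.
- Duplicate gene rows on input are collapsed by mean (logged);
  duplicate sample identifiers are an error; `NA` cells are missing,
  never zero.

## Known limitations

- Programs are single (A, I) pairs per target; alternative or
  condition-specific programs for one gene are not represented.
- The regression stage is linear in set means; strongly sub-additive or
  saturating regulation will be mis-scored.
- The hypergeometric edge test treats targets as exchangeable; in real
  networks target overlap is structured, so edge p-values are
  optimistic and the 0.01 cut is a convention, not an error rate.
- Influence requires ≥ 5 targets per side even after padding; sparse
  regulators are dropped rather than estimated.
- Query mapping assumes the query platform shares most regulon genes
  with the reference; the correlated-gene imputation helps with
  scattered gaps, not with wholesale platform mismatch.
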