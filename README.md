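# coregmap

Co-regulatory network inference, per-sample regulator influence, and
supervised reference mapping for bulk gene-expression cohorts.

## The problem

Bulk tumor transcriptomes mix technical batch effects, microenvironment
signal, and the actual regulatory state of the tumor cells. A robust way
to compare samples across cohorts is to move from gene space to
*regulator activity* space: infer once which target genes each
transcription factor (TF/co-TF) activates or represses, then score every
sample by how strongly each regulator's program is engaged. Activity
estimates computed as a within-sample contrast between gene sets largely
cancel per-cohort shifts, which makes multi-cohort "metacohort" maps and
cross-platform classification practical. `coregmap` implements that
workflow end to end for anyone with a gene × sample expression matrix
(log-scale microarray or log-CPM RNA-seq) and a list of candidate
regulators.

## The method

1. **Program inference** (`coregmap.grn`). Expression is ternarized per
   gene (−1/0/+1 at ±*t*·sd around the median). A frequent-itemset
   (Apriori) search over the regulator rows enumerates candidate
   co-activator sets (jointly +1) and co-inhibitor sets (jointly −1).
   For each target gene every admissible pair (A, I) is scored by an
   association rule — the fraction of non-zero target samples where the
   unanimity state of A and I predicts the target's state (inhibition
   dominant) — the best candidates are re-scored by the R² of
   `target ~ meanExpr(A) + meanExpr(I)`, and the final program maximizes
   a merged score that can fold in external regulation/cooperation
   evidence.
2. **Cooperativity network** (`coregmap.cooperativity`). Regulators
   *i, j* are linked when their regulons share ≥ 5 targets and the
   overlap is hypergeometrically significant (p < 0.01); edge strength
   is the Jaccard coefficient |Tᵢ∩Tⱼ| / |Tᵢ∪Tⱼ|.
3. **Influence** (`coregmap.influence`). The activity of regulator *r*
   in a sample is the Welch *t* statistic contrasting its activated
   targets A^r against its repressed targets I^r:

   Influence(r) = (mean E(A^r) − mean E(I^r)) / √(s²_A/|A^r| + s²_I/|I^r|),

   computed only when both sides carry ≥ 5 targets (small sides are
   padded by best regression R²; incomputable cells take the regulator's
   median influence).
4. **Reference map** (`coregmap.reference_map`). Influences are
   z-scaled, reduced to 20 PCs, clustered with Leiden on a shared
   nearest-neighbor graph (resolution 0.8), and embedded in 2-D with
   UMAP. All transformation state is frozen in a reusable bundle.
5. **Query mapping** (`coregmap.query_map`). New cohorts are pushed
   through the same network, scaling and PCA, classified with a
   one-vs-rest RBF SVM (a call is *confident* when the posterior
   exceeds 0.75), and placed on the embedding by distance-weighted
   nearest reference neighbors.
6. **Markers** (`coregmap.markers`). Per-class differentially
   influencing regulators (one-vs-rest Wilcoxon rank-sum, detection
   fraction ≥ 0.25, |Δmean| ≥ 0.20, Bonferroni-adjusted p < 0.05), with
   optional cross-referencing against CRISPR CERES dependency screens.

A fully seeded synthetic generator (`coregmap.synthetic`) plants
class-structured regulator activities, co-activator complexes, Gaussian
noise, and per-gene batch offsets, so the whole pipeline is testable
without any external download.

## Worked example

```python
from coregmap import (
    generate_grn, simulate_expression, infer_grn, build_coregnet,
    build_regulon_splits, influence_matrix, build_reference_map,
    train_classifier, map_query,
)

truth = generate_grn(n_regulators=12, n_targets=60, seed=0)
expr, classes, _ = simulate_expression(truth, n_samples_per_class=40, sigma=0.25, seed=1)

grn = infer_grn(expr, truth.regulators)
net = build_coregnet(grn)
infl = influence_matrix(expr, build_regulon_splits(grn))
bundle = build_reference_map(infl.values, seed=2)
bundle.classifier = train_classifier(infl, classes, seed=2, scaling=bundle.scaling)
print(f"programs: {len(grn)}  cooperative edges: {len(net.edges)}  "
      f"map clusters: {bundle.labels.nunique()}  modularity: {bundle.modularity:.3f}")

qexpr, qlab, _ = simulate_expression(truth, n_samples_per_class=3, sigma=0.25, seed=3)
res = map_query(qexpr[qlab.index[qlab == "C1"]], grn, bundle)
print(res[["predicted_class", "probability", "confident"]].round(3))
```

prints

```
programs: 60  cooperative edges: 6  map clusters: 3  modularity: 0.666
        predicted_class  probability  confident
C1_S000              C1        0.980       True
C1_S001              C1        0.954       True
C1_S002              C1        0.978       True
```

All 60 inferred programs match the planted truth exactly, the six
planted co-activator complexes surface as the cooperativity edges, the
three planted classes reappear as the three map clusters, and three
fresh replicates of class C1 are all confidently assigned back to C1.

## Command line

Every stage is also a subcommand (`coregmap simulate | infer-grn |
coregnet | influence | build-map | query | markers`), reading and
writing TSV/GraphML and sharing a YAML config:

```sh
coregmap simulate --out sim/ --seed 7
coregmap infer-grn --expr sim/expression.tsv --regulators sim/regulators.txt --out grn.tsv
coregmap coregnet --grn grn.tsv --out net.graphml
coregmap influence --expr sim/expression.tsv --grn grn.tsv --out infl.tsv
coregmap build-map --influence infl.tsv --out refmap/ --seed 7
coregmap query --expr sim/expression.tsv --grn grn.tsv --refmap refmap/ --out mapped.tsv
coregmap markers --influence infl.tsv --labels sim/labels.tsv --out markers/
```

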