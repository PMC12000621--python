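"""Supervised mapping of query cohorts onto a reference map.

A query expression matrix is pushed through the reference network
(influence computation), the frozen reference scaling and PCA, a
one-vs-rest RBF support-vector classifier trained on the reference
influences, and a nearest-reference-neighbor projection onto the
reference 2-D embedding. A sample is called *confident* when its
posterior class probability exceeds 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .influence import build_regulon_splits, influence_matrix
from .reference_map import ReferenceMapBundle

__all__ = ["ClassifierModel", "train_classifier", "classify", "project_query", "map_query"]

CONFIDENCE_THRESHOLD = 0.75


@dataclass
class ClassifierModel:
    """One-vs-rest RBF SVM with calibrated posteriors."""

    estimator: OneVsRestClassifier
    feature_order: list  # regulators, fixed at training
    classes: list

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.feature_order if f not in X.columns]
        if missing:
            raise ValueError(f"query is missing regulators: {missing[:10]}")
        proba = self.estimator.predict_proba(X[self.feature_order].to_numpy())
        return pd.DataFrame(proba, index=X.index, columns=self.classes)


def train_classifier(infl, labels, seed: int = 0, scaling=None) -> ClassifierModel:
    """Train the one-vs-rest RBF SVM on (scaled) influences.

    ``infl`` is regulators × samples (an :class:`InfluenceMatrix` or
    plain DataFrame); ``labels`` maps each sample to its class. When a
    reference :class:`ScalingParams` is given, it is applied first so
    query samples can be scaled identically. Per-class probabilities
    come from Platt scaling with a seed-fixed internal CV, normalized
    across the one-vs-rest estimators to sum to 1.
    """
    if hasattr(infl, "provenance"):  # InfluenceMatrix
        values = infl.values
    elif isinstance(infl, pd.DataFrame):
        values = infl
    else:
        raise TypeError("infl must be an InfluenceMatrix or a DataFrame")
    X = (scaling.apply(values) if scaling is not None else values).T  # samples × regs
    y = pd.Series(labels).reindex(X.index)
    if y.isna().any():
        raise ValueError("every sample needs a class label")
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"classes with fewer than 5 samples: {small}")
    # per-class RBF SVM, sigmoid-calibrated with a deterministic internal CV
    est = OneVsRestClassifier(
        CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), ensemble=False)
    )
    # fixed sample order for determinism regardless of input ordering
    order = np.argsort(X.index.to_numpy())
    est.fit(X.to_numpy()[order], y.to_numpy()[order])
    return ClassifierModel(
        estimator=est, feature_order=list(X.columns), classes=list(est.classes_)
    )


def classify(model: ClassifierModel, query_infl: pd.DataFrame) -> pd.DataFrame:
    """Assign each query sample its argmax-probability class.

    ``query_infl`` is regulators × samples on the same scale the model
    was trained on. Returns a frame with ``predicted_class``,
    ``probability`` and ``confident`` (probability > 0.75).
    """
    proba = model.predict_proba(query_infl.T)
    best = proba.to_numpy().argmax(axis=1)
    prob = proba.to_numpy()[np.arange(len(best)), best]
    return pd.DataFrame(
        {
            "predicted_class": [model.classes[i] for i in best],
            "probability": prob,
            "confident": prob > CONFIDENCE_THRESHOLD,
        },
        index=proba.index,
    )


def project_query(bundle: ReferenceMapBundle, query_scores: pd.DataFrame, k_project: int = 10):
    """Place query samples on the reference embedding.

    Coordinates are the 1/(d+ε) weighted average of the ``k_project``
    nearest reference samples' embedded coordinates (Euclidean distance
    in the shared PCA space, ε = 1e-8). Returns ``(coords, neighbors)``
    where ``neighbors`` lists (reference id, distance) pairs per query.
    """
    if bundle.scores.shape[0] == 0:
        raise ValueError("reference bundle contains no samples")
    k = min(k_project, bundle.scores.shape[0])
    if k < 1:
        raise ValueError("k_project must be >= 1")
    ref = bundle.scores.to_numpy(dtype=float)
    q = query_scores[bundle.scores.columns].to_numpy(dtype=float)
    d2 = ((q[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(d2)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    emb = bundle.embedding.to_numpy(dtype=float)
    coords, neighbors = [], []
    for row, nbr in enumerate(order):
        d = dist[row, nbr]
        w = 1.0 / (d + 1e-8)
        w = w / w.sum()
        coords.append(w @ emb[nbr])
        neighbors.append([(bundle.embedding.index[j], float(dist[row, j])) for j in nbr])
    coords = pd.DataFrame(coords, index=query_scores.index, columns=["UMAP1", "UMAP2"])
    return coords, neighbors


def map_query(
    expr_query: pd.DataFrame,
    grn,
    bundle: ReferenceMapBundle,
    model: ClassifierModel | None = None,
    reference_expr: pd.DataFrame | None = None,
    min_genes: int = 5,
    k_project: int = 10,
) -> pd.DataFrame:
    """Full query pipeline: influence → scale → PCA → classify → project.

    Returns one row per query sample: predicted class, posterior
    probability, confidence flag, embedding coordinates, and the
    nearest reference neighbors with distances.
    """
    if expr_query.size == 0:
        raise ValueError("query expression matrix is empty")
    model = model or bundle.classifier
    if model is None:
        raise ValueError("no classifier: pass one or attach it to the bundle")
    try:
        splits = build_regulon_splits(grn, min_genes=min_genes)
        infl = influence_matrix(expr_query, splits, reference=reference_expr)
    except ValueError as err:
        raise ValueError(f"influence stage failed: {err}") from err
    try:
        scaled = bundle.scaling.apply(infl.values)
    except ValueError as err:
        raise ValueError(f"scaling stage failed: {err}") from err
    scores = bundle.pca.transform(scaled)
    result = classify(model, scaled)
    coords, neighbors = project_query(bundle, scores, k_project=k_project)
    result = result.join(coords)
    result["neighbors"] = [
        ";".join(f"{name}:{d:.6g}" for name, d in nb) for nb in neighbors
    ]
    return result
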