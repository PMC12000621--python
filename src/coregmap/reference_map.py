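"""Clustered low-dimensional reference map of sample heterogeneity.

From an influence matrix (regulators × samples) the map is built as:
per-regulator z-scaling with clipping → PCA (default 20 components) →
shared-nearest-neighbor (SNN) graph on the PCA scores → Leiden
modularity clustering at a resolution parameter → 2-D UMAP embedding.
All scaling/PCA/embedding state is frozen in a
:class:`ReferenceMapBundle` so query cohorts can be pushed through the
identical transformation later.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ScalingParams",
    "PcaModel",
    "ClusterDiagnostics",
    "ReferenceMapBundle",
    "scale_features",
    "fit_pca",
    "snn_graph",
    "cluster_graph",
    "fit_umap",
    "silhouette_by_class",
    "build_reference_map",
]


@dataclass
class ScalingParams:
    center: pd.Series  # per-regulator mean
    scale: pd.Series  # per-regulator sd (0 for constant rows)
    clip: float = 10.0

    def apply(self, infl: pd.DataFrame) -> pd.DataFrame:
        """Re-apply the frozen transformation (rows = regulators)."""
        missing = [r for r in self.center.index if r not in infl.index]
        if missing:
            raise ValueError(f"missing regulators in input: {missing[:5]}")
        sub = infl.loc[self.center.index]
        denom = self.scale.replace(0.0, np.inf)
        z = sub.sub(self.center, axis=0).div(denom, axis=0)
        return z.clip(-self.clip, self.clip)


def scale_features(infl: pd.DataFrame, clip: float = 10.0):
    """Z-score each regulator across samples, clipping extremes.

    Constant regulators scale to all zeros. Returns the scaled matrix
    and the parameters needed to re-apply the identical transform.
    """
    if infl.shape[1] < 2:
        raise ValueError("need at least 2 samples to scale")
    center = infl.mean(axis=1)
    scale = infl.std(axis=1, ddof=1)
    # numerically constant rows: force scale 0 so they map to all zeros
    tol = 1e-12 * np.maximum(1.0, center.abs())
    scale[scale < tol] = 0.0
    params = ScalingParams(center=center, scale=scale, clip=float(clip))
    return params.apply(infl), params


@dataclass
class PcaModel:
    mean: pd.Series  # per-feature (regulator) mean over samples
    components: pd.DataFrame  # features × components
    explained_variance: np.ndarray

    def transform(self, scaled: pd.DataFrame) -> pd.DataFrame:
        """Project samples (columns of a regulator × sample frame)."""
        X = scaled.loc[self.mean.index].T.to_numpy(dtype=float)  # samples × features
        scores = (X - self.mean.to_numpy()) @ self.components.to_numpy()
        return pd.DataFrame(scores, index=scaled.columns, columns=self.components.columns)


def fit_pca(scaled: pd.DataFrame, n_components: int = 20, seed: int = 0):
    """PCA on samples (columns) in regulator feature space.

    Uses the full SVD solver, so results are deterministic; component
    signs are fixed by scikit-learn's sign convention. Returns the
    model and the sample scores (samples × components).
    """
    X = scaled.T.to_numpy(dtype=float)  # samples × features
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    cols = [f"PC{i+1}" for i in range(n_components)]
    model = PcaModel(
        mean=pd.Series(pca.mean_, index=scaled.index),
        components=pd.DataFrame(pca.components_.T, index=scaled.index, columns=cols),
        explained_variance=pca.explained_variance_,
    )
    return model, pd.DataFrame(scores, index=scaled.columns, columns=cols)


def snn_graph(scores: pd.DataFrame, k: int = 20, prune: float = 1 / 15) -> igraph.Graph:
    """Shared-nearest-neighbor graph on sample scores.

    Each sample's neighborhood is its k nearest samples (Euclidean,
    self included). Edge weight between two samples is the Jaccard
    overlap of their neighborhoods; edges with weight ≤ ``prune`` are
    dropped.
    """
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    X = scores.to_numpy()
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    idx = nn.kneighbors(X, return_distance=False)  # self is its own nearest neighbor
    member = np.zeros((n, n), dtype=bool)
    member[np.arange(n)[:, None], idx] = True
    member[np.arange(n), np.arange(n)] = True  # self always included
    inter = (member.astype(np.int32) @ member.T.astype(np.int32)).astype(float)
    sizes = member.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    w = inter / union
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if inter[i, j] > 0 and w[i, j] > prune:
                edges.append((i, j))
                weights.append(w[i, j])
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    g.vs["name"] = list(scores.index)
    return g


def cluster_graph(graph: igraph.Graph, resolution: float = 0.8, seed: int = 0):
    """Leiden modularity clustering at the given resolution.

    Returns ``(labels, modularity)``; labels are contiguous integers in
    vertex order and the modularity is evaluated on the weighted graph
    at resolution 1 (the standard definition).
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    modularity = graph.modularity(labels, weights=weights)
    return labels, float(modularity)


def fit_umap(scores: pd.DataFrame, n_neighbors: int = 30, min_dist: float = 0.3, seed: int = 0):
    """2-D UMAP of the sample scores with a reusable fitted model.

    ``random_state`` pins the layout, so identical seeds reproduce
    identical coordinates.
    """
    import umap  # deferred: heavy import

    if scores.shape[0] < n_neighbors + 1:
        raise ValueError("too few samples for the requested n_neighbors")
    model = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, n_components=2, random_state=seed
    )
    coords = np.asarray(model.fit_transform(scores.to_numpy()), dtype=np.float64)
    return pd.DataFrame(coords, index=scores.index, columns=["UMAP1", "UMAP2"]), model


@dataclass
class ClusterDiagnostics:
    per_class_silhouette: dict
    per_class_size: dict
    modularity: float | None = None

    @property
    def mean_silhouette(self) -> float:
        sizes = self.per_class_size
        total = sum(sizes.values())
        return sum(self.per_class_silhouette[c] * sizes[c] for c in sizes) / total


def silhouette_by_class(scores: pd.DataFrame, labels) -> ClusterDiagnostics:
    """Euclidean silhouette averaged per class; singletons score 0."""
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 classes for silhouettes")
    sil = silhouette_samples(scores.to_numpy(), labels)
    per_sil, per_size = {}, {}
    for c in uniq:
        mask = labels == c
        per_size[c] = int(mask.sum())
        per_sil[c] = 0.0 if per_size[c] == 1 else float(sil[mask].mean())
    return ClusterDiagnostics(per_class_silhouette=per_sil, per_class_size=per_size)


@dataclass
class ReferenceMapBundle:
    """Frozen reference map: everything needed to place new samples."""

    scaling: ScalingParams
    pca: PcaModel
    scores: pd.DataFrame  # reference samples × PCs
    labels: pd.Series  # cluster label per reference sample
    embedding: pd.DataFrame  # reference samples × (UMAP1, UMAP2)
    snn_k: int
    snn_prune: float
    resolution: float
    modularity: float
    seed: int
    umap_model: object | None = None
    classifier: object | None = None  # attached by query_map.train_classifier

    def save(self, path) -> None:
        """Serialize to a directory (TSVs + manifest; models pickled)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        scaling = pd.DataFrame({"center": self.scaling.center, "scale": self.scaling.scale})
        scaling.to_csv(path / "scaling.tsv", sep="\t")
        pca = self.pca.components.copy()
        pca.insert(0, "mean", self.pca.mean)
        pca.to_csv(path / "pca.tsv", sep="\t")
        self.scores.to_csv(path / "scores.tsv", sep="\t")
        self.labels.rename("label").to_frame().to_csv(path / "labels.tsv", sep="\t")
        self.embedding.to_csv(path / "embedding.tsv", sep="\t")
        manifest = {
            "clip": self.scaling.clip,
            "explained_variance": [float(v) for v in self.pca.explained_variance],
            "snn_k": self.snn_k,
            "snn_prune": self.snn_prune,
            "resolution": self.resolution,
            "modularity": self.modularity,
            "seed": self.seed,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for name, obj in (("umap_model.pkl", self.umap_model), ("classifier.pkl", self.classifier)):
            if obj is not None:
                with open(path / name, "wb") as fh:
                    pickle.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "ReferenceMapBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        scaling_df = pd.read_csv(path / "scaling.tsv", sep="\t", index_col=0)
        scaling = ScalingParams(
            center=scaling_df["center"], scale=scaling_df["scale"], clip=manifest["clip"]
        )
        pca_df = pd.read_csv(path / "pca.tsv", sep="\t", index_col=0)
        pca = PcaModel(
            mean=pca_df["mean"],
            components=pca_df.drop(columns="mean"),
            explained_variance=np.asarray(manifest["explained_variance"]),
        )
        scores = pd.read_csv(path / "scores.tsv", sep="\t", index_col=0)
        labels = pd.read_csv(path / "labels.tsv", sep="\t", index_col=0)["label"]
        embedding = pd.read_csv(path / "embedding.tsv", sep="\t", index_col=0)
        models = {}
        for key, name in (("umap_model", "umap_model.pkl"), ("classifier", "classifier.pkl")):
            f = path / name
            if f.exists():
                with open(f, "rb") as fh:
                    models[key] = pickle.load(fh)
        return cls(
            scaling=scaling,
            pca=pca,
            scores=scores,
            labels=labels,
            embedding=embedding,
            snn_k=manifest["snn_k"],
            snn_prune=manifest["snn_prune"],
            resolution=manifest["resolution"],
            modularity=manifest["modularity"],
            seed=manifest["seed"],
            umap_model=models.get("umap_model"),
            classifier=models.get("classifier"),
        )


def build_reference_map(
    infl: pd.DataFrame,
    n_components: int = 20,
    snn_k: int = 20,
    snn_prune: float = 1 / 15,
    resolution: float = 0.8,
    umap_neighbors: int = 30,
    umap_min_dist: float = 0.3,
    clip: float = 10.0,
    seed: int = 0,
    keep_umap_model: bool = True,
) -> ReferenceMapBundle:
    """Scale → PCA → SNN → Leiden → UMAP, frozen into a bundle."""
    scaled, scaling = scale_features(infl, clip=clip)
    n_components = min(n_components, scaled.shape[0], scaled.shape[1])
    pca_model, scores = fit_pca(scaled, n_components=n_components, seed=seed)
    k = min(snn_k, scores.shape[0] - 1)
    graph = snn_graph(scores, k=k, prune=snn_prune)
    labels, modularity = cluster_graph(graph, resolution=resolution, seed=seed)
    nb = min(umap_neighbors, scores.shape[0] - 1)
    embedding, umap_model = fit_umap(scores, n_neighbors=nb, min_dist=umap_min_dist, seed=seed)
    return ReferenceMapBundle(
        scaling=scaling,
        pca=pca_model,
        scores=scores,
        labels=pd.Series(labels, index=infl.columns, name="label"),
        embedding=embedding,
        snn_k=k,
        snn_prune=snn_prune,
        resolution=resolution,
        modularity=modularity,
        seed=seed,
        umap_model=umap_model if keep_umap_model else None,
    )
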