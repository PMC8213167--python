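"""Per-sample clustering, centroid meta-clustering and cell classification.

Clustering is algorithm-agnostic: a plugin is any callable
``(matrix, params, seed) -> integer labels`` (label ``-1`` marks unassigned
noise events).  Each sample is clustered independently; inter-sample
comparisons are made by *meta-clustering* the per-sample cluster centroids
(per-dimension medians, min-max scaled per dimension across samples before
meta-clustering).  Both per-sample clusters and meta-clusters can be
committed to a :class:`~autocyto.model.FileGroup` as Population documents,
so downstream feature extraction treats gated, clustered and classified
populations identically.

Supervised cell classification accepts any model with a scikit-learn style
``fit``/``predict`` API, reports stratified k-fold cross-validated weighted
F1 and a confusion matrix, and likewise emits Population documents.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.cluster import KMeans, AgglomerativeClustering
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

from .errors import ContractError, LabellingError, ParameterError, SchemaError
from .model import FileGroup, Population

__all__ = [
    "ClusterResult",
    "MetaClusterResult",
    "cluster_sample",
    "meta_cluster",
    "clusters_to_populations",
    "train_classifier",
    "register_clusterer",
    "get_clusterer",
]


# ---------------------------------------------------------------------------
# Plugin registry

_CLUSTERERS: Dict[str, Callable] = {}


def register_clusterer(name: str, fn: Callable) -> None:
    """Register a plugin ``fn(matrix, params, seed) -> integer labels``."""
    _CLUSTERERS[name] = fn


def get_clusterer(plugin: Union[str, Callable]) -> Callable:
    if callable(plugin):
        return plugin
    if plugin not in _CLUSTERERS:
        raise ParameterError(f"no clustering plugin registered under {plugin!r}")
    return _CLUSTERERS[plugin]


def _kmeans_plugin(matrix, params, seed):
    km = KMeans(n_clusters=int(params.get("n_clusters", 8)), n_init=10,
                random_state=seed)
    return km.fit_predict(matrix)


def _agglomerative_plugin(matrix, params, seed):
    model = AgglomerativeClustering(
        n_clusters=int(params.get("n_clusters", 8)),
        linkage=params.get("linkage", "ward"))
    return model.fit_predict(matrix)


def _single_cluster_plugin(matrix, params, seed):
    return np.zeros(np.asarray(matrix).shape[0], dtype=int)


register_clusterer("kmeans", _kmeans_plugin)
register_clusterer("agglomerative", _agglomerative_plugin)
register_clusterer("single", _single_cluster_plugin)


# ---------------------------------------------------------------------------
# Results


@dataclass
class ClusterResult:
    sample_id: object
    labels: np.ndarray              # per-event; -1 = unassigned
    centroids: np.ndarray           # cluster x dims (per-dim medians)
    cluster_ids: List[int]          # row order of ``centroids``
    dims: List[str]
    params: dict = field(default_factory=dict)
    seed: int = 42

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def proportions(self) -> Dict[int, float]:
        n = self.labels.size
        return {c: float((self.labels == c).sum()) / n for c in self.cluster_ids}


@dataclass
class MetaClusterResult:
    assignments: Dict[Tuple[object, int], int]   # (sample, cluster) -> meta id
    meta_centroids: np.ndarray
    meta_ids: List[int]
    dims: List[str]
    sample_proportions: Dict[object, Dict[int, float]]  # per-sample, per cluster

    def clusters_in_meta(self, meta_id: int) -> List[Tuple[object, int]]:
        return [sc for sc, m in self.assignments.items() if m == meta_id]


# ---------------------------------------------------------------------------
# Operations


def cluster_sample(data: np.ndarray, plugin: Union[str, Callable],
                   params: Optional[dict] = None, seed: int = 42,
                   sample_id: object = None,
                   dims: Optional[Sequence[str]] = None,
                   centroid_statistic: str = "median") -> ClusterResult:
    """Cluster one sample's events with a plugin and summarise centroids."""
    x = np.asarray(data, float)
    if x.ndim != 2:
        raise ParameterError("cluster_sample expects an (events x dims) matrix")
    params = dict(params or {})
    labels = np.asarray(get_clusterer(plugin)(x, params, seed))
    if labels.shape != (x.shape[0],):
        raise ContractError(
            f"plugin returned {labels.shape} labels for {x.shape[0]} events")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == labels.astype(int)):
            raise ContractError("plugin labels must be integers")
        labels = labels.astype(int)
    if labels.size and labels.min() < -1:
        raise ContractError("plugin labels must be >= -1")
    stat = np.median if centroid_statistic == "median" else np.mean
    cluster_ids = sorted(int(c) for c in np.unique(labels) if c != -1)
    centroids = np.array([stat(x[labels == c], axis=0) for c in cluster_ids]) \
        if cluster_ids else np.empty((0, x.shape[1]))
    return ClusterResult(sample_id, labels, centroids, cluster_ids,
                         list(dims or [str(j) for j in range(x.shape[1])]),
                         params, seed)


def meta_cluster(results: Sequence[ClusterResult],
                 plugin: Union[str, Callable] = "kmeans",
                 params: Optional[dict] = None, seed: int = 42
                 ) -> MetaClusterResult:
    """Cluster the stacked per-sample centroids to match populations across
    samples.

    Centroids are min-max scaled per dimension across all samples before the
    plugin runs; meta-centroids are the per-dimension medians of member
    centroids on the original scale.
    """
    if len(results) < 2:
        raise ParameterError("meta-clustering needs >= 2 samples")
    dims = results[0].dims
    for r in results[1:]:
        if r.dims != dims:
            raise SchemaError("all samples must share dimensions for "
                              "meta-clustering")
    keys = [(r.sample_id, c) for r in results for c in r.cluster_ids]
    stacked = np.vstack([r.centroids for r in results if r.n_clusters])
    if stacked.shape[0] < 2:
        raise ParameterError("need >= 2 centroids to meta-cluster")
    lo, hi = stacked.min(axis=0), stacked.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (stacked - lo) / span
    labels = np.asarray(get_clusterer(plugin)(scaled, dict(params or {}), seed))
    if labels.shape != (stacked.shape[0],):
        raise ContractError("meta-clustering plugin returned wrong label count")
    meta_ids = sorted(int(m) for m in np.unique(labels) if m != -1)
    meta_centroids = np.array([np.median(stacked[labels == m], axis=0)
                               for m in meta_ids]) \
        if meta_ids else np.empty((0, stacked.shape[1]))
    assignments = {k: int(m) for k, m in zip(keys, labels)}
    proportions = {r.sample_id: r.proportions() for r in results}
    return MetaClusterResult(assignments, meta_centroids, meta_ids, dims,
                             proportions)


def clusters_to_populations(fg: FileGroup,
                            result: Union[ClusterResult, MetaClusterResult],
                            parent: str = "root",
                            prefix: Optional[str] = None) -> FileGroup:
    """Commit clusters (or this sample's meta-clusters) as Population documents.

    Labels are indexed against the parent population's events.  Unassigned
    events (label -1) belong to no child.  Returns the updated FileGroup.
    """
    parent_pop = fg.populations.get(parent)
    if parent_pop is None:
        raise SchemaError(f"parent population {parent!r} not found")
    if isinstance(result, ClusterResult):
        if result.labels.size != parent_pop.n:
            raise ContractError(
                f"cluster labels ({result.labels.size}) misaligned with parent "
                f"events ({parent_pop.n})")
        prefix = prefix or "cluster"
        for c in result.cluster_ids:
            idx = parent_pop.index[result.labels == c]
            fg.add_population(Population(f"{prefix}_{c}", parent, idx,
                                         source="cluster"))
        return fg
    # MetaClusterResult: translate this sample's clusters through their meta id
    prefix = prefix or "meta"
    sample_clusters = {c: m for (sid, c), m in result.assignments.items()
                       if sid == fg.sample_id}
    if not sample_clusters:
        raise SchemaError(f"no meta-cluster assignments for sample "
                          f"{fg.sample_id!r}")
    base = None
    for name, pop in fg.populations.items():
        if pop.source == "cluster" and pop.parent == parent:
            base = base or {}
            base[int(name.rsplit("_", 1)[1])] = pop.index
    if base is None:
        raise SchemaError("commit per-sample clusters before meta-clusters")
    for m in sorted(set(sample_clusters.values())):
        members = [base[c] for c, mm in sample_clusters.items()
                   if mm == m and c in base]
        if not members:
            continue
        idx = np.unique(np.concatenate(members))
        fg.add_population(Population(f"{prefix}_{m}", parent, idx,
                                     source="cluster"))
    return fg


# ---------------------------------------------------------------------------
# Supervised classification


def _training_matrix(fg: FileGroup, label_populations: Sequence[str],
                     channels: Sequence[str]):
    seen = {}
    for name in label_populations:
        pop = fg.populations.get(name)
        if pop is None:
            raise SchemaError(f"training population {name!r} not found")
        for i in pop.index:
            if i in seen:
                raise LabellingError(
                    f"event {i} belongs to both {seen[i]!r} and {name!r}")
            seen[i] = name
    rows = np.array(sorted(seen), dtype=int)
    y = np.array([seen[i] for i in rows])
    cols = [fg.primary.column_index(c) for c in channels]
    return fg.primary.values[np.ix_(rows, cols)], y


def train_classifier(model, training: Sequence[Tuple[FileGroup, Sequence[str]]],
                     target: FileGroup, channels: Sequence[str],
                     parent: str = "root", n_splits: int = 5, seed: int = 42):
    """Train a fit/predict model on labelled populations and classify a sample.

    ``training`` is a sequence of ``(FileGroup, population names)`` whose
    populations provide non-overlapping event labels.  Returns
    ``(target FileGroup with classifier populations, metrics)`` where metrics
    holds the stratified k-fold cross-validated weighted F1 and the training
    confusion matrix.
    """
    xs, ys = [], []
    for fg, pops in training:
        x, y = _training_matrix(fg, pops, channels)
        xs.append(x)
        ys.append(y)
    X = np.vstack(xs)
    y = np.concatenate(ys)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise LabellingError("training data must contain >= 2 classes")

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        model.fit(X[tr], y[tr])
        scores.append(f1_score(y[te], model.predict(X[te]),
                               average="weighted", zero_division=0))
    model.fit(X, y)
    cm = confusion_matrix(y, model.predict(X), labels=classes)

    target_parent = target.populations.get(parent)
    if target_parent is None:
        raise SchemaError(f"parent population {parent!r} not found in target")
    cols = [target.primary.column_index(c) for c in channels]
    Xt = target.primary.values[np.ix_(target_parent.index, cols)]
    pred = model.predict(Xt)
    for cls in classes:
        idx = target_parent.index[pred == cls]
        target.add_population(Population(str(cls), parent, idx,
                                         source="classifier"))
    metrics = {
        "f1_weighted_cv": float(np.mean(scores)),
        "f1_weighted_cv_folds": [float(s) for s in scores],
        "confusion_matrix": cm,
        "classes": classes,
    }
    return target, metrics
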