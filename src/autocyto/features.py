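"""Population feature space and the endpoint feature-selection cascade.

The feature space is a subjects x features table: per-population summary
statistics (fraction of parent, fraction of root, event count — averaged
across classification methods where a population was derived by more than
one), joined with subject metadata covariates, and labelled with a
per-subject endpoint.  The selection cascade then runs:

1. collinearity filter — of each highly rank-correlated (|Spearman rho| >=
   threshold) feature pair, the lower-variance member is dropped;
2. variance filter — features whose min-max-scaled variance falls below a
   floor are dropped;
3. PCA report — component scores, unit-norm loadings, explained variance;
4. L1 path — an L1-regularised linear model (hinge-loss SVM or logistic)
   refitted over a descending grid of the inverse regularisation strength C;
   a feature's *persistence* is the smallest C at which its coefficient
   stays nonzero, so features that survive into strongly constrained models
   rank first;
5. shallow decision tree (gini) — an interpretable cutoff report;
6. group comparison — two-sided Mann-Whitney U per feature with Holm
   step-down adjustment of the p-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier, export_text
from statsmodels.stats.multitest import multipletests

from .errors import ModellingError, ParameterError, SchemaError

__all__ = [
    "FeatureTable",
    "extract_features",
    "collinearity_filter",
    "variance_filter",
    "pca_report",
    "l1_path",
    "tree_report",
    "group_compare",
    "holm_adjust",
]

NONZERO_TOL = 1e-6


@dataclass
class FeatureTable:
    """Subjects x features with an endpoint label column.

    ``data`` is indexed by subject id; ``endpoint`` names the label column;
    every other column is a feature.  ``provenance`` records, per feature,
    which population sources contributed.
    """

    data: pd.DataFrame
    endpoint: str = "endpoint"
    provenance: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.endpoint not in self.data.columns:
            raise SchemaError(f"endpoint column {self.endpoint!r} missing")

    @property
    def feature_names(self) -> List[str]:
        return [c for c in self.data.columns if c != self.endpoint]

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    def labels(self) -> pd.Series:
        return self.data[self.endpoint]

    def complete_cases(self) -> "FeatureTable":
        return FeatureTable(self.data.dropna(), self.endpoint,
                            dict(self.provenance))

    def drop(self, features: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.drop(columns=list(features)),
                            self.endpoint, {k: v for k, v in
                                            self.provenance.items()
                                            if k not in set(features)})

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject_id")

    @staticmethod
    def from_csv(path, endpoint: str = "endpoint") -> "FeatureTable":
        return FeatureTable(pd.read_csv(path, index_col="subject_id"), endpoint)


def _standardise(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - X.mean(axis=0)) / sd


def _minmax_variance(col: pd.Series) -> float:
    x = col.to_numpy(float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return 0.0
    span = x.max() - x.min()
    if span == 0:
        return 0.0
    return float(((x - x.min()) / span).var(ddof=0))


# ---------------------------------------------------------------------------
# Extraction


def extract_features(project, experiment_name: str,
                     populations: Sequence[str],
                     statistics: Sequence[str] = ("fraction_of_parent",),
                     aliases: Optional[Dict[str, Sequence[str]]] = None,
                     metadata_covariates: Sequence[str] = (),
                     endpoint_key: str = "endpoint") -> FeatureTable:
    """Build the subjects x population-statistics table for one experiment.

    ``aliases`` maps a canonical population name to the stored population
    names produced by different methods (gates, classifiers, clusters); the
    statistic is averaged across whichever are present (cross-method mean)
    and missing populations are recorded as NaN with a warning.  Metadata
    covariates and the endpoint label are joined from Subject documents.
    """
    bad = [s for s in statistics
           if s not in ("fraction_of_parent", "fraction_of_root", "count")]
    if bad:
        raise ParameterError(f"unknown statistics {bad}")
    exp = project.experiments.get(experiment_name)
    if exp is None:
        raise SchemaError(f"experiment {experiment_name!r} not found")
    aliases = {p: list(aliases.get(p, [p])) if aliases else [p]
               for p in populations}

    rows = {}
    provenance: Dict[str, List[str]] = {}
    for sid, fg in sorted(exp.filegroups.items()):
        subject = project.subjects.get(fg.subject_id)
        key = fg.subject_id if fg.subject_id is not None else sid
        row = rows.setdefault(key, {})
        root_n = fg.populations["root"].n
        for pop_name in populations:
            found = [fg.populations[a] for a in aliases[pop_name]
                     if a in fg.populations]
            if not found:
                warnings.warn(f"population {pop_name!r} missing for sample "
                              f"{sid!r}; recorded as NaN")
            for stat in statistics:
                feature = f"{pop_name}_{stat}" if len(statistics) > 1 else pop_name
                vals = []
                for pop in found:
                    if stat == "count":
                        vals.append(pop.n)
                    elif stat == "fraction_of_root":
                        vals.append(pop.n / root_n if root_n else np.nan)
                    else:
                        parent_n = fg.populations[pop.parent].n if pop.parent else root_n
                        vals.append(pop.n / parent_n if parent_n else np.nan)
                row[feature] = float(np.mean(vals)) if vals else np.nan
                provenance.setdefault(feature, sorted(
                    {p.source for p in found}))
        if subject is not None:
            for cov in metadata_covariates:
                row[cov] = subject.metadata.get(cov, np.nan)
            row["endpoint"] = subject.metadata.get(endpoint_key, np.nan)
        else:
            row.setdefault("endpoint", np.nan)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    cols = [c for c in df.columns if c != "endpoint"] + ["endpoint"]
    return FeatureTable(df[cols], "endpoint", provenance)


# ---------------------------------------------------------------------------
# Filters


def collinearity_filter(ft: FeatureTable, threshold: float = 0.9
                        ) -> Tuple[FeatureTable, pd.DataFrame]:
    """Drop the lower-variance member of each |Spearman rho| >= threshold pair.

    Pairs are processed in descending |rho| (ties: lexicographic pair name),
    so the surviving set is invariant to feature-column order.  Returns the
    reduced table and a report of (feature_a, feature_b, rho, dropped).
    """
    feats = ft.feature_names
    report_rows = []
    if len(feats) < 2:
        return ft, pd.DataFrame(columns=["feature_a", "feature_b", "rho", "dropped"])
    X = ft.features().to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X, nan_policy="omit").statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    variances = {f: _minmax_variance(ft.data[f]) for f in feats}
    pairs = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            r = rho[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                a, b = sorted((feats[i], feats[j]))
                pairs.append((-abs(r), a, b, r))
    pairs.sort()
    dropped = set()
    for _, a, b, r in pairs:
        if a in dropped or b in dropped:
            continue
        # lower variance loses; tie: drop the lexicographically later name
        if variances[a] < variances[b]:
            loser = a
        elif variances[b] < variances[a]:
            loser = b
        else:
            loser = max(a, b)
        dropped.add(loser)
        report_rows.append({"feature_a": a, "feature_b": b, "rho": float(r),
                            "dropped": loser})
    report = pd.DataFrame(report_rows,
                          columns=["feature_a", "feature_b", "rho", "dropped"])
    return ft.drop(sorted(dropped)), report


def variance_filter(ft: FeatureTable, floor: float = 0.02
                    ) -> Tuple[FeatureTable, pd.DataFrame]:
    """Remove features whose min-max-scaled variance is below ``floor``."""
    rows = [{"feature": f, "scaled_variance": _minmax_variance(ft.data[f])}
            for f in ft.feature_names]
    report = pd.DataFrame(rows, columns=["feature", "scaled_variance"])
    doomed = [r["feature"] for r in rows if r["scaled_variance"] < floor]
    return ft.drop(doomed), report


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAReport:
    scores: pd.DataFrame            # subjects x components
    loadings: pd.DataFrame          # components x features, unit-norm rows
    explained_variance_ratio: np.ndarray


def pca_report(ft: FeatureTable, n_components: int = 2) -> PCAReport:
    """PCA on standardised complete-case features."""
    ct = ft.complete_cases()
    X = ct.features().to_numpy(float)
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        raise ParameterError(
            f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(_standardise(X))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAReport(
        pd.DataFrame(scores, index=ct.data.index, columns=comp_names),
        pd.DataFrame(pca.components_, index=comp_names,
                     columns=ct.feature_names),
        pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# L1 path


@dataclass
class L1PathReport:
    C_grid: np.ndarray
    coefficients: pd.DataFrame      # index C (descending), columns features
    persistence: pd.Series          # feature -> smallest C with nonzero coef
    ranking: List[str]              # most persistent first


def default_C_grid(n: int = 30) -> np.ndarray:
    """30 log-spaced C values across 4 decades, descending."""
    return np.logspace(2, -2, n)


def l1_path(ft: FeatureTable, C_grid: Optional[np.ndarray] = None,
            model: str = "svm", seed: int = 42) -> L1PathReport:
    """Coefficient paths of an L1-regularised linear model over a C grid.

    Smaller C = stronger regularisation; a feature's persistence is the
    smallest C at which |coef| > 1e-6 (NaN if never nonzero).  The ranking
    orders features by ascending persistence, ties by descending max |coef|.
    """
    ct = ft.complete_cases()
    y = ct.labels().to_numpy()
    if len(np.unique(y)) != 2:
        raise ModellingError("L1 path requires a binary endpoint")
    X = _standardise(ct.features().to_numpy(float))
    if C_grid is None:
        C_grid = default_C_grid()
    C_grid = np.asarray(C_grid, float)
    if np.any(np.diff(C_grid) > 0):
        raise ParameterError("C_grid must be descending")
    coefs = np.zeros((C_grid.size, X.shape[1]))
    for i, C in enumerate(C_grid):
        if model == "svm":
            est = LinearSVC(C=C, penalty="l1", loss="squared_hinge",
                            dual=False, max_iter=20000, random_state=seed)
        elif model == "logistic":
            est = LogisticRegression(C=C, penalty="l1", solver="liblinear",
                                     max_iter=5000, random_state=seed)
        else:
            raise ParameterError(f"unknown model {model!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        coefs[i] = est.coef_.ravel()
    feats = ct.feature_names
    coef_df = pd.DataFrame(coefs, index=C_grid, columns=feats)
    persistence = {}
    for f in feats:
        nz = C_grid[np.abs(coef_df[f].to_numpy()) > NONZERO_TOL]
        persistence[f] = float(nz.min()) if nz.size else np.nan
    pers = pd.Series(persistence)
    max_abs = coef_df.abs().max()
    order = sorted(feats, key=lambda f: (
        np.inf if np.isnan(pers[f]) else pers[f], -max_abs[f], f))
    return L1PathReport(C_grid, coef_df, pers, order)


# ---------------------------------------------------------------------------
# Decision tree


@dataclass
class TreeReport:
    tree: Optional[DecisionTreeClassifier]
    root_feature: Optional[str]
    root_threshold: Optional[float]
    training_accuracy: float
    rendering: str


def _gini(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - np.square(p).sum())


def _best_stump(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str]):
    """Exhaustive depth-1 split: max gini decrease over all features and
    midpoints.  Equal-decrease ties break towards the larger standardised
    margin at the cutoff (the more robust split), then feature order."""
    n = y.size
    parent = _gini(y)
    best = None  # (decrease, margin, -feature_index, feature, cutoff)
    for j, fname in enumerate(feature_names):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        sd = x.std(ddof=0)
        for i in range(n - 1):
            if xs[i] == xs[i + 1]:
                continue
            cutoff = 0.5 * (xs[i] + xs[i + 1])
            dec = parent - ((i + 1) / n * _gini(ys[:i + 1])
                            + (n - i - 1) / n * _gini(ys[i + 1:]))
            margin = (xs[i + 1] - xs[i]) / sd if sd > 0 else 0.0
            key = (dec, margin, -j)
            if best is None or key > best[0]:
                best = (key, fname, float(cutoff))
    return best


def tree_report(ft: FeatureTable, max_depth: int = 1,
                criterion: str = "gini", seed: int = 42) -> TreeReport:
    """Fit a shallow decision tree and report the root split.

    ``max_depth=0`` returns a majority-class stub.  Depth-1 stumps are fitted
    by exhaustive split search (deterministic, documented tie-break); deeper
    trees delegate to scikit-learn.
    """
    ct = ft.complete_cases()
    y = ct.labels().to_numpy()
    X = ct.features().to_numpy(float)
    if max_depth == 0:
        classes, counts = np.unique(y, return_counts=True)
        majority = classes[int(np.argmax(counts))]
        acc = float(counts.max() / counts.sum())
        return TreeReport(None, None, None, acc,
                          f"majority-class stub -> {majority!r} "
                          f"(accuracy {acc:.3f})")
    if max_depth == 1 and criterion == "gini":
        found = _best_stump(X, y, ct.feature_names)
        if found is None:  # all features constant
            classes, counts = np.unique(y, return_counts=True)
            acc = float(counts.max() / counts.sum())
            return TreeReport(None, None, None, acc, "no usable split")
        _, fname, cutoff = found
        col = ct.data[fname].to_numpy(float)
        pred = np.empty(y.size, dtype=object)
        for side in (col <= cutoff, col > cutoff):
            classes, counts = np.unique(y[side], return_counts=True)
            pred[side] = classes[int(np.argmax(counts))]
        acc = float((pred == y).mean())
        rendering = (f"|--- {fname} <= {cutoff:.6g}\n"
                     f"|--- {fname} >  {cutoff:.6g}\n"
                     f"(training accuracy {acc:.3f})")
        return TreeReport(None, fname, cutoff, acc, rendering)
    tree = DecisionTreeClassifier(max_depth=max_depth, criterion=criterion,
                                  random_state=seed)
    tree.fit(X, y)
    acc = float(tree.score(X, y))
    root_feature = root_threshold = None
    if tree.tree_.feature[0] >= 0:
        root_feature = ct.feature_names[tree.tree_.feature[0]]
        root_threshold = float(tree.tree_.threshold[0])
    rendering = export_text(tree, feature_names=ct.feature_names)
    return TreeReport(tree, root_feature, root_threshold, acc, rendering)


# ---------------------------------------------------------------------------
# Group comparison


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (family-wise error control)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def group_compare(ft: FeatureTable, features: Optional[Sequence[str]] = None,
                  exact_limit: int = 8) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature with Holm-adjusted p-values.

    The exact null distribution is used when the smaller group has at most
    ``exact_limit`` subjects and the feature has no ties; otherwise the
    tie-corrected normal approximation.
    """
    y = ft.labels()
    groups = [g for g in pd.unique(y.dropna())]
    if len(groups) != 2:
        raise ModellingError("group comparison requires exactly two groups")
    features = list(features or ft.feature_names)
    rows = []
    for f in features:
        sub = ft.data[[f]].join(y.rename("_y")).dropna()
        a = sub.loc[sub["_y"] == groups[0], f].to_numpy(float)
        b = sub.loc[sub["_y"] == groups[1], f].to_numpy(float)
        if a.size == 0 or b.size == 0:
            raise ModellingError(f"feature {f!r} has an empty group")
        method = "exact" if (min(a.size, b.size) <= exact_limit
                             and np.unique(np.concatenate([a, b])).size
                             == a.size + b.size) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"feature": f, "U": float(res.statistic),
                     "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out
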