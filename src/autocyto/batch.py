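"""Batch-effect diagnostics and pluggable global correction.

Technical variation between acquisition runs ("batch effect") shows up as
distributional drift unrelated to biology.  This module provides:

* :func:`select_reference` — choose the "average" sample: the one whose
  channel covariance matrix has the smallest mean Frobenius (entrywise
  Euclidean) distance to every other sample's covariance matrix.
* :func:`lisi` — the local inverse Simpson's index: for each event, the
  effective number of batches represented among its k nearest neighbours
  (1 = fully batch-segregated, B = perfectly mixed across B batches).
* :func:`correct_batches` — the preprocessing contract around a pluggable
  global corrector: biexponential (or configured) transform, per-dimension
  unit-variance scaling, pooling with origin labels, optional per-sample
  down-sampling, then delegation to a registered plugin.  Default corrector
  parameters are sigma = 0.2 and max_iter = 5.  Shipped plugins are
  ``identity`` and ``mean_center`` (per-batch mean centring, for tests and
  as a minimal working corrector); heavyweight correctors register through
  the same signature.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, ContractError, ParameterError
from .fcs import EventMatrix
from .transforms import TransformSpec, apply_transform, zscale

__all__ = [
    "select_reference",
    "lisi",
    "correct_batches",
    "register_corrector",
    "BatchAssessment",
    "BatchCorrectionResult",
    "DEFAULT_CORRECTOR_PARAMS",
]

DEFAULT_CORRECTOR_PARAMS = {"sigma": 0.2, "max_iter": 5}


def _as_array(sample) -> np.ndarray:
    if isinstance(sample, EventMatrix):
        return sample.values
    return np.asarray(sample, float)


@dataclass
class BatchAssessment:
    """Result bundle of a batch-effect assessment."""

    reference_sample_id: object
    sample_ids: List[object]
    covariance_distances: np.ndarray  # symmetric, zero diagonal
    lisi_before: Optional[np.ndarray] = None
    lisi_after: Optional[np.ndarray] = None
    k_neighbors: Optional[int] = None


def select_reference(samples: Union[Dict[object, np.ndarray], Sequence[np.ndarray]]
                     ) -> BatchAssessment:
    """Pick the sample minimising the mean covariance distance to all others.

    ``samples`` maps sample id -> (events x dims) array (or is a sequence,
    in which case positional indices are the ids).  Distance between two
    samples is the Frobenius norm of the difference of their channel
    covariance matrices.  Ties break towards the earlier sample id in sorted
    order; the full distance matrix is returned for reporting.
    """
    if not isinstance(samples, dict):
        samples = {i: s for i, s in enumerate(samples)}
    if len(samples) < 2:
        raise ParameterError("need >= 2 samples to select a reference")
    ids = sorted(samples, key=lambda i: str(i))
    covs = {}
    for sid in ids:
        x = _as_array(samples[sid])
        if x.shape[0] < x.shape[1] + 1:
            raise ParameterError(
                f"sample {sid!r} has too few events for a covariance estimate")
        covs[sid] = np.cov(x, rowvar=False)
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(covs[ids[i]] - covs[ids[j]], ord="fro")
            dist[i, j] = dist[j, i] = d
    mean_dist = dist.sum(axis=1) / (n - 1)
    winner = ids[int(np.argmin(mean_dist))]  # argmin takes the first on ties
    return BatchAssessment(winner, ids, dist)


def lisi(values: np.ndarray, batch_labels: Sequence, k: int = 90) -> np.ndarray:
    """Per-event local inverse Simpson's index over hard k-nearest neighbours.

    For each event, the proportions ``p_b`` of each batch among its ``k``
    Euclidean nearest neighbours (self excluded) give
    ``LISI = 1 / sum_b p_b**2``, bounded in ``[1, B]``.
    """
    x = np.asarray(values, float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(batch_labels)
    if labels.shape[0] != x.shape[0]:
        raise ParameterError("batch labels length must match event count")
    n = x.shape[0]
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than n={n}")
    _, codes = np.unique(labels, return_inverse=True)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nbrs.kneighbors(x)
    neigh = codes[idx[:, 1:]]  # drop self
    b = codes.max() + 1
    counts = np.zeros((n, b))
    for c in range(b):
        counts[:, c] = (neigh == c).sum(axis=1)
    p = counts / k
    return 1.0 / np.square(p).sum(axis=1)


# ---------------------------------------------------------------------------
# Corrector plugin registry

_CORRECTORS: Dict[str, Callable] = {}


def register_corrector(name: str, fn: Callable) -> None:
    """Register a corrector plugin ``fn(matrix, batch_labels, params) -> matrix``."""
    _CORRECTORS[name] = fn


def _identity_corrector(matrix, batch_labels, params):
    return matrix


def _mean_center_corrector(matrix, batch_labels, params):
    """Per-batch mean centring (then re-adding the global mean): removes pure
    location batch shifts without touching within-batch covariance."""
    x = np.array(matrix, float, copy=True)
    labels = np.asarray(batch_labels)
    global_mean = x.mean(axis=0)
    for b in np.unique(labels):
        rows = labels == b
        x[rows] -= x[rows].mean(axis=0)
    return x + global_mean


register_corrector("identity", _identity_corrector)
register_corrector("mean_center", _mean_center_corrector)


@dataclass
class BatchCorrectionResult:
    corrected: np.ndarray           # rows aligned with batch_labels
    prepared: np.ndarray            # transformed + scaled input to the plugin
    batch_labels: np.ndarray
    params: dict = field(default_factory=dict)


def correct_batches(samples: Dict[object, np.ndarray],
                    corrector: Union[str, Callable] = "identity",
                    params: Optional[dict] = None,
                    transform: Optional[TransformSpec] = None,
                    downsample: Optional[int] = None,
                    seed: int = 42) -> BatchCorrectionResult:
    """Run the global correction pipeline around a corrector plugin.

    Each sample is transformed (biexponential by default), pooled with its
    origin label, scaled per dimension to zero mean / unit variance, then
    passed to the plugin with ``params`` (defaults merged with
    ``sigma = 0.2`` and ``max_iter = 5``).  ``downsample`` caps events per
    sample by uniform random sampling with the stored ``seed``.
    """
    if isinstance(corrector, str):
        if corrector not in _CORRECTORS:
            raise ConfigurationError(
                f"no corrector plugin registered under {corrector!r}")
        fn = _CORRECTORS[corrector]
    elif callable(corrector):
        fn = corrector
    else:
        raise ConfigurationError("corrector must be a name or a callable")
    if transform is None:
        transform = TransformSpec("biexponential")
    merged = dict(DEFAULT_CORRECTOR_PARAMS)
    merged.update(params or {})
    merged["seed"] = seed

    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    dims = None
    for sid in sorted(samples, key=lambda i: str(i)):
        x = _as_array(samples[sid])
        if dims is None:
            dims = x.shape[1]
        elif x.shape[1] != dims:
            raise ParameterError("samples must share dimensions")
        if downsample is not None and x.shape[0] > downsample:
            rows = rng.choice(x.shape[0], size=downsample, replace=False)
            x = x[np.sort(rows)]
        blocks.append(apply_transform(x, transform))
        labels.extend([sid] * x.shape[0])
    pooled = np.vstack(blocks)
    labels = np.asarray(labels)
    prepared = zscale(pooled)

    corrected = fn(prepared, labels, merged)
    corrected = np.asarray(corrected, float)
    if corrected.shape != prepared.shape:
        raise ContractError(
            f"corrector returned shape {corrected.shape}, "
            f"expected {prepared.shape}")
    return BatchCorrectionResult(corrected, prepared, labels, merged)
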