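"""Landmark registration: align a sample's 1-D density to a reference.

Landmarks are points of maximum kernel-density; landmarks of the reference
and target are pooled and grouped by K-means, and within every group that
contains exactly one landmark from each source a warp knot (target position
-> reference position) is recorded.  The warping function is a monotone
cubic (PCHIP) interpolation through the knots, continued with identity slope
beyond the outermost knots, so it is strictly increasing on all of R and
maps each target landmark exactly onto its reference landmark.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .errors import InsufficientDataError, RegistrationError

__all__ = ["find_landmarks", "register", "LandmarkWarp", "density_grid"]

DEFAULT_PROMINENCE_FRAC = 0.05  # peaks below 5% of max density are noise


def density_grid(values: np.ndarray, bandwidth=None, gridsize: int = 1000,
                 pct_range=(0.1, 99.9)):
    """Gaussian KDE evaluated on a regular grid over a percentile range.

    ``bandwidth`` follows :class:`scipy.stats.gaussian_kde` semantics: None
    (Silverman's rule), a scalar factor, or a string rule name.
    """
    x = np.asarray(values, float).ravel()
    if x.size < 2:
        raise InsufficientDataError("need >= 2 events for a density estimate")
    lo, hi = np.percentile(x, pct_range)
    if hi <= lo:
        lo, hi = x.min() - 0.5, x.max() + 0.5
    grid = np.linspace(lo, hi, gridsize)
    if np.ptp(x) == 0:
        x = x + np.random.default_rng(0).normal(0, 1e-9, x.size)
    kde = gaussian_kde(x, bw_method="silverman" if bandwidth is None else bandwidth)
    return grid, kde(grid)


def find_landmarks(values: np.ndarray, bandwidth=None,
                   prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                   gridsize: int = 1000) -> np.ndarray:
    """Local maxima of the KDE above a prominence floor, sorted ascending.

    Always returns at least one landmark (the global density maximum).
    """
    x = np.asarray(values, float).ravel()
    if x.size < 10:
        raise InsufficientDataError("need >= 10 events to find landmarks")
    grid, dens = density_grid(x, bandwidth=bandwidth, gridsize=gridsize)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    return np.sort(grid[peaks])


@dataclass
class LandmarkWarp:
    """Piecewise monotone map aligning target landmarks to reference landmarks."""

    reference_landmarks: np.ndarray
    target_landmarks: np.ndarray
    knots_target: np.ndarray
    knots_reference: np.ndarray

    def __post_init__(self):
        t, r = np.asarray(self.knots_target, float), np.asarray(self.knots_reference, float)
        if t.size != r.size or t.size == 0:
            raise RegistrationError("warp requires matched knot arrays")
        self._single = t.size == 1
        if not self._single:
            self._pchip = PchipInterpolator(t, r, extrapolate=False)
        self._t0, self._t1 = t[0], t[-1]
        self._r0, self._r1 = r[0], r[-1]

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._single:
            return x + (self._r0 - self._t0)
        out = np.empty_like(x, dtype=float)
        below = x < self._t0
        above = x > self._t1
        inside = ~(below | above)
        out[below] = self._r0 + (x[below] - self._t0)   # identity-slope tails
        out[above] = self._r1 + (x[above] - self._t1)
        out[inside] = self._pchip(x[inside])
        return out

    def to_document(self) -> dict:
        return {
            "reference_landmarks": np.asarray(self.reference_landmarks).tolist(),
            "target_landmarks": np.asarray(self.target_landmarks).tolist(),
            "knots_target": np.asarray(self.knots_target).tolist(),
            "knots_reference": np.asarray(self.knots_reference).tolist(),
        }


def _pair_landmarks(ref_lm: np.ndarray, tgt_lm: np.ndarray,
                    k: Optional[int], seed: int):
    """Group pooled landmarks with K-means; each cluster containing at least
    one landmark from each source yields one (target, reference) knot pair
    (the closest such pair when a cluster holds several)."""
    if k is None:
        k = max(ref_lm.size, tgt_lm.size)
    pooled = np.concatenate([ref_lm, tgt_lm])
    source = np.array([0] * ref_lm.size + [1] * tgt_lm.size)
    k = min(k, pooled.size)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(pooled[:, None])
    pairs: List[tuple] = []
    for c in range(k):
        members = labels == c
        refs = pooled[members & (source == 0)]
        tgts = pooled[members & (source == 1)]
        if refs.size >= 1 and tgts.size >= 1:
            # closest cross-source pair within the cluster
            d = np.abs(refs[:, None] - tgts[None, :])
            i, j = np.unravel_index(np.argmin(d), d.shape)
            pairs.append((float(tgts[j]), float(refs[i])))
    return pairs


def register(target: np.ndarray,
             reference: Optional[np.ndarray] = None,
             reference_landmarks: Optional[Sequence[float]] = None,
             k: Optional[int] = None, bandwidth=None, seed: int = 42):
    """Warp ``target`` values so their density landmarks align to a reference.

    The reference may be given as a raw 1-D sample or as precomputed landmark
    positions (as stored in a fitted gate).  Returns
    ``(LandmarkWarp, warped_values)``.  Raises :class:`RegistrationError`
    when no landmark pair can be formed.
    """
    target = np.asarray(target, float).ravel()
    if target.size < 10:
        raise InsufficientDataError("need >= 10 target events to register")
    if reference_landmarks is not None:
        ref_lm = np.sort(np.asarray(reference_landmarks, float).ravel())
    elif reference is not None:
        reference = np.asarray(reference, float).ravel()
        if reference.size < 10:
            raise InsufficientDataError("need >= 10 reference events to register")
        ref_lm = find_landmarks(reference, bandwidth=bandwidth)
    else:
        raise RegistrationError("a reference sample or landmarks are required")
    tgt_lm = find_landmarks(target, bandwidth=bandwidth)

    if ref_lm.size == tgt_lm.size and k is None:
        # equal landmark counts: a monotone warp preserves order, so rank
        # pairing is the correct correspondence regardless of shift size
        pairs = list(zip(tgt_lm.tolist(), ref_lm.tolist()))
    else:
        pairs = _pair_landmarks(ref_lm, tgt_lm, k, seed)
    if not pairs:
        raise RegistrationError("no landmark pairs could be matched")
    pairs.sort()
    # enforce strict monotonicity in both coordinates
    knots_t, knots_r = [], []
    for t, r in pairs:
        if knots_t and (t <= knots_t[-1] or r <= knots_r[-1]):
            continue
        knots_t.append(t)
        knots_r.append(r)
    warp = LandmarkWarp(ref_lm, tgt_lm, np.array(knots_t), np.array(knots_r))
    return warp, warp(target)
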