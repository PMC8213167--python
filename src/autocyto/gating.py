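"""Autonomous gates: density thresholds, Gaussian-mixture ellipses, population
matching, exhaustive hyperparameter search and sequential strategy application.

A :class:`Gate` is *defined* (fitted) on example data; the populations found
there are stored as references — a median-fluorescence-intensity (MFI) vector
for threshold gates, a convex hull for ellipse/polygon gates — together with
the density landmarks of the example data.  When the gate is applied to a new
sample the algorithm is refitted (optionally across an exhaustive
hyperparameter grid, optionally after landmark registration of each dimension
against the stored reference density) and the resulting candidate populations
are matched back to the references: minimum Euclidean MFI distance for
threshold gates, minimum Hausdorff distance between convex hulls for
geometric gates.  Gates stack into a :class:`GatingStrategy` applied in
sequence, emitting :class:`~autocyto.model.Population` documents.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

from .errors import (
    ConfigurationError,
    DegenerateHullError,
    FitError,
    InsufficientDataError,
    NotFoundError,
    ParameterError,
    SchemaError,
)
from .model import FileGroup, Population
from .registration import density_grid, find_landmarks, register
from .transforms import TransformSpec, make_transform

logger = logging.getLogger(__name__)

__all__ = [
    "GateGeometry",
    "fit_threshold_gate",
    "fit_ellipse_gate",
    "population_hull",
    "hausdorff",
    "match_populations",
    "hyperparameter_search",
    "Gate",
    "GatingStrategy",
    "GRID_CAP",
]

GRID_CAP = 512


# ---------------------------------------------------------------------------
# Geometry


@dataclass
class GateGeometry:
    """Serializable geometric record of how a population was cut."""

    kind: str  # threshold1d | threshold2d | polygon | ellipse
    dims: List[str]
    thresholds: Optional[List[float]] = None
    vertices: Optional[np.ndarray] = None
    center: Optional[np.ndarray] = None
    covariance: Optional[np.ndarray] = None
    conf_level: Optional[float] = None
    transforms: Dict[str, TransformSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("threshold1d", "threshold2d", "polygon", "ellipse"):
            raise ParameterError(f"unknown geometry kind {self.kind!r}")
        if self.vertices is not None:
            self.vertices = np.asarray(self.vertices, float)
        if self.center is not None:
            self.center = np.asarray(self.center, float)
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, float)
            if not np.allclose(self.covariance, self.covariance.T):
                raise ParameterError("ellipse covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
                raise ParameterError("ellipse covariance must be positive definite")

    def to_document(self) -> dict:
        return {
            "kind": self.kind,
            "dims": list(self.dims),
            "thresholds": None if self.thresholds is None else list(map(float, self.thresholds)),
            "vertices": None if self.vertices is None else self.vertices.tolist(),
            "center": None if self.center is None else self.center.tolist(),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "conf_level": self.conf_level,
            "transforms": {d: s.to_document() for d, s in self.transforms.items()},
        }

    @staticmethod
    def from_document(doc: dict) -> "GateGeometry":
        return GateGeometry(
            doc["kind"], list(doc["dims"]),
            doc.get("thresholds"),
            None if doc.get("vertices") is None else np.asarray(doc["vertices"]),
            None if doc.get("center") is None else np.asarray(doc["center"]),
            None if doc.get("covariance") is None else np.asarray(doc["covariance"]),
            doc.get("conf_level"),
            {d: TransformSpec.from_document(s)
             for d, s in doc.get("transforms", {}).items()})


def population_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points, vertices in counter-clockwise order."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("hull requires an (n, 2) array")
    if pts.shape[0] < 3:
        raise DegenerateHullError("need >= 3 points for a hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate point set: {exc}") from exc
    return pts[hull.vertices]  # Qhull returns CCW order in 2-D


def hausdorff(hull_a: np.ndarray, hull_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two hull vertex sets."""
    a, b = np.asarray(hull_a, float), np.asarray(hull_b, float)
    if a.size == 0 or b.size == 0:
        raise DegenerateHullError("empty hull")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


# ---------------------------------------------------------------------------
# Threshold gates


def _threshold_1d(x: np.ndarray, bandwidth=None,
                  min_peak_threshold: float = 0.05,
                  q_fallback: float = 0.95) -> float:
    """Density valley between the two largest peaks, or a quantile fallback.

    The KDE is evaluated on a 1000-point grid; peaks below
    ``min_peak_threshold`` (a fraction of the maximum density) are ignored.
    With >= 2 surviving peaks the threshold is the point of minimum density
    between the two tallest; with a single peak it is the ``q_fallback``
    empirical quantile.
    """
    grid, dens = density_grid(x, bandwidth=bandwidth)
    peaks, props = find_peaks(dens, height=min_peak_threshold * dens.max())
    if peaks.size >= 2:
        order = np.argsort(props["peak_heights"])[::-1]
        p1, p2 = sorted(peaks[order[:2]])
        valley = p1 + int(np.argmin(dens[p1:p2 + 1]))
        return float(grid[valley])
    return float(np.quantile(x, q_fallback))


def fit_threshold_gate(data: np.ndarray, bandwidth=None,
                       min_peak_threshold: float = 0.05,
                       q_fallback: float = 0.95
                       ) -> Tuple[GateGeometry, Dict[str, np.ndarray]]:
    """Fit a 1- or 2-D density threshold gate.

    Returns the geometry and a dict of boolean child masks keyed by sign
    string: ``"+"``/``"-"`` in 1-D, ``"++"``, ``"+-"``, ``"-+"``, ``"--"``
    in 2-D (sign order follows column order; ``+`` means value >= threshold).
    The children always partition the input exactly.
    """
    x = np.asarray(data, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise InsufficientDataError("need >= 2 events for a threshold gate")
    d = x.shape[1]
    if d not in (1, 2):
        raise ParameterError("threshold gates are 1- or 2-dimensional")
    thresholds = [_threshold_1d(x[:, j], bandwidth, min_peak_threshold, q_fallback)
                  for j in range(d)]
    signs = [("+", "-")] * d
    children: Dict[str, np.ndarray] = {}
    for combo in itertools.product(*signs):
        mask = np.ones(x.shape[0], dtype=bool)
        for j, s in enumerate(combo):
            mask &= (x[:, j] >= thresholds[j]) if s == "+" else (x[:, j] < thresholds[j])
        children["".join(combo)] = mask
    geom = GateGeometry("threshold1d" if d == 1 else "threshold2d",
                        dims=[str(j) for j in range(d)], thresholds=thresholds)
    return geom, children


# ---------------------------------------------------------------------------
# Ellipse gates


def fit_ellipse_gate(data: np.ndarray, n_components: int = 2,
                     conf_level: float = 0.95, covariance_type: str = "full",
                     seed: int = 42
                     ) -> Tuple[List[GateGeometry], List[np.ndarray]]:
    """Fit a Gaussian mixture and cut one confidence ellipse per component.

    A child population is the event set whose squared Mahalanobis distance to
    the component mean is at most the chi-square(2) quantile at
    ``conf_level``.  Children may overlap (ellipses are independent).
    """
    x = np.asarray(data, float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ParameterError("ellipse gates are 2-dimensional")
    if x.shape[0] < n_components * 5:
        raise InsufficientDataError(
            f"need >= {n_components * 5} events for {n_components} components")
    if not 0 <= conf_level <= 1:
        raise ParameterError("conf_level must be in [0, 1]")
    gmm = GaussianMixture(n_components=n_components,
                          covariance_type=covariance_type, random_state=seed)
    gmm.fit(x)
    if not gmm.converged_:
        raise FitError(
            f"GMM did not converge (n_components={n_components}, "
            f"lower_bound={gmm.lower_bound_:.4g})")
    q = chi2.ppf(conf_level, df=2) if conf_level > 0 else 0.0
    geoms, masks = [], []
    for k in range(n_components):
        mean = gmm.means_[k]
        if covariance_type == "full":
            cov = gmm.covariances_[k]
        elif covariance_type == "tied":
            cov = gmm.covariances_
        elif covariance_type == "diag":
            cov = np.diag(gmm.covariances_[k])
        else:  # spherical
            cov = np.eye(2) * gmm.covariances_[k]
        delta = x - mean
        md2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
        masks.append(md2 <= q if conf_level > 0 else np.zeros(x.shape[0], bool))
        geoms.append(GateGeometry("ellipse", dims=["0", "1"], center=mean,
                                  covariance=cov, conf_level=conf_level))
    return geoms, masks


# ---------------------------------------------------------------------------
# Population matching


def _mfi(points: np.ndarray) -> np.ndarray:
    return np.median(np.asarray(points, float), axis=0)


def match_populations(candidates: Sequence[Tuple[object, object]],
                      references: Sequence[Tuple[str, object]],
                      mode: str = "mfi"):
    """Greedy injective matching of candidate populations to references.

    ``candidates`` is a sequence of ``(candidate_id, descriptor)`` and
    ``references`` of ``(name, descriptor)``; descriptors are MFI vectors
    (``mode="mfi"``, Euclidean distance) or hull vertex arrays
    (``mode="hull"``, Hausdorff distance).  Pairs are assigned in ascending
    distance order, each candidate used at most once; ties break on the
    earlier reference, then the earlier candidate.  Returns
    ``(assignment: name -> candidate_id, scores: name -> distance)``.
    """
    if not candidates:
        raise NotFoundError("no candidate populations to match")
    if mode not in ("mfi", "hull"):
        raise ParameterError(f"unknown match mode {mode!r}")
    dist = hausdorff if mode == "hull" else (
        lambda a, b: float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float))))
    entries = []
    for ri, (rname, rdesc) in enumerate(references):
        for ci, (cid, cdesc) in enumerate(candidates):
            entries.append((dist(cdesc, rdesc), ri, ci))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    assignment: Dict[str, object] = {}
    scores: Dict[str, float] = {}
    used_refs, used_cands = set(), set()
    for d, ri, ci in entries:
        if ri in used_refs or ci in used_cands:
            continue
        used_refs.add(ri)
        used_cands.add(ci)
        assignment[references[ri][0]] = candidates[ci][0]
        scores[references[ri][0]] = d
    return assignment, scores


# ---------------------------------------------------------------------------
# Gate


class Gate:
    """A single autonomous gate, defined on example data and reapplied to new
    samples with population matching.

    Parameters
    ----------
    gate_name : str
    parent : name of the parent population the gate consumes.
    dims : 1 or 2 channel names.
    algorithm : ``"threshold"`` or ``"ellipse"``.
    hyperparameters : base parameter values for the algorithm.
    hyperparameter_grid : param -> list of values searched exhaustively on
        application (cartesian product, capped at :data:`GRID_CAP`).
    transforms : per-dim :class:`TransformSpec` applied before fitting.
    landmark_registration : warp each dimension to the example density on
        application.
    children : threshold gates: sign string -> population name (unnamed signs
        are not committed); ellipse gates: population name -> prototype point
        (component assignment at definition is by nearest component mean).
    """

    def __init__(self, gate_name: str, parent: str, dims: Sequence[str],
                 algorithm: str = "threshold",
                 hyperparameters: Optional[dict] = None,
                 hyperparameter_grid: Optional[Dict[str, list]] = None,
                 transforms: Optional[Dict[str, TransformSpec]] = None,
                 landmark_registration: bool = False,
                 children: Optional[dict] = None):
        if algorithm not in ("threshold", "ellipse"):
            raise ParameterError(f"unknown gate algorithm {algorithm!r}")
        if not 1 <= len(dims) <= 2:
            raise ParameterError("gates are 1- or 2-dimensional")
        if algorithm == "ellipse" and len(dims) != 2:
            raise ParameterError("ellipse gates need exactly 2 dims")
        self.gate_name = gate_name
        self.parent = parent
        self.dims = list(dims)
        self.algorithm = algorithm
        self.hyperparameters = dict(hyperparameters or {})
        self.hyperparameter_grid = {k: list(v) for k, v in
                                    (hyperparameter_grid or {}).items()}
        self.transforms = {d: transforms.get(d, TransformSpec()) if transforms
                           else TransformSpec() for d in self.dims}
        self.landmark_registration = landmark_registration
        self.children = children
        # set at fit time
        self.references: List[dict] = []
        self.reference_landmarks: Dict[str, np.ndarray] = {}
        self.fitted = False

    # -- helpers ----------------------------------------------------------

    def _transform(self, x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x, dtype=float)
        for j, d in enumerate(self.dims):
            out[:, j] = make_transform(self.transforms[d]).forward(x[:, j])
        return out

    def _grid_points(self) -> List[dict]:
        if not self.hyperparameter_grid:
            return [dict(self.hyperparameters)]
        keys = sorted(self.hyperparameter_grid)
        combos = list(itertools.product(*(self.hyperparameter_grid[k] for k in keys)))
        if len(combos) > GRID_CAP:
            raise ConfigurationError(
                f"hyperparameter grid of size {len(combos)} exceeds cap {GRID_CAP}")
        points = []
        for combo in combos:
            p = dict(self.hyperparameters)
            p.update(dict(zip(keys, combo)))
            points.append(p)
        return points

    def _fit_once(self, xt: np.ndarray, params: dict, seed: int):
        """One algorithm fit; returns list of (cand_id, mask, geometry)."""
        if self.algorithm == "threshold":
            geom, children = fit_threshold_gate(
                xt,
                bandwidth=params.get("bandwidth"),
                min_peak_threshold=params.get("min_peak_threshold", 0.05),
                q_fallback=params.get("q_fallback", 0.95))
            geom.dims = list(self.dims)
            geom.transforms = dict(self.transforms)
            return [(sign, mask, geom) for sign, mask in children.items()]
        geoms, masks = fit_ellipse_gate(
            xt,
            n_components=int(params.get("n_components", 2)),
            conf_level=params.get("conf_level", 0.95),
            covariance_type=params.get("covariance_type", "full"),
            seed=seed)
        out = []
        for k, (g, m) in enumerate(zip(geoms, masks)):
            g.dims = list(self.dims)
            g.transforms = dict(self.transforms)
            out.append((k, m, g))
        return out

    @staticmethod
    def _descriptor(points: np.ndarray, mode: str):
        if points.shape[0] == 0:
            return None
        if mode == "mfi":
            return _mfi(points)
        if points.ndim != 2 or points.shape[1] != 2:
            return None  # hulls are 2-D only; matching falls back to MFI
        try:
            return population_hull(points)
        except DegenerateHullError:
            return None

    @property
    def match_mode(self) -> str:
        return "mfi" if self.algorithm == "threshold" else "hull"

    def _child_name(self, cand_id) -> Optional[str]:
        if self.algorithm == "threshold":
            if self.children:
                return self.children.get(cand_id)
            return f"{self.gate_name}{cand_id}"
        return None  # ellipse naming handled via prototypes at fit

    # -- definition -------------------------------------------------------

    def fit(self, data: np.ndarray, seed: int = 42) -> Dict[str, np.ndarray]:
        """Define the gate on example data (already sliced to ``dims``).

        Stores per-reference descriptors (MFI and, when non-degenerate, the
        convex hull) and the example density landmarks, and returns the named
        example populations as local row-index arrays.
        """
        x = np.asarray(data, float)
        if x.ndim == 1:
            x = x[:, None]
        xt = self._transform(x)
        fits = self._fit_once(xt, dict(self.hyperparameters), seed)
        self.references = []
        result: Dict[str, np.ndarray] = {}
        if self.algorithm == "threshold":
            for cand_id, mask, geom in fits:
                name = self._child_name(cand_id)
                if name is None or mask.sum() == 0:
                    continue
                self.references.append({
                    "name": name, "sign": cand_id,
                    "mfi": _mfi(xt[mask]),
                    "hull": self._descriptor(xt[mask], "hull"),
                    "geometry": geom})
                result[name] = np.flatnonzero(mask)
        else:
            if not self.children:
                proto = {f"{self.gate_name}_{k}": None for k, _, _ in fits}
            else:
                proto = dict(self.children)
            means = [(cid, geom.center) for cid, _, geom in fits]
            taken = set()
            for name, point in proto.items():
                if point is None:
                    cand = next((cid for cid, _ in means if cid not in taken), None)
                else:
                    dists = sorted((float(np.linalg.norm(np.asarray(point) - m)), cid)
                                   for cid, m in means if cid not in taken)
                    cand = dists[0][1] if dists else None
                if cand is None:
                    continue
                taken.add(cand)
                _, mask, geom = fits[cand]
                if mask.sum() == 0:
                    continue
                self.references.append({
                    "name": name, "sign": None,
                    "mfi": _mfi(xt[mask]),
                    "hull": self._descriptor(xt[mask], "hull"),
                    "geometry": geom})
                result[name] = np.flatnonzero(mask)
        if not self.references:
            raise FitError(f"gate {self.gate_name!r} produced no reference "
                           "populations on the example data")
        for j, d in enumerate(self.dims):
            self.reference_landmarks[d] = find_landmarks(xt[:, j])
        self.fitted = True
        return result

    # -- application ------------------------------------------------------

    def apply(self, data: np.ndarray, search: bool = False,
              register_landmarks: bool = False, seed: int = 42
              ) -> Dict[str, Tuple[np.ndarray, GateGeometry]]:
        """Apply a fitted gate to new data (sliced to ``dims``).

        Returns name -> (local row indices, geometry).  With ``search``, the
        algorithm is refitted at every grid point.  For threshold gates the
        grid point with the smallest total matching distance (most matched
        references first) wins as a whole, so the committed children always
        form one sign partition of the parent; for geometric gates each
        reference independently takes its best candidate across all grid
        points.  Ties break towards the lowest grid index.
        """
        if not self.fitted:
            raise ConfigurationError(f"gate {self.gate_name!r} is not fitted")
        x = np.asarray(data, float)
        if x.ndim == 1:
            x = x[:, None]
        xt = self._transform(x)
        if register_landmarks and self.landmark_registration:
            for j, d in enumerate(self.dims):
                try:
                    _, xt[:, j] = register(
                        xt[:, j], reference_landmarks=self.reference_landmarks[d],
                        seed=seed)
                except Exception as exc:  # registration failure: keep data as-is
                    logger.warning("registration skipped on %s/%s: %s",
                                   self.gate_name, d, exc)
        grid = self._grid_points() if search else [dict(self.hyperparameters)]
        mode = self.match_mode
        refs = [(r["name"], r["mfi" if mode == "mfi" else "hull"])
                for r in self.references]
        best: Dict[str, tuple] = {}
        for gi, params in enumerate(grid):
            fits = self._fit_once(xt, params, seed)
            cands = []
            for cand_id, mask, geom in fits:
                desc = self._descriptor(xt[mask], mode)
                if desc is None and mode == "hull":
                    desc = self._descriptor(xt[mask], "mfi")  # MFI fallback
                if desc is None:
                    continue
                cands.append((cand_id, desc, mask, geom,
                              desc.ndim if hasattr(desc, "ndim") else 0))
            if not cands:
                continue
            # hull-mode candidates that fell back to MFI are matched by MFI
            # against the reference MFI
            match_cands, match_refs = [], refs
            for cid, desc, mask, geom, _ in cands:
                match_cands.append((cid, desc))
            if mode == "hull" and any(np.asarray(d).ndim == 1 for _, d in match_cands):
                match_cands = [(cid, _mfi(xt[mask]))
                               for cid, desc, mask, geom, _ in cands]
                match_refs = [(r["name"], r["mfi"]) for r in self.references]
                assignment, scores = match_populations(match_cands, match_refs, "mfi")
            else:
                assignment, scores = match_populations(match_cands, match_refs, mode)
            by_id = {cid: (mask, geom) for cid, desc, mask, geom, _ in cands}
            if self.algorithm == "threshold":
                # one partition per gate: grid point with most matched refs,
                # then smallest total distance, wins as a whole
                key = (-len(assignment), sum(scores.values()))
                if "_grid" not in best or key < best["_grid"][0]:
                    best["_grid"] = (key, gi, {
                        name: (np.flatnonzero(by_id[cid][0]), by_id[cid][1])
                        for name, cid in assignment.items()})
            else:
                for name, cid in assignment.items():
                    s = scores[name]
                    if name not in best or s < best[name][0]:
                        mask, geom = by_id[cid]
                        best[name] = (s, gi, np.flatnonzero(mask), geom)
        if self.algorithm == "threshold":
            return best["_grid"][2] if "_grid" in best else {}
        return {name: (idx, geom) for name, (s, gi, idx, geom)
                in best.items()}

    # -- serialization ----------------------------------------------------

    def to_document(self) -> dict:
        return {
            "gate_name": self.gate_name, "parent": self.parent,
            "dims": self.dims, "algorithm": self.algorithm,
            "hyperparameters": self.hyperparameters,
            "hyperparameter_grid": self.hyperparameter_grid,
            "transforms": {d: s.to_document() for d, s in self.transforms.items()},
            "landmark_registration": self.landmark_registration,
            "children": (None if self.children is None else
                         {k: (list(v) if isinstance(v, (list, tuple, np.ndarray))
                              else v) for k, v in self.children.items()}),
            "fitted": self.fitted,
            "references": [
                {"name": r["name"], "sign": r["sign"],
                 "mfi": np.asarray(r["mfi"]).tolist(),
                 "hull": None if r["hull"] is None else np.asarray(r["hull"]).tolist(),
                 "geometry": r["geometry"].to_document()}
                for r in self.references],
            "reference_landmarks": {d: np.asarray(v).tolist()
                                    for d, v in self.reference_landmarks.items()},
        }

    @staticmethod
    def from_document(doc: dict) -> "Gate":
        gate = Gate(doc["gate_name"], doc["parent"], doc["dims"],
                    doc["algorithm"], doc.get("hyperparameters"),
                    doc.get("hyperparameter_grid"),
                    {d: TransformSpec.from_document(s)
                     for d, s in doc.get("transforms", {}).items()},
                    doc.get("landmark_registration", False),
                    doc.get("children"))
        gate.fitted = doc.get("fitted", False)
        gate.references = [
            {"name": r["name"], "sign": r["sign"],
             "mfi": np.asarray(r["mfi"]),
             "hull": None if r["hull"] is None else np.asarray(r["hull"]),
             "geometry": GateGeometry.from_document(r["geometry"])}
            for r in doc.get("references", [])]
        gate.reference_landmarks = {d: np.asarray(v)
                                    for d, v in doc.get("reference_landmarks", {}).items()}
        return gate


# ---------------------------------------------------------------------------
# Strategy


class GatingStrategy:
    """An ordered stack of gates forming a population tree from ``root``."""

    def __init__(self, name: str, gates: Optional[List[Gate]] = None):
        self.name = name
        self.gates: List[Gate] = list(gates or [])

    def add_gate(self, gate: Gate) -> "GatingStrategy":
        known = {"root"}
        for g in self.gates:
            known.update(r["name"] for r in g.references)
            if g.children and g.algorithm == "threshold":
                known.update(v for v in g.children.values())
            elif g.children:
                known.update(g.children.keys())
        if gate.parent not in known:
            raise ConfigurationError(
                f"gate {gate.gate_name!r} parent {gate.parent!r} is not "
                "produced by an earlier gate")
        self.gates.append(gate)
        return self

    def _gate_input(self, fg: FileGroup, gate: Gate) -> Optional[np.ndarray]:
        missing = [d for d in gate.dims if d not in fg.primary.channel_names]
        if missing:
            raise SchemaError(
                f"sample {fg.sample_id!r} is missing channels {missing}")
        if gate.parent not in fg.populations:
            logger.warning("gate %s skipped: parent %s missing in %s",
                           gate.gate_name, gate.parent, fg.sample_id)
            return None
        if fg.populations[gate.parent].n == 0:
            logger.warning("gate %s skipped: parent %s empty in %s",
                           gate.gate_name, gate.parent, fg.sample_id)
            return None
        return fg.population_data(gate.parent, gate.dims)

    def fit(self, fg: FileGroup, seed: int = 42) -> FileGroup:
        """Define every gate in order on the example sample, committing the
        example populations."""
        for gate in self.gates:
            x = self._gate_input(fg, gate)
            if x is None:
                continue
            result = gate.fit(x, seed=seed)
            self._commit(fg, gate, {n: (idx, gate.references[i]["geometry"])
                                    for i, (n, idx) in enumerate(result.items())})
        return fg

    def apply(self, fg: FileGroup, search: bool = False,
              register_landmarks: bool = False, seed: int = 42) -> FileGroup:
        """Apply all fitted gates in order to a (compensated) sample."""
        for gate in self.gates:
            if not gate.fitted:
                raise ConfigurationError(
                    f"gate {gate.gate_name!r} must be fitted before application")
            x = self._gate_input(fg, gate)
            if x is None:
                continue
            result = gate.apply(x, search=search,
                                register_landmarks=register_landmarks, seed=seed)
            self._commit(fg, gate, result)
        return fg

    @staticmethod
    def _commit(fg: FileGroup, gate: Gate, result) -> None:
        parent_index = fg.populations[gate.parent].index
        for name, (local_idx, geom) in result.items():
            if name in fg.populations:
                existing = fg.populations[name]
                if np.array_equal(existing.index, parent_index[local_idx]):
                    continue
                fg.remove_population(name)
            fg.add_population(Population(
                name, gate.parent, parent_index[np.asarray(local_idx, int)],
                source="gate", geometry=geom,
                transform_record=dict(gate.transforms)))

    def to_document(self) -> dict:
        return {"name": self.name, "gates": [g.to_document() for g in self.gates]}

    @staticmethod
    def from_document(doc: dict) -> "GatingStrategy":
        strat = GatingStrategy(doc["name"])
        strat.gates = [Gate.from_document(g) for g in doc["gates"]]
        return strat


def hyperparameter_search(gate: Gate, data: np.ndarray, seed: int = 42):
    """Exhaustively refit ``gate`` over its hyperparameter grid on ``data``.

    Convenience wrapper over :meth:`Gate.apply` with ``search=True``; per
    reference population the winner across all grid points is selected by
    :func:`match_populations` (MFI mode for threshold gates, hull mode for
    geometric gates), with ties broken towards the lowest grid index.
    """
    return gate.apply(data, search=True, seed=seed)
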