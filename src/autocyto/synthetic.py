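"""Synthetic multi-sample cytometry cohorts with ground truth.

Each sample draws events from a shared per-population multivariate Gaussian
mixture, then perturbs them with a per-sample (batch) affine model — a
per-channel location shift ~ N(0, tau^2) and scale factor ~ LogNormal(0,
s^2), emulating inter-run drift in fluorescent intensity — and finally mixes
channels with a spillover matrix so that compensation is exercised on
ingestion.  Per-sample population frequencies are drawn from a Dirichlet
around the base frequencies (between-subject biological variation); in
"case" samples one population's frequency is multiplied by a configured
effect before renormalisation.  Ground-truth per-event labels and realised
frequencies are returned alongside every sample, so gating, clustering and
feature-selection results can be scored against the truth.

The flagship cohort (:func:`flagship_cohort`) has 14 samples of which 4 are
cases, 6 channels and 5 populations including one rare (1%) population, with
the case effect elevating a neutrophil-like population.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fcs import EventMatrix, SpilloverMatrix, write_fcs
from .gating import Gate, GatingStrategy
from .model import Experiment, FileGroup, Panel, Project, Subject
from .fcs import compensate

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "SyntheticSample",
    "generate_cohort",
    "flagship_cohort",
    "flagship_strategy",
    "cohort_to_project",
    "write_cohort",
]


@dataclass
class PopulationSpec:
    name: str
    mean: np.ndarray
    cov: np.ndarray
    frequency: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        cov = np.asarray(self.cov, float)
        if cov.ndim == 0:
            cov = np.eye(self.mean.size) * float(cov)
        elif cov.ndim == 1:
            cov = np.diag(cov)
        self.cov = cov
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ParameterError(f"population {self.name!r}: cov shape mismatch")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise ParameterError(f"population {self.name!r}: cov not positive "
                                 "definite")
        if not 0 < self.frequency <= 1:
            raise ParameterError(f"population {self.name!r}: frequency must be "
                                 "in (0, 1]")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    channels: List[str]
    populations: List[PopulationSpec]
    n_samples: int = 14
    n_cases: int = 4
    events_per_sample: int = 6000
    markers: Optional[List[str]] = None
    batch_shift_sd: float = 0.3       # tau: per-channel location shift SD
    batch_scale_sd: float = 0.08      # s: per-channel LogNormal scale SD
    frequency_dispersion: Optional[float] = 60.0  # Dirichlet concentration
    spillover: Optional[SpilloverMatrix] = None
    case_effect: Optional[Tuple[str, float]] = None  # (population, multiplier)
    seed: int = 42

    def __post_init__(self):
        freqs = np.array([p.frequency for p in self.populations])
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ParameterError(f"base frequencies sum to {freqs.sum()}, not 1")
        if self.case_effect is not None:
            name, mult = self.case_effect
            if name not in {p.name for p in self.populations}:
                raise ParameterError(f"case-effect population {name!r} unknown")
            if mult <= 0:
                raise ParameterError("case-effect multiplier must be > 0")
        if self.n_cases > self.n_samples:
            raise ParameterError("n_cases cannot exceed n_samples")
        for p in self.populations:
            if p.mean.size != len(self.channels):
                raise ParameterError(
                    f"population {p.name!r} mean has {p.mean.size} dims for "
                    f"{len(self.channels)} channels")
        if self.markers is None:
            self.markers = [""] * len(self.channels)


@dataclass
class SyntheticSample:
    sample_id: str
    subject_id: str
    observed: EventMatrix             # after batch perturbation and spillover
    true_labels: np.ndarray           # per-event population names
    true_frequencies: Dict[str, float]
    is_case: bool
    metadata: Dict[str, object] = field(default_factory=dict)


def _sample_frequencies(spec: CohortSpec, is_case: bool, rng) -> np.ndarray:
    freqs = np.array([p.frequency for p in spec.populations], float)
    if is_case and spec.case_effect is not None:
        name, mult = spec.case_effect
        i = [p.name for p in spec.populations].index(name)
        freqs[i] *= mult
        freqs /= freqs.sum()
    if spec.frequency_dispersion is not None:
        freqs = rng.dirichlet(freqs * spec.frequency_dispersion)
        freqs = np.clip(freqs, 1e-6, None)
        freqs /= freqs.sum()
    return freqs


def generate_cohort(spec: CohortSpec) -> List[SyntheticSample]:
    """Draw the full cohort; fully reproducible from ``spec.seed``."""
    master = np.random.SeedSequence(spec.seed)
    child_seeds = master.spawn(spec.n_samples)
    names = [p.name for p in spec.populations]
    samples = []
    for i in range(spec.n_samples):
        rng = np.random.default_rng(child_seeds[i])
        is_case = i < spec.n_cases
        freqs = _sample_frequencies(spec, is_case, rng)
        counts = rng.multinomial(spec.events_per_sample, freqs)
        blocks, labels = [], []
        for pop, c in zip(spec.populations, counts):
            if c == 0:
                continue
            blocks.append(rng.multivariate_normal(pop.mean, pop.cov, size=c))
            labels.extend([pop.name] * c)
        x = np.vstack(blocks)
        labels = np.array(labels)
        order = rng.permutation(x.shape[0])
        x, labels = x[order], labels[order]
        # per-sample affine batch perturbation per channel
        shift = rng.normal(0.0, spec.batch_shift_sd, size=len(spec.channels))
        scale = rng.lognormal(0.0, spec.batch_scale_sd, size=len(spec.channels))
        x = x * scale + shift
        # spillover mixing: observed = true @ S over the spillover channels
        if spec.spillover is not None:
            cols = [spec.channels.index(l) for l in spec.spillover.labels]
            x[:, cols] = x[:, cols] @ spec.spillover.S
        true_freq = {n: float((labels == n).sum()) / labels.size for n in names}
        samples.append(SyntheticSample(
            sample_id=f"sample_{i:02d}",
            subject_id=f"subject_{i:02d}",
            observed=EventMatrix(x, list(spec.channels), list(spec.markers)),
            true_labels=labels,
            true_frequencies=true_freq,
            is_case=is_case,
            metadata={
                "endpoint": "case" if is_case else "control",
                "age": float(np.round(rng.normal(60, 10), 1)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "batch_shift": shift.tolist(),
                "batch_scale": scale.tolist(),
            }))
    return samples


# ---------------------------------------------------------------------------
# Flagship cohort: the default study conditions used across the test suite


def _flagship_spillover(channels: Sequence[str]) -> SpilloverMatrix:
    k = len(channels)
    S = np.eye(k)
    rng = np.random.default_rng(7)
    for i in range(k):
        for j in range(k):
            if i != j and abs(i - j) == 1:
                S[i, j] = 0.02 + 0.04 * rng.random()  # neighbouring detectors
    return SpilloverMatrix(list(channels), S)


FLAGSHIP_CHANNELS = ["FL1", "FL2", "FL3", "FL4", "FL5", "FL6"]
FLAGSHIP_MARKERS = ["CD3", "CD4", "CD14", "Va7.2", "CD161", "CD45"]


def flagship_cohort(seed: int = 42, events_per_sample: int = 6000,
                    n_samples: int = 14, n_cases: int = 4) -> CohortSpec:
    """14 samples (4 cases), 6 channels, 5 populations incl. one at 1%.

    The populations are laid out so a three-gate threshold strategy can
    isolate each: FL1 separates T-like from non-T events, FL2 splits the
    T-like branch, and the FL4 x FL5 quadrants split the non-T branch into
    monocyte-like, neutrophil-like and a rare MAIT-like population.  Cases
    carry a 6x elevation of the neutrophil-like frequency (neutrophils are
    scarce in stable controls and dominate in acute infection).
    """
    hi, lo, sd = 3.2, 0.0, 0.5
    m = {
        #               FL1 FL2 FL3 FL4 FL5 FL6
        "tcell_cd4":   [hi, hi, lo, lo, lo, 3.0],
        "tcell_cd8":   [hi, lo, lo, lo, lo, 3.0],
        "monocyte":    [lo, lo, 1.0, hi, hi, 3.0],
        "neutrophil":  [lo, lo, 1.0, lo, lo, 3.0],
        "mait_like":   [lo, lo, 1.0, hi, lo, 3.0],
    }
    freqs = {"tcell_cd4": 0.34, "tcell_cd8": 0.31, "monocyte": 0.30,
             "neutrophil": 0.04, "mait_like": 0.01}
    pops = [PopulationSpec(n, m[n], np.eye(6) * sd ** 2, freqs[n])
            for n in m]
    return CohortSpec(
        channels=list(FLAGSHIP_CHANNELS),
        markers=list(FLAGSHIP_MARKERS),
        populations=pops,
        n_samples=n_samples, n_cases=n_cases,
        events_per_sample=events_per_sample,
        batch_shift_sd=0.3, batch_scale_sd=0.08,
        frequency_dispersion=60.0,
        spillover=_flagship_spillover(FLAGSHIP_CHANNELS),
        case_effect=("neutrophil", 12.0),
        seed=seed)


def flagship_strategy(search_grid: bool = True,
                      landmark_registration: bool = True) -> GatingStrategy:
    """Threshold-gate strategy recovering the five flagship populations."""
    grid = {"bandwidth": [0.5, 1.0]} if search_grid else None
    # the rare low-side peak of the myeloid quadrants needs a lower peak floor
    myeloid_grid = ({"bandwidth": [0.5, 1.0], "min_peak_threshold": [0.01, 0.05]}
                    if search_grid else None)
    strat = GatingStrategy("flagship")
    strat.add_gate(Gate(
        "gate_lineage", parent="root", dims=["FL1"], algorithm="threshold",
        hyperparameter_grid=grid, landmark_registration=landmark_registration,
        children={"+": "tcell", "-": "non_tcell"}))
    strat.add_gate(Gate(
        "gate_tcell_subset", parent="tcell", dims=["FL2"],
        algorithm="threshold", hyperparameter_grid=grid,
        landmark_registration=landmark_registration,
        children={"+": "tcell_cd4", "-": "tcell_cd8"}))
    strat.add_gate(Gate(
        "gate_myeloid", parent="non_tcell", dims=["FL4", "FL5"],
        algorithm="threshold", hyperparameter_grid=myeloid_grid,
        hyperparameters={"min_peak_threshold": 0.01},
        landmark_registration=landmark_registration,
        children={"++": "monocyte", "+-": "mait_like", "--": "neutrophil"}))
    return strat


# ---------------------------------------------------------------------------
# Bridging into the document model


def cohort_to_project(samples: Sequence[SyntheticSample], spec: CohortSpec,
                      project_name: str = "synthetic",
                      experiment_name: str = "panel_a",
                      compensate_on_entry: bool = True) -> Project:
    """Build a Project from generated samples, compensating at entry."""
    project = Project(project_name)
    panel = Panel(list(zip(spec.channels, spec.markers)))
    exp = project.add_experiment(Experiment(experiment_name, panel))
    for s in samples:
        project.add_subject(Subject(s.subject_id, dict(s.metadata)))
        em = s.observed
        if compensate_on_entry and spec.spillover is not None:
            em = compensate(em, spec.spillover)
        exp.add_filegroup(FileGroup(s.sample_id, s.subject_id, em))
    return project


def write_cohort(samples: Sequence[SyntheticSample], spec: CohortSpec,
                 out_dir) -> None:
    """Write FCS files, per-event truth CSVs and a tidy metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for s in samples:
        write_fcs(s.observed, out / f"{s.sample_id}.fcs",
                  spillover=spec.spillover)
        pd.DataFrame({"event": np.arange(s.true_labels.size),
                      "population": s.true_labels}).to_csv(
            out / f"{s.sample_id}_truth.csv", index=False)
        meta_rows.append({"sample_id": s.sample_id,
                          "subject_id": s.subject_id,
                          **{k: v for k, v in s.metadata.items()
                             if not isinstance(v, list)}})
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
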