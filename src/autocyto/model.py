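"""Document data model: project -> experiment -> subject -> sample -> populations.

A :class:`Project` houses :class:`Experiment` documents (staining conditions)
and :class:`Subject` documents (free-form metadata).  Each biological sample
is a :class:`FileGroup` holding the compensated primary event matrix, any
staining controls (e.g. FMO), and a tree of :class:`Population` documents.
Populations never copy event data: they record 0-based row indices into the
sample's primary matrix, along with the gate geometry and transforms under
which they were identified.

Persistence is a backend-agnostic contract (``put``/``get``/``delete``/
``list`` of JSON-like documents keyed by path) with two shipped backends:
:class:`MemoryStore` and :class:`JsonFileStore`.  ``load(save(p)) == p``
exactly, including population indices and gate definitions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .errors import (
    ContainmentError,
    MigrationError,
    NotFoundError,
    SchemaError,
    StructuralError,
)
from .fcs import EventMatrix
from .transforms import TransformSpec

SCHEMA_VERSION = 1

__all__ = [
    "Panel",
    "Subject",
    "Population",
    "FileGroup",
    "Experiment",
    "Project",
    "MemoryStore",
    "JsonFileStore",
]


@dataclass
class Panel:
    """Ordered (channel, marker) pairs; marker may be empty for scatter/time."""

    channels: List[tuple]

    def __post_init__(self):
        names = [c for c, _ in self.channels]
        if len(set(names)) != len(names):
            raise SchemaError("panel channel names must be unique")

    @property
    def channel_names(self) -> List[str]:
        return [c for c, _ in self.channels]

    def to_document(self):
        return {"channels": [[c, m] for c, m in self.channels]}

    @staticmethod
    def from_document(doc):
        return Panel([tuple(cm) for cm in doc["channels"]])


@dataclass
class Subject:
    subject_id: str
    metadata: Dict[str, object] = field(default_factory=dict)

    def to_document(self):
        return {"subject_id": self.subject_id, "metadata": dict(self.metadata)}

    @staticmethod
    def from_document(doc):
        return Subject(doc["subject_id"], dict(doc.get("metadata", {})))


@dataclass
class Population:
    """Named subset of a sample's events.

    ``index`` is a sorted array of unique 0-based row ids into the sample's
    primary event matrix; ``source`` records how the population was derived.
    """

    name: str
    parent: Optional[str]
    index: np.ndarray
    source: str = "gate"
    geometry: Optional[object] = None  # GateGeometry or None
    transform_record: Dict[str, TransformSpec] = field(default_factory=dict)

    def __post_init__(self):
        idx = np.asarray(self.index, dtype=np.int64)
        if idx.size and (np.any(np.diff(np.sort(idx)) == 0)):
            raise ContainmentError(f"population {self.name!r} has duplicate indices")
        self.index = np.sort(idx)
        if self.source not in ("gate", "classifier", "cluster", "root"):
            raise SchemaError(f"unknown population source {self.source!r}")

    @property
    def n(self) -> int:
        return int(self.index.size)

    def to_document(self):
        from .gating import GateGeometry  # local import to avoid cycle
        geom = self.geometry.to_document() if isinstance(self.geometry, GateGeometry) else None
        return {
            "name": self.name,
            "parent": self.parent,
            "index": self.index.tolist(),
            "source": self.source,
            "geometry": geom,
            "transform_record": {d: s.to_document()
                                 for d, s in self.transform_record.items()},
        }

    @staticmethod
    def from_document(doc):
        from .gating import GateGeometry
        geom = GateGeometry.from_document(doc["geometry"]) if doc.get("geometry") else None
        return Population(
            doc["name"], doc["parent"], np.asarray(doc["index"], dtype=np.int64),
            doc.get("source", "gate"), geom,
            {d: TransformSpec.from_document(s)
             for d, s in doc.get("transform_record", {}).items()})


class FileGroup:
    """All single-cell data and derived populations for one biological sample."""

    def __init__(self, sample_id: str, subject_id: Optional[str],
                 primary: EventMatrix,
                 controls: Optional[Dict[str, EventMatrix]] = None):
        self.sample_id = sample_id
        self.subject_id = subject_id
        self.primary = primary
        self.controls = dict(controls or {})
        root = Population("root", None, np.arange(primary.n_events), source="root")
        self.populations: Dict[str, Population] = {"root": root}

    # -- population tree -------------------------------------------------
    def add_population(self, pop: Population) -> "FileGroup":
        """Store ``pop``; parent must exist and contain ``pop.index``."""
        if pop.name == "root":
            raise StructuralError("cannot replace the root population")
        if pop.parent not in self.populations:
            raise StructuralError(
                f"parent population {pop.parent!r} not found for {pop.name!r}")
        parent = self.populations[pop.parent]
        if pop.index.size:
            if pop.index.min() < 0 or pop.index.max() >= self.primary.n_events:
                raise ContainmentError(f"population {pop.name!r} index out of range")
            if not np.isin(pop.index, parent.index).all():
                raise ContainmentError(
                    f"population {pop.name!r} is not contained in parent "
                    f"{pop.parent!r}")
        existing = self.populations.get(pop.name)
        if existing is not None and not (
                existing.parent == pop.parent
                and np.array_equal(existing.index, pop.index)):
            raise StructuralError(f"population {pop.name!r} already exists")
        self.populations[pop.name] = pop
        return self

    def remove_population(self, name: str) -> "FileGroup":
        """Delete a population and all of its descendants."""
        if name == "root":
            raise StructuralError("cannot delete the root population")
        if name not in self.populations:
            raise NotFoundError(f"population {name!r} not found")
        doomed = {name}
        changed = True
        while changed:
            changed = False
            for pop in self.populations.values():
                if pop.parent in doomed and pop.name not in doomed:
                    doomed.add(pop.name)
                    changed = True
        for n in doomed:
            del self.populations[n]
        return self

    def children_of(self, name: str) -> List[str]:
        return [p.name for p in self.populations.values() if p.parent == name]

    def population_data(self, name: str, channels: Optional[List[str]] = None
                        ) -> np.ndarray:
        """Event rows of a population, optionally restricted to channels."""
        if name not in self.populations:
            raise NotFoundError(f"population {name!r} not found")
        rows = self.populations[name].index
        if channels is None:
            return self.primary.values[rows]
        cols = [self.primary.column_index(c) for c in channels]
        return self.primary.values[np.ix_(rows, cols)]

    # -- serialization ----------------------------------------------------
    def to_document(self):
        return {
            "sample_id": self.sample_id,
            "subject_id": self.subject_id,
            "populations": {n: p.to_document() for n, p in self.populations.items()},
        }

    @staticmethod
    def from_document(doc, primary: EventMatrix,
                      controls: Optional[Dict[str, EventMatrix]] = None
                      ) -> "FileGroup":
        fg = FileGroup(doc["sample_id"], doc.get("subject_id"), primary, controls)
        fg.populations = {n: Population.from_document(p)
                          for n, p in doc["populations"].items()}
        return fg


class Experiment:
    """A set of staining conditions: a panel plus its FileGroups."""

    def __init__(self, name: str, panel: Panel):
        self.name = name
        self.panel = panel
        self.filegroups: Dict[str, FileGroup] = {}

    def add_filegroup(self, fg: FileGroup) -> "Experiment":
        if fg.primary.channel_names != self.panel.channel_names:
            raise SchemaError(
                f"sample {fg.sample_id!r} channels do not match panel")
        if fg.sample_id in self.filegroups:
            raise StructuralError(f"sample {fg.sample_id!r} already registered")
        self.filegroups[fg.sample_id] = fg
        return self


class Project:
    def __init__(self, name: str):
        self.name = name
        self.experiments: Dict[str, Experiment] = {}
        self.subjects: Dict[str, Subject] = {}

    def add_experiment(self, exp: Experiment) -> Experiment:
        if exp.name in self.experiments:
            raise StructuralError(f"experiment {exp.name!r} already exists")
        self.experiments[exp.name] = exp
        return exp

    def add_subject(self, subject: Subject) -> Subject:
        if subject.subject_id in self.subjects:
            raise StructuralError(f"subject {subject.subject_id!r} already exists")
        self.subjects[subject.subject_id] = subject
        return subject

    # -- persistence ------------------------------------------------------
    def save(self, store) -> None:
        store.put(f"{self.name}/project.json", {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "experiments": sorted(self.experiments),
            "subjects": [s.to_document() for _, s in sorted(self.subjects.items())],
        })
        for ename, exp in self.experiments.items():
            store.put(f"{self.name}/experiments/{ename}.json", {
                "name": ename,
                "panel": exp.panel.to_document(),
                "filegroups": sorted(exp.filegroups),
            })
            for sid, fg in exp.filegroups.items():
                doc = fg.to_document()
                base = f"{self.name}/experiments/{ename}/filegroups/{sid}"
                doc["primary"] = store.put_matrix(f"{base}/primary", fg.primary)
                doc["controls"] = {c: store.put_matrix(f"{base}/control_{c}", m)
                                   for c, m in fg.controls.items()}
                store.put(f"{base}.json", doc)

    @staticmethod
    def load(name: str, store) -> "Project":
        doc = store.get(f"{name}/project.json")
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise MigrationError(
                f"schema version {doc.get('schema_version')} != {SCHEMA_VERSION}")
        project = Project(doc["name"])
        for sdoc in doc["subjects"]:
            project.add_subject(Subject.from_document(sdoc))
        for ename in doc["experiments"]:
            edoc = store.get(f"{name}/experiments/{ename}.json")
            exp = Experiment(ename, Panel.from_document(edoc["panel"]))
            for sid in edoc["filegroups"]:
                base = f"{name}/experiments/{ename}/filegroups/{sid}"
                fdoc = store.get(f"{base}.json")
                primary = store.get_matrix(fdoc["primary"])
                controls = {c: store.get_matrix(ref)
                            for c, ref in fdoc.get("controls", {}).items()}
                exp.add_filegroup(FileGroup.from_document(fdoc, primary, controls))
            project.experiments[ename] = exp
        return project


# ---------------------------------------------------------------------------
# Persistence backends


class MemoryStore:
    """Dict-backed store; documents are round-tripped through JSON for parity
    with the on-disk backend."""

    def __init__(self):
        self._docs: Dict[str, str] = {}
        self._matrices: Dict[str, EventMatrix] = {}

    def put(self, key: str, doc: dict) -> None:
        self._docs[key] = json.dumps(doc, sort_keys=True)

    def get(self, key: str) -> dict:
        if key not in self._docs:
            raise NotFoundError(f"document {key!r} not found")
        return json.loads(self._docs[key])

    def put_matrix(self, key: str, m: EventMatrix) -> str:
        self._matrices[key] = m.copy()
        return key

    def get_matrix(self, key: str) -> EventMatrix:
        if key not in self._matrices:
            raise NotFoundError(f"matrix {key!r} not found")
        return self._matrices[key].copy()

    def list(self, prefix: str = "") -> List[str]:
        return sorted(k for k in self._docs if k.startswith(prefix))


class JsonFileStore:
    """Documents as JSON files under a root directory; event matrices as CSV
    sidecars referenced by relative path."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, key: str) -> Path:
        return self.root / key

    def put(self, key: str, doc: dict) -> None:
        p = self._path(key)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(doc, sort_keys=True, indent=1))

    def get(self, key: str) -> dict:
        p = self._path(key)
        if not p.exists():
            raise NotFoundError(f"document {key!r} not found")
        return json.loads(p.read_text())

    def put_matrix(self, key: str, m: EventMatrix) -> str:
        rel = key + ".csv"
        p = self._path(rel)
        p.parent.mkdir(parents=True, exist_ok=True)
        header = ",".join(m.channel_names) + "\n" + ",".join(m.marker_names)
        np.savetxt(p, m.values, delimiter=",", header=header, comments="#",
                   fmt="%.17g")
        return rel

    def get_matrix(self, ref: str) -> EventMatrix:
        p = self._path(ref)
        if not p.exists():
            raise NotFoundError(f"matrix {ref!r} not found")
        with open(p) as fh:
            channels = fh.readline().lstrip("#").strip().split(",")
            markers = fh.readline().lstrip("#").strip().split(",")
            values = np.loadtxt(fh, delimiter=",", ndmin=2)
        if values.size == 0:
            values = values.reshape(0, len(channels))
        markers = [m if m else "" for m in markers]
        return EventMatrix(values, channels, markers)

    def list(self, prefix: str = "") -> List[str]:
        return sorted(str(p.relative_to(self.root)) for p in self.root.rglob("*.json")
                      if str(p.relative_to(self.root)).startswith(prefix))
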