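"""End-to-end pipeline runner.

Wires the modules into the recommended workflow — synthesise/import ->
autonomous gating -> batch report -> per-sample clustering + meta-clustering
-> feature extraction — driven by a validated configuration mapping and a
single global seed from which each step derives its own (stable, name-hashed)
seed.  Each step's outputs are committed to the store/output directory and a
machine-readable run log (step, params, seed, duration, warnings) is written.
Steps are independently invocable through the CLI; the pipeline runner is
convenience sugar over the same functions.
"""
from __future__ import annotations

import json
import time
import zlib
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import batch as batch_mod
from . import clustering as clustering_mod
from . import features as features_mod
from .errors import SchemaError
from .model import JsonFileStore
from .synthetic import (
    cohort_to_project,
    flagship_cohort,
    flagship_strategy,
    generate_cohort,
    write_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "step_seed", "gate_cohort_recovery"]

_ALLOWED_KEYS = {
    "out_dir", "seed", "events_per_sample", "n_samples", "n_cases",
    "hyperparameter_search", "landmark_registration", "cluster_plugin",
    "n_clusters", "lisi_k", "store", "verbosity",
}


def step_seed(global_seed: int, step: str) -> int:
    """Stable per-step seed derived from the global seed and step name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(step.encode())) % (2 ** 31)


class RunConfig(dict):
    """Validated pipeline configuration (plain mapping with schema check)."""

    def __init__(self, mapping: Optional[dict] = None, **kwargs):
        merged = dict(mapping or {})
        merged.update(kwargs)
        unknown = set(merged) - _ALLOWED_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        merged.setdefault("seed", 42)
        merged.setdefault("out_dir", "autocyto_run")
        merged.setdefault("events_per_sample", 6000)
        merged.setdefault("n_samples", 14)
        merged.setdefault("n_cases", 4)
        merged.setdefault("hyperparameter_search", True)
        merged.setdefault("landmark_registration", True)
        merged.setdefault("cluster_plugin", "kmeans")
        merged.setdefault("n_clusters", 5)
        merged.setdefault("lisi_k", 90)
        super().__init__(merged)


def gate_cohort_recovery(samples, spec, search: bool = True,
                         register: bool = True, seed: int = 42):
    """Fit the flagship strategy on the first sample, apply to the cohort and
    score recovered population fractions against ground truth.

    Returns ``(project, recovery DataFrame, pearson_r)`` where the DataFrame
    holds one row per (sample, population) with true and recovered fractions.
    """
    project = cohort_to_project(samples, spec)
    exp = next(iter(project.experiments.values()))
    strategy = flagship_strategy(search_grid=search,
                                 landmark_registration=register)
    fgs = [exp.filegroups[s.sample_id] for s in samples]
    strategy.fit(fgs[0], seed=seed)
    for fg in fgs[1:]:
        strategy.apply(fg, search=search, register_landmarks=register,
                       seed=seed)
    pop_names = [p.name for p in spec.populations]
    rows = []
    for s, fg in zip(samples, fgs):
        n = fg.primary.n_events
        for p in pop_names:
            rec = fg.populations[p].n / n if p in fg.populations else 0.0
            rows.append({"sample_id": s.sample_id, "population": p,
                         "true_fraction": s.true_frequencies[p],
                         "recovered_fraction": rec})
    df = pd.DataFrame(rows)
    r = float(pearsonr(df["true_fraction"], df["recovered_fraction"])[0])
    return project, df, r


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full workflow on the flagship synthetic cohort.

    Returns a summary dict (also written as ``run_log.json`` in the output
    directory) and writes the feature CSV, recovery CSV and LISI report.
    A failing step raises, naming the step.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log: List[dict] = []
    summary: Dict[str, object] = {"steps": log, "seed": config["seed"]}

    def run_step(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn(step_seed(config["seed"], name))
        except Exception as exc:
            log.append({"step": name, "status": "failed", "error": str(exc)})
            _write_log(out, summary)
            raise RuntimeError(f"pipeline step {name!r} failed: {exc}") from exc
        log.append({"step": name, "status": "ok",
                    "seed": step_seed(config["seed"], name),
                    "duration_s": round(time.perf_counter() - t0, 3)})
        return result

    # 1. synthesise cohort
    def _synth(seed):
        spec = flagship_cohort(seed=seed,
                               events_per_sample=config["events_per_sample"],
                               n_samples=config["n_samples"],
                               n_cases=config["n_cases"])
        return spec, generate_cohort(spec)
    spec, samples = run_step("synth", _synth)
    write_cohort(samples, spec, out / "cohort")

    # 2. autonomous gating with recovery scoring
    def _gate(seed):
        return gate_cohort_recovery(
            samples, spec, search=config["hyperparameter_search"],
            register=config["landmark_registration"], seed=seed)
    project, recovery, r = run_step("gate", _gate)
    recovery.to_csv(out / "gating_recovery.csv", index=False)
    summary["gating_recovery_pearson_r"] = r

    exp = next(iter(project.experiments.values()))
    fgs = {sid: fg for sid, fg in exp.filegroups.items()}

    # 3. batch report: reference selection + LISI on the T-cell branch
    def _batch(seed):
        slices = {sid: fg.population_data("tcell", ["FL2", "FL3"])
                  for sid, fg in fgs.items() if "tcell" in fg.populations}
        assess = batch_mod.select_reference(slices)
        pooled = np.vstack(list(slices.values()))
        labels = np.concatenate([[sid] * v.shape[0]
                                 for sid, v in slices.items()])
        k = min(config["lisi_k"], pooled.shape[0] - 1)
        assess.lisi_before = batch_mod.lisi(pooled, labels, k=k)
        assess.k_neighbors = k
        return assess
    assess = run_step("batch_report", _batch)
    summary["reference_sample"] = str(assess.reference_sample_id)
    summary["median_lisi"] = float(np.median(assess.lisi_before))

    # 4. per-sample clustering + meta-clustering
    def _cluster(seed):
        results = []
        for sid, fg in sorted(fgs.items()):
            res = clustering_mod.cluster_sample(
                fg.primary.values, config["cluster_plugin"],
                {"n_clusters": config["n_clusters"]}, seed=seed,
                sample_id=sid, dims=fg.primary.channel_names)
            clustering_mod.clusters_to_populations(fg, res, parent="root")
            results.append(res)
        meta = clustering_mod.meta_cluster(
            results, "kmeans", {"n_clusters": config["n_clusters"]}, seed=seed)
        for sid, fg in sorted(fgs.items()):
            clustering_mod.clusters_to_populations(fg, meta, parent="root")
        return meta
    meta = run_step("cluster", _cluster)
    summary["n_meta_clusters"] = len(meta.meta_ids)

    # 5. feature extraction
    def _features(seed):
        pop_names = [p.name for p in spec.populations]
        ft = features_mod.extract_features(
            project, next(iter(project.experiments)), pop_names,
            statistics=("fraction_of_root",),
            metadata_covariates=("age",))
        return ft
    ft = run_step("features", _features)
    ft.to_csv(out / "features.csv")
    summary["n_features"] = len(ft.feature_names)

    if config.get("store"):
        project.save(JsonFileStore(config["store"]))

    _write_log(out, summary)
    return summary


def _write_log(out: Path, summary: dict) -> None:
    (out / "run_log.json").write_text(json.dumps(summary, indent=1))
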