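"""Reproducible end-to-end runs: simulate -> classify -> counts -> trajectory.

Every stage reads and writes plain files under the output directory, so
intermediates are auditable and no stage can mutate another's inputs.
Re-running with the same configuration reproduces all artifacts
bit-exactly. The run report (JSON) records every resolved parameter, seeds
and per-stage cell counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    DEFAULT_HIGH_PERCENTILE,
    DEFAULT_LOW_PERCENTILE,
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_N_BINS,
    classify_events,
    default_population_rules,
    rules_from_dict,
)
from .counts import cohort_count_table
from .diffusion import DiffusionParams
from .exceptions import ConfigError, CytotrajectError
from .io_cytometry import EventTable, SampleMeta, write_event_table
from .synthetic_data import default_sim_config, simulate_cohort
from .trajectory import (
    DEFAULT_STEP_FRAC,
    DEFAULT_SUBSAMPLE_CAP,
    DEFAULT_TOP_DCS,
    DEFAULT_WINDOW_FRAC,
    run_patient_trajectory,
)

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["patient_id", "timepoint_months", "wbc_count",
                    "neutrophil_count"]


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    n_patients: int = 3
    cells_per_sample: int = 1000
    seed: int = 0
    cofactor: float = 5.0
    classify_method: str = "tsne"
    classify_seed: int = 0
    n_bins: int = DEFAULT_N_BINS
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE
    high_percentile: float = DEFAULT_HIGH_PERCENTILE
    low_percentile: float = DEFAULT_LOW_PERCENTILE
    population_rules: dict | None = None      # None -> canonical defaults
    diffusion: dict = field(default_factory=dict)
    window_frac: float = DEFAULT_WINDOW_FRAC
    step_frac: float = DEFAULT_STEP_FRAC
    n_top_dcs: int = DEFAULT_TOP_DCS
    subsample_cap: int = DEFAULT_SUBSAMPLE_CAP
    trajectory_populations: tuple = ("B", "NK", "basophil")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "trajectory_populations" in raw:
            raw["trajectory_populations"] = tuple(raw["trajectory_populations"])
        return cls(**raw)

    def rules(self):
        if self.population_rules is None:
            return default_population_rules()
        return rules_from_dict(self.population_rules)

    def diffusion_params(self) -> DiffusionParams:
        return DiffusionParams(seed=self.seed, **self.diffusion)


def write_clinical_csv(metas, path) -> None:
    pd.DataFrame(
        [(m.patient_id, m.timepoint_months, m.wbc_count, m.neutrophil_count)
         for m in metas],
        columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def read_clinical_csv(path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path} missing columns: {sorted(missing)}")
    return [SampleMeta(str(r.patient_id), float(r.timepoint_months),
                       float(r.wbc_count), float(r.neutrophil_count))
            for r in df.itertuples()]


def _sample_name(patient: str, tp: float) -> str:
    return f"{patient}_t{tp:g}"


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_full(config: RunConfig, out_dir) -> dict:
    """Execute the whole pipeline under ``out_dir``; returns the run report."""
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    # -- stage 1: synthetic cohort -------------------------------------
    sim = default_sim_config(n_patients=config.n_patients,
                             cells_per_sample=config.cells_per_sample,
                             seed=config.seed)
    tables, metas, truth = simulate_cohort(sim)
    cohort_dir = os.path.join(out_dir, "cohort")
    os.makedirs(cohort_dir, exist_ok=True)
    for (patient, tp), events in tables.items():
        write_event_table(events, os.path.join(
            cohort_dir, _sample_name(patient, tp) + ".csv"))
    write_clinical_csv(metas, os.path.join(out_dir, "clinical.csv"))
    truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    report["stages"]["simulate"] = {
        "n_samples": len(tables),
        "cells_per_sample": config.cells_per_sample,
        "n_cells_total": int(sum(t.n_cells for t in tables.values())),
    }

    # -- stage 2: classification (pooled per patient) ------------------
    rules = config.rules()
    labeled: dict = {}
    patients = sorted({p for p, _ in tables})
    for patient in patients:
        tps = sorted(tp for p, tp in tables if p == patient)
        pooled = EventTable(
            np.vstack([tables[(patient, tp)].intensities for tp in tps]),
            sim.panel,
            pd.concat([tables[(patient, tp)].annotations for tp in tps],
                      ignore_index=True),
            tables[(patient, tps[0])].transform_state)
        pooled_labeled = classify_events(
            pooled, rules, method=config.classify_method,
            seed=config.classify_seed, n_bins=config.n_bins,
            min_prominence_frac=config.min_prominence_frac,
            high_percentile=config.high_percentile,
            low_percentile=config.low_percentile)
        offset = 0
        for tp in tps:
            n = tables[(patient, tp)].n_cells
            labeled[(patient, tp)] = pooled_labeled.select(
                np.arange(offset, offset + n))
            offset += n
    labeled_dir = os.path.join(out_dir, "labeled")
    os.makedirs(labeled_dir, exist_ok=True)
    for (patient, tp), events in labeled.items():
        write_event_table(events, os.path.join(
            labeled_dir, _sample_name(patient, tp) + ".csv"))
    label_counts = pd.concat(
        [t.annotations for t in labeled.values()], ignore_index=True)[
        "population"].value_counts().to_dict()
    report["stages"]["classify"] = {
        "method": config.classify_method,
        "label_counts": {str(k): int(v) for k, v in sorted(label_counts.items())},
    }

    # -- stage 3: absolute counts --------------------------------------
    count_table = cohort_count_table(list(labeled.values()), metas)
    count_table.to_csv(os.path.join(out_dir, "counts.csv"), index=False)
    report["stages"]["counts"] = {"n_rows": int(len(count_table))}

    # -- stage 4: trajectories -----------------------------------------
    traj_dir = os.path.join(out_dir, "trajectories")
    os.makedirs(traj_dir, exist_ok=True)
    traj_reports = {}
    for patient in patients:
        patient_tables = [labeled[(patient, tp)]
                          for p, tp in sorted(tables) if p == patient]
        for population in config.trajectory_populations:
            try:
                run = run_patient_trajectory(
                    patient_tables, population,
                    params=config.diffusion_params(),
                    window_frac=config.window_frac,
                    step_frac=config.step_frac,
                    n_top_dcs=config.n_top_dcs,
                    subsample_cap=config.subsample_cap)
            except CytotrajectError as exc:
                raise type(exc)(
                    f"trajectory stage failed for {patient}/{population}: "
                    f"{exc}") from exc
            prefix = os.path.join(traj_dir, f"{patient}_{population}")
            run.ranking.table.to_csv(prefix + "_ranking.csv", index=False)
            for prof in run.profiles:
                prof.bins.to_csv(
                    f"{prefix}_DC{prof.dc_index}_profile.csv", index=False)
            _write_json(run.report, prefix + "_report.json")
            traj_reports[f"{patient}/{population}"] = {
                "top_dcs": run.report["top_dcs"],
                "pseudotime_dc": run.report["pseudotime_dc"],
                "n_cells_merged": run.report["n_cells_merged"],
            }
    report["stages"]["trajectory"] = traj_reports

    _write_json(report, os.path.join(out_dir, "run_report.json"))
    return report


def artifact_checksums(out_dir) -> dict[str, str]:
    """SHA-256 of every file under ``out_dir`` (relative path -> digest)."""
    sums = {}
    for root, _, files in os.walk(out_dir):
        for name in sorted(files):
            path = os.path.join(root, name)
            rel = os.path.relpath(path, out_dir)
            with open(path, "rb") as fh:
                sums[rel] = hashlib.sha256(fh.read()).hexdigest()
    return sums
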