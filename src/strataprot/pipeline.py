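"""End-to-end orchestration: simulate -> preprocess -> differential
abundance -> panels -> sample-size -> survival -> enrichment.

One ``RunConfig`` and one integer seed drive the whole run; per-stage
seeds are derived deterministically from the global seed and the stage
name, so any stage can be rerun in isolation with the same stream.
Stages communicate only through files in the run directory; a manifest
records the config hash, seed, per-stage status and row counts. A stage
failure is recorded and later independent stages are still attempted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparisons import full_comparison_plan
from .data_io import (join_matrix_metadata, read_abundance, read_annotation,
                      read_metadata, write_abundance, write_annotation,
                      write_metadata, write_table)
from .diffabund import run_all_comparisons
from .enrichment import hypergeom_ora, top_terms
from .panels import DEFAULT_SIZES, build_panel, sample_size_curve
from .preprocess import filter_by_group_presence, log2_transform, median_center
from .survival import all_survival_tasks, screen_proteome
from .synthetic_data import (SurvivalConfig, desk_shape, generate_cohort,
                             reference_cohort_shape, standard_planted_effects,
                             synthetic_annotation)

logger = logging.getLogger("strataprot")

STAGES = ("simulate", "preprocess", "diffabund", "panels", "samplesize",
          "survival", "enrichment")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (global seed + stage-name hash)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Every tunable of a pipeline run; keys mirror the YAML config one-to-one."""

    # inputs; leave paths None to simulate a cohort instead
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    matrix_format: str = "wide"
    shape: str = "desk"  # simulated cohort shape: desk | full
    n_proteins: int = 200
    plant_defaults: bool = True  # plant the standard recoverable effect battery
    # preprocessing
    min_fraction: float = 0.7
    median_center: bool = False
    # differential abundance
    fdr: float = 0.05
    fc: float = 1.5
    fc_scale: str = "linear"
    min_side: int = 3
    # panels
    cap: int = 5
    tolerance: float = 0.01
    train_fraction: float = 0.8
    panel_kinds: tuple[str, ...] = ("one_vs_rest", "pairwise")
    # sample-size simulation
    reps: int = 200
    sizes: tuple[int, ...] = DEFAULT_SIZES
    size_train_fraction: float = 0.7
    # survival
    boot: int = 1000
    boot_p: float = 0.2
    endpoints: tuple[str, ...] = ("os", "dss")
    abundance_coding: str = "dichotomized_median"
    # bootstrap FDR-passers only by default (final calls identical: the
    # composite rule requires FDR < threshold anyway); raise to bootstrap all
    boot_all_threshold: int = 0
    # enrichment
    top_terms: int = 5
    # stage toggles
    run_panels: bool = True
    run_samplesize: bool = True
    run_survival: bool = True
    run_enrichment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1 and 0 < self.boot_p <= 1):
            raise ValueError("fdr and boot_p must be in (0, 1)")
        if self.cap < 1 or self.tolerance < 0 or self.reps < 1:
            raise ValueError("cap >= 1, tolerance >= 0, reps >= 1 required")
        self.sizes = tuple(sorted(int(s) for s in self.sizes))
        self.panel_kinds = tuple(self.panel_kinds)
        self.endpoints = tuple(self.endpoints)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every enabled stage; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "version": __version__,
        "lib_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }

    t_last = time.monotonic()

    def record(stage: str, status: str, **info) -> None:
        nonlocal t_last
        now = time.monotonic()
        manifest["stages"][stage] = {"status": status,
                                     "seconds": round(now - t_last, 2), **info}
        t_last = now
        logger.info("stage %s: %s (%.2fs)", stage, status,
                    manifest["stages"][stage]["seconds"])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    # ---- simulate / load -----------------------------------------------------
    matrix = meta = annotation = None
    try:
        if config.matrix_path:
            matrix = read_abundance(config.matrix_path, format=config.matrix_format)
            meta = read_metadata(config.metadata_path)
            matrix, meta = join_matrix_metadata(matrix, meta)
            if config.annotation_path:
                annotation = read_annotation(config.annotation_path)
            record("simulate", "skipped", note="external inputs supplied")
        else:
            sim_seed = stage_seed(config.seed, "simulate")
            shape_fn = reference_cohort_shape if config.shape == "full" else desk_shape
            kw = {}
            if config.plant_defaults:
                da_eff, hz_eff = standard_planted_effects(config.n_proteins)
                kw = {"planted_da": da_eff, "survival": SurvivalConfig(planted=hz_eff)}
            sim = shape_fn(n_proteins=config.n_proteins, seed=sim_seed, **kw)
            matrix, meta, truth = generate_cohort(sim)
            annotation = synthetic_annotation(matrix.protein_ids, seed=sim_seed)
            write_abundance(matrix, out / "matrix_raw.tsv")
            write_metadata(meta, out / "metadata.tsv")
            write_annotation(annotation, out / "annotation.tsv")
            write_table(truth.da_effects, out / "truth_da_effects.tsv")
            write_table(truth.hazard_effects, out / "truth_hazard_effects.tsv")
            record("simulate", "complete", n_proteins=matrix.n_proteins,
                   n_samples=matrix.n_samples)
    except Exception as exc:
        record("simulate", "failed", error=str(exc))
        raise  # nothing downstream can run without inputs

    # ---- preprocess -----------------------------------------------------------
    try:
        filtered, report = filter_by_group_presence(matrix, meta,
                                                    min_fraction=config.min_fraction)
        log2m = log2_transform(filtered) if filtered.scale == "raw" else filtered
        if config.median_center:
            log2m = median_center(log2m)
        write_abundance(log2m, out / "matrix_log2_filtered.tsv")
        write_table(report.to_frame(), out / "filter_report.tsv")
        record("preprocess", "complete", n_before=report.n_before,
               n_after=report.n_after)
    except Exception as exc:
        record("preprocess", "failed", error=str(exc))
        raise

    # ---- differential abundance ----------------------------------------------
    da_tables: dict[str, pd.DataFrame] = {}
    plan = full_comparison_plan()
    try:
        da_tables, summary = run_all_comparisons(
            log2m, meta, plan, fdr_threshold=config.fdr, fc_threshold=config.fc,
            fc_scale=config.fc_scale, min_side=config.min_side)
        da_dir = out / "da"
        da_dir.mkdir(exist_ok=True)
        for label, tbl in da_tables.items():
            write_table(tbl, da_dir / f"{label}.tsv")
        write_table(summary, da_dir / "summary.tsv")
        record("diffabund", "complete", n_comparisons=len(da_tables),
               n_daps_total=int(summary["n_dap"].sum()))
    except Exception as exc:
        record("diffabund", "failed", error=str(exc))
        summary = None

    # ---- panels ----------------------------------------------------------------
    panels = {}
    if config.run_panels and da_tables:
        try:
            pdir = out / "panels"
            pdir.mkdir(exist_ok=True)
            rows = []
            panel_seed = stage_seed(config.seed, "panels")
            for spec in plan:
                if spec.kind not in config.panel_kinds or spec.label not in da_tables:
                    continue
                model = build_panel(log2m, meta, spec, da_tables[spec.label],
                                    cap=config.cap, tolerance=config.tolerance,
                                    train_fraction=config.train_fraction,
                                    seed=panel_seed)
                if model is None:
                    continue
                panels[spec.label] = model
                write_table(model.to_frame(), pdir / f"{spec.label}_panel.tsv")
                write_table(model.roc_points, pdir / f"{spec.label}_roc.tsv")
                rows.append((spec.label, len(model.selected), model.auc,
                             model.sensitivity, model.specificity))
            write_table(pd.DataFrame(rows, columns=["comparison", "panel_size",
                                                    "auc", "sensitivity",
                                                    "specificity"]),
                        pdir / "summary.tsv")
            record("panels", "complete", n_panels=len(panels))
        except Exception as exc:
            record("panels", "failed", error=str(exc))
    else:
        record("panels", "skipped",
               note="disabled" if not config.run_panels else "no DA tables")

    # ---- sample-size curves -----------------------------------------------------
    if config.run_samplesize and panels:
        try:
            sdir = out / "samplesize"
            sdir.mkdir(exist_ok=True)
            ss_seed = stage_seed(config.seed, "samplesize")
            n_curves = 0
            for spec in plan:
                if spec.label not in panels:
                    continue
                model = panels[spec.label]
                target, reference = spec.resolve(meta)
                X = log2m.values.loc[model.selected, target + reference].T
                y = np.r_[np.ones(len(target)), np.zeros(len(reference))]
                curve = sample_size_curve(X, y, model.selected, sizes=config.sizes,
                                          reps=config.reps,
                                          train_fraction=config.size_train_fraction,
                                          seed=ss_seed)
                write_table(curve, sdir / f"{spec.label}_sizes.tsv")
                n_curves += 1
            record("samplesize", "complete", n_curves=n_curves)
        except Exception as exc:
            record("samplesize", "failed", error=str(exc))
    else:
        record("samplesize", "skipped",
               note="disabled" if not config.run_samplesize else "no panels")

    # ---- survival ---------------------------------------------------------------
    screens: dict[str, pd.DataFrame] = {}
    if config.run_survival:
        try:
            vdir = out / "survival"
            vdir.mkdir(exist_ok=True)
            surv_seed = stage_seed(config.seed, "survival")
            rows = []
            for task in all_survival_tasks(config.endpoints):
                tbl = screen_proteome(log2m, meta, task, fdr_threshold=config.fdr,
                                      boot_threshold=config.boot_p, B=config.boot,
                                      seed=surv_seed,
                                      abundance_coding=config.abundance_coding,
                                      bootstrap_all_threshold=config.boot_all_threshold)
                screens[task.label] = tbl
                write_table(tbl, vdir / f"{task.label}.tsv")
                rows.append((task.label, len(tbl),
                             int((tbl["call"] != "ns").sum()) if len(tbl) else 0))
            write_table(pd.DataFrame(rows, columns=["task", "n_fitted",
                                                    "n_significant"]),
                        vdir / "summary.tsv")
            record("survival", "complete", n_tasks=len(screens))
        except Exception as exc:
            record("survival", "failed", error=str(exc))
    else:
        record("survival", "skipped", note="disabled")

    # ---- enrichment ----------------------------------------------------------------
    if config.run_enrichment and screens and annotation is not None:
        try:
            edir = out / "enrichment"
            edir.mkdir(exist_ok=True)
            universe = set(log2m.protein_ids)
            n_runs = 0
            for label, tbl in screens.items():
                for direction in ("decreased_risk", "increased_risk"):
                    hits = set(tbl.loc[tbl["call"] == direction, "protein_id"]) \
                        if len(tbl) else set()
                    if not hits:
                        continue
                    terms = hypergeom_ora(hits, universe, annotation)
                    write_table(terms, edir / f"{label}_{direction}.tsv")
                    tops = top_terms(terms, k=config.top_terms,
                                     fdr_threshold=config.fdr)
                    write_table(tops, edir / f"{label}_{direction}_top.tsv")
                    n_runs += 1
            record("enrichment", "complete", n_runs=n_runs)
        except Exception as exc:
            record("enrichment", "failed", error=str(exc))
    elif config.run_enrichment and not screens:
        record("enrichment", "skipped",
               note="survival stage disabled or empty: no prognostic hit sets "
                    "to enrich")
    elif config.run_enrichment:
        record("enrichment", "skipped", note="no annotation supplied")
    else:
        record("enrichment", "skipped", note="disabled")

    return manifest
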