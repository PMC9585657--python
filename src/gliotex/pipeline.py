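"""End-to-end orchestration: phantom or manifest → features → grid report.

A single JSON config drives the run; unknown keys are rejected so typos
cannot silently change a study. All randomness fans out from one
pipeline-level seed (phantom generation, fold assignment, penalty CV),
making every report replayable. ``model_grid`` sweeps the configured
{analysis mode} x {sequence} x {kernel} x {validation scheme} grid and
emits one AUC/accuracy row per cell.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as gio
from .features import ExtractionConfig, extract_feature_vector, feature_names
from .model import KERNELS, CVResult, crossvalidate
from .phantom import PhantomCohort, PhantomSpec, generate_phantom_cohort
from .sampling import aggregate_multislice, enumerate_slice_instances, group_aware_split

logger = logging.getLogger(__name__)

SEQUENCE_CHOICES = ("T1C", "T2", "T1C+T2")
MODE_CHOICES = ("single_slice", "multislice")


@dataclasses.dataclass
class PipelineConfig:
    """Normalized configuration of one pipeline run (defaults = study grid)."""

    manifest: str | None = None          # path to a cohort manifest CSV, or
    phantom: dict | None = None          # kwargs for PhantomSpec (one of the two)
    ssf_levels: tuple = (0, 2, 3, 4, 5, 6)
    ng: int = 64
    glcm_distances: tuple = (1, 4)
    min_roi_pixels: int = 16
    modes: tuple = ("multislice",)
    sequences: tuple = ("T1C+T2",)
    kernels: tuple = ("quadratic",)
    validation: tuple = ("cv10",)
    C: float = 1.0
    lambda_grid_size: int = 40
    select: bool = True
    global_selection: bool = False
    grouped_slices: bool = True
    seed: int = 0
    outdir: str = "gliotex_out"

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            ssf_levels=tuple(self.ssf_levels),
            ng=self.ng,
            glcm_distances=tuple(self.glcm_distances),
            min_roi_pixels=self.min_roi_pixels,
        )


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}
_TUPLE_FIELDS = ("ssf_levels", "glcm_distances", "modes", "sequences", "kernels", "validation")


def validate_config(doc: dict | str | Path) -> PipelineConfig:
    """Normalize a config dict or JSON file path; strict about unknown keys."""
    if not isinstance(doc, dict):
        with open(doc) as fh:
            doc = json.load(fh)
    unknown = set(doc) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**doc)
    for name in _TUPLE_FIELDS:
        setattr(cfg, name, tuple(getattr(cfg, name)))
    if cfg.manifest is None and cfg.phantom is None:
        raise ValueError("config needs either 'manifest' or 'phantom'")
    if cfg.manifest is not None and cfg.phantom is not None:
        raise ValueError("config must give only one of 'manifest' and 'phantom'")
    if cfg.ng < 2:
        raise ValueError(f"ng must be >= 2, got {cfg.ng}")
    if cfg.C <= 0:
        raise ValueError(f"C must be positive, got {cfg.C}")
    for k in cfg.kernels:
        if k not in KERNELS:
            raise ValueError(f"unknown kernel {k!r}; expected one of {KERNELS}")
    for m in cfg.modes:
        if m not in MODE_CHOICES:
            raise ValueError(f"unknown mode {m!r}; expected one of {MODE_CHOICES}")
    for s in cfg.sequences:
        if s not in SEQUENCE_CHOICES:
            raise ValueError(f"unknown sequence {s!r}; expected one of {SEQUENCE_CHOICES}")
    for v in cfg.validation:
        if not (v.startswith("cv") or v.startswith("holdout:")):
            raise ValueError(f"unknown validation scheme {v!r}")
    return cfg


# ---------------------------------------------------------------------------
# feature extraction over a cohort
# ---------------------------------------------------------------------------

def _load_cohort_from_manifest(manifest_path: str | Path):
    manifest = gio.read_manifest(manifest_path)
    for _, row in manifest.iterrows():
        volumes = {
            "T1C": gio.read_volume(row["path_t1c"], "T1C"),
            "T2": gio.read_volume(row["path_t2w"], "T2"),
        }
        mask = gio.read_mask(row["path_mask"])
        yield str(row["patient_id"]), volumes, mask, str(row["label"])


def _iter_cohort(cohort: PhantomCohort):
    for p in cohort.patients:
        yield p.patient_id, p.volumes, p.mask, p.label


def extract_cohort_features(
    cohort_iter, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Slice-level feature table for a whole cohort, both sequences joined.

    One row per (patient, tumor-bearing slice) with the 82 features of each
    sequence side by side (164 columns), plus patient_id/slice_index/label.
    """
    cfg = config or ExtractionConfig()
    per_patient: dict[str, pd.DataFrame] = {}
    labels: dict[str, str] = {}
    for pid, volumes, mask, label in cohort_iter:
        tables = []
        for tag in ("T1C", "T2"):
            t = extract_feature_vector(volumes[tag], mask, tag, cfg)
            tables.append(t.set_index("slice_index"))
        joined = tables[0].join(tables[1], how="inner").reset_index()
        per_patient[pid] = joined
        labels[pid] = label
    return enumerate_slice_instances(per_patient, labels)


def sequence_columns(sequence: str, config: ExtractionConfig | None = None) -> list[str]:
    """Feature columns belonging to one sequence choice (82 or 164 names)."""
    if sequence == "T1C+T2":
        return feature_names("T1C", config) + feature_names("T2", config)
    return feature_names(sequence, config)


# ---------------------------------------------------------------------------
# the model grid
# ---------------------------------------------------------------------------

def model_grid(
    slice_table: pd.DataFrame,
    config: PipelineConfig,
    extraction: ExtractionConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple, CVResult]]:
    """Run every configured {mode} x {sequence} x {kernel} x {validation} cell.

    Returns the grid report (one row per cell: instance counts per class,
    AUC with either class positive, accuracy) plus the per-cell
    :class:`CVResult` objects keyed by the cell tuple.
    """
    extraction = extraction or config.extraction_config()
    datasets = {"single_slice": slice_table}
    if "multislice" in config.modes:
        datasets["multislice"] = aggregate_multislice(slice_table)
    rows = []
    results: dict[tuple, CVResult] = {}
    for mode in config.modes:
        table = datasets[mode]
        n_pos = int((table["label"] == "mutant").sum())
        n_neg = len(table) - n_pos
        for sequence in config.sequences:
            cols = sequence_columns(sequence, extraction)
            for kernel in config.kernels:
                for scheme in config.validation:
                    splits = group_aware_split(
                        table, scheme, seed=config.seed, grouped=config.grouped_slices
                    )
                    res = crossvalidate(
                        table,
                        cols,
                        splits,
                        kernel=kernel,
                        C=config.C,
                        select=config.select,
                        global_selection=config.global_selection,
                        n_lambda=config.lambda_grid_size,
                        seed=config.seed,
                    )
                    key = (mode, sequence, kernel, scheme)
                    results[key] = res
                    rows.append(
                        {
                            "mode": mode,
                            "sequence": sequence,
                            "kernel": kernel,
                            "validation": scheme,
                            "n_negative": n_neg,
                            "n_positive": n_pos,
                            "n_candidate_features": len(cols),
                            "auc_positive": res.auc_positive,
                            "auc_negative": res.auc_negative,
                            "accuracy": res.metrics.accuracy,
                        }
                    )
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the configured pipeline end to end, writing artifacts to disk.

    Writes the slice-level feature table, the grid report (CSV + JSON with
    per-cell retained features and the seed), pooled ROC points per cell,
    and the normalized config echo. Returns the report as a dict.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config_echo.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=list)

    extraction = cfg.extraction_config()
    if cfg.phantom is not None:
        spec = PhantomSpec(**{**cfg.phantom, "seed": cfg.phantom.get("seed", cfg.seed)})
        cohort_iter = _iter_cohort(generate_phantom_cohort(spec))
    else:
        cohort_iter = _load_cohort_from_manifest(cfg.manifest)

    logger.info("extracting features")
    slice_table = extract_cohort_features(cohort_iter, extraction)
    gio.write_feature_table(slice_table, outdir / "features_single_slice.csv")
    if "multislice" in cfg.modes:
        gio.write_feature_table(
            aggregate_multislice(slice_table), outdir / "features_multislice.csv"
        )

    logger.info("running model grid")
    grid, results = model_grid(slice_table, cfg, extraction)
    grid.to_csv(outdir / "grid_report.csv", index=False)

    cells = {}
    for key, res in results.items():
        cell_name = "__".join(key).replace(":", "-")
        roc = pd.DataFrame({"score": res.scores, "label": res.y_true})
        roc.to_csv(outdir / f"roc_points__{cell_name}.csv", index=False)
        cells["|".join(key)] = {
            "auc_positive": res.auc_positive,
            "auc_negative": res.auc_negative,
            "accuracy": res.metrics.accuracy,
            "confusion": dataclasses.asdict(res.confusion),
            "retained_features": res.retained_features,
        }
    report = {
        "seed": cfg.seed,
        "n_instances": int(len(slice_table)),
        "decisions": {
            "ng": cfg.ng,
            "ssf_levels": list(cfg.ssf_levels),
            "glcm_distances": list(cfg.glcm_distances),
            "aggregation": "unweighted_mean",
            "sigma_per_ssf": extraction.sigma_per_ssf,
            "selection": "global" if cfg.global_selection else "nested",
        },
        "cells": cells,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete: %s", outdir)
    return report
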