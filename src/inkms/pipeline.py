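"""End-to-end orchestration: read -> consolidate -> normalize -> align ->
screen -> classify -> annotate, with every stage's table written to disk
and a single deterministic JSON summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from .alignment import AlignParams, align_and_build
from .classify import KernelParams, crossval, make_folds_by_document, roc_auc
from .errors import InkmsError, PipelineError, ValidationError
from .screening import (
    ScreenParams,
    differential_analysis,
    filter_features,
    select_diagnostic,
)
from .spectra_io import TraceParams, load_sample, manifest_metas, normalize_tus, read_manifest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    manifest: Path
    data_dir: Path
    out_dir: Path
    trace: TraceParams = field(default_factory=TraceParams)
    align: AlignParams = field(default_factory=AlignParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    annotation_ppm: float = 5.0
    global_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        if self.annotation_ppm <= 0:
            raise ValidationError("annotation_ppm must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML config; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs = {}
        for key in ("manifest", "data_dir", "out_dir"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        sub = {
            "trace": (TraceParams, ("ppm_tol", "min_scan_fraction", "intensity_summary")),
            "align": (AlignParams, ("ppm_tol",)),
            "screen": (ScreenParams, ("min_present", "q_threshold", "impute_value", "log_base")),
            "kernel": (KernelParams, ("gamma_mode", "gamma_value", "margin_hardness")),
        }
        for name, (cls_, fields_) in sub.items():
            picked = {
                f: raw.pop(f"{name}_{f}") for f in fields_ if f"{name}_{f}" in raw
            }
            kwargs[name] = cls_(**picked)
        for key in ("annotation_ppm", "global_filter", "seed"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ValidationError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and return the summary dict.

    Writes, under ``config.out_dir``: feature_matrix.csv, differential.csv,
    filtered_matrix.csv, roc.csv, annotations.csv, ink_calls.csv and
    summary.json.  Deterministic given the same inputs and seed; any stage
    failure aborts with the stage name and cause.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "manifest"
    try:
        manifest = read_manifest(config.manifest)
        metas = manifest_metas(manifest)
        file_of = dict(zip(manifest.sample_id, manifest.file))

        stage = "load+normalize"
        samples = []
        for meta in metas:
            pl = load_sample(config.data_dir / file_of[meta.sample_id], meta, config.trace)
            samples.append(normalize_tus(pl))
        logger.info("loaded %d samples", len(samples))

        stage = "align"
        matrix = align_and_build(samples, config.align)
        matrix.to_csv(out / "feature_matrix.csv")
        logger.info("aligned %d features x %d samples", matrix.n_features, len(metas))

        stage = "screen"
        diff = differential_analysis(matrix, config.screen)
        diff.to_csv(out / "differential.csv", index=False, float_format="%.6g")
        diagnostics = select_diagnostic(diff, config.screen)
        filtered = filter_features(matrix, config.screen)
        filtered.to_csv(out / "filtered_matrix.csv")
        n_sig = int((diff["q_value"] < config.screen.q_threshold).sum())

        stage = "classify"
        plan = make_folds_by_document(metas)
        cv = crossval(
            filtered, plan, config.kernel, config.screen,
            global_filter=config.global_filter,
        )
        roc = roc_auc(cv)
        pd.DataFrame(
            {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
        ).to_csv(out / "roc.csv", index=False, float_format="%.6g")

        stage = "annotate"
        ann_rows = _annotate.annotate_features(
            filtered.feature_mz, ppm_tol=config.annotation_ppm
        )
        pd.DataFrame(
            ann_rows,
            columns=[
                "observed_mz", "formula", "adduct", "theoretical_mz",
                "ppm_error", "annotation_name", "author",
            ],
        ).to_csv(out / "annotations.csv", index=False, float_format="%.6f")
        ink_rows = []
        for s in samples:
            for ink_name, detected, matched in _annotate.detect_ink_signature(
                s, ppm_tol=config.annotation_ppm
            ):
                ink_rows.append(
                    {
                        "sample_id": s.meta.sample_id,
                        "ink": ink_name,
                        "detected": int(detected),
                        "matched_mz": "" if matched is None else f"{matched:.6f}",
                    }
                )
        pd.DataFrame(ink_rows).to_csv(out / "ink_calls.csv", index=False)

        stage = "summary"
        summary = {
            "seed": config.seed,
            "n_samples": len(metas),
            "n_blanks": len(matrix.blank_ids()),
            "n_features_pre_filter": int(matrix.n_features),
            "n_features_post_filter": int(filtered.n_features),
            "n_significant": n_sig,
            "n_diagnostic_blank_free": int(len(diagnostics)),
            "n_folds": len(plan.folds),
            "auc": _round(roc.auc),
            "mean_fold_accuracy": _round(float(np.mean(cv.fold_accuracy))),
            "n_annotated": len(ann_rows),
            "ink_detections": {
                row["sample_id"]: {}
                for row in ink_rows
            },
            "global_filter": bool(config.global_filter),
        }
        for row in ink_rows:
            summary["ink_detections"][row["sample_id"]][row["ink"]] = bool(row["detected"])
        (out / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=2) + "\n"
        )
        return summary
    except InkmsError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    except OSError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
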