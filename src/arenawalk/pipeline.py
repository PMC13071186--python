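"""End-to-end reproducible pipeline over all stages.

A single YAML config (one master seed, per-stage sections whose defaults
are the reference protocol values: binarisation threshold 60, 5x5 blur,
up to 10 erosions, 3-frame smoothing, 60 fps, 1-mm wall band, 2/3-radius
inner zone, the published hyperparameter grids) drives
synthesis -> autolabelling -> tracking -> features -> statistics ->
classification. Every run directory carries a manifest with seeds,
parameter hash and per-stage status, sufficient to reproduce all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import GridSpec, compare_groups
from .errors import ConfigError, StageError
from .features import (FEATURE_COLUMNS, TrajectoryRecord, build_feature_table,
                       write_feature_table)
from .geometry import ArenaGeometry
from .groupstats import analyze_feature_table
from .synthgen import (BodyShape, MotionPreset, default_arena, default_presets,
                       make_cohort, render_frame, truth_detections)
from .autolabel import LabelParams, evaluate_detection, export_dataset, label_frame, PartDetection
from .tracking import (TrackingConfig, Trajectory, apply_speed_filter,
                       extract_segment, smooth, track_video)

log = logging.getLogger("arenawalk.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]


@dataclass
class SynthSection:
    enabled: bool = True
    groups: list[str] = field(default_factory=lambda: ["control", "lc10", "lc30"])
    sexes: list[str] = field(default_factory=lambda: ["male", "female"])
    n_per_cell: int = 4
    n_frames: int = 1800
    fps: float = 60.0
    noise_sd: float = 5.0
    frame_shape: list[int] = field(default_factory=lambda: [540, 960])
    radius_px: float = 250.0
    px_to_mm: float = 0.11
    write_ground_truth: bool = False


@dataclass
class AutolabelSection:
    enabled: bool = True
    n_label_frames: int = 200
    n_videos: int = 6
    blur_kernel: int = 5
    threshold: float = 60.0
    max_iters: int = 10
    iou_threshold: float = 0.5
    ratios: list[float] = field(default_factory=lambda: [0.7, 0.2, 0.1])


@dataclass
class TrackingSection:
    enabled: bool = True
    n_tracked_videos: int = 2
    n_track_frames: int = 200
    smooth_window: int = 3
    speed_cap: float = 50.0
    stop_speed: float = 0.5
    max_gap: int = 5
    segment_s: float | None = None   # None = use the whole desk-scale recording


@dataclass
class FeaturesSection:
    enabled: bool = True
    wall_band_mm: float = 1.0
    inner_fraction: float = 2.0 / 3.0
    min_dwell: int = 2


@dataclass
class StatsSection:
    enabled: bool = True
    alpha: float = 0.05


@dataclass
class ClassifySection:
    enabled: bool = True
    pairs: list[str] = field(default_factory=lambda: ["control-lc30", "control-lc10", "lc10-lc30"])
    models: list[str] = field(default_factory=lambda: ["svm", "rf", "knn"])
    shap: bool = False
    k_outer: int = 4
    k_inner: int = 4


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None   # real frames; required when synth is off
    synth: SynthSection = field(default_factory=SynthSection)
    autolabel: AutolabelSection = field(default_factory=AutolabelSection)
    tracking: TrackingSection = field(default_factory=TrackingSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    stats: StatsSection = field(default_factory=StatsSection)
    classify: ClassifySection = field(default_factory=ClassifySection)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {"synth": SynthSection, "autolabel": AutolabelSection,
                    "tracking": TrackingSection, "features": FeaturesSection,
                    "stats": StatsSection, "classify": ClassifySection}
        kwargs = {}
        for key, val in raw.items():
            if key in sections:
                kwargs[key] = sections[key](**(val or {}))
            elif key in ("seed", "input_dir"):
                kwargs[key] = val
            else:
                raise ConfigError(f"unknown config key '{key}'")
        return cls(**kwargs)

    def param_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _condition(traj: Trajectory, tcfg: TrackingSection) -> Trajectory:
    out = smooth(traj, tcfg.smooth_window)
    out = apply_speed_filter(out, tcfg.speed_cap).trajectory
    if tcfg.segment_s is not None:
        out = extract_segment(out, tcfg.segment_s)
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all enabled stages; returns the manifest dict.

    Any stage failure raises :class:`StageError` after writing a
    partial-results manifest to the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.synth.enabled and (config.input_dir is None
                                     or not Path(config.input_dir).exists()):
        raise ConfigError("synthesis disabled and input_dir missing or nonexistent")
    logging.basicConfig(level=logging.INFO)
    manifest: dict = {"package": "arenawalk", "version": __version__,
                      "seed": config.seed, "param_hash": config.param_hash(),
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": {}}
    config.to_yaml(out / "config.yaml")

    def _finish_stage(name, status, **info):
        manifest["stages"][name] = {"status": status, **info}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    arena = default_arena(tuple(config.synth.frame_shape),
                          radius=config.synth.radius_px,
                          px_to_mm=config.synth.px_to_mm)
    arena = ArenaGeometry(centre=arena.centre, radius=arena.radius,
                          px_to_mm=arena.px_to_mm,
                          wall_band_mm=config.features.wall_band_mm,
                          inner_fraction=config.features.inner_fraction)
    (out / "arena.json").write_text(json.dumps(arena.to_dict(), indent=2))

    cohort = []
    if config.synth.enabled:
        try:
            log.info("synth: simulating cohort")
            presets = {g: default_presets()[g] for g in config.synth.groups}
            cohort = make_cohort(presets, config.synth.sexes,
                                 config.synth.n_per_cell, config.synth.n_frames,
                                 config.synth.fps, arena, seed=config.seed)
            import pandas as pd
            pd.DataFrame([{"uid": m.uid, "group": m.group, "sex": m.sex}
                          for m in cohort]).to_csv(out / "cohort.csv", index=False)
            if config.synth.write_ground_truth:
                gt_dir = out / "ground_truth"
                gt_dir.mkdir(exist_ok=True)
                for m in cohort:
                    m.truth.to_csv(gt_dir / f"{m.uid}.csv")
            _finish_stage("synth", "ok", n_individuals=len(cohort))
        except Exception as exc:
            _finish_stage("synth", "failed", error=str(exc))
            raise StageError("synth", str(exc)) from exc

    lp = LabelParams(blur_kernel=config.autolabel.blur_kernel,
                     threshold=config.autolabel.threshold,
                     max_iters=config.autolabel.max_iters)
    fshape = tuple(config.synth.frame_shape)
    if config.autolabel.enabled and cohort:
        try:
            log.info("autolabel: labelling %d frames", config.autolabel.n_label_frames)
            n_videos = min(config.autolabel.n_videos, len(cohort))
            per_video = max(config.autolabel.n_label_frames // n_videos, 1)
            preds, truths, images = [], [], []
            for vi in range(n_videos):
                member = cohort[vi * len(cohort) // n_videos]
                idxs = np.linspace(0, member.truth.n_frames - 1, per_video).astype(int)
                for k, fi in enumerate(idxs):
                    img, _ = render_frame(member.truth, int(fi),
                                          noise_sd=config.synth.noise_sd,
                                          frame_shape=fshape,
                                          seed=config.seed * 1000 + vi * 100 + k)
                    truths.append(list(truth_detections(member.truth, int(fi), fshape)))
                    try:
                        h, b = label_frame(img, lp)
                        preds.append([h, b])
                    except Exception:
                        preds.append([])
                    images.append(img)
            metrics = evaluate_detection(preds, truths,
                                         config.autolabel.iou_threshold)
            counts = export_dataset(preds, fshape, out / "dataset",
                                    tuple(config.autolabel.ratios),
                                    seed=config.seed)
            (out / "autolabel_metrics.json").write_text(json.dumps({
                "precision": metrics.precision, "recall": metrics.recall,
                "f1": metrics.f1, "map50": metrics.map50,
                "per_class": {c: vars(m) for c, m in metrics.per_class.items()},
                "split_counts": vars(counts)}, indent=2))
            _finish_stage("autolabel", "ok", precision=metrics.precision,
                          recall=metrics.recall,
                          split_counts=dataclasses.asdict(counts)
                          if dataclasses.is_dataclass(counts) else vars(counts))
        except Exception as exc:
            _finish_stage("autolabel", "failed", error=str(exc))
            raise StageError("autolabel", str(exc)) from exc

    tcfg = config.tracking
    track_config = TrackingConfig(fps=config.synth.fps, px_to_mm=arena.px_to_mm,
                                  smooth_window=tcfg.smooth_window,
                                  speed_cap=tcfg.speed_cap,
                                  stop_speed=tcfg.stop_speed,
                                  max_gap=tcfg.max_gap, segment_s=tcfg.segment_s)
    if tcfg.enabled and cohort:
        try:
            log.info("tracking: %d demonstration videos", tcfg.n_tracked_videos)
            errors = []
            for vi in range(min(tcfg.n_tracked_videos, len(cohort))):
                member = cohort[vi]
                n_tf = min(tcfg.n_track_frames, member.truth.n_frames)
                frames = (render_frame(member.truth, i,
                                       noise_sd=config.synth.noise_sd,
                                       frame_shape=fshape,
                                       seed=config.seed * 7000 + vi * 1000 + i)[0]
                          for i in range(n_tf))
                traj = track_video(frames, track_config, lp)
                traj.to_csv(out / f"track_{member.uid}.csv")
                err = np.nanmedian(np.linalg.norm(
                    traj.part_xy("head") - member.truth.head[:n_tf], axis=1))
                errors.append(float(err))
            _finish_stage("tracking", "ok", median_head_error_px=errors)
        except Exception as exc:
            _finish_stage("tracking", "failed", error=str(exc))
            raise StageError("tracking", str(exc)) from exc

    table = None
    if config.features.enabled and cohort:
        try:
            log.info("features: building the cohort feature table")
            records = []
            for m in cohort:
                traj = Trajectory.from_parts(m.truth.part_positions(),
                                             fps=m.truth.fps,
                                             px_to_mm=arena.px_to_mm)
                traj = _condition(traj, tcfg)
                records.append(TrajectoryRecord(traj, arena, group=m.group,
                                                sex=m.sex, uid=m.uid))
            table = build_feature_table(records, track_config,
                                        min_dwell=config.features.min_dwell)
            write_feature_table(table, out / "features.csv",
                                out / "feature_units.json")
            _finish_stage("features", "ok", n_rows=len(table))
        except Exception as exc:
            _finish_stage("features", "failed", error=str(exc))
            raise StageError("features", str(exc)) from exc

    if config.stats.enabled and table is not None:
        try:
            log.info("stats: nonparametric comparisons")
            stats_table = analyze_feature_table(table, FEATURE_COLUMNS,
                                                alpha=config.stats.alpha)
            stats_table.to_csv(out / "stats.csv", index=False)
            _finish_stage("stats", "ok", n_tests=len(stats_table))
        except Exception as exc:
            _finish_stage("stats", "failed", error=str(exc))
            raise StageError("stats", str(exc)) from exc

    if config.classify.enabled and table is not None:
        try:
            log.info("classify: %s", config.classify.pairs)
            summary = {}
            for pair in config.classify.pairs:
                res = compare_groups(table, pair, models=config.classify.models,
                                     seed=config.seed,
                                     k_outer=config.classify.k_outer,
                                     k_inner=config.classify.k_inner,
                                     shap=config.classify.shap)
                key = "-".join(res.pair)
                summary[key] = {
                    "mean_accuracy": res.mean_accuracy,
                    "mean_precision": res.mean_precision,
                    "models": {m: {"accuracy": r.accuracy,
                                   "precision": r.precision,
                                   "recall": r.recall, "f1": r.f1,
                                   "confusion": r.confusion.tolist(),
                                   "fold_params": r.fold_params}
                               for m, r in res.results.items()},
                }
                if res.shap_summary is not None:
                    res.shap_values.to_csv(out / f"shap_{key}.csv", index=False)
                    summary[key]["shap_mean_abs"] = res.shap_summary.to_dict()
            (out / "classification.json").write_text(json.dumps(summary, indent=2))
            _finish_stage("classify", "ok",
                          mean_accuracy={k: v["mean_accuracy"]
                                         for k, v in summary.items()})
        except Exception as exc:
            _finish_stage("classify", "failed", error=str(exc))
            raise StageError("classify", str(exc)) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
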