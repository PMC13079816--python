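"""End-to-end orchestration: simulate -> render -> count -> classify -> LCR.

A run is fully described by a :class:`RunConfig` (strict schema, unknown keys
rejected) plus a master seed; every stochastic stage receives its own seed
derived from the master by fixed offsets, so stages can be rerun in
isolation and the whole run is reproducible bit-for-bit (timestamps in the
report aside).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .nuclei_detection import DetectionConfig, count_cells, detections_to_frame
from .synthetic_imaging import (
    DEFAULT_FIELD_UM,
    DEFAULT_PITCH_UM,
    FIModel,
    KINETICS_PRESETS,
    KineticsParams,
    render_image,
    simulate_timecourse,
    write_image_tiff,
)
from .viability_stats import (
    DEFAULT_AREA_MM2,
    DEFAULT_FI_THRESHOLD_AU,
    DayCounts,
    LCRSeries,
    build_lcr_series,
    classify_viability,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "ConfigError",
    "validate_config",
    "run_pipeline",
]

_SEED_MOD = 2**31


def derive_seed(master: int, *offsets: int) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    s = master % _SEED_MOD
    for off in offsets:
        s = (s * 1_000_003 + off + 12_345) % _SEED_MOD
    return s


class ConfigError(ValueError):
    """Aggregated configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(
            f"  - {v}" for v in violations))


class KineticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n0: float = Field(180.0, gt=0)
    growth_per_day: float = Field(1.0, gt=0)
    dead_persistence: float = Field(0.5, ge=0, le=1)

    def to_params(self) -> KineticsParams:
        return KineticsParams(self.n0, self.growth_per_day, self.dead_persistence)


class ImagingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    field_width_um: float = Field(DEFAULT_FIELD_UM[1], gt=0)
    field_height_um: float = Field(DEFAULT_FIELD_UM[0], gt=0)
    pitch_um: float = Field(DEFAULT_PITCH_UM, gt=0)
    psf_sigma_um: float = Field(2.0, ge=0)
    background_au: float = Field(10.0, ge=0)
    noise_sigma_au: float = Field(1.0, ge=0)
    min_spacing_um: float | None = Field(15.0, gt=0)
    margin_um: float = Field(25.0, ge=0)


class DetectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    roi_size_px: int = Field(15, ge=3)
    stride_px: int = Field(1, ge=1)
    detection_threshold_au: float = Field(2.0, ge=0)
    min_separation_px: int = Field(15, ge=1)
    # small aperture so the measured FI tracks the nucleus peak intensity,
    # keeping the live/dead threshold on the peak-FI scale
    aperture_px: int = Field(3, ge=1)

    def to_config(self) -> DetectionConfig:
        return DetectionConfig(
            roi_size_px=self.roi_size_px,
            stride_px=self.stride_px,
            detection_threshold_au=self.detection_threshold_au,
            min_separation_px=self.min_separation_px,
            aperture_px=self.aperture_px,
        )


class StatsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    area_mm2: float = Field(DEFAULT_AREA_MM2, gt=0)
    fi_threshold_au: float = Field(DEFAULT_FI_THRESHOLD_AU, ge=0)
    error_mode: Literal["printed", "standard"] = "printed"


class RunConfig(BaseModel):
    """Full pipeline configuration; serialisable, strict about unknown keys."""

    model_config = ConfigDict(extra="forbid")
    conditions: dict[str, KineticsConfig] = Field(
        default_factory=lambda: {
            name: KineticsConfig(growth_per_day=k.growth_per_day)
            for name, k in KINETICS_PRESETS.items()
        }
    )
    days: int = Field(4, ge=1)
    images_per_day: int = Field(10, ge=1)
    seed: int = Field(0, ge=0)
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    detection: DetectionSettings = Field(default_factory=DetectionSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)
    write_images: bool = False


def validate_config(raw_text: str) -> RunConfig:
    """Parse and validate a YAML run configuration, reporting all violations."""
    try:
        data = yaml.safe_load(raw_text)
    except yaml.YAMLError as exc:
        raise ConfigError([f"not parseable as YAML: {exc}"]) from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(["top level must be a mapping"])
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        violations = [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(violations) from exc


@dataclass
class RunReport:
    """Results of one pipeline run plus everything needed to reproduce it."""

    config: RunConfig
    day_counts: dict[str, dict[int, DayCounts]]
    lcr_series: dict[str, LCRSeries]
    detections: pd.DataFrame
    summary: pd.DataFrame
    version: str = __version__
    started_at: str = ""
    finished_at: str = ""


def _process_condition(
    name: str, cond_index: int, config: RunConfig
) -> tuple[dict[int, DayCounts], pd.DataFrame]:
    img = config.imaging
    det_cfg = config.detection.to_config()
    kinetics = config.conditions[name].to_params()
    scenes, _truth = simulate_timecourse(
        kinetics,
        days=config.days,
        images_per_day=config.images_per_day,
        field_width_um=img.field_width_um,
        field_height_um=img.field_height_um,
        min_spacing_um=img.min_spacing_um,
        margin_um=img.margin_um,
        seed=derive_seed(config.seed, cond_index, 1),
    )
    rows = []
    live_counts: dict[int, list[int]] = {}
    for day, day_scenes in scenes.items():
        live_counts[day] = []
        for i, scene in enumerate(day_scenes):
            frame = render_image(
                scene,
                pitch_um=img.pitch_um,
                psf_sigma_um=img.psf_sigma_um,
                background_au=img.background_au,
                noise_sigma_au=img.noise_sigma_au,
                seed=derive_seed(config.seed, cond_index, 2, day, i),
            )
            detections = count_cells(frame, det_cfg)
            n_live = 0
            for det in detections:
                label = classify_viability(det.fi_au, config.stats.fi_threshold_au)
                if label == "live":
                    n_live += 1
                rows.append((name, day, i, det.row_px, det.col_px,
                             det.fi_au, det.score, label))
            live_counts[day].append(n_live)
    day_counts = {
        day: DayCounts.from_counts(day, counts, config.stats.area_mm2)
        for day, counts in live_counts.items()
    }
    detections_df = pd.DataFrame(
        rows,
        columns=["condition", "day", "image", "row_px", "col_px",
                 "fi_au", "score", "label"],
    )
    return day_counts, detections_df


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Run the full synthetic viability pipeline for every configured condition.

    Writes (when ``outdir`` is given) ``detections.csv``, ``summary.csv`` and
    ``report.txt``; with ``config.write_images`` also the per-day TIFFs.
    Deterministic under a fixed config and seed.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    if not config.conditions:
        raise ValueError("at least one condition is required")
    all_day_counts: dict[str, dict[int, DayCounts]] = {}
    all_series: dict[str, LCRSeries] = {}
    det_frames = []
    summary_rows = []
    for cond_index, name in enumerate(sorted(config.conditions)):
        day_counts, det_df = _process_condition(name, cond_index, config)
        if 0 not in day_counts:
            raise ValueError(f"condition {name!r}: Day 0 missing, LCR undefined")
        series = build_lcr_series(day_counts, error_mode=config.stats.error_mode)
        all_day_counts[name] = day_counts
        all_series[name] = series
        det_frames.append(det_df)
        for day in sorted(day_counts):
            dc = day_counts[day]
            summary_rows.append((
                name, day, len(dc.x_i), dc.x_bar, dc.sigma,
                dc.concentration_per_mm2, series.lcr[day], series.lcr_err[day],
            ))

    detections = pd.concat(det_frames, ignore_index=True)
    summary = pd.DataFrame(
        summary_rows,
        columns=["condition", "day", "n_images", "x_bar", "sigma",
                 "concentration_per_mm2", "lcr", "lcr_err"],
    )
    report = RunReport(
        config=config,
        day_counts=all_day_counts,
        lcr_series=all_series,
        detections=detections,
        summary=summary,
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    if outdir is not None:
        _write_outputs(report, Path(outdir))
    return report


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.detections.to_csv(outdir / "detections.csv", index=False)
    report.summary.to_csv(outdir / "summary.csv", index=False)
    payload = {
        "version": report.version,
        "started_at": report.started_at,
        "finished_at": report.finished_at,
        "config": report.config.model_dump(),
        "three_day_avg": {
            name: {"value": s.three_day_avg, "error": s.three_day_avg_err}
            for name, s in report.lcr_series.items()
        },
    }
    (outdir / "report.txt").write_text(json.dumps(payload, indent=2) + "\n")
    if report.config.write_images:
        _rewrite_images(report.config, outdir)


def _rewrite_images(config: RunConfig, outdir: Path) -> None:
    # regenerate scenes/images from the same derived seeds used for counting
    img = config.imaging
    for cond_index, name in enumerate(sorted(config.conditions)):
        scenes, truth = simulate_timecourse(
            config.conditions[name].to_params(),
            days=config.days,
            images_per_day=config.images_per_day,
            field_width_um=img.field_width_um,
            field_height_um=img.field_height_um,
            min_spacing_um=img.min_spacing_um,
            margin_um=img.margin_um,
            seed=derive_seed(config.seed, cond_index, 1),
        )
        cond_dir = outdir / "images" / name
        for day, day_scenes in scenes.items():
            day_dir = cond_dir / f"day{day}"
            day_dir.mkdir(parents=True, exist_ok=True)
            for i, scene in enumerate(day_scenes):
                frame = render_image(
                    scene,
                    pitch_um=img.pitch_um,
                    psf_sigma_um=img.psf_sigma_um,
                    background_au=img.background_au,
                    noise_sigma_au=img.noise_sigma_au,
                    seed=derive_seed(config.seed, cond_index, 2, day, i),
                )
                write_image_tiff(frame, day_dir / f"img{i:02d}.tif")
        truth.to_csv(cond_dir / "ground_truth.csv", index=False)
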