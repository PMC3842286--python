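"""End-to-end orchestration: frames -> vectors -> front line -> model -> reach.

A single :class:`PipelineConfig` drives the whole chain, either from a
synthetic cloud (simulate + render) or from a stack of recorded frames on
disk. All randomness flows from the synthetic config's seed; identical
config and seed reproduce identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, PlumekinError, StageError
from .frontline import (
    DEFAULT_DROPLET_CUTOFF_UM,
    FrontlineSeries,
    exclude_fast_falling,
    extract_frontline,
    export_velocity_map,
)
from .imaging import FrameSequence, binarize_sequence, load_frames, write_frames
from .kinematics import (
    DecayModel,
    NATURAL_CONVECTION_CMS,
    ReachResult,
    fit_decay,
    reach_at_momentum_loss,
)
from .piv import InterrogationGrid, VectorField, compute_vector_field
from .synthetic import GroundTruth, SynthConfig, render_frames, simulate_trajectories

logger = logging.getLogger("plumekin")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    mode: str = "synthetic"  # 'synthetic' | 'frames'
    synth: SynthConfig | None = None
    frames_pattern: str | None = None
    dt: float = 1.0 / 300.0  # frames mode only (synthetic carries its own)
    pixel_size: float = 4.4 / 21.0
    mouth_position: tuple[float, float] = (0.0, 0.0)
    grid: InterrogationGrid = field(default_factory=InterrogationGrid)
    window: tuple[float, float] = (0.04, 0.20)
    droplet_cutoff_um: float = DEFAULT_DROPLET_CUTOFF_UM
    v_threshold: float = NATURAL_CONVECTION_CMS
    fix_offset: float | str | None = None
    t_anchor: float = 0.0
    h_anchor: float = 0.0
    direction: str = "+x"
    robust_fit: bool = False
    binarize_for_tracking: bool = False
    label: str = ""
    output_dir: str | None = None
    write_frame_images: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "frames"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.synth is None:
            raise ConfigError("synthetic mode requires a SynthConfig")
        if self.mode == "frames" and not self.frames_pattern:
            raise ConfigError("frames mode requires a frames_pattern")
        if self.window[0] >= self.window[1]:
            raise ConfigError("analysis window must satisfy t_min < t_max")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    frames: FrameSequence
    truth: GroundTruth | None
    fields: list[VectorField]
    series: FrontlineSeries
    model: DecayModel
    reach: ReachResult
    timings: dict[str, float]

    def summary(self) -> dict:
        return {
            "label": self.config.label,
            "n_frames": self.frames.n_frames,
            "n_fields": len(self.fields),
            "n_frontline_points": len(self.series),
            "model": self.model.to_dict(),
            "reach": self.reach.to_dict(),
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PlumekinError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("acquire")
def _acquire(config: PipelineConfig) -> tuple[FrameSequence, GroundTruth | None]:
    if config.mode == "synthetic":
        truth = simulate_trajectories(config.synth)
        frames = render_frames(truth, config.synth)
        return frames, truth
    frames = load_frames(
        config.frames_pattern,
        dt=config.dt,
        pixel_size=config.pixel_size,
        mouth_position=config.mouth_position,
    )
    return frames, None


@_stage("track")
def _track(frames: FrameSequence, config: PipelineConfig) -> list[VectorField]:
    seq = frames
    if config.binarize_for_tracking:
        seq = binarize_sequence(seq)
    fields = []
    for i in range(seq.n_frames - 1):
        f = compute_vector_field(seq.frame(i), seq.frame(i + 1), config.grid)
        fields.append(f)
        logger.debug(
            "frame pair %d: %d/%d valid vectors, %d abandonments",
            i, f.n_valid, len(f), int(f.abandonment_counts.sum()),
        )
    return fields


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run simulate/load -> track -> front line -> fit -> reach.

    Writes (when ``output_dir`` is set) the per-pair vector-field CSV, the
    front-line CSV with a JSON sidecar, the fitted model and reach JSONs,
    and a run manifest echoing the configuration.
    """
    config.validate()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    frames, truth = _acquire(config)
    timings["acquire_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fields = _track(frames, config)
    fields = [exclude_fast_falling(f, config.droplet_cutoff_um) for f in fields]
    timings["track_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mouth_x = frames.mouth_position[0]
    series = extract_frontline(
        fields, mouth_x, direction=config.direction,
        window=config.window, label=config.label,
    )
    # A retreating distal margin is a tracking artifact: the decay law is
    # strictly positive, so non-positive points are left out of the fit.
    pos = series.vh > 0
    if not pos.all():
        logger.info("dropping %d non-positive front-line points", int((~pos).sum()))
    model = fit_decay(
        (series.t[pos], series.vh[pos]),
        fix_offset=config.fix_offset,
        robust=config.robust_fit,
    )
    reach = reach_at_momentum_loss(
        model, v_threshold=config.v_threshold,
        t_anchor=config.t_anchor, h_anchor=config.h_anchor,
    )
    timings["analyse_s"] = time.perf_counter() - t0

    report = RunReport(
        config=config, frames=frames, truth=truth, fields=fields,
        series=series, model=model, reach=reach, timings=timings,
    )
    if config.output_dir:
        _write_outputs(report)
    logger.info(
        "%s: A=%.1f cm/s, k=%.2f /s, c=%.1f cm/s, t*=%.4f s, reach=%.1f cm",
        config.label or "run", model.amplitude, model.rate, model.offset,
        reach.t_stop, reach.reach,
    )
    return report


def _write_outputs(report: RunReport) -> None:
    out = report.config.output_dir
    os.makedirs(out, exist_ok=True)
    tables = []
    for i, f in enumerate(report.fields):
        df = f.to_dataframe()
        df.insert(0, "frame_index", i)
        tables.append(df)
    pd.concat(tables, ignore_index=True).to_csv(
        os.path.join(out, "vector_fields.csv"), index=False
    )
    report.series.to_dataframe().to_csv(
        os.path.join(out, "frontline.csv"), index=False
    )
    mouth_x = report.frames.mouth_position[0]
    export_velocity_map(report.fields, mouth_x, report.config.direction).to_csv(
        os.path.join(out, "velocity_map.csv"), index=False
    )
    with open(os.path.join(out, "frontline_meta.json"), "w") as fh:
        json.dump(
            {
                "label": report.config.label,
                "window_s": list(report.series.window),
                "n_points": len(report.series),
            },
            fh, indent=2,
        )
    with open(os.path.join(out, "model.json"), "w") as fh:
        json.dump(report.model.to_dict(), fh, indent=2)
    with open(os.path.join(out, "reach.json"), "w") as fh:
        json.dump(report.reach.to_dict(), fh, indent=2)
    manifest = {
        "plumekin_version": __version__,
        "numpy_version": np.__version__,
        "config": report.config.to_dict(),
        "timings_s": report.timings,
        "valid_vectors_per_frame": [f.n_valid for f in report.fields],
        "abandonments_per_frame": [
            int(f.abandonment_counts.sum()) for f in report.fields
        ],
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if report.config.write_frame_images:
        write_frames(report.frames, os.path.join(out, "frames"))
    if report.truth is not None:
        report.truth.save(out)
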