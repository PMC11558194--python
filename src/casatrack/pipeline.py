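"""End-to-end composition: video → detect → track → motility summary.

The pipeline is deterministic: a video plus a configuration fully determine
every output table.  The acquisition convention is that a "1 s at 30 fps"
clip holds 31 samples spanning 30 inter-frame intervals, so the elapsed
time (M-1)Δt in the velocity denominators equals the nominal clip duration
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import detection, io, linking, motility
from .detection import SegmentationConfig
from .errors import ConfigError
from .linking import LinkingConfig, default_gate
from .render import VideoStack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full analysis run.

    ``fps`` and ``pixel_size`` override the video's metadata when given.
    When ``linking`` is None the gate defaults to ``default_gate(fps)``
    (twice the distance the fastest plausible sperm covers per frame).
    """

    fps: float | None = None
    pixel_size: float | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    linking: LinkingConfig | None = None
    min_frames_vap: int = motility.DEFAULT_MIN_FRAMES_VAP

    def __post_init__(self) -> None:
        if self.fps is not None and self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.min_frames_vap < 2:
            raise ConfigError("min_frames_vap must be >= 2")


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown keys in '{section}' section: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a nested dict, rejecting unknown keys."""
    data = dict(data or {})
    seg = data.pop("segmentation", {})
    link = data.pop("linking", None)
    top_valid = {"fps", "pixel_size", "min_frames_vap"}
    unknown = set(data) - top_valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if isinstance(seg, dict):
        seg = _build_section(SegmentationConfig, seg, "segmentation")
    if isinstance(link, dict):
        link = _build_section(LinkingConfig, link, "linking")
    return PipelineConfig(segmentation=seg, linking=link, **data)


def config_from_yaml(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """All intermediate and final tables of one run."""

    detections_by_frame: list[list[detection.Detection]]
    tracks: list[linking.Track]
    records: list[motility.MotilityRecord]
    summary: pd.DataFrame | None
    config: PipelineConfig

    @property
    def detections_df(self) -> pd.DataFrame:
        rows = [
            {
                "frame": d.frame_index,
                "x_um": d.x_um,
                "y_um": d.y_um,
                "row_px": d.centroid_px[0],
                "col_px": d.centroid_px[1],
                "area_um2": d.area_um2,
                "mean_intensity": d.mean_intensity,
            }
            for dets in self.detections_by_frame
            for d in dets
        ]
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(columns=detection.DETECTION_COLUMNS)
        return df[detection.DETECTION_COLUMNS]

    @property
    def tracks_df(self) -> pd.DataFrame:
        return linking.tracks_to_dataframe(self.tracks)

    @property
    def records_df(self) -> pd.DataFrame:
        return motility.records_to_dataframe(self.records)


def run_pipeline(video: VideoStack, config: PipelineConfig | None = None) -> PipelineResult:
    """Detect, link and summarise one video stack."""
    config = config or PipelineConfig()
    fps = config.fps if config.fps is not None else video.fps
    if config.pixel_size is not None and config.pixel_size != video.pixel_size:
        video = VideoStack(
            frames=video.frames, fps=video.fps, pixel_size=config.pixel_size
        )
    link_cfg = config.linking or LinkingConfig(max_link_distance=default_gate(fps))

    dets = detection.detect_video(video, config.segmentation)
    tracks = linking.build_tracks(dets, link_cfg, fps=fps)
    records = [
        motility.motility_record_from_track(tr, min_frames_vap=config.min_frames_vap)
        for tr in tracks
    ]
    summary = motility.summarize_population(records) if records else None
    n_short = sum(1 for r in records if r.VAP is None)
    if n_short:
        log.warning("%d track(s) shorter than %d frames: VAP/STR/WOB undefined",
                    n_short, config.min_frames_vap)
    return PipelineResult(
        detections_by_frame=dets, tracks=tracks, records=records,
        summary=summary, config=config,
    )


def run_pipeline_file(
    video_path,
    config: PipelineConfig | None = None,
    outdir=None,
    fps: float | None = None,
    pixel_size: float | None = None,
) -> PipelineResult:
    """Run on a video file and optionally write all output CSVs + a run log."""
    config = config or PipelineConfig()
    video = io.read_video(video_path, fps=fps or config.fps,
                          pixel_size=pixel_size or config.pixel_size)
    result = run_pipeline(video, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_csv(result.detections_df, outdir / "detections.csv")
        io.write_csv(result.tracks_df, outdir / "tracks.csv")
        io.write_csv(result.records_df, outdir / "motility.csv")
        if result.summary is not None:
            result.summary.rename_axis("parameter").reset_index().to_csv(
                outdir / "summary.csv", index=False
            )
        run_log = {
            "video": str(video_path),
            "config_hash": _config_hash(config),
            "n_frames": video.n_frames,
            "fps": video.fps,
            "pixel_size_um": video.pixel_size,
            "n_detections": int(sum(len(d) for d in result.detections_by_frame)),
            "n_tracks": len(result.tracks),
        }
        with open(outdir / "run.json", "w") as fh:
            json.dump(run_log, fh, indent=2)
    return result
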