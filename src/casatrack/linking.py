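"""Frame-to-frame detection linking into per-sperm tracks.

Consecutive frames are linked by a gated, globally cost-minimal one-to-one
assignment (Hungarian algorithm) under Euclidean centroid distance: among
assignments that maximise the number of within-gate matches, the one with
the smallest total distance is chosen.  This is deterministic and, unlike
greedy nearest-neighbour linking, resolves crossing trajectories correctly.

Track management is sequential: matched detections extend their track;
unmatched detections open new tracks; a track not extended for more than
``max_frame_gap`` frames is closed.  Tracks shorter than
``min_track_length`` are discarded and surviving tracks renumbered densely
in creation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ConfigError, InvalidInputError
from .detection import Detection

#: Cost assigned to out-of-gate pairs: large enough that the optimiser
#: always prefers any set of feasible matches over an infeasible one.
_INFEASIBLE = 1e12

#: Linked-track CSV schema (same as the simulator's ground-truth export).
TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um"]


@dataclass(frozen=True)
class LinkingConfig:
    """Gating and track-management parameters.

    ``max_link_distance`` (μm) is the hard gate on a single-frame link; use
    :func:`default_gate` for a speed-based default.  ``max_frame_gap`` is
    the number of consecutive missed frames tolerated before a track closes
    (0 = no gap closing, the default: interpolating across gaps would feed
    invented positions into the velocity formulas).
    """

    max_link_distance: float = 10.0   # μm
    max_frame_gap: int = 0
    min_track_length: int = 2

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ConfigError("max_link_distance must be positive")
        if self.max_frame_gap < 0:
            raise ConfigError("max_frame_gap must be >= 0")
        if self.min_track_length < 2:
            raise ConfigError("min_track_length must be >= 2")


def default_gate(fps: float, max_speed_um_s: float = 100.0, safety: float = 2.0) -> float:
    """Gate covering the fastest plausible sperm with a safety factor, μm.

    ``max_speed * dt * safety``: at 30 fps the default is ~6.7 μm.
    """
    if fps <= 0:
        raise InvalidInputError("fps must be positive")
    return max_speed_um_s * safety / fps


@dataclass
class Track:
    """Time-ordered chain of detections for one sperm identity."""

    track_id: int
    detections: list[Detection]
    fps: float

    def __post_init__(self) -> None:
        frames = [d.frame_index for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise InvalidInputError("detection frame indices must be strictly increasing")
        if self.fps <= 0:
            raise InvalidInputError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections], dtype=int)

    @property
    def x_um(self) -> np.ndarray:
        return np.array([d.x_um for d in self.detections])

    @property
    def y_um(self) -> np.ndarray:
        return np.array([d.y_um for d in self.detections])

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.fps


def link_frames(
    current: Sequence[Detection],
    next_frame: Sequence[Detection],
    config: LinkingConfig | None = None,
    gate: float | None = None,
) -> list[tuple[int, int]]:
    """Gated optimal one-to-one assignment between two detection lists.

    Returns (index_current, index_next) pairs sorted by index_current.
    ``gate`` overrides ``config.max_link_distance`` (used by the track
    builder to scale the gate across frame gaps).
    """
    config = config or LinkingConfig()
    gate = config.max_link_distance if gate is None else gate
    if not current or not next_frame:
        return []
    a = np.array([[d.x_um, d.y_um] for d in current])
    b = np.array([[d.x_um, d.y_um] for d in next_frame])
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    cost = np.where(dist <= gate, dist, _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= gate
    ]
    return sorted(pairs)


def build_tracks(
    detections_by_frame: Sequence[Sequence[Detection]],
    config: LinkingConfig | None = None,
    fps: float = 30.0,
) -> list[Track]:
    """Assemble per-frame detections into tracks across a whole clip.

    Detections within each frame are canonically sorted by centroid before
    assignment so the output does not depend on input ordering.  The gate
    for a track that missed ``g`` frames scales to ``gate * (g + 1)``.
    """
    config = config or LinkingConfig()
    open_tracks: list[dict] = []   # {"detections": [...], "last_frame": int, "created": int}
    closed: list[dict] = []
    created = 0

    for f, dets in enumerate(detections_by_frame):
        dets = sorted(dets, key=lambda d: d.centroid_px)
        # Retire tracks whose gap budget is exhausted.
        still_open = []
        for tr in open_tracks:
            if f - tr["last_frame"] > config.max_frame_gap + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        matched_det: set[int] = set()
        if open_tracks and dets:
            heads = np.array(
                [[tr["detections"][-1].x_um, tr["detections"][-1].y_um] for tr in open_tracks]
            )
            pts = np.array([[d.x_um, d.y_um] for d in dets])
            dist = np.linalg.norm(heads[:, None, :] - pts[None, :, :], axis=2)
            gaps = np.array([f - tr["last_frame"] for tr in open_tracks], dtype=float)
            gates = config.max_link_distance * gaps
            feasible = dist <= gates[:, None]
            cost = np.where(feasible, dist, _INFEASIBLE)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if feasible[i, j]:
                    open_tracks[i]["detections"].append(dets[j])
                    open_tracks[i]["last_frame"] = f
                    matched_det.add(j)
        for j, det in enumerate(dets):
            if j not in matched_det:
                open_tracks.append(
                    {"detections": [det], "last_frame": f, "created": created}
                )
                created += 1

    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr["created"])
    tracks = []
    for tr in closed:
        if len(tr["detections"]) >= config.min_track_length:
            tracks.append(Track(track_id=len(tracks), detections=tr["detections"], fps=fps))
    return tracks


def tracks_to_dataframe(tracks: Sequence[Track]):
    """Long-format table matching the ground-truth CSV schema."""
    rows = []
    for tr in tracks:
        for d in tr.detections:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": d.frame_index,
                    "time_s": d.frame_index / tr.fps,
                    "x_um": d.x_um,
                    "y_um": d.y_um,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=TRACK_COLUMNS)
    return df[TRACK_COLUMNS]
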