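"""CASA motility parameters for a single tracked sperm head.

For a trajectory (x_j, y_j), j = 1..M, sampled at a uniform inter-frame time
``delta_t``:

* VCL (curvilinear velocity) — total point-to-point path length divided by
  the elapsed time (M-1)*delta_t.
* VSL (straight-line velocity) — start-to-end displacement divided by the
  same elapsed time.
* VAP (average path velocity) — VCL evaluated on the 5-point moving-average
  smoothed path (x̄_k = mean of x over the window k-2..k+2).
* LIN = VSL/VCL, STR = VSL/VAP, WOB = VAP/VCL — dimensionless path-shape
  ratios, stored as fractions and conventionally reported as percentages.

Boundary handling for the smoother: the centred window shrinks symmetrically
at the first/last two samples (sizes 1, 3, 5, ..., 5, 3, 1), so the smoothed
path keeps length M, the (M-1)*delta_t denominator stays consistent, and the
endpoints are preserved (which guarantees VSL <= VAP on every track).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientLengthError, InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .linking import Track

#: Minimum number of frames for VAP (and the VAP-dependent ratios):
#: with a 5-point window, M >= 7 leaves at least two fully interior points.
DEFAULT_MIN_FRAMES_VAP = 7

#: Column order used by per-track CSV exports.
RECORD_COLUMNS = ["track_id", "VCL", "VSL", "VAP", "LIN", "STR", "WOB", "M", "delta_t"]


@dataclass(frozen=True)
class MotilityRecord:
    """Kinematic summary of one track.

    Velocities are in μm/s; ratios are fractions in [0, 1] (``None`` when
    undefined, i.e. for a track with zero VCL or VAP).
    """

    track_id: int
    VCL: float
    VSL: float
    VAP: float | None
    LIN: float | None
    STR: float | None
    WOB: float | None
    M: int
    delta_t: float

    def as_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "VCL": self.VCL,
            "VSL": self.VSL,
            "VAP": self.VAP,
            "LIN": self.LIN,
            "STR": self.STR,
            "WOB": self.WOB,
            "M": self.M,
            "delta_t": self.delta_t,
        }


def _as_coords(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    return x, y


def vcl(x, y, delta_t: float) -> float:
    """Curvilinear velocity: sum of segment lengths over (M-1)*delta_t, μm/s."""
    x, y = _as_coords(x, y)
    m = len(x)
    if m < 2:
        raise InsufficientLengthError(f"VCL needs at least 2 points, got {m}")
    if delta_t <= 0:
        raise InvalidInputError("delta_t must be positive")
    seg = np.hypot(np.diff(x), np.diff(y))
    return float(seg.sum() / ((m - 1) * delta_t))


def vsl(x, y, delta_t: float) -> float:
    """Straight-line velocity: endpoint displacement over (M-1)*delta_t, μm/s."""
    x, y = _as_coords(x, y)
    m = len(x)
    if m < 2:
        raise InsufficientLengthError(f"VSL needs at least 2 points, got {m}")
    if delta_t <= 0:
        raise InvalidInputError("delta_t must be positive")
    return float(math.hypot(x[-1] - x[0], y[-1] - y[0]) / ((m - 1) * delta_t))


def _moving_mean_truncated(v: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Centred moving mean whose window shrinks symmetrically at the ends.

    Window half-widths are min(k, n-1-k, half_window), i.e. sizes
    1, 3, 5, ..., 5, 3, 1 for the default 5-point smoother.  Keeping the
    windows centred leaves the endpoints unsmoothed, so a straight
    constant-speed path is exactly invariant and the smoothed path always
    connects the raw endpoints (hence VSL <= VAP).
    """
    n = len(v)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), half_window)
    return (csum[idx + half + 1] - csum[idx - half]) / (2 * half + 1)


def smooth_path(x, y, half_window: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """5-point (by default) moving-average path used by VAP; output length M."""
    x, y = _as_coords(x, y)
    if len(x) == 0:
        return x.copy(), y.copy()
    return _moving_mean_truncated(x, half_window), _moving_mean_truncated(y, half_window)


def vap(x, y, delta_t: float, min_frames: int = DEFAULT_MIN_FRAMES_VAP) -> float:
    """Average path velocity: VCL of the smoothed path, μm/s.

    Requires ``min_frames`` samples (default 7) so the 5-point window has
    meaningful interior support.
    """
    x, y = _as_coords(x, y)
    if len(x) < min_frames:
        raise InsufficientLengthError(
            f"VAP needs at least {min_frames} points, got {len(x)}"
        )
    xs, ys = smooth_path(x, y)
    return vcl(xs, ys, delta_t)


def motility_record(
    x,
    y,
    delta_t: float,
    track_id: int = 0,
    min_frames_vap: int = DEFAULT_MIN_FRAMES_VAP,
) -> MotilityRecord:
    """Compute the full MotilityRecord for one trajectory.

    Ratios are left ``None`` (undefined) for tracks with zero VCL or zero VAP,
    and VAP/STR/WOB are ``None`` for tracks shorter than ``min_frames_vap``.
    """
    x, y = _as_coords(x, y)
    m = len(x)
    v_cl = vcl(x, y, delta_t)
    v_sl = vsl(x, y, delta_t)
    v_ap: float | None
    if m >= min_frames_vap:
        v_ap = vap(x, y, delta_t, min_frames=min_frames_vap)
    else:
        v_ap = None
    lin = v_sl / v_cl if v_cl > 0 else None
    s_tr = v_sl / v_ap if (v_ap is not None and v_ap > 0) else None
    wob = v_ap / v_cl if (v_ap is not None and v_cl > 0) else None
    return MotilityRecord(
        track_id=track_id, VCL=v_cl, VSL=v_sl, VAP=v_ap,
        LIN=lin, STR=s_tr, WOB=wob, M=m, delta_t=delta_t,
    )


def motility_record_from_track(
    track: "Track", min_frames_vap: int = DEFAULT_MIN_FRAMES_VAP
) -> MotilityRecord:
    """MotilityRecord for a linked Track (uniform frame spacing required)."""
    frames = track.frames
    if len(frames) >= 2 and np.any(np.diff(frames) != 1):
        raise InvalidInputError(
            f"track {track.track_id} has frame gaps; motility formulas assume "
            "uniform inter-frame time"
        )
    return motility_record(
        track.x_um, track.y_um, 1.0 / track.fps,
        track_id=track.track_id, min_frames_vap=min_frames_vap,
    )


def records_to_dataframe(records: Iterable[MotilityRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        df = pd.DataFrame(columns=RECORD_COLUMNS)
    return df[RECORD_COLUMNS]


def records_from_dataframe(
    df: pd.DataFrame, fps: float, min_frames_vap: int = DEFAULT_MIN_FRAMES_VAP
) -> list[MotilityRecord]:
    """Per-track records from a long-format track table.

    Expects columns ``track_id, frame, x_um, y_um`` (the track CSV schema).
    Tracks with frame gaps are skipped with a warning, as the velocity
    formulas assume uniform sampling.
    """
    import logging

    log = logging.getLogger(__name__)
    out = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        frames = grp["frame"].to_numpy()
        if len(frames) < 2:
            continue
        if np.any(np.diff(frames) != 1):
            log.warning("track %s has frame gaps; skipped", tid)
            continue
        out.append(
            motility_record(
                grp["x_um"].to_numpy(), grp["y_um"].to_numpy(), 1.0 / fps,
                track_id=int(tid), min_frames_vap=min_frames_vap,
            )
        )
    return out


def summarize_population(
    records: Sequence[MotilityRecord], as_percent: bool = False
) -> pd.DataFrame:
    """Population mean ± sample SD (ddof=1) per motility parameter.

    Returns a DataFrame indexed by parameter with columns ``mean``, ``sd``
    and ``n`` (number of tracks contributing, i.e. with the parameter
    defined).  A parameter with a single contributing track gets sd = 0.
    With ``as_percent=True`` the ratio rows (LIN/STR/WOB) are scaled to %.
    """
    if len(records) == 0:
        raise InvalidInputError("summarize_population requires at least one record")
    rows = {}
    for name in ["VCL", "VSL", "VAP", "LIN", "STR", "WOB"]:
        vals = np.array(
            [getattr(r, name) for r in records if getattr(r, name) is not None],
            dtype=float,
        )
        if name in ("LIN", "STR", "WOB") and as_percent:
            vals = vals * 100.0
        if len(vals) == 0:
            rows[name] = {"mean": np.nan, "sd": np.nan, "n": 0}
        else:
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows[name] = {"mean": float(vals.mean()), "sd": sd, "n": len(vals)}
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd", "n"]]
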