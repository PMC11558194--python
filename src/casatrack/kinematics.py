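"""Ground-truth sperm head kinematics simulator.

No public sperm-video dataset accompanies the dark-field CASA workflow this
package implements, so every pipeline stage is validated against simulated
trajectories with known kinematics.  The motion model is deliberately
minimal but reproduces the qualitative structure of real CASA data
(VCL > VAP > VSL, WOB < 1):

* centre path — constant-speed 2-D propagation whose heading performs a
  Brownian random walk (variance ``heading_diffusion`` rad²/s);
* head wobble — a sinusoidal lateral displacement of amplitude
  ``wobble_amplitude`` and frequency ``wobble_frequency`` about the centre
  path, applied along the instantaneous path normal with a uniform random
  phase per sperm;
* an immotile fraction whose tracks have zero progressive speed and no
  wobble (Brownian positional noise only);
* optional isotropic Gaussian positional noise per sample.

Speeds are drawn from a normal distribution truncated at zero.  Motion is
2-D: the 10 μm-deep counting chamber confines swimming essentially to the
focal plane.  Tracks that leave the rectangular field of view are truncated
at the first exit (not reflected), which exercises variable-length-track
handling downstream.

This module also carries ``ground_truth_motility``, an independent
brute-force implementation of the motility formulas (plain Python loops),
used as the oracle against which the vectorised :mod:`casatrack.motility`
module is verified.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientLengthError, InvalidInputError
from .motility import DEFAULT_MIN_FRAMES_VAP, MotilityRecord

log = logging.getLogger(__name__)

#: Ground-truth CSV schema (shared with the linked-track export, so the two
#: can be diffed directly).
TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um"]

#: Temperature gradient used by the temperature-response recipe, °C.
TEMPERATURE_GRID = (26.0, 28.0, 30.0, 32.0, 34.0, 37.0)


@dataclass(frozen=True)
class KinematicsParams:
    """Population-level motion parameters.

    Defaults emulate moderately motile human sperm in a counting chamber:
    progressive speeds of a few tens of μm/s with a several-μm lateral head
    displacement beating near 10 Hz, and a minority immotile fraction.
    """

    progressive_speed_mean: float = 25.0   # μm/s
    progressive_speed_sd: float = 8.0      # μm/s
    wobble_amplitude: float = 2.5          # μm
    wobble_frequency: float = 10.0         # Hz
    heading_diffusion: float = 0.5         # rad²/s
    immotile_fraction: float = 0.2         # dimensionless
    positional_noise_sd: float = 0.1       # μm

    def __post_init__(self) -> None:
        for name in (
            "progressive_speed_mean", "progressive_speed_sd", "wobble_amplitude",
            "wobble_frequency", "heading_diffusion", "positional_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not 0.0 <= self.immotile_fraction <= 1.0:
            raise InvalidInputError("immotile_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TemperatureModel:
    """Linear speed-temperature response.

    Mean progressive speed increases by ``speed_slope`` (μm/s)/°C away from
    ``reference_temperature``; wobble parameters are unaffected (observed
    head-wobble amplitude does not change appreciably with chamber
    temperature).
    """

    reference_temperature: float = 26.0    # °C
    speed_slope: float = 1.0               # (μm/s)/°C

    def __post_init__(self) -> None:
        if self.speed_slope < 0:
            raise InvalidInputError("speed_slope must be >= 0 for the default model")


@dataclass(frozen=True)
class GroundTruthTrack:
    """Simulated head positions of one sperm on a uniform time grid."""

    track_id: int
    times: np.ndarray  # s, uniformly spaced at 1/fps
    x: np.ndarray      # μm
    y: np.ndarray      # μm

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise InvalidInputError("times, x and y must have equal length")
        if len(self.times) < 2:
            raise InvalidInputError("a track needs at least 2 samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise InvalidInputError("times must be strictly increasing with constant step")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def delta_t(self) -> float:
        return float(self.times[1] - self.times[0])


def _draw_speeds(params: KinematicsParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Progressive speeds from a normal truncated at zero."""
    mu, sd = params.progressive_speed_mean, params.progressive_speed_sd
    if sd == 0:
        return np.full(n, mu)
    a = (0.0 - mu) / sd  # lower truncation at 0 in standard units
    return sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def simulate_tracks(
    params: KinematicsParams,
    n_sperm: int,
    duration: float,
    fps: float,
    field_of_view: tuple[float, float] = (512.0, 512.0),
    seed: int = 0,
    *,
    min_separation: float | None = None,
    spawn_margin: float = 0.0,
) -> list[GroundTruthTrack]:
    """Simulate ``n_sperm`` ground-truth head trajectories.

    Parameters
    ----------
    duration, fps:
        A clip of ``duration`` seconds sampled at ``fps`` contains
        ``round(duration*fps) + 1`` frames, so the elapsed time
        (M-1)/fps equals ``duration`` exactly.
    field_of_view:
        (width, height) of the rectangular chamber field, μm.  Tracks are
        truncated at their first exit; tracks left with fewer than 2
        in-field samples are dropped (their ids stay reserved so surviving
        ids still index the spawn order).
    min_separation:
        Optional minimum pairwise distance between spawn positions, μm
        (rejection-sampled); useful for building well-separated scenes.
    spawn_margin:
        Keep spawn positions at least this far from the field edges, μm.

    Identical ``seed`` and parameters give bitwise-identical output.
    """
    if n_sperm < 1:
        raise InvalidInputError("n_sperm must be >= 1")
    if fps <= 0 or duration <= 0:
        raise InvalidInputError("fps and duration must be positive")
    width, height = field_of_view
    if width <= 0 or height <= 0:
        raise InvalidInputError("field_of_view dimensions must be positive")
    if spawn_margin * 2 >= min(width, height):
        raise InvalidInputError("spawn_margin leaves no room to place sperm")

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * fps)) + 1
    dt = 1.0 / fps
    t = np.arange(n_frames) * dt

    # Spawn positions (optionally with a minimum pairwise separation).
    lo = np.array([spawn_margin, spawn_margin])
    hi = np.array([width - spawn_margin, height - spawn_margin])
    positions = np.empty((n_sperm, 2))
    placed = 0
    attempts = 0
    while placed < n_sperm:
        cand = rng.uniform(lo, hi)
        if min_separation is not None and placed > 0:
            d2 = np.sum((positions[:placed] - cand) ** 2, axis=1)
            if np.min(d2) < min_separation**2:
                attempts += 1
                if attempts > 100_000:
                    raise InvalidInputError(
                        "could not place sperm with the requested min_separation; "
                        "enlarge the field of view or reduce n_sperm"
                    )
                continue
        positions[placed] = cand
        placed += 1

    immotile = rng.random(n_sperm) < params.immotile_fraction
    speeds = _draw_speeds(params, n_sperm, rng)
    speeds[immotile] = 0.0
    headings0 = rng.uniform(0.0, 2.0 * np.pi, n_sperm)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_sperm)

    tracks: list[GroundTruthTrack] = []
    for i in range(n_sperm):
        # Heading random walk (frozen for immotile sperm: no wobble either).
        dtheta = rng.normal(0.0, np.sqrt(params.heading_diffusion * dt), n_frames - 1)
        theta = headings0[i] + np.concatenate([[0.0], np.cumsum(dtheta)])
        steps = speeds[i] * dt * np.column_stack([np.cos(theta[:-1]), np.sin(theta[:-1])])
        center = positions[i] + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

        if immotile[i] or params.wobble_amplitude == 0:
            head = center
        else:
            lateral = params.wobble_amplitude * np.sin(
                2.0 * np.pi * params.wobble_frequency * t + phases[i]
            )
            normal = np.column_stack([-np.sin(theta), np.cos(theta)])
            head = center + lateral[:, None] * normal

        if params.positional_noise_sd > 0:
            head = head + rng.normal(0.0, params.positional_noise_sd, head.shape)

        inside = (
            (head[:, 0] >= 0) & (head[:, 0] <= width)
            & (head[:, 1] >= 0) & (head[:, 1] <= height)
        )
        if not inside[0]:
            continue  # spawn pushed out by noise; id stays reserved
        exit_idx = np.argmin(inside) if not inside.all() else n_frames
        if exit_idx < 2:
            continue
        tracks.append(
            GroundTruthTrack(
                track_id=i,
                times=t[:exit_idx].copy(),
                x=head[:exit_idx, 0].copy(),
                y=head[:exit_idx, 1].copy(),
            )
        )
    return tracks


def ground_truth_motility(
    track: GroundTruthTrack, min_frames_vap: int = 2
) -> MotilityRecord:
    """Brute-force motility oracle: direct loop summation of the formulas.

    Implemented independently of :mod:`casatrack.motility` (plain Python
    arithmetic, explicit windows) so the two can cross-check each other.
    """
    xs = [float(v) for v in track.x]
    ys = [float(v) for v in track.y]
    m = len(xs)
    if m < 2:
        raise InsufficientLengthError("motility oracle needs at least 2 samples")
    dt = track.delta_t
    elapsed = (m - 1) * dt

    path = 0.0
    for j in range(m - 1):
        path += ((xs[j + 1] - xs[j]) ** 2 + (ys[j + 1] - ys[j]) ** 2) ** 0.5
    v_cl = path / elapsed

    v_sl = ((xs[-1] - xs[0]) ** 2 + (ys[-1] - ys[0]) ** 2) ** 0.5 / elapsed

    v_ap = None
    if m >= min_frames_vap:
        xbar, ybar = [], []
        for k in range(m):
            half = min(k, m - 1 - k, 2)  # symmetric shrinking centred window
            lo, hi = k - half, k + half
            window = hi - lo + 1
            xbar.append(sum(xs[lo : hi + 1]) / window)
            ybar.append(sum(ys[lo : hi + 1]) / window)
        smooth = 0.0
        for j in range(m - 1):
            smooth += ((xbar[j + 1] - xbar[j]) ** 2 + (ybar[j + 1] - ybar[j]) ** 2) ** 0.5
        v_ap = smooth / elapsed

    lin = v_sl / v_cl if v_cl > 0 else None
    s_tr = v_sl / v_ap if (v_ap is not None and v_ap > 0) else None
    wob = v_ap / v_cl if (v_ap is not None and v_cl > 0) else None
    return MotilityRecord(
        track_id=track.track_id, VCL=v_cl, VSL=v_sl, VAP=v_ap,
        LIN=lin, STR=s_tr, WOB=wob, M=m, delta_t=dt,
    )


def apply_temperature(
    params: KinematicsParams, model: TemperatureModel, temperature: float
) -> KinematicsParams:
    """Scale the mean progressive speed linearly with chamber temperature.

    Wobble parameters are unchanged.  Temperatures outside the 20–40 °C
    advisory range are allowed but logged.
    """
    if not 20.0 <= temperature <= 40.0:
        log.warning("temperature %.1f °C outside the 20–40 °C advisory range", temperature)
    new_mean = params.progressive_speed_mean + model.speed_slope * (
        temperature - model.reference_temperature
    )
    if new_mean < 0:
        log.warning("temperature model drove mean speed below 0; clipping to 0")
        new_mean = 0.0
    return dataclasses.replace(params, progressive_speed_mean=new_mean)


def temperature_sweep(
    params: KinematicsParams,
    model: TemperatureModel,
    temperatures: Sequence[float] = TEMPERATURE_GRID,
    n_sperm: int = 50,
    duration: float = 1.0,
    fps: float = 30.0,
    field_of_view: tuple[float, float] = (512.0, 512.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Simulated temperature-response experiment.

    Simulates one chamber per temperature (common random numbers: the same
    seed is reused at every temperature, so the speed draws differ only by
    the temperature-shifted mean) and summarises mean VCL/VSL/VAP via the
    motility module.  Returns the per-temperature table and the
    least-squares slope of mean VCL against temperature, (μm/s)/°C.
    """
    from . import motility

    rows = []
    for temp in temperatures:
        p_t = apply_temperature(params, model, temp)
        tracks = simulate_tracks(
            p_t, n_sperm, duration, fps, field_of_view, seed=seed, spawn_margin=5.0
        )
        recs = [
            motility.motility_record(tr.x, tr.y, tr.delta_t, track_id=tr.track_id)
            for tr in tracks
            if tr.n_frames >= DEFAULT_MIN_FRAMES_VAP
        ]
        summary = motility.summarize_population(recs)
        rows.append(
            {
                "temperature_C": temp,
                "mean_VCL": summary.loc["VCL", "mean"],
                "mean_VSL": summary.loc["VSL", "mean"],
                "mean_VAP": summary.loc["VAP", "mean"],
                "n_tracks": len(recs),
            }
        )
    df = pd.DataFrame(rows)
    slope = float(np.polyfit(df["temperature_C"], df["mean_VCL"], 1)[0])
    return df, slope


# ---------------------------------------------------------------------------
# Export / import and ground-truth matching utilities
# ---------------------------------------------------------------------------

def tracks_to_dataframe(tracks: Sequence[GroundTruthTrack]) -> pd.DataFrame:
    """Long-format table with columns track_id, frame, time_s, x_um, y_um."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": np.round(tr.times / tr.delta_t).astype(int),
                    "time_s": tr.times,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRACK_COLUMNS]


def tracks_from_dataframe(df: pd.DataFrame) -> list[GroundTruthTrack]:
    out = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        out.append(
            GroundTruthTrack(
                track_id=int(tid),
                times=grp["time_s"].to_numpy(float),
                x=grp["x_um"].to_numpy(float),
                y=grp["y_um"].to_numpy(float),
            )
        )
    return out


def match_to_ground_truth(
    recovered: Sequence,
    truth: Sequence[GroundTruthTrack],
    tol_um: float = 5.0,
    frame_stride: int = 1,
) -> dict[int, int | None]:
    """Map each recovered track to a ground-truth identity, or None.

    A recovered track (anything with ``track_id``, ``frames``, ``x_um``,
    ``y_um`` attributes) matches ground-truth sperm ``g`` iff at *every* one
    of its frames the recovered position lies within ``tol_um`` of g's true
    position and g is the nearest sperm at that frame.  Tracks that switch
    identity or drift beyond tolerance map to ``None``.  ``frame_stride``
    maps recovered frame indices onto the ground-truth grid when the
    recovered video was temporally subsampled.
    """
    # Per-frame lookup of true positions.
    by_frame: dict[int, list[tuple[int, float, float]]] = {}
    for g in truth:
        for j in range(g.n_frames):
            f = int(round(g.times[j] / g.delta_t))
            by_frame.setdefault(f, []).append((g.track_id, float(g.x[j]), float(g.y[j])))

    result: dict[int, int | None] = {}
    for tr in recovered:
        ids = set()
        ok = True
        for f, x, y in zip(tr.frames, tr.x_um, tr.y_um):
            cands = by_frame.get(int(f) * frame_stride, [])
            if not cands:
                ok = False
                break
            d2 = [(x - cx) ** 2 + (y - cy) ** 2 for _, cx, cy in cands]
            k = int(np.argmin(d2))
            if d2[k] > tol_um**2:
                ok = False
                break
            ids.add(cands[k][0])
            if len(ids) > 1:
                ok = False
                break
        result[tr.track_id] = ids.pop() if (ok and len(ids) == 1) else None
    return result
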