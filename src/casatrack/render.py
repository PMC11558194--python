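"""Render ground-truth tracks into synthetic dark-field video frames.

In dark-field contrast sperm heads scatter light into the objective and
appear as bright blobs on a dark background.  Each head is rendered as an
anisotropic 2-D Gaussian whose long axis follows the instantaneous heading;
segmentation and tracking only consume the head centroid, so blob shape and
SNR are the relevant photometric properties, not textured realism.  The
half-maximum contour of the Gaussian is an ellipse with the configured
semi-axes, so the nominal apparent head area is ``pi * a * b``.

Noise is additive Gaussian read noise.  Optional distractors emulate
sub-threshold debris and out-of-plane particles: dim small specks and
bright large debris, both outside the sperm area band, static up to a
per-frame positional jitter.  The read-noise and distractor random streams
are split from the seed independently, so enabling distractors does not
alter the noise field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, InvalidInputError
from .kinematics import GroundTruthTrack

#: Half-max contour radius of a Gaussian in units of sigma.
_HALF_MAX_SIGMA = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class OpticsConfig:
    """Photometric and geometric model of the synthetic dark-field camera.

    ``head_semi_axes`` are the semi-axes (μm) of the half-maximum intensity
    contour; the defaults give a nominal apparent head area of
    ``pi * 2.0 * 1.25 ≈ 7.9`` μm², inside the 3–30 μm² band used by the
    particle filter.  Intensities are gray levels at ``bit_depth``.
    """

    pixel_size: float = 0.5                       # μm/px at the sample plane
    frame_shape: tuple[int, int] = (512, 512)     # (rows, cols)
    head_semi_axes: tuple[float, float] = (2.0, 1.25)   # μm (major, minor)
    head_peak_intensity: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 5.0
    bit_depth: int = 8
    # Distractors: dim sub-band specks and bright over-band debris.
    n_distractors: int = 0
    distractor_area_range: tuple[float, float] = (0.5, 2.0)   # μm²
    distractor_peak_intensity: float = 15.0
    n_debris: int = 0
    debris_area_range: tuple[float, float] = (40.0, 80.0)     # μm²
    debris_peak_intensity: float = 160.0
    distractor_jitter_sd: float = 0.2                         # μm per frame
    distractor_min_clearance: float = 12.0                    # μm from any head

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.head_peak_intensity <= self.background_level:
            raise ConfigError("head_peak_intensity must exceed background_level")
        if self.bit_depth not in (8, 12, 16):
            raise ConfigError("bit_depth must be 8, 12 or 16")
        if any(a <= 0 for a in self.head_semi_axes):
            raise ConfigError("head semi-axes must be positive")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ConfigError("noise_sd and background_level must be non-negative")

    @property
    def head_area_um2(self) -> float:
        """Nominal apparent head area (half-max ellipse), μm²."""
        return math.pi * self.head_semi_axes[0] * self.head_semi_axes[1]

    @property
    def max_gray(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class VideoStack:
    """Frames plus the acquisition metadata the formulas depend on."""

    frames: np.ndarray       # (time, rows, cols), unsigned integer
    fps: float
    pixel_size: float        # μm/px

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise InvalidInputError("frames must be a (time, rows, cols) array")
        if self.fps <= 0 or self.pixel_size <= 0:
            raise InvalidInputError("fps and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        """Elapsed time (M-1)/fps: 31 frames at 30 fps span exactly 1 s."""
        return (self.n_frames - 1) / self.fps


def _add_gaussian_blob(
    canvas: np.ndarray,
    x_um: float,
    y_um: float,
    theta: float,
    sigma_u: float,
    sigma_v: float,
    peak: float,
    pixel_size: float,
) -> None:
    """Accumulate an oriented Gaussian blob onto ``canvas`` (in place).

    Only a +/- 4 sigma window is evaluated.  x maps to columns, y to rows;
    μm coordinates equal pixel index times pixel_size at pixel centres.
    """
    rows, cols = canvas.shape
    r0 = y_um / pixel_size
    c0 = x_um / pixel_size
    half = 4.0 * max(sigma_u, sigma_v) / pixel_size
    rlo = max(int(math.floor(r0 - half)), 0)
    rhi = min(int(math.ceil(r0 + half)) + 1, rows)
    clo = max(int(math.floor(c0 - half)), 0)
    chi = min(int(math.ceil(c0 + half)) + 1, cols)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    dx = cc * pixel_size - x_um
    dy = rr * pixel_size - y_um
    u = math.cos(theta) * dx + math.sin(theta) * dy
    v = -math.sin(theta) * dx + math.cos(theta) * dy
    canvas[rlo:rhi, clo:chi] += peak * np.exp(
        -(u**2 / (2.0 * sigma_u**2) + v**2 / (2.0 * sigma_v**2))
    )


def _headings(track: GroundTruthTrack) -> np.ndarray:
    """Per-sample heading angle from path increments (rad); 0 when static."""
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    theta = np.zeros(track.n_frames)
    moving = (dx != 0) | (dy != 0)
    seg_theta = np.arctan2(dy, dx)
    # Forward-fill headings over zero-length segments.
    last = 0.0
    for j in range(track.n_frames - 1):
        if moving[j]:
            last = seg_theta[j]
        theta[j] = last
    theta[-1] = last
    return theta


def _place_distractors(
    n: int,
    area_range: tuple[float, float],
    optics: OpticsConfig,
    rng: np.random.Generator,
    head_tree: cKDTree | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Base positions (μm) and isotropic sigmas (μm) for one distractor class."""
    width = optics.frame_shape[1] * optics.pixel_size
    height = optics.frame_shape[0] * optics.pixel_size
    positions = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        cand = rng.uniform([0.0, 0.0], [width, height])
        if head_tree is not None and optics.distractor_min_clearance > 0:
            if head_tree.query(cand)[0] < optics.distractor_min_clearance:
                attempts += 1
                if attempts > 200_000:
                    raise ConfigError(
                        "could not place distractors clear of sperm heads; "
                        "reduce counts or clearance"
                    )
                continue
        positions[placed] = cand
        placed += 1
    areas = rng.uniform(area_range[0], area_range[1], n)
    # Half-max disc of area A has radius sqrt(A/pi) = sigma * sqrt(2 ln 2).
    sigmas = np.sqrt(areas / math.pi) / _HALF_MAX_SIGMA
    return positions, sigmas


def render_video(
    tracks: Sequence[GroundTruthTrack],
    optics: OpticsConfig | None = None,
    seed: int = 0,
    n_frames: int | None = None,
    fps: float | None = None,
) -> VideoStack:
    """Render tracks into a dark-field video stack.

    ``n_frames``/``fps`` default to the longest track's grid and must be
    given explicitly for an empty scene.  Identical seed and inputs yield
    identical frames.
    """
    optics = optics or OpticsConfig()
    if tracks:
        dts = {round(tr.delta_t, 12) for tr in tracks}
        if len(dts) != 1:
            raise InvalidInputError("all tracks must share the same frame interval")
        track_fps = 1.0 / tracks[0].delta_t
        if fps is not None and not math.isclose(fps, track_fps, rel_tol=1e-9):
            raise InvalidInputError("fps does not match the tracks' time grid")
        fps = track_fps
        if n_frames is None:
            n_frames = max(tr.n_frames for tr in tracks)
    if n_frames is None or fps is None:
        raise InvalidInputError("an empty scene needs explicit n_frames and fps")

    noise_seq, distractor_seq = np.random.SeedSequence(seed).spawn(2)
    noise_rng = np.random.default_rng(noise_seq)
    distractor_rng = np.random.default_rng(distractor_seq)

    sigma_u = optics.head_semi_axes[0] / _HALF_MAX_SIGMA
    sigma_v = optics.head_semi_axes[1] / _HALF_MAX_SIGMA
    peak = optics.head_peak_intensity - optics.background_level
    headings = [_headings(tr) for tr in tracks]

    head_tree = None
    if (optics.n_distractors or optics.n_debris) and tracks:
        pts = np.concatenate([np.column_stack([tr.x, tr.y]) for tr in tracks])
        head_tree = cKDTree(pts)
    speck_pos, speck_sig = _place_distractors(
        optics.n_distractors, optics.distractor_area_range, optics, distractor_rng, head_tree
    )
    debris_pos, debris_sig = _place_distractors(
        optics.n_debris, optics.debris_area_range, optics, distractor_rng, head_tree
    )
    speck_peak = optics.distractor_peak_intensity
    debris_peak = optics.debris_peak_intensity - optics.background_level

    frames = np.empty((n_frames, *optics.frame_shape), dtype=np.float64)
    for f in range(n_frames):
        canvas = np.full(optics.frame_shape, float(optics.background_level))
        for tr, theta in zip(tracks, headings):
            if f < tr.n_frames:
                _add_gaussian_blob(
                    canvas, tr.x[f], tr.y[f], theta[f],
                    sigma_u, sigma_v, peak, optics.pixel_size,
                )
        for (px, py), sig in zip(speck_pos, speck_sig):
            jx, jy = distractor_rng.normal(0.0, optics.distractor_jitter_sd, 2)
            _add_gaussian_blob(canvas, px + jx, py + jy, 0.0, sig, sig,
                               speck_peak, optics.pixel_size)
        for (px, py), sig in zip(debris_pos, debris_sig):
            jx, jy = distractor_rng.normal(0.0, optics.distractor_jitter_sd, 2)
            _add_gaussian_blob(canvas, px + jx, py + jy, 0.0, sig, sig,
                               debris_peak, optics.pixel_size)
        if optics.noise_sd > 0:
            canvas += noise_rng.normal(0.0, optics.noise_sd, optics.frame_shape)
        frames[f] = canvas

    np.clip(np.rint(frames), 0, optics.max_gray, out=frames)
    dtype = np.uint8 if optics.bit_depth <= 8 else np.uint16
    return VideoStack(frames=frames.astype(dtype), fps=float(fps),
                      pixel_size=optics.pixel_size)


def subsample_fps(video: VideoStack, target_fps: float) -> VideoStack:
    """Temporal subsampling: keep every (fps/target_fps)-th frame from frame 0.

    The stride must be an exact integer (e.g. 100 → 10 fps keeps frames
    0, 10, 20, ...); a non-integer stride raises.
    """
    if target_fps <= 0:
        raise InvalidInputError("target_fps must be positive")
    ratio = video.fps / target_fps
    stride = int(round(ratio))
    if stride < 1 or not math.isclose(ratio, stride, rel_tol=1e-9):
        raise InvalidInputError(
            f"target fps {target_fps} does not evenly divide {video.fps}"
        )
    return VideoStack(
        frames=video.frames[::stride].copy(), fps=target_fps,
        pixel_size=video.pixel_size,
    )
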