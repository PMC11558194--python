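"""Video and table I/O.

Video fixtures are multi-page TIFF (primary) or AVI/MP4; the acquisition
frame rate and pixel calibration are not reliably stored by those
containers, so they travel in a small YAML sidecar (``<video>.yaml``) and
can be overridden by explicit arguments.  Missing calibration is a hard
error — there is no silent default, because every velocity in the pipeline
depends on fps and μm/px.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidInputError
from .render import VideoStack

log = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_MOVIE_SUFFIXES = {".avi", ".mp4", ".mov", ".mkv"}

#: Rec. 709 luminance weights for collapsing colour frames to grayscale.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_video(video: VideoStack, path) -> Path:
    """Write a multi-page TIFF plus a YAML sidecar with fps and μm/px."""
    path = Path(path)
    if path.suffix.lower() not in _TIFF_SUFFIXES:
        raise InvalidInputError("write_video writes multi-page TIFF (.tif/.tiff)")
    tifffile.imwrite(path, video.frames, photometric="minisblack")
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"fps": float(video.fps), "pixel_size_um": float(video.pixel_size)}, fh
        )
    return path


def read_video(path, fps: float | None = None, pixel_size: float | None = None) -> VideoStack:
    """Load a video as a grayscale VideoStack at native bit depth.

    Colour inputs are collapsed by luminance.  fps / pixel_size are taken
    from explicit arguments first, then from the sidecar; if either is
    still unknown, an error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"video file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        frames = tifffile.imread(path)
    elif suffix in _MOVIE_SUFFIXES:
        import imageio.v3 as iio

        frames = iio.imread(path)
    else:
        raise InvalidInputError(f"unsupported video format: {suffix}")

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim == 4:  # (time, rows, cols, channels) → luminance
        frames = np.tensordot(frames[..., :3].astype(float), _LUMA, axes=([-1], [0]))
        frames = np.rint(frames).astype(np.uint8)
    if frames.ndim != 3:
        raise InvalidInputError(f"{path}: expected a stack of 2-D frames")

    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    fps = fps if fps is not None else meta.get("fps")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if fps is None:
        raise InvalidInputError(
            f"{path}: frame rate unknown — pass fps explicitly or provide a sidecar"
        )
    if pixel_size is None:
        raise InvalidInputError(
            f"{path}: pixel calibration unknown — pass pixel_size explicitly "
            "or provide a sidecar"
        )
    return VideoStack(frames=frames, fps=float(fps), pixel_size=float(pixel_size))


# ---------------------------------------------------------------------------
# CSV helpers (schemas defined by the producing modules)
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"track_id", "frame", "x_um", "y_um"}
    missing = needed - set(df.columns)
    if missing:
        raise InvalidInputError(f"track CSV missing columns: {sorted(missing)}")
    return df
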