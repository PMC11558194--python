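"""Per-frame sperm-head extraction from dark-field frames.

Three steps: threshold segmentation (bright objects over a dark background),
8-connected component analysis with intensity-weighted sub-pixel centroids,
and a particle filter keeping components with apparent area inside a closed
band (default 3–30 μm², the apparent size of a sperm head), which rejects
both noise specks and large debris.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label, regionprops

from .errors import ConfigError, InvalidInputError
from .render import VideoStack

log = logging.getLogger(__name__)

#: Detections CSV schema.
DETECTION_COLUMNS = ["frame", "x_um", "y_um", "row_px", "col_px", "area_um2", "mean_intensity"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold and particle-filter settings.

    ``threshold_method``:

    * ``"multiotsu"`` (default) — three-class Otsu, taking the upper class
      boundary.  Sperm heads occupy a tiny pixel fraction of a dark-field
      frame, so two-class Otsu can split the background noise instead of
      separating the bright heads; the three-class variant reserves one
      class for the heads and stays deterministic and parameter-free.
    * ``"otsu"`` — classic two-class Otsu per frame.
    * ``"fixed"`` — the configured ``fixed_threshold`` in gray levels,
      for exactly reproducing a given run.

    ``pre_blur_sigma`` (px) optionally smooths the frame before
    thresholding; off by default.
    """

    threshold_method: str = "multiotsu"
    fixed_threshold: float | None = None
    min_area: float = 3.0     # μm²
    max_area: float = 30.0    # μm²
    pre_blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("multiotsu", "otsu", "fixed"):
            raise ConfigError("threshold_method must be 'multiotsu', 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("fixed threshold_method requires fixed_threshold")
        if not 0 < self.min_area < self.max_area:
            raise ConfigError("need 0 < min_area < max_area")
        if self.pre_blur_sigma < 0:
            raise ConfigError("pre_blur_sigma must be non-negative")


@dataclass(frozen=True)
class Detection:
    """One segmented particle in one frame.

    ``centroid_px`` is (row, col) sub-pixel; ``centroid_um`` is (x, y) with
    x = col * pixel_size and y = row * pixel_size (origin at the centre of
    pixel (0, 0)).
    """

    frame_index: int
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]
    area_um2: float
    mean_intensity: float

    @property
    def x_um(self) -> float:
        return self.centroid_um[0]

    @property
    def y_um(self) -> float:
        return self.centroid_um[1]


def segment_frame(frame: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean mask of pixels brighter than the threshold.

    With Otsu's method a constant-intensity frame has no threshold; an
    all-false mask is returned with a logged warning.
    """
    config = config or SegmentationConfig()
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise InvalidInputError("frame must be a non-empty 2-D array")
    img = frame.astype(float)
    if config.pre_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, config.pre_blur_sigma)
    if config.threshold_method == "fixed":
        thr = float(config.fixed_threshold)
    else:
        if np.all(img == img.flat[0]):
            log.warning("constant-intensity frame: Otsu threshold undefined, empty mask")
            return np.zeros(frame.shape, dtype=bool)
        if config.threshold_method == "multiotsu":
            try:
                thr = float(threshold_multiotsu(img, classes=3)[-1])
            except ValueError:
                # Fewer than 3 distinct gray levels: fall back to two-class.
                thr = float(threshold_otsu(img))
        else:
            thr = float(threshold_otsu(img))
    return img > thr


def extract_particles(
    mask: np.ndarray,
    frame: np.ndarray,
    pixel_size: float,
    frame_index: int = 0,
) -> list[Detection]:
    """Unfiltered detections: one per 8-connected component of ``mask``.

    Centroids are intensity-weighted means over member pixels; area is
    pixel count times ``pixel_size`` squared.
    """
    mask = np.asarray(mask, dtype=bool)
    frame = np.asarray(frame)
    if mask.shape != frame.shape:
        raise InvalidInputError("mask and frame must have the same shape")
    if pixel_size <= 0:
        raise ConfigError("pixel_size must be positive")
    labelled = label(mask, connectivity=2)
    out = []
    for prop in regionprops(labelled, intensity_image=frame.astype(float)):
        row, col = prop.centroid_weighted
        out.append(
            Detection(
                frame_index=frame_index,
                centroid_px=(float(row), float(col)),
                centroid_um=(float(col) * pixel_size, float(row) * pixel_size),
                area_um2=float(prop.area) * pixel_size**2,
                mean_intensity=float(prop.intensity_mean),
            )
        )
    return out


def area_filter(
    detections: list[Detection], config: SegmentationConfig | None = None
) -> list[Detection]:
    """Keep detections with min_area <= area <= max_area (closed interval)."""
    config = config or SegmentationConfig()
    return [d for d in detections if config.min_area <= d.area_um2 <= config.max_area]


def detect_frame(
    frame: np.ndarray,
    pixel_size: float,
    config: SegmentationConfig | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """segment → extract → area-filter for a single frame."""
    config = config or SegmentationConfig()
    mask = segment_frame(frame, config)
    return area_filter(extract_particles(mask, frame, pixel_size, frame_index), config)


def detect_video(
    video: VideoStack, config: SegmentationConfig | None = None
) -> list[list[Detection]]:
    """Filtered detections per frame for a whole video stack."""
    config = config or SegmentationConfig()
    return [
        detect_frame(video.frames[f], video.pixel_size, config, frame_index=f)
        for f in range(video.n_frames)
    ]
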