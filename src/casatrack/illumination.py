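"""LED-array illumination geometry and bright-/dark-field mode classification.

A ring LED array sits a fixed distance below the sample plane.  Each LED
illuminates the specimen at an angle ``alpha = arctan(r / d)`` where ``r`` is
the radial offset of its ring and ``d`` the array-to-sample distance.  The
objective collects rays inside its acceptance half-angle
``theta = arcsin(NA)``.  A pattern whose LEDs all lie inside the acceptance
cone produces bright-field (BF) contrast, one entirely outside produces
dark-field (DF) contrast, and any mixture superposes the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import yaml

from .errors import ConfigError, InvalidInputError

#: Default ring LED counts: a central LED plus four concentric rings (61 total).
DEFAULT_RING_COUNTS = (1, 8, 12, 16, 24)

#: Default ring radii in mm (8 mm pitch).  Chosen together with the 40 mm
#: array-to-sample distance so that at NA = 0.3 the central LED and first
#: annulus illuminate inside the acceptance cone (BF) while the outer three
#: rings — including the third ring used for DF sperm imaging — fall outside.
DEFAULT_RING_RADII = (0.0, 8.0, 16.0, 24.0, 32.0)

DEFAULT_DISTANCE_MM = 40.0


class ImagingMode(Enum):
    """Contrast regime produced by an illumination pattern."""

    BRIGHT_FIELD = "bright_field"
    DARK_FIELD = "dark_field"
    MIXED = "mixed"


@dataclass(frozen=True)
class LEDArrayConfig:
    """Geometry of the concentric-ring LED board.

    Parameters
    ----------
    ring_radii:
        Radial distance of each ring from the array centre, mm, strictly
        increasing.  The central LED is ring 0 with radius 0.
    ring_counts:
        Number of LEDs on each ring.
    array_to_sample_distance:
        Axial distance from the LED plane to the sample plane, mm.
    led_colors:
        Optional per-ring RGB triples, used only to describe patterns
        (e.g. Rheinberg-style colour coding); geometry ignores them.
    """

    ring_radii: Sequence[float] = DEFAULT_RING_RADII
    ring_counts: Sequence[int] = DEFAULT_RING_COUNTS
    array_to_sample_distance: float = DEFAULT_DISTANCE_MM
    led_colors: Sequence[tuple[int, int, int]] = field(
        default_factory=lambda: tuple((255, 255, 255) for _ in DEFAULT_RING_COUNTS)
    )

    def __post_init__(self) -> None:
        if len(self.ring_radii) != len(self.ring_counts):
            raise ConfigError("ring_radii and ring_counts must have equal length")
        radii = tuple(float(r) for r in self.ring_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ConfigError("ring radii must be strictly increasing")
        if radii[0] < 0:
            raise ConfigError("ring radii must be non-negative")
        if self.array_to_sample_distance <= 0:
            raise ConfigError("array_to_sample_distance must be positive")
        if any(c < 1 for c in self.ring_counts):
            raise ConfigError("every ring must hold at least one LED")

    @property
    def n_rings(self) -> int:
        return len(self.ring_counts)

    @property
    def n_leds(self) -> int:
        return int(sum(self.ring_counts))


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective magnification and numerical aperture (air objective)."""

    magnification: float = 10.0
    numerical_aperture: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ConfigError("numerical aperture must lie in (0, 1) for an air objective")
        if self.magnification <= 0:
            raise ConfigError("magnification must be positive")

    @property
    def acceptance_half_angle_deg(self) -> float:
        """theta = arcsin(NA), degrees."""
        return math.degrees(math.asin(self.numerical_aperture))


@dataclass(frozen=True)
class IlluminationPattern:
    """A set of active LEDs given as (ring_index, position_index) pairs."""

    active_leds: frozenset[tuple[int, int]]

    def __init__(self, active_leds: Iterable[tuple[int, int]]):
        object.__setattr__(
            self, "active_leds", frozenset((int(r), int(p)) for r, p in active_leds)
        )

    def validate(self, array: LEDArrayConfig) -> None:
        for ring, pos in self.active_leds:
            if not 0 <= ring < array.n_rings:
                raise IndexError(f"ring index {ring} out of range [0, {array.n_rings})")
            if not 0 <= pos < array.ring_counts[ring]:
                raise IndexError(
                    f"position {pos} out of range for ring {ring} "
                    f"({array.ring_counts[ring]} LEDs)"
                )

    @classmethod
    def center(cls) -> "IlluminationPattern":
        return cls([(0, 0)])

    @classmethod
    def ring(cls, ring_index: int, array: LEDArrayConfig | None = None) -> "IlluminationPattern":
        array = array or LEDArrayConfig()
        if not 0 <= ring_index < array.n_rings:
            raise IndexError(f"ring index {ring_index} out of range [0, {array.n_rings})")
        return cls((ring_index, p) for p in range(array.ring_counts[ring_index]))

    def union(self, other: "IlluminationPattern") -> "IlluminationPattern":
        return IlluminationPattern(self.active_leds | other.active_leds)


def led_angle(array: LEDArrayConfig, ring_index: int) -> float:
    """Illumination angle alpha of a ring, degrees in [0, 90).

    Point-source geometry: ``alpha = arctan(ring_radius / distance)``.
    Refraction through the chamber is not modelled.
    """
    if not 0 <= ring_index < array.n_rings:
        raise IndexError(f"ring index {ring_index} out of range [0, {array.n_rings})")
    return math.degrees(
        math.atan2(float(array.ring_radii[ring_index]), array.array_to_sample_distance)
    )


def classify_mode(
    pattern: IlluminationPattern,
    array: LEDArrayConfig | None = None,
    objective: ObjectiveSpec | None = None,
) -> ImagingMode:
    """Classify an LED pattern as BRIGHT_FIELD, DARK_FIELD or MIXED.

    BRIGHT_FIELD iff every active LED has alpha < theta; DARK_FIELD iff every
    active LED has alpha > theta; MIXED otherwise.  An LED with alpha exactly
    equal to theta is treated as mixed-contributing (marginal rays are not
    collected reliably), so it prevents both pure classifications.
    """
    array = array or LEDArrayConfig()
    objective = objective or ObjectiveSpec()
    if not pattern.active_leds:
        raise InvalidInputError("cannot classify an empty illumination pattern")
    pattern.validate(array)
    theta = objective.acceptance_half_angle_deg
    angles = [led_angle(array, ring) for ring, _ in pattern.active_leds]
    if all(a < theta for a in angles):
        return ImagingMode.BRIGHT_FIELD
    if all(a > theta for a in angles):
        return ImagingMode.DARK_FIELD
    return ImagingMode.MIXED


def load_pattern(path) -> IlluminationPattern:
    """Read a pattern file: YAML with an ``active`` list of [ring, index] pairs."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "active" not in data:
        raise InvalidInputError(f"pattern file {path} must contain an 'active' list")
    return IlluminationPattern((int(r), int(p)) for r, p in data["active"])
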