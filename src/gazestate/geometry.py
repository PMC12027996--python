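"""Screen geometry and pixel <-> visual-angle conversion.

Gaze positions arrive from the tracker in screen pixels.  All kinematic
quantities downstream (amplitudes, velocities) are expressed in degrees of
visual angle, computed per axis from the offset to the screen centre:

    angle = arctan(offset_mm / viewing_distance_mm)

The default geometry is a 511.8 x 288.3 mm, 1920 x 1080 px display viewed
from 500 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical display geometry used for angular conversion."""

    screen_width_mm: float = 511.8
    screen_height_mm: float = 288.3
    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_mm: float = 500.0

    def __post_init__(self) -> None:
        for name in ("screen_width_mm", "screen_height_mm", "width_px",
                     "height_px", "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def px_pitch_x(self) -> float:
        return self.screen_width_mm / self.width_px

    @property
    def px_pitch_y(self) -> float:
        return self.screen_height_mm / self.height_px

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


DEFAULT_GEOMETRY = DisplayGeometry()


def px_to_deg(position_px, geometry: DisplayGeometry = DEFAULT_GEOMETRY,
              axis: str = "x"):
    """Convert screen-pixel coordinates to degrees from the screen centre.

    Sign-preserving and odd about the centre: x grows rightward, y grows
    downward (screen convention).  Accepts scalars or arrays.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    pitch = geometry.px_pitch_x if axis == "x" else geometry.px_pitch_y
    center = geometry.center_px[0] if axis == "x" else geometry.center_px[1]
    offset_mm = (np.asarray(position_px, dtype=float) - center) * pitch
    return np.degrees(np.arctan2(offset_mm, geometry.viewing_distance_mm))


def deg_to_px(angle_deg, geometry: DisplayGeometry = DEFAULT_GEOMETRY,
              axis: str = "x"):
    """Inverse of :func:`px_to_deg` (tangent-screen projection)."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    pitch = geometry.px_pitch_x if axis == "x" else geometry.px_pitch_y
    center = geometry.center_px[0] if axis == "x" else geometry.center_px[1]
    offset_mm = np.tan(np.radians(np.asarray(angle_deg, dtype=float))) \
        * geometry.viewing_distance_mm
    return offset_mm / pitch + center
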