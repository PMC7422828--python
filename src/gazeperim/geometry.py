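"""Tangent-screen geometry: visual-field degrees <-> screen pixels.

The display is a flat (tangent) screen viewed from ~60 cm, with the eye
assumed on the normal through the screen centre.  The angle subtended by a
pixel offset ``u`` cm from centre is ``atan(u / d)`` per axis, so angular
offsets map to pixels through a per-axis tangent construction.  Because
equal visual angles cover more screen at higher screen eccentricity, a
stimulus of fixed angular diameter (Goldmann III, 0.43 deg) must be drawn
physically larger toward the edges, and its footprint also scales with the
moment-to-moment viewing distance; :func:`stimulus_footprint` computes the
compensated extent.

Placement validity combines three checks: the warped footprint must lie
fully on-screen, it must avoid configured prohibited zones (regions of the
panel where stimuli may never appear, by default the degraded bottom
corners), and the target ray must stay within the tracker's trackable
cone.  An invalid placement is signalled, not raised: the session layer
responds with a refixation trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScreenModel",
    "ViewerState",
    "Placement",
    "screen_angular_extent",
    "field_offset_to_px",
    "px_to_field_offset",
    "stimulus_footprint",
    "placement_valid",
]

GOLDMANN_III_DIAMETER_DEG = 0.43

#: default prohibited rectangles (px, x0,y0,x1,y1; origin top-left, y down):
#: the two bottom screen corners, where gaze classification degrades.
DEFAULT_PROHIBITED_ZONES = ((0, 1240, 300, 1440), (2260, 1240, 2560, 1440))


@dataclass(frozen=True)
class ScreenModel:
    width_cm: float = 59.7
    height_cm: float = 33.6
    width_px: int = 2560
    height_px: int = 1440
    prohibited_zones: tuple[tuple[float, float, float, float], ...] = DEFAULT_PROHIBITED_ZONES

    def __post_init__(self) -> None:
        if min(self.width_cm, self.height_cm, self.width_px, self.height_px) <= 0:
            raise ValueError("screen dimensions must be positive")
        sx, sy = self.px_per_cm_x, self.px_per_cm_y
        if abs(sx - sy) / sx > 0.01:
            raise ValueError("pixel scale must match across axes within 1%")
        for x0, y0, x1, y1 in self.prohibited_zones:
            if not (0 <= x0 < x1 <= self.width_px and 0 <= y0 < y1 <= self.height_px):
                raise ValueError("prohibited zones must lie within screen bounds")

    @property
    def px_per_cm_x(self) -> float:
        return self.width_px / self.width_cm

    @property
    def px_per_cm_y(self) -> float:
        return self.height_px / self.height_cm

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)

    def in_prohibited_zone(self, x_px: float, y_px: float) -> bool:
        return any(
            x0 <= x_px <= x1 and y0 <= y_px <= y1
            for x0, y0, x1, y1 in self.prohibited_zones
        )


@dataclass
class ViewerState:
    """Current viewer: distance (time-varying), fixation point, trackbox."""

    viewing_distance_cm: float = 60.0
    fixation_px: tuple[float, float] = (1280.0, 720.0)
    trackbox_deg: tuple[float, float] = (27.0, 15.0)  # half-extents, (x, y)

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing distance must be positive")
        if min(self.trackbox_deg) <= 0:
            raise ValueError("trackbox half-extents must be positive")


@dataclass(frozen=True)
class Placement:
    """Outcome of a placement attempt (failure is a signal, not an error)."""

    px: tuple[float, float]
    valid: bool
    reason: str = ""


def screen_angular_extent(screen: ScreenModel, distance_cm: float) -> tuple[float, float]:
    """Full angular extent (width, height) of the screen in degrees."""
    if distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    w = 2.0 * math.degrees(math.atan(screen.width_cm / (2.0 * distance_cm)))
    h = 2.0 * math.degrees(math.atan(screen.height_cm / (2.0 * distance_cm)))
    return (w, h)


def _px_to_angle(px: float, center: float, px_per_cm: float, d: float,
                 positive_up: bool = False) -> float:
    u = (px - center) / px_per_cm
    if positive_up:
        u = -u
    return math.degrees(math.atan(u / d))


def _angle_to_px(theta_deg: float, center: float, px_per_cm: float, d: float,
                 positive_up: bool = False) -> float:
    u = d * math.tan(math.radians(theta_deg))
    if positive_up:
        u = -u
    return center + u * px_per_cm


def gaze_angles(px: tuple[float, float], viewer: ViewerState,
                screen: ScreenModel) -> tuple[float, float]:
    """Visual angles (deg) of a screen point from the eye (x right, y up)."""
    cx, cy = screen.center_px
    d = viewer.viewing_distance_cm
    ax = _px_to_angle(px[0], cx, screen.px_per_cm_x, d)
    ay = _px_to_angle(px[1], cy, screen.px_per_cm_y, d, positive_up=True)
    return (ax, ay)


def field_offset_to_px(offset_deg: tuple[float, float], viewer: ViewerState,
                       screen: ScreenModel) -> Placement:
    """Pixel position at a visual-field offset from the current fixation.

    The target ray is placed so the per-axis angle between fixation and
    target equals the requested offset.  Returns a :class:`Placement`; an
    off-screen or prohibited position is flagged invalid, not raised.
    """
    fx, fy = gaze_angles(viewer.fixation_px, viewer, screen)
    tx, ty = fx + offset_deg[0], fy + offset_deg[1]
    cx, cy = screen.center_px
    d = viewer.viewing_distance_cm
    # a ray at >= 90 deg from the screen normal can never hit the screen
    if max(abs(tx), abs(ty)) >= 90.0:
        return Placement((math.nan, math.nan), False, "off_screen")
    px = _angle_to_px(tx, cx, screen.px_per_cm_x, d)
    py = _angle_to_px(ty, cy, screen.px_per_cm_y, d, positive_up=True)
    placement = Placement((px, py), True)
    ok, reason = _check_placement((px, py), (tx, ty), viewer, screen)
    if not ok:
        return Placement((px, py), False, reason)
    return placement


def angles_to_px(angles_deg: tuple[float, float], distance_cm: float,
                 screen: ScreenModel) -> tuple[float, float]:
    """Screen point whose ray from the eye sits at the given visual angles."""
    cx, cy = screen.center_px
    px = _angle_to_px(angles_deg[0], cx, screen.px_per_cm_x, distance_cm)
    py = _angle_to_px(angles_deg[1], cy, screen.px_per_cm_y, distance_cm,
                      positive_up=True)
    return (px, py)


def px_to_field_offset(px: tuple[float, float], viewer: ViewerState,
                       screen: ScreenModel) -> tuple[float, float]:
    """Inverse of :func:`field_offset_to_px` (visual-field degrees)."""
    fx, fy = gaze_angles(viewer.fixation_px, viewer, screen)
    ax, ay = gaze_angles(px, viewer, screen)
    return (ax - fx, ay - fy)


def stimulus_footprint(target_px: tuple[float, float], viewer: ViewerState,
                       screen: ScreenModel,
                       diameter_deg: float = GOLDMANN_III_DIAMETER_DEG,
                       ) -> tuple[float, float]:
    """Physical extent (px) subtending ``diameter_deg`` at the eye.

    Per axis: ``d * (tan(theta + delta/2) - tan(theta - delta/2))`` at the
    target's screen angle ``theta`` -- larger at greater screen
    eccentricity, and proportional to the viewing distance near centre.
    """
    ax, ay = gaze_angles(target_px, viewer, screen)
    d = viewer.viewing_distance_cm
    half = diameter_deg / 2.0
    wx = d * (math.tan(math.radians(ax + half)) - math.tan(math.radians(ax - half)))
    wy = d * (math.tan(math.radians(ay + half)) - math.tan(math.radians(ay - half)))
    return (wx * screen.px_per_cm_x, abs(wy) * screen.px_per_cm_y)


def _check_placement(px: tuple[float, float], angles: tuple[float, float],
                     viewer: ViewerState, screen: ScreenModel,
                     diameter_deg: float = GOLDMANN_III_DIAMETER_DEG,
                     ) -> tuple[bool, str]:
    x, y = px
    if not (0 <= x <= screen.width_px and 0 <= y <= screen.height_px):
        return False, "off_screen"
    wx, wy = stimulus_footprint(px, viewer, screen, diameter_deg)
    if not (wx / 2 <= x <= screen.width_px - wx / 2
            and wy / 2 <= y <= screen.height_px - wy / 2):
        return False, "off_screen"
    corners = [(x - wx / 2, y - wy / 2), (x + wx / 2, y - wy / 2),
               (x - wx / 2, y + wy / 2), (x + wx / 2, y + wy / 2), (x, y)]
    if any(screen.in_prohibited_zone(px_, py_) for px_, py_ in corners):
        return False, "prohibited_zone"
    if abs(angles[0]) > viewer.trackbox_deg[0] or abs(angles[1]) > viewer.trackbox_deg[1]:
        return False, "outside_trackbox"
    return True, ""


def placement_valid(offset_deg: tuple[float, float], viewer: ViewerState,
                    screen: ScreenModel) -> tuple[bool, str]:
    """Whether a target at ``offset_deg`` from fixation can be shown."""
    placement = field_offset_to_px(offset_deg, viewer, screen)
    return placement.valid, placement.reason
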