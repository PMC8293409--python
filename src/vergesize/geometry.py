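"""Deterministic binocular viewing geometry for the dichoptic apparatus.

Coordinates: cyclopean origin midway between the eyes, x lateral (right
positive), z toward the screen.  All lengths in cm, all angles in degrees.
The eye is modelled as a single nodal point.

The apparatus places two targets on a display at a fixed distance and
drives vergence by changing their lateral separation: the left eye sees
only the right target and vice versa, so the crossed lines of sight
intersect nearer than the screen, at the vergence-specified distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ViewingGeometry",
    "vergence_angle",
    "distance_from_vergence",
    "mean_vergence_rate",
    "mean_target_speed",
    "screen_target_separation",
    "project_constant_angle_target",
    "angular_size_of_offset_disc",
    "vergence_range_fraction",
    "DEFAULT_IPD_CM",
]

#: Default interpupillary distance (cm).  Reproduces the apparatus'
#: printed 1.4 deg/s mean vergence rate for a 50->25 cm sweep over 5 s.
DEFAULT_IPD_CM = 6.3


@dataclass(frozen=True)
class ViewingGeometry:
    """Apparatus constants for one run.

    ``fixation_start``/``fixation_end`` are the vergence-specified
    distances at trial onset and offset; they may be nearer than the
    screen (that is the point of the dichoptic arrangement).
    """

    ipd: float = DEFAULT_IPD_CM
    screen_distance: float = 160.0
    fixation_start: float = 50.0
    fixation_end: float = 25.0
    duration: float = 5.0
    target_angular_size: float = 3.0

    def __post_init__(self) -> None:
        for name in ("ipd", "screen_distance", "fixation_start", "fixation_end"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")
        if not (0.0 < self.target_angular_size < 90.0):
            raise ValueError("target_angular_size must lie in (0, 90) degrees")


def vergence_angle(fixation_distance, ipd: float = DEFAULT_IPD_CM):
    """Vergence angle (deg) for binocular fixation at ``fixation_distance`` cm.

    Symmetric fixation on the midline: each eye sits at lateral offset
    ±ipd/2, so the full vergence angle is 2*arctan(ipd / (2*d)).  Strictly
    decreasing and convex in distance; tends to 0 as d -> inf (np.inf is
    accepted and maps to exactly 0).
    """
    d = np.asarray(fixation_distance, dtype=float)
    if np.any(d <= 0):
        raise ValueError("fixation_distance must be positive")
    if not (ipd > 0):
        raise ValueError("ipd must be positive")
    out = np.degrees(2.0 * np.arctan2(ipd / 2.0, d))
    return float(out) if out.ndim == 0 else out


def distance_from_vergence(angle_deg, ipd: float = DEFAULT_IPD_CM):
    """Fixation distance (cm) from a vergence angle (deg); inverse of
    :func:`vergence_angle`."""
    a = np.asarray(angle_deg, dtype=float)
    if np.any((a <= 0) | (a >= 180)):
        raise ValueError("vergence angle must lie in (0, 180) degrees")
    if not (ipd > 0):
        raise ValueError("ipd must be positive")
    out = ipd / (2.0 * np.tan(np.radians(a) / 2.0))
    return float(out) if out.ndim == 0 else out


def mean_vergence_rate(geom: ViewingGeometry) -> float:
    """Magnitude of the mean vergence-angle change rate over a trial (deg/s)."""
    dv = vergence_angle(geom.fixation_end, geom.ipd) - vergence_angle(
        geom.fixation_start, geom.ipd
    )
    return abs(dv) / geom.duration


def mean_target_speed(geom: ViewingGeometry) -> float:
    """Magnitude of the mean motion-in-depth speed of the fixation point (cm/s)."""
    return abs(geom.fixation_end - geom.fixation_start) / geom.duration


def screen_target_separation(
    screen_distance: float, fixation_distance: float, ipd: float = DEFAULT_IPD_CM
) -> float:
    """Lateral separation (cm) of the dichoptic targets on the display.

    The crossed lines of sight (left eye to right target, right eye to left
    target) intersect at ``fixation_distance``; similar triangles give a
    required on-screen separation of ipd*(D - d)/d.  Zero when fixation is
    at the screen, monotone decreasing in fixation distance.
    """
    if not (screen_distance > 0 and fixation_distance > 0 and ipd > 0):
        raise ValueError("all distances must be positive")
    if fixation_distance > screen_distance:
        raise ValueError(
            "uncrossed arrangement (fixation beyond the screen) is not supported"
        )
    return ipd * (screen_distance - fixation_distance) / fixation_distance


def project_constant_angle_target(
    eye_offset: float,
    fixation_distance: float,
    screen_distance: float,
    angular_extent: float,
    fixation_offset: float = 0.0,
) -> tuple[float, float]:
    """On-screen x-coordinates of the edges of a constant-retinal-angle target.

    The eye sits at ``(eye_offset, 0)``, gazing through the fixation point
    ``(fixation_offset, fixation_distance)``.  A target subtending exactly
    ``angular_extent`` degrees at the eye, centred on the gaze direction,
    is projected from the eye's nodal point onto the display plane at
    ``z = screen_distance``.  Returns the two edge x-coordinates, for the
    rays at gaze - extent/2 and gaze + extent/2 respectively.

    For gaze normal to the screen the total extent is
    2*D*tan(extent/2); for oblique gaze the half-extent on the side of
    greater obliquity is larger.
    """
    if not (0.0 < angular_extent < 90.0):
        raise ValueError("angular_extent must lie in (0, 90) degrees")
    if not (fixation_distance > 0 and screen_distance > 0):
        raise ValueError("distances must be positive")
    gaze = np.arctan2(fixation_offset - eye_offset, fixation_distance)
    half = np.radians(angular_extent) / 2.0
    edges = []
    for ray in (gaze - half, gaze + half):
        if abs(ray) >= np.pi / 2.0:
            raise ValueError("edge ray is parallel to or away from the screen plane")
        edges.append(eye_offset + screen_distance * np.tan(ray))
    return (float(edges[0]), float(edges[1]))


def angular_size_of_offset_disc(
    centre_offset: float, diameter: float, viewing_distance: float
) -> float:
    """Angular size (deg) of a disc whose centre is laterally offset from the eye.

    arctan((c + r)/d) - arctan((c - r)/d) with r = diameter/2: even in the
    offset, maximal when the disc is straight ahead, and strictly
    decreasing in |offset|.  This is why, when cross-fusing two coins, the
    fused (contralateral, more offset) images are smaller than the directly
    viewed ones.
    """
    if not (diameter > 0):
        raise ValueError("diameter must be positive")
    if not (viewing_distance > 0):
        raise ValueError("viewing_distance must be positive")
    r = diameter / 2.0
    return float(
        np.degrees(
            np.arctan((centre_offset + r) / viewing_distance)
            - np.arctan((centre_offset - r) / viewing_distance)
        )
    )


def vergence_range_fraction(near: float, far: float, ipd: float = DEFAULT_IPD_CM) -> float:
    """Fraction of the total vergence range from ``near`` to infinity that is
    consumed by moving fixation from ``near`` out to ``far``.

    (v(near) - v(far)) / v(near), in [0, 1]; ``far`` may be ``np.inf``.
    """
    if not (0 < near < far):
        raise ValueError("require 0 < near < far")
    v_near = vergence_angle(near, ipd)
    v_far = vergence_angle(far, ipd) if np.isfinite(far) else 0.0
    return (v_near - v_far) / v_near
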