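"""Shared angle conventions.

All pixel coordinates in this package are ``(x, y)`` with ``x`` the column
index and ``y`` the row index (rows increase downward, as stored on disk).
Angles are reported in degrees in ``(-180, 180]`` with

* ``0``    → pointing right (+x), the direction of *decreasing* gradient
  concentration once a frame is in canonical orientation,
* ``±180`` → pointing left (-x), toward *increasing* concentration,
* positive angles pointing up on screen.

Because rows increase downward, "up on screen" is negative ``dy``; every
angle is therefore computed as ``atan2(-dy, dx)``.  Keeping this in one
module guarantees the synthetic generator and the morphometry code can
never disagree about signs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "vector_angle_deg", "hflip_deg", "rot180_deg", "unit_vector"]


def wrap_deg(angle):
    """Wrap angle(s) in degrees into the half-open interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    # -((-a+180)%360 - 180) maps 180 -> 180 and -180 -> 180; the modulo can
    # still round to an exact -180.0 (and produce -0.0), so repair both.
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped) + 0.0
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def vector_angle_deg(p_from, p_to):
    """Direction of the vector from ``p_from`` to ``p_to`` in degrees.

    Points are ``(x, y)`` pixel coordinates with y increasing downward.
    """
    dx = float(p_to[0]) - float(p_from[0])
    dy = float(p_to[1]) - float(p_from[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("direction undefined for coincident points")
    return wrap_deg(np.degrees(np.arctan2(-dy, dx)))


def hflip_deg(angle):
    """Angle after mirroring the scene across a vertical axis.

    theta -> sign(theta) * (180 - |theta|), with sign(0) taken as +1 so
    that 0 maps to 180 (a rightward vector becomes leftward).
    """
    a = np.asarray(angle, dtype=float)
    sign = np.where(a >= 0.0, 1.0, -1.0)
    out = sign * (180.0 - np.abs(a))
    out = wrap_deg(out)
    if np.ndim(angle) == 0:
        return float(out)
    return out


def rot180_deg(angle):
    """Angle after rotating the scene by 180 degrees: theta -> theta + 180, wrapped."""
    return wrap_deg(np.asarray(angle, dtype=float) + 180.0) if np.ndim(angle) else wrap_deg(float(angle) + 180.0)


def unit_vector(angle_deg):
    """Unit step ``(dx, dy)`` in row-down pixel coordinates for an angle."""
    rad = np.deg2rad(angle_deg)
    return np.cos(rad), -np.sin(rad)
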