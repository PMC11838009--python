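"""Volume/area primitives: channel width, spherical caps, tapered middles.

All formulas are exact closed forms for a spherical cap of base diameter D
and height h, a cone frustum (or square-pyramid frustum) of wall inclination
alpha, and a cylinder (or square prism).  These are the building blocks the
incompressibility solver assembles into full cell shapes.
"""

from __future__ import annotations

import math
from typing import Literal

from .params import ConstrictionGeometry, InvalidGeometryError


def channel_width(x: float, geometry: ConstrictionGeometry) -> float:
    """Channel width at axial position ``x`` (um).

    Inside the constriction (x >= X0) the width is ``d``; upstream the ramp
    widens as ``d - 2 tan(alpha) (x - X0)``.  Total function: never raises.
    """
    if x >= geometry.X0:
        return geometry.d
    return geometry.d - 2.0 * math.tan(geometry.alpha) * (x - geometry.X0)


def cap_height_tangent(D_base: float, alpha: float, end: Literal["front", "rear"]) -> float:
    """Cap height for a spherical cap tangent to the ramp wall.

    Tangency to a wall inclined at ``alpha`` fixes the height in terms of the
    base diameter: the rear (upstream) cap bulges past the equator,
    ``h = (D/2)(tan a + sec a)``, while the front (downstream) cap is shallower,
    ``h = (D/2)(sec a - tan a)``.  Both caps then have radius D/(2 cos a).
    """
    if D_base <= 0:
        raise InvalidGeometryError("cap base diameter must be positive")
    t = math.tan(alpha)
    s = math.sqrt(1.0 + t * t)  # sec(alpha)
    if end == "rear":
        return 0.5 * D_base * (t + s)
    if end == "front":
        return 0.5 * D_base * (s - t)
    raise ValueError(f"end must be 'front' or 'rear', got {end!r}")


def cap_geometry(
    D_base: float,
    alpha: float | None = None,
    end: Literal["front", "rear"] | None = None,
    h: float | None = None,
) -> tuple[float, float, float, float]:
    """Spherical-cap height, radius, volume and lateral area.

    Either pass an explicit height ``h``, or ``alpha`` + ``end`` for the
    wall-tangency height.  Returns ``(h, R, V, A)`` with
    ``V = (pi h / 6)(3 D^2/4 + h^2)``, ``A = pi (D^2/4 + h^2)`` (spherical
    surface only, the base disc is internal) and ``R = (D^2/4 + h^2)/(2h)``.
    """
    if D_base <= 0:
        raise InvalidGeometryError("cap base diameter must be positive")
    if h is None:
        if alpha is None or end is None:
            raise ValueError("provide either h, or alpha and end")
        h = cap_height_tangent(D_base, alpha, end)
    if h <= 0:
        raise InvalidGeometryError("cap height must be positive")
    a2 = D_base * D_base / 4.0
    V = math.pi * h / 6.0 * (3.0 * a2 + h * h)
    A = math.pi * (a2 + h * h)
    R = (a2 + h * h) / (2.0 * h)
    return h, R, V, A


def middle_section(
    Dr: float, Df: float, alpha: float, mode: str = "conical"
) -> tuple[float, float]:
    """Volume and lateral area of the tapered middle section.

    Conical: frustum of a cone, ``V = pi (Dr^3 - Df^3) / (24 tan a)``,
    lateral area ``A = pi (Dr^2 - Df^2) / (4 sin a)`` (slant factor 1/sin a).
    Pyramidal (square cross section of side D): ``V = (Dr^3 - Df^3)/(6 tan a)``,
    ``A = (Dr^2 - Df^2)/sin a``.
    """
    if alpha == 0:
        raise InvalidGeometryError("degenerate taper: alpha = 0")
    if Df <= 0 or Dr < Df:
        raise InvalidGeometryError(f"need Dr >= Df > 0, got Dr={Dr}, Df={Df}")
    t = math.tan(alpha)
    s = math.sin(alpha)
    if mode == "conical":
        V = math.pi * (Dr**3 - Df**3) / (24.0 * t)
        A = math.pi * (Dr**2 - Df**2) / (4.0 * s)
    elif mode == "pyramidal":
        V = (Dr**3 - Df**3) / (6.0 * t)
        A = (Dr**2 - Df**2) / s
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return V, A


def straight_section(d: float, L: float, mode: str = "conical") -> tuple[float, float]:
    """Volume and lateral area of a cylinder (or square prism) of length L."""
    if L < 0:
        raise InvalidGeometryError("straight-section length must be >= 0")
    if mode == "conical":
        return math.pi * d * d / 4.0 * L, math.pi * d * L
    if mode == "pyramidal":
        return d * d * L, 4.0 * d * L
    raise ValueError(f"unknown mode {mode!r}")
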