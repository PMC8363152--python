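"""Spherical-cap and polygon geometry shared by all other modules.

A clathrin-coated pit (CCP) is modelled throughout as a spherical cap of
radius of curvature ``R`` rising a height ``h`` above the flat membrane
plane.  The cap surface area is ``A = 2*pi*R*h`` exactly, so any two of
``(R, h, A)`` determine the third; the closed sphere (a coated vesicle)
is the limiting cap with ``h = 2R`` and ``A = 4*pi*R**2``.

The polygon helpers cover the flat-lattice reference values used when
interpreting triskelion inter-arm angles: interior angles of regular
pentagons/hexagons/heptagons and the angle sums expected for a hub that
participates in a given triple of regular polygons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

import numpy as np

__all__ = [
    "SphericalCap",
    "cap_area",
    "cap_height",
    "delta_area",
    "aspect_ratio",
    "regular_polygon_interior_angle",
    "expected_angle_sum",
]

_REL_TOL = 1e-9


def cap_area(R: float, h: float) -> float:
    """Surface area ``2*pi*R*h`` of a spherical cap (nm^2).

    Parameters
    ----------
    R : float
        Radius of curvature in nm, ``R > 0``.
    h : float
        Cap height above the base plane in nm, ``0 < h <= 2R``.
    """
    if not (R > 0 and h > 0):
        raise ValueError(f"cap requires R > 0 and h > 0, got R={R}, h={h}")
    if h > 2 * R * (1 + _REL_TOL):
        raise ValueError(f"cap height h={h} exceeds sphere diameter 2R={2 * R}")
    return 2.0 * math.pi * R * h


def cap_height(R: float, A: float) -> float:
    """Cap height ``A / (2*pi*R)`` in nm, the inverse of :func:`cap_area`."""
    if not (R > 0 and A > 0):
        raise ValueError(f"cap requires R > 0 and A > 0, got R={R}, A={A}")
    if A > 4 * math.pi * R**2 * (1 + _REL_TOL):
        raise ValueError(f"cap area A={A} exceeds sphere area 4*pi*R^2={4 * math.pi * R ** 2}")
    return A / (2.0 * math.pi * R)


def delta_area(A: float, R: float) -> float:
    """In-plane membrane area consumed by forming a cap: ``A**2 / (4*pi*R**2)``.

    This is the difference between the curved cap area and the flat disc it
    replaces; it equals ``pi*h**2`` for every valid cap, which is the form in
    which the membrane-tension energy is most easily recognised.
    """
    if R <= 0 or A < 0:
        raise ValueError(f"requires R > 0 and A >= 0, got R={R}, A={A}")
    if A > 4 * math.pi * R**2 * (1 + _REL_TOL):
        raise ValueError(f"cap area A={A} exceeds sphere area for R={R}")
    return A**2 / (4.0 * math.pi * R**2)


@dataclass(frozen=True)
class SphericalCap:
    """Geometric state of one CCP.

    Attributes
    ----------
    R : float
        Radius of curvature (nm).
    h : float
        Cap height above the base plane (nm), in ``(0, 2R]``; ``h = 2R`` is a
        closed sphere.
    A : float
        Cap surface area ``2*pi*R*h`` (nm^2), derived.
    theta : float
        Angle (degrees) at the cap foot between the base membrane plane and
        the sphere tangent, ``theta = degrees(arccos(1 - h/R))``; a
        hemisphere has ``theta = 90``, a closed sphere ``theta = 180``.
    center : tuple of float
        Sphere centre in nm, ``(0, 0, h - R)`` by default (base plane z = 0).
    """

    R: float
    h: float
    center: Tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        cap_area(self.R, self.h)  # validates domain
        if self.center == (0.0, 0.0, 0.0):
            object.__setattr__(self, "center", (0.0, 0.0, self.h - self.R))

    @property
    def A(self) -> float:
        return 2.0 * math.pi * self.R * self.h

    @property
    def theta(self) -> float:
        c = 1.0 - self.h / self.R
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    @property
    def footprint_radius(self) -> float:
        """Radius (nm) of the cap outline projected on the base plane."""
        if self.h <= self.R:
            return math.sqrt(max(self.h * (2.0 * self.R - self.h), 0.0))
        return self.R  # beyond hemisphere the equator shadows the foot

    @property
    def is_closed(self) -> bool:
        return math.isclose(self.h, 2.0 * self.R, rel_tol=1e-9)

    @classmethod
    def from_R_h(cls, R: float, h: float) -> "SphericalCap":
        return cls(R=R, h=h)

    @classmethod
    def from_R_A(cls, R: float, A: float) -> "SphericalCap":
        return cls(R=R, h=cap_height(R, A))

    @classmethod
    def from_A_h(cls, A: float, h: float) -> "SphericalCap":
        if not (A > 0 and h > 0):
            raise ValueError(f"requires A > 0 and h > 0, got A={A}, h={h}")
        return cls(R=A / (2.0 * math.pi * h), h=h)

    def delta_area(self) -> float:
        return delta_area(self.A, self.R)


def aspect_ratio(cap: SphericalCap) -> float:
    """Cap aspect ratio ``h/R`` in ``(0, 2]``.

    Caps of fixed aspect ratio lie on equal-membrane-bending-energy contours.
    """
    return cap.h / cap.R


def regular_polygon_interior_angle(n: int) -> float:
    """Interior angle ``(n-2)*180/n`` in degrees of a regular n-gon, n >= 3."""
    if n < 3:
        raise ValueError(f"polygon needs at least 3 vertices, got {n}")
    return (n - 2) * 180.0 / n


def expected_angle_sum(config: Iterable[int]) -> float:
    """Inter-arm angle sum (degrees) of a hub joining three regular polygons.

    ``(6, 6, 5) -> 348``, ``(6, 5, 5) -> 336``, ``(5, 5, 5) -> 324``; a hub
    in a flat hexagonal tiling ``(6, 6, 6)`` sums to 360.
    """
    sizes = list(config)
    return float(sum(regular_polygon_interior_angle(n) for n in sizes))
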