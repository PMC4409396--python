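"""Spherocylindrical cell footprints.

Rod-shaped bacteria such as *Bacillus subtilis* project to a spherocylinder
in the 2D focal plane: a rectangle of size ``(length - 2*radius) x
(2*radius)`` capped by two half-discs of the same radius.  Membrane proteins
imaged by PALM appear within this footprint, so the simulator places
emitters inside it and downstream checks can verify containment.

All coordinates are nanometres in the sample plane, x to the right and
y down, consistent with image row/column order elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised for geometrically impossible cell shapes."""


@dataclass(frozen=True)
class CellGeometry:
    """A rod-shaped (spherocylindrical) cell outline in the sample plane.

    Parameters
    ----------
    center : (float, float)
        Mid-cell position in nm.
    orientation : float
        Angle of the long axis in radians (0 = along +x).
    length : float
        Pole-to-pole length in nm (includes both caps).
    radius : float
        Half-width in nm.
    """

    center: tuple[float, float]
    orientation: float
    length: float
    radius: float

    @property
    def half_core(self) -> float:
        """Half-length of the cylindrical core (between the cap centres)."""
        return 0.5 * self.length - self.radius

    @property
    def axis(self) -> np.ndarray:
        return np.array([np.cos(self.orientation), np.sin(self.orientation)])

    @property
    def area(self) -> float:
        """Footprint area: core rectangle plus two half-discs."""
        return (self.length - 2.0 * self.radius) * 2.0 * self.radius + np.pi * self.radius**2

    def axis_endpoints(self) -> np.ndarray:
        """The two cap centres, shape (2, 2)."""
        c = np.asarray(self.center, dtype=float)
        return np.stack([c - self.half_core * self.axis, c + self.half_core * self.axis])

    def contains(self, points) -> np.ndarray:
        """Boolean containment test for an (n, 2) array of nm positions."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - np.asarray(self.center, dtype=float)
        s = np.clip(rel @ self.axis, -self.half_core, self.half_core)
        closest = s[:, None] * self.axis
        d2 = np.sum((rel - closest) ** 2, axis=1)
        return d2 <= self.radius**2

    def sample_interior(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly inside the footprint (rejection sampling)."""
        out = np.empty((n, 2))
        got = 0
        cos_t, sin_t = np.cos(self.orientation), np.sin(self.orientation)
        cx, cy = self.center
        while got < n:
            m = max(16, int(1.5 * (n - got)))
            lx = rng.uniform(-0.5 * self.length, 0.5 * self.length, m)
            ly = rng.uniform(-self.radius, self.radius, m)
            s = np.clip(lx, -self.half_core, self.half_core)
            keep = (lx - s) ** 2 + ly**2 <= self.radius**2
            lx, ly = lx[keep], ly[keep]
            take = min(len(lx), n - got)
            out[got : got + take, 0] = cx + lx[:take] * cos_t - ly[:take] * sin_t
            out[got : got + take, 1] = cy + lx[:take] * sin_t + ly[:take] * cos_t
            got += take
        return out

    def bounding_box(self, pad: float = 0.0) -> tuple[float, float, float, float]:
        """Axis-aligned bounding box ``(xmin, xmax, ymin, ymax)`` in nm."""
        cx, cy = self.center
        ex = self.half_core * abs(np.cos(self.orientation)) + self.radius + pad
        ey = self.half_core * abs(np.sin(self.orientation)) + self.radius + pad
        return (cx - ex, cx + ex, cy - ey, cy + ey)


def make_cell_geometry(
    length: float,
    radius: float,
    center: tuple[float, float] = (0.0, 0.0),
    orientation: float = 0.0,
) -> CellGeometry:
    """Validate and build a :class:`CellGeometry`.

    Raises
    ------
    GeometryError
        If ``radius <= 0`` or ``length < 2 * radius``.
    """
    if radius <= 0:
        raise GeometryError(f"radius must be positive, got {radius}")
    if length < 2 * radius:
        raise GeometryError(
            f"length ({length}) must be at least twice the radius ({radius})"
        )
    return CellGeometry(
        center=(float(center[0]), float(center[1])),
        orientation=float(orientation),
        length=float(length),
        radius=float(radius),
    )
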