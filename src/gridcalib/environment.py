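"""Cage geometry: convex polygonal enclosures with two reference walls.

Every enclosure is a simple convex polygon with two designated *reference
walls* that meet at the origin: ``wall_x`` (angle ``phi`` to the horizontal
axis, the cage lying counterclockwise of it) and ``wall_y`` (angle ``psi``,
the cage lying clockwise of it).  All wall-distance-cell coordinates are
perpendicular distances to the infinite lines carrying these walls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon


@dataclass(frozen=True)
class Environment:
    """A convex polygonal cage with two reference walls through the origin.

    Attributes
    ----------
    vertices : (k, 2) array of polygon vertices in counterclockwise order,
        starting at the origin.
    wall_x, wall_y : index pairs ``(i, j)`` into ``vertices`` naming the two
        reference walls.  ``wall_x`` runs *from* the origin (cage
        counterclockwise of it), ``wall_y`` runs *to* the origin (cage
        clockwise of it).
    phi, psi : angles (radians) of wall_x / wall_y to the horizontal axis.
    lx_max, ly_max : distance from wall_x / wall_y to the farthest parallel
        line through a cage point (the maximal perpendicular extents).
    """

    vertices: np.ndarray
    wall_x: tuple[int, int]
    wall_y: tuple[int, int]
    phi: float
    psi: float
    lx_max: float
    ly_max: float
    _poly: Polygon = field(repr=False, compare=False, default=None)

    @property
    def polygon(self) -> Polygon:
        return self._poly

    # -- queries -----------------------------------------------------------

    def contains(self, p, tol: float = 1e-9) -> bool:
        """True if point ``p`` lies inside the cage (boundary inclusive)."""
        return self._poly.buffer(tol).contains(Point(float(p[0]), float(p[1])))

    def wall_angle(self, wall: str) -> float:
        if wall == "x":
            return self.phi
        if wall == "y":
            return self.psi
        raise ValueError(f"unknown wall identifier {wall!r}")

    def wall_distance(self, p, wall: str) -> float:
        """Perpendicular distance from ``p`` to the line carrying a wall.

        The line goes through the origin at angle ``phi`` (wall "x") or
        ``psi`` (wall "y"); the distance is the absolute cross product of
        ``p`` with the wall's unit direction vector.
        """
        a = self.wall_angle(wall)
        return abs(float(p[0]) * math.sin(a) - float(p[1]) * math.cos(a))

    def signed_wall_coords(self, xs, ys):
        """Vectorized (d_x, d_y): distances to wall_y and wall_x.

        ``d_x`` is the distance to wall_y (the coordinate the x-vector of
        WDCs encodes), ``d_y`` the distance to wall_x.  Positive inside the
        cage by the orientation conventions.
        """
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        d_x = xs * math.sin(self.psi) - ys * math.cos(self.psi)
        d_y = -(xs * math.sin(self.phi) - ys * math.cos(self.phi))
        return d_x, d_y

    def opposing_wall_line(self, wall: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (point, unit direction) of the cage wall opposite ``wall``.

        The opposing wall is the polygon edge whose perpendicular distance
        from the reference wall's line is largest (measured at the edge
        midpoint); for the shapes in scope this is the intuitive far wall.
        """
        a = self.wall_angle(wall)
        u = np.array([math.cos(a), math.sin(a)])
        ref = self.wall_x if wall == "x" else self.wall_y
        verts = self.vertices
        k = len(verts)
        best, best_d = None, -1.0
        for i in range(k):
            j = (i + 1) % k
            if {i, j} == set(ref):
                continue
            mid = 0.5 * (verts[i] + verts[j])
            d = abs(mid[0] * u[1] - mid[1] * u[0])
            if d > best_d:
                best_d, best = d, (i, j)
        i, j = best
        direction = verts[j] - verts[i]
        direction = direction / np.linalg.norm(direction)
        return verts[i].copy(), direction

    def span_lengths(self, p, option: str = "ii") -> tuple[float, float]:
        """Local or maximal spans (l_x, l_y) used to scale WDC peaks.

        Option "ii": the fixed maximal extents ``(lx_max, ly_max)``
        independent of ``p``.  Option "i": for each reference wall, the sum
        of perpendicular distances from ``p`` to that wall's line and to the
        opposing cage wall's line, i.e. the local cage width at ``p``.
        """
        if option == "ii":
            return self.lx_max, self.ly_max
        if option != "i":
            raise ValueError(f"span option must be 'i' or 'ii', got {option!r}")
        spans = []
        for wall in ("x", "y"):
            d_near = self.wall_distance(p, wall)
            q, u = self.opposing_wall_line(wall)
            rel = np.asarray(p, dtype=float) - q
            d_far = abs(rel[0] * u[1] - rel[1] * u[0])
            spans.append(d_near + d_far)
        return spans[0], spans[1]

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"vertices": self.vertices.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "Environment":
        return make_environment("polygon", json.loads(s)["vertices"])


def _wall_extent(verts: np.ndarray, angle: float) -> float:
    """Max perpendicular distance of any vertex from the line at ``angle``."""
    u = np.array([math.cos(angle), math.sin(angle)])
    d = np.abs(verts[:, 0] * u[1] - verts[:, 1] * u[0])
    return float(d.max())


def make_environment(shape: str, *args) -> Environment:
    """Build a cage from a shape descriptor.

    Supported descriptors::

        make_environment("square", side)
        make_environment("rectangle", width, height)
        make_environment("isosceles_trapezoid", length, tall_side, short_side)
        make_environment("polygon", [(x0, y0), (x1, y1), ...])

    The first vertex must be the origin; the first edge is wall_x and the
    last edge (closing back to the origin) is wall_y.  The trapezoid has its
    two parallel sides vertical: the tall one at x=0 (wall_y) and the short
    one, vertically centered, at x=length; wall_x is the rising bottom wall.
    """
    if shape == "square":
        (side,) = args
        verts = [(0, 0), (side, 0), (side, side), (0, side)]
    elif shape == "rectangle":
        width, height = args
        verts = [(0, 0), (width, 0), (width, height), (0, height)]
    elif shape == "isosceles_trapezoid":
        length, tall, short = args
        if not (0 < short <= tall):
            raise ValueError("trapezoid requires 0 < short_side <= tall_side")
        off = (tall - short) / 2.0
        verts = [(0, 0), (length, off), (length, off + short), (0, tall)]
    elif shape == "polygon":
        (verts,) = args
    else:
        raise ValueError(f"unknown shape descriptor {shape!r}")

    verts = np.asarray(verts, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 two-dimensional vertices")
    if not np.allclose(verts[0], 0.0, atol=1e-12):
        raise ValueError("first vertex must be the origin (wall intersection)")

    poly = Polygon(verts)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("polygon is not simple or has zero area")
    hull = poly.convex_hull
    if abs(hull.area - poly.area) > 1e-9 * max(poly.area, 1.0):
        raise ValueError("polygon must be convex")
    if poly.exterior.is_ccw is False:
        verts = verts[::-1]
        verts = np.roll(verts, 1, axis=0)  # keep origin first
        poly = Polygon(verts)

    k = len(verts)
    wall_x = (0, 1)          # edge leaving the origin, cage counterclockwise of it
    wall_y = (k - 1, 0)      # edge entering the origin, cage clockwise of it
    phi = math.atan2(verts[1][1] - verts[0][1], verts[1][0] - verts[0][0])
    # wall_y direction taken *away* from the origin so psi is its axis angle
    psi = math.atan2(verts[k - 1][1], verts[k - 1][0])
    env = Environment(
        vertices=verts,
        wall_x=wall_x,
        wall_y=wall_y,
        phi=phi,
        psi=psi,
        lx_max=_wall_extent(verts, phi),
        ly_max=_wall_extent(verts, psi),
        _poly=poly,
    )
    return env


def default_trapezoid() -> Environment:
    """The default isosceles trapezoid test cage (length 30, sides 30 and 10)."""
    return make_environment("isosceles_trapezoid", 30.0, 30.0, 10.0)
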