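"""Microchannel geometry and obstacle handling for transmigrating cells.

The transmigration channel mimics a microfluidic device: a wide large
channel (LC, 15 μm), a narrow subnucleus barrier (SNB, 3.3 μm wide and
10 μm long) and a second LC segment, embedded in an open domain.  The free
region available to membrane nodes is the union of the open half-planes
before/after the channel and the three channel rectangles; walls block
motion (the normal displacement component is removed and positions are
clamped to the free region) and exert friction proportional to the local
repelling force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TubeGeometry", "CellObstacle"]


@dataclass(frozen=True)
class TubeGeometry:
    """Straight horizontal channel: LC – SNB – LC along +x.

    ``entrance_x`` is the x-coordinate of the channel mouth and ``axis_y``
    the channel axis.  Widths/lengths in μm.
    """

    entrance_x: float
    axis_y: float
    lc_width: float = 15.0
    snb_width: float = 3.3
    snb_length: float = 10.0
    lc_length: float = 50.0
    #: tapered inlet from the loading reservoir: the half-width ramps
    #: linearly from taper_halfwidth down to the LC half-width over
    #: taper_length μm before the entrance, so the entry compression is
    #: gradual rather than an abrupt square shoulder
    taper_length: float = 12.0
    taper_halfwidth: float = 10.8

    def __post_init__(self):
        if not self.snb_width < self.lc_width:
            raise ValueError("the SNB must be narrower than the LC")

    # landmark x-coordinates ------------------------------------------------
    @property
    def x0(self) -> float:          # channel entrance
        return self.entrance_x

    @property
    def x1(self) -> float:          # SNB entrance
        return self.entrance_x + self.lc_length

    @property
    def x2(self) -> float:          # SNB exit
        return self.x1 + self.snb_length

    @property
    def x3(self) -> float:          # channel exit
        return self.x2 + self.lc_length

    @property
    def lc_halfwidth(self) -> float:
        return 0.5 * self.lc_width

    @property
    def snb_halfwidth(self) -> float:
        return 0.5 * self.snb_width

    def halfwidth(self, x: np.ndarray) -> np.ndarray:
        """Local channel half-width; +inf outside the channel x-range."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        hw = np.full_like(x, np.inf)
        if self.taper_length > 0:
            in_taper = (x >= self.x0 - self.taper_length) & (x < self.x0)
            frac = (self.x0 - x[in_taper]) / self.taper_length
            hw[in_taper] = (self.lc_halfwidth
                            + (self.taper_halfwidth - self.lc_halfwidth) * frac)
        in_lc = ((x >= self.x0) & (x <= self.x1)) | ((x >= self.x2) & (x <= self.x3))
        in_snb = (x > self.x1) & (x < self.x2)
        hw[in_lc] = self.lc_halfwidth
        hw[in_snb] = self.snb_halfwidth
        return hw

    def solid_mask(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies inside the solid chip material flanking
        the channel (the device is impermeable: signalling molecules cross
        the channel strip only through the channel itself)."""
        pts = np.atleast_2d(points)
        x = pts[:, 0]
        dy = np.abs(pts[:, 1] - self.axis_y)
        in_strip = (x > self.x0 - self.taper_length) & (x < self.x3)
        return in_strip & (dy > self.halfwidth(x))

    def feasible(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(points)
        dy = np.abs(pts[:, 1] - self.axis_y)
        return dy <= self.halfwidth(pts[:, 0]) + tol

    # -- projection onto the free region ---------------------------------
    def clamp(self, points: np.ndarray) -> np.ndarray:
        """Squeeze points into the locally admissible channel width.

        A membrane node inside the channel x-range must lie within the local
        half-width at its axial position; violating nodes are projected onto
        the wall at that position.  The squeeze a node experiences when it
        advances past a narrowing (mouth or SNB entrance) models the cell
        body flowing around the step — the walls compress the cell, they do
        not block its axial progress.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        hw = self.halfwidth(pts[:, 0])
        dy = pts[:, 1] - self.axis_y
        pts[:, 1] = self.axis_y + np.clip(dy, -hw, hw)
        return pts

    # -- wall contact -----------------------------------------------------
    def wall_contact(self, points: np.ndarray, tol: float = 1e-6):
        """Contact state of membrane nodes against the channel walls.

        Returns (mask, normals, tangents); ``normals`` point from the channel
        interior into the wall (the direction the cell presses), valid where
        ``mask`` is set.  Only the horizontal wall surfaces carry contact:
        a node is in contact when it sits on the local half-width at its
        axial position.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = len(pts)
        x = pts[:, 0]
        dy = pts[:, 1] - self.axis_y
        ay = np.abs(dy)
        sgn = np.where(dy >= 0, 1.0, -1.0)
        hw = self.halfwidth(x)
        mask = np.isfinite(hw) & (np.abs(ay - hw) <= tol)
        normals = np.zeros((k, 2))
        # wall surface |dy| = hw(x): the pressing normal tilts with the
        # local wall slope (nonzero only in the tapered inlet)
        eps = 1e-6
        with np.errstate(invalid="ignore"):
            hwp = (self.halfwidth(x + eps) - self.halfwidth(x - eps)) / (2 * eps)
        hwp[~np.isfinite(hwp)] = 0.0
        nx = -hwp[mask]
        ny = np.ones(int(mask.sum()))
        nrm = np.sqrt(nx ** 2 + ny ** 2)
        normals[mask, 0] = nx / nrm
        normals[mask, 1] = sgn[mask] * ny / nrm
        tangents = np.column_stack([-normals[:, 1], normals[:, 0]])
        return mask, normals, tangents


class CellObstacle:
    """Another cell acting as an impenetrable obstacle.

    The obstacle boundary normal at a contacting node is approximated by the
    radial direction from the other cell's centre; clamping pushes intruding
    nodes back to the other cell's membrane (shapely nearest-point query).
    """

    def __init__(self, other_cell, tol: float = 1e-6):
        self.other = other_cell
        self.tol = tol
        from shapely import make_valid
        from shapely.geometry import Polygon
        poly = Polygon(other_cell.nodes)
        self._boundary = poly.exterior
        self._poly = poly if poly.is_valid else make_valid(poly)

    def feasible(self, points: np.ndarray, tol: float | None = None) -> np.ndarray:
        from shapely import contains_xy
        pts = np.atleast_2d(points)
        return ~contains_xy(self._poly, pts[:, 0], pts[:, 1])

    def clamp(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        bad = ~self.feasible(pts)
        if np.any(bad):
            from shapely.geometry import Point
            centre = self.other.centre
            for i in np.flatnonzero(bad):
                q = self._boundary.interpolate(self._boundary.project(Point(pts[i])))
                p = np.array([q.x, q.y])
                # nudge just outside along the outward radial direction
                r = p - centre
                nr = np.linalg.norm(r)
                if nr > 1e-12:
                    p = p + (1e-9 / nr) * r
                pts[i] = p
        return pts

    def wall_contact(self, points: np.ndarray, tol: float | None = None):
        tol = self.tol if tol is None else tol
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        from shapely import distance, points as shp_points
        d = distance(self._boundary, shp_points(pts))
        inside = ~self.feasible(pts)
        mask = (d <= tol) | inside
        centre = self.other.centre
        r = pts - centre
        nr = np.linalg.norm(r, axis=1)
        nr[nr < 1e-12] = 1.0
        normals = -r / nr[:, None]   # pressing toward the other cell's centre
        tangents = np.column_stack([-normals[:, 1], normals[:, 0]])
        return mask, normals, tangents
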