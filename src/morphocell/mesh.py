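"""Triangular meshes on rectangular domains.

The computational domain is a fixed (Eulerian) rectangle; substrate
deformation is carried by velocity/strain/displacement fields living on the
mesh, never by moving mesh points.  Meshes are tensor-product triangulations:
two monotone coordinate arrays define a quad grid, each quad is split into two
triangles.  Arbitrary "mandatory" coordinate lines (e.g. microchannel walls)
are inserted exactly, and axis-aligned refinement boxes give local resolution
without hanging nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder


@dataclass(frozen=True)
class RectangleDomain:
    """Axis-aligned rectangle [x0, x0+lx] x [y0, y0+ly] (μm)."""

    lx: float
    ly: float
    x0: float = 0.0
    y0: float = 0.0
    #: coordinate lines that must appear exactly as mesh lines
    mandatory_x: tuple = ()
    mandatory_y: tuple = ()
    #: (xmin, xmax, hx) / (ymin, ymax, hy) local target spacings
    refine_x: tuple = ()
    refine_y: tuple = ()

    def __post_init__(self):
        if self.lx <= 0 or self.ly <= 0:
            raise ValueError("degenerate domain: rectangle sides must be positive")

    @property
    def area(self) -> float:
        return self.lx * self.ly


def _axis_points(lo: float, hi: float, h: float, mandatory, refine) -> np.ndarray:
    """1-D grid on [lo, hi] with spacing <= h (locally finer inside refine
    intervals) containing every mandatory coordinate exactly."""
    anchors = {lo, hi, *(float(m) for m in mandatory if lo < m < hi)}
    for (rlo, rhi, _) in refine:
        anchors.update(float(r) for r in (rlo, rhi) if lo < r < hi)
    anchors = sorted(anchors)
    pts = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        # local target spacing: smallest h whose refine interval overlaps
        h_loc = h
        for (rlo, rhi, rh) in refine:
            if rlo < b and rhi > a:
                h_loc = min(h_loc, rh)
        n = max(1, int(np.ceil((b - a) / h_loc - 1e-12)))
        pts.append(np.linspace(a, b, n + 1)[:-1])
    pts.append(np.array([hi]))
    return np.concatenate(pts)


class Mesh:
    """P1 triangulation of a rectangle with precomputed element geometry.

    Attributes
    ----------
    vertices : (n, 2) float array, μm
    triangles : (m, 3) int array, counter-clockwise vertex triples
    areas : (m,) positive triangle areas
    grads : (m, 3, 2) constant gradients of the three local basis functions
    boundary_edges : (k, 2) int array of boundary vertex pairs
    boundary_normals : (k, 2) outward unit normals
    h : characteristic (maximum) edge length, μm
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.triangles = np.asarray(triangles, dtype=np.int32)
        self._build_geometry()

    # -- construction ---------------------------------------------------
    @classmethod
    def rectangle(cls, domain: RectangleDomain, target_h: float) -> "Mesh":
        if target_h <= 0:
            raise ValueError("target mesh size must be positive")
        xs = _axis_points(domain.x0, domain.x0 + domain.lx, target_h,
                          domain.mandatory_x, domain.refine_x)
        ys = _axis_points(domain.y0, domain.y0 + domain.ly, target_h,
                          domain.mandatory_y, domain.refine_y)
        nx, ny = len(xs), len(ys)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        verts = np.column_stack([X.ravel(), Y.ravel()])
        idx = np.arange(nx * ny).reshape(nx, ny)
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[1:, 1:].ravel()
        d = idx[:-1, 1:].ravel()
        # alternate the quad diagonal for a symmetric union-jack-free pattern
        tris = np.concatenate([
            np.column_stack([a, b, c]),
            np.column_stack([a, c, d]),
        ])
        return cls(verts, tris)

    def _build_geometry(self):
        v = self.vertices
        t = self.triangles
        p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        e1 = p1 - p0
        e2 = p2 - p0
        cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        # enforce counter-clockwise orientation
        flip = cross < 0
        if np.any(flip):
            t[flip, 1], t[flip, 2] = t[flip, 2].copy(), t[flip, 1].copy()
            p1, p2 = v[t[:, 1]], v[t[:, 2]]
            e1, e2 = p1 - p0, p2 - p0
            cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        if np.any(cross <= 0):
            raise ValueError("degenerate triangle with non-positive area")
        self.areas = 0.5 * cross
        # P1 basis gradients: grad phi_i = rot90(opposite edge) / (2A)
        g = np.empty((len(t), 3, 2))
        pts = (p0, p1, p2)
        for i in range(3):
            pj, pk = pts[(i + 1) % 3], pts[(i + 2) % 3]
            edge = pk - pj
            g[:, i, 0] = -edge[:, 1]
            g[:, i, 1] = edge[:, 0]
        g /= (2.0 * self.areas)[:, None, None]
        self.grads = g
        edge_len = np.stack([np.linalg.norm(v[t[:, (i + 1) % 3]] - v[t[:, i]], axis=1)
                             for i in range(3)])
        self.h = float(edge_len.max())
        self._build_boundary()
        self._tri = Triangulation(v[:, 0], v[:, 1], t)
        self._finder = TrapezoidMapTriFinder(self._tri)

    def _build_boundary(self):
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        bmask = counts[inv] == 1
        be = edges[bmask]          # oriented with domain on the left (CCW tris)
        self.boundary_edges = be
        d = self.vertices[be[:, 1]] - self.vertices[be[:, 0]]
        ln = np.linalg.norm(d, axis=1)
        # outward normal of a CCW-oriented boundary edge is the right-hand rotation
        self.boundary_normals = np.column_stack([d[:, 1], -d[:, 0]]) / ln[:, None]
        self.boundary_edge_lengths = ln
        self.boundary_vertices = np.unique(be)

    # -- queries ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def find_triangles(self, points: np.ndarray) -> np.ndarray:
        """Containing triangle index for each point; raises if any escapes."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tri = np.asarray(self._finder(pts[:, 0], pts[:, 1]))
        if np.any(tri < 0):
            # points exactly on the outer boundary can be missed by the
            # trapezoid map; retry with a tiny inward nudge
            bad = np.flatnonzero(tri < 0)
            centre = 0.5 * (self.vertices.min(axis=0) + self.vertices.max(axis=0))
            nudged = pts[bad] + 1e-9 * (centre - pts[bad])
            tri[bad] = np.asarray(self._finder(nudged[:, 0], nudged[:, 1]))
        if np.any(tri < 0):
            bad = np.flatnonzero(tri < 0)
            raise ValueError(
                f"point(s) outside the mesh at indices {bad.tolist()}: "
                f"{pts[bad[:5]].tolist()}")
        return tri

    def barycentric(self, points: np.ndarray, tri_idx: np.ndarray | None = None):
        """(tri_idx, (k,3) barycentric weights) for each point."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if tri_idx is None:
            tri_idx = self.find_triangles(pts)
        t = self.triangles[tri_idx]
        p0 = self.vertices[t[:, 0]]
        # lambda_i(x) = lambda_i(p0) + grad_i . (x - p0); lambda at p0 = e_0
        d = pts - p0
        g = self.grads[tri_idx]
        lam = np.einsum("kid,kd->ki", g, d)
        lam[:, 0] += 1.0
        # guard tiny negatives from roundoff at element borders
        return tri_idx, lam

    def interpolate(self, nodal_values: np.ndarray, points: np.ndarray,
                    tri_idx: np.ndarray | None = None) -> np.ndarray:
        """P1 interpolation of per-vertex scalar or vector data at points."""
        vals = np.asarray(nodal_values, dtype=float)
        tri_idx, lam = self.barycentric(points, tri_idx)
        t = self.triangles[tri_idx]
        out = np.einsum("ki,ki...->k...", lam, vals[t])
        return out

    def vertex_patch_areas(self) -> np.ndarray:
        """Sum of adjacent triangle areas per vertex (for recovery averaging)."""
        w = np.zeros(self.n_vertices)
        for i in range(3):
            np.add.at(w, self.triangles[:, i], self.areas)
        return w
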