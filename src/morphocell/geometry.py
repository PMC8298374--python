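"""Cell boundary geometry: shape templates, area, shape index, orientation.

A cell is a closed polygon of N membrane nodes tethered by springs to the cell
centre (the arithmetic mean of the nodes).  Equilibrium templates are circles,
ellipses and hypocycloids (the four-cusped astroid models the dendritic
myofibroblast phenotype); differentiation morphs an ellipse into a
hypocycloid by linear interpolation of the template parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShapeTemplate", "CellState", "generate_equilibrium_shape",
    "polygon_area", "polygon_perimeter", "cell_area", "cell_csi",
    "shape_index", "optimal_rotation", "rotation_matrix", "morph_parameters",
]


# -- templates -----------------------------------------------------------

@dataclass(frozen=True)
class ShapeTemplate:
    """Equilibrium cell-shape template.

    ``circle``: radius R.  ``ellipse``: semi-axes (a_e, b_e).
    ``hypocycloid``: base/rolling radii (a_h, b_h); a_h = 4 b_h is the
    astroid.  ``morphing``: starts elliptic, interpolates toward the
    hypocycloid with rate ``lam_w`` (min⁻¹) from onset time ``t_w`` (min).
    """

    kind: str = "circle"
    R: float = 5.0
    a_e: float = 6.25
    b_e: float = 4.0
    a_h: float = 20.0 / math.sqrt(6.0)
    b_h: float = 5.0 / math.sqrt(6.0)
    lam_w: float = 10.0
    t_w: float = 0.0

    def __post_init__(self):
        if self.kind == "circle" and self.R <= 0:
            raise ValueError("circle radius must be positive")
        if self.kind in ("ellipse", "morphing") and not self.a_e >= self.b_e > 0:
            raise ValueError("ellipse axes must satisfy a_e >= b_e > 0")
        if self.kind in ("hypocycloid", "morphing") and not self.a_h > self.b_h > 0:
            raise ValueError("hypocycloid radii must satisfy a_h > b_h > 0")

    def omega(self, t: float) -> float:
        """Differentiation progress ω(t) = 1 - exp(-λ_ω (t - t_ω)), 0 before t_ω."""
        if t < self.t_w:
            return 0.0
        return 1.0 - math.exp(-self.lam_w * (t - self.t_w))


def morph_parameters(t: float, template: ShapeTemplate) -> tuple[float, float]:
    """Blended shape parameters (R_a, R_b) at time t.

    R_a = a_h ω + a_e (1-ω) and likewise R_b; before the differentiation
    onset the elliptic parameters are returned unchanged.
    """
    w = template.omega(t)
    return (template.a_h * w + template.a_e * (1.0 - w),
            template.b_h * w + template.b_e * (1.0 - w))


def _circle_offsets(R: float, N: int) -> np.ndarray:
    th = 2.0 * np.pi * np.arange(N) / N
    return R * np.column_stack([np.cos(th), np.sin(th)])


def _ellipse_offsets(a: float, b: float, N: int) -> np.ndarray:
    th = 2.0 * np.pi * np.arange(N) / N
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def _hypocycloid_offsets(a: float, b: float, N: int) -> np.ndarray:
    th = 2.0 * np.pi * np.arange(N) / N
    r = (a - b) / b
    x = (a - b) * np.cos(th) + b * np.cos(r * th)
    y = (a - b) * np.sin(th) - b * np.sin(r * th)
    return np.column_stack([x, y])


def generate_equilibrium_shape(template: ShapeTemplate, N: int,
                               t: float = 0.0) -> np.ndarray:
    """N equilibrium node offsets (relative to the cell centre), uniform in
    the curve parameter.  Morphing templates blend the elliptic and
    hypocycloid node sets pointwise with weight ω(t)."""
    if N < 4:
        raise ValueError("a cell needs at least 4 membrane nodes")
    if template.kind == "circle":
        off = _circle_offsets(template.R, N)
    elif template.kind == "ellipse":
        off = _ellipse_offsets(template.a_e, template.b_e, N)
    elif template.kind == "hypocycloid":
        off = _hypocycloid_offsets(template.a_h, template.b_h, N)
    elif template.kind == "morphing":
        # pointwise blend of the two node sets, rescaled so the area
        # interpolates linearly in ω (the raw blend inflates the area at
        # mid-morph; rescaling keeps equal-volume phenotypes equal-volume)
        w = template.omega(t)
        E = _ellipse_offsets(template.a_e, template.b_e, N)
        H = _hypocycloid_offsets(template.a_h, template.b_h, N)
        off = (1.0 - w) * E + w * H
        target = (1.0 - w) * polygon_area(E) + w * polygon_area(H)
        off *= math.sqrt(target / polygon_area(off))
    else:
        raise ValueError(f"unknown template kind {template.kind!r}")
    return off - off.mean(axis=0)


# -- polygon measures ----------------------------------------------------

def polygon_area(nodes: np.ndarray, signed: bool = False) -> float:
    """Shoelace area of a closed polygon given by ordered vertices."""
    x, y = nodes[:, 0], nodes[:, 1]
    a = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(a) if signed else float(abs(a))


def polygon_perimeter(nodes: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(nodes, -1, axis=0) - nodes, axis=1).sum())


def shape_index(nodes: np.ndarray) -> float:
    """Cell shape index CSI = 4πA / l²: 1 for a disc, < 1 otherwise."""
    l = polygon_perimeter(nodes)
    if l <= 0:
        raise ValueError("zero-perimeter polygon has no shape index")
    return 4.0 * np.pi * polygon_area(nodes) / l ** 2


def cell_area(cell: "CellState") -> float:
    """Shoelace area of the cell polygon; warns on degenerate/self-
    intersecting boundaries instead of failing."""
    import warnings
    a = polygon_area(cell.nodes)
    if a == 0.0:
        warnings.warn("degenerate (zero-area) cell polygon", stacklevel=2)
    elif not _is_simple(cell.nodes):
        warnings.warn("self-intersecting cell polygon; shoelace area is "
                      "algebraic", stacklevel=2)
    return a


def cell_csi(cell: "CellState") -> float:
    """Cell shape index of the cell polygon."""
    return shape_index(cell.nodes)


def rotation_matrix(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


def optimal_rotation(equilibrium: np.ndarray, current: np.ndarray):
    """Angle minimising Σ‖B(φ) x̃_i − x_i‖² and the rotation matrix B(φ̃).

    Closed form: φ̃ = atan2(Σ x̃_i × x_i, Σ x̃_i · x_i).  Both point sets must
    be expressed relative to the cell centre.  Returns (phi, B, degenerate);
    ``degenerate`` flags all-zero offsets, for which φ̃ = 0.
    """
    equilibrium = np.asarray(equilibrium, dtype=float)
    current = np.asarray(current, dtype=float)
    if equilibrium.shape != current.shape or len(equilibrium) < 2:
        raise ValueError("need two equally sized point sets of length >= 2")
    dot = float(np.einsum("ij,ij->", equilibrium, current))
    cross = float(np.sum(equilibrium[:, 0] * current[:, 1]
                         - equilibrium[:, 1] * current[:, 0]))
    if abs(dot) < 1e-300 and abs(cross) < 1e-300:
        return 0.0, np.eye(2), True
    phi = math.atan2(cross, dot) % (2.0 * np.pi)
    return phi, rotation_matrix(phi), False


def _is_simple(nodes: np.ndarray) -> bool:
    from shapely.geometry import Polygon
    return Polygon(nodes).is_valid


# -- cell state ----------------------------------------------------------

@dataclass
class CellState:
    """Polygonal cell with spring-tethered membrane nodes.

    ``nodes`` are absolute positions (μm); ``offsets`` are the equilibrium
    node offsets x̂_j relative to the centre.  ``E_c`` is the membrane spring
    rate (min⁻¹) in the node-displacement law; ``E_c_elastic`` (kg/(μm·min²))
    enters the Hertz contact modulus — the model uses one numeral for both by
    default.  ``P`` is the traction magnitude per unit membrane length
    (kg/min²).
    """

    nodes: np.ndarray
    offsets: np.ndarray
    E_c: float = 5.0
    E_c_elastic: float = 5.0
    nu_c: float = 0.32
    P: float = 10.0
    phenotype: str = "fibroblast"
    R: float = 5.0
    csi0: float = field(default=0.0)
    area0: float = field(default=0.0)
    phi: float = 0.0
    template: ShapeTemplate | None = None

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.nodes) < 4:
            raise ValueError("a cell needs at least 4 membrane nodes")
        if self.csi0 == 0.0:
            self.csi0 = shape_index(self.offsets)
        if self.area0 == 0.0:
            self.area0 = polygon_area(self.offsets)

    @classmethod
    def from_template(cls, template: ShapeTemplate, centre, N: int = 40,
                      **kw) -> "CellState":
        off = generate_equilibrium_shape(template, N)
        centre = np.asarray(centre, dtype=float)
        R = kw.pop("R", template.R if template.kind == "circle"
                   else float(np.linalg.norm(off, axis=1).max()))
        return cls(nodes=centre + off, offsets=off, R=R, template=template, **kw)

    # geometry ----------------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def centre(self) -> np.ndarray:
        return self.nodes.mean(axis=0)

    def area(self) -> float:
        return polygon_area(self.nodes)

    def perimeter(self) -> float:
        return polygon_perimeter(self.nodes)

    def csi(self) -> float:
        return shape_index(self.nodes)

    def is_simple(self) -> bool:
        return _is_simple(self.nodes)

    def segments(self):
        """(midpoints, lengths, inward unit normals) of the membrane segments.

        Segment j joins node j to node j+1 (cyclic).  Normals point toward
        the cell centre for a counter-clockwise polygon.
        """
        nxt = np.roll(self.nodes, -1, axis=0)
        mid = 0.5 * (self.nodes + nxt)
        d = nxt - self.nodes
        ln = np.linalg.norm(d, axis=1)
        ok = ln > 1e-12
        # inward normal of a CCW edge = left-hand rotation of the tangent
        n = np.zeros_like(d)
        n[ok] = np.column_stack([-d[ok, 1], d[ok, 0]]) / ln[ok, None]
        if polygon_area(self.nodes, signed=True) < 0:
            n = -n
        return mid, ln, n

    def node_weights(self) -> np.ndarray:
        """Membrane length attributed to each node (half of both incident
        segments) — the ΔΓ weights for node-centred point forces."""
        ln = np.linalg.norm(np.roll(self.nodes, -1, axis=0) - self.nodes, axis=1)
        return 0.5 * (ln + np.roll(ln, 1))

    def orientation(self):
        """Optimal rotation of the equilibrium offsets onto the current ones."""
        rel = self.nodes - self.centre
        return optimal_rotation(self.offsets, rel)

    def equilibrium_targets(self) -> np.ndarray:
        """x_c + B(φ̃) x̂_j — the spring anchor of every node."""
        phi, B, _ = self.orientation()
        self.phi = phi
        return self.centre + self.offsets @ B.T

    def set_equilibrium_offsets(self, offsets: np.ndarray,
                                reset_reference: bool = True):
        self.offsets = np.asarray(offsets, dtype=float)
        if reset_reference:
            self.csi0 = shape_index(self.offsets)
            self.area0 = polygon_area(self.offsets)
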