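"""Cellular point-force systems: traction, cell–cell Hertz repulsion and
microchannel wall repulsion.

All forces are applied to the substrate as point forces at membrane segment
midpoints (or nodes, for wall contact), discretised with Dirac deltas.  The
repulsion magnitude follows a linearised two-dimensional Hertz contact law:
the total repelling force is Q̃ = (π/4) d E* with penetration depth d and
equivalent modulus 1/E* = (1−ν1²)/E1 + (1−ν2²)/E2, spread uniformly over the
contacting membrane length ‖l_m‖.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CellState

__all__ = [
    "PointForceSet", "ContactSet", "traction_forces", "equivalent_modulus",
    "hertz_total_force", "detect_cell_cell_contacts", "cell_cell_forces",
    "microtube_wall_forces",
]

#: 1 kg/(μm·min²) expressed in pascal
KG_UM_MIN2_TO_PA = 1e-6 / (60.0 ** 2) / 1e-12  # = 277.78 Pa


@dataclass
class PointForceSet:
    """Point forces on the substrate: application points, vectors, segment
    lengths and a provenance tag (traction | cell-cell | wall)."""

    points: np.ndarray          # (k, 2) μm
    forces: np.ndarray          # (k, 2) kg·μm/min²
    lengths: np.ndarray         # (k,) ΔΓ_j, μm
    tag: str = "traction"
    indices: np.ndarray | None = None   # originating node/segment indices

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.forces = np.atleast_2d(np.asarray(self.forces, dtype=float))
        self.lengths = np.atleast_1d(np.asarray(self.lengths, dtype=float))
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("non-finite force vector")

    @property
    def resultant(self) -> np.ndarray:
        return self.forces.sum(axis=0) if len(self.forces) else np.zeros(2)

    def torque_about(self, centre) -> float:
        r = self.points - np.asarray(centre, dtype=float)
        return float(np.sum(r[:, 0] * self.forces[:, 1]
                            - r[:, 1] * self.forces[:, 0]))

    @staticmethod
    def empty(tag: str = "traction") -> "PointForceSet":
        return PointForceSet(np.zeros((0, 2)), np.zeros((0, 2)),
                             np.zeros(0), tag)

    def merged_with(self, other: "PointForceSet") -> "PointForceSet":
        return PointForceSet(
            np.vstack([self.points, other.points]),
            np.vstack([self.forces, other.forces]),
            np.concatenate([self.lengths, other.lengths]),
            tag=self.tag if self.tag == other.tag else "mixed")


@dataclass
class ContactSet:
    """Contacting membrane segments of one cell against one obstacle/cell."""

    segment_indices: np.ndarray     # indices into the cell's segments/nodes
    depths: np.ndarray              # d(x_j) >= 0, μm
    lengths: np.ndarray             # ΔΓ_j of the contacting segments, μm
    E_star: float                   # equivalent modulus, kg/(μm·min²)
    full_overlap: bool = False

    def __post_init__(self):
        if np.any(self.depths < 0):
            raise ValueError("negative penetration depth in contact set")

    @property
    def contact_length(self) -> float:
        """‖l_m‖ = Σ ΔΓ over the contacting segments."""
        return float(self.lengths.sum())

    @property
    def is_empty(self) -> bool:
        return len(self.segment_indices) == 0


# -- elementary laws -----------------------------------------------------

def equivalent_modulus(E1: float, nu1: float, E2: float = np.inf,
                       nu2: float = 0.0) -> float:
    """Hertz equivalent modulus; E2 = inf models a rigid wall."""
    if E1 <= 0 or E2 <= 0:
        raise ValueError("Young's moduli must be positive")
    if abs(nu1) >= 1 or abs(nu2) >= 1:
        raise ValueError("Poisson ratios must satisfy |nu| < 1")
    inv = (1.0 - nu1 ** 2) / E1
    if np.isfinite(E2):
        inv += (1.0 - nu2 ** 2) / E2
    return 1.0 / inv


def hertz_total_force(d: float, E_star: float) -> float:
    """Total repulsive force Q̃ = (π/4) d E*; no tensile contact (d < 0 → 0)."""
    if d < 0:
        return 0.0
    return 0.25 * np.pi * d * E_star


# -- traction ------------------------------------------------------------

def traction_forces(cell: CellState, P: float | None = None) -> PointForceSet:
    """Inward pulling tractions, one per membrane segment.

    Magnitude P·ΔΓ_j along the inward unit normal at the segment midpoint;
    zero-length segments are skipped with a warning.
    """
    P = cell.P if P is None else P
    if P < 0:
        raise ValueError("traction magnitude must be non-negative")
    mid, ln, n_in = cell.segments()
    ok = ln > 1e-12
    if not np.all(ok):
        warnings.warn("skipping zero-length membrane segment(s)", stacklevel=2)
    f = P * ln[ok, None] * n_in[ok]
    return PointForceSet(mid[ok], f, ln[ok], tag="traction")


# -- cell–cell contact ---------------------------------------------------

def detect_cell_cell_contacts(cell_i: CellState, cell_k: CellState) -> ContactSet:
    """Contacts of cell_i's membrane against cell_k.

    The penetration depth is the overlap of the equilibrium envelopes,
    d = max(0, R_i + R_k − ‖x_c,i − x_c,k‖), shared by both cells; the
    contacting segments are those whose midpoints lie inside cell_k's
    equilibrium envelope (disc of radius R_k about its centre).
    """
    ci, ck = cell_i.centre, cell_k.centre
    dist = float(np.linalg.norm(ci - ck))
    E_star = equivalent_modulus(cell_i.E_c_elastic, cell_i.nu_c,
                                cell_k.E_c_elastic, cell_k.nu_c)
    d = max(0.0, cell_i.R + cell_k.R - dist)
    if d <= 0.0:
        return ContactSet(np.zeros(0, dtype=int), np.zeros(0), np.zeros(0),
                          E_star)
    mid, ln, _ = cell_i.segments()
    inside = np.linalg.norm(mid - ck, axis=1) < cell_k.R
    idx = np.flatnonzero(inside)
    full = dist < 1e-9 and len(idx) == cell_i.N
    if full:
        warnings.warn("full overlap of two cells (identical positions) — "
                      "simulation bug signal", stacklevel=2)
    return ContactSet(idx, np.full(len(idx), d), ln[idx], E_star,
                      full_overlap=full)


def cell_cell_forces(cell: CellState, contacts: ContactSet,
                     P: float | None = None) -> PointForceSet:
    """Traction with Hertz repulsion substituted on contacting segments.

    Free segments pull inward with magnitude P·ΔΓ; contacting segments push
    outward with per-length magnitude Q = Q̃/‖l_m‖ where Q̃ = (π/4) d E*.
    """
    P = cell.P if P is None else P
    mid, ln, n_in = cell.segments()
    if contacts.is_empty:
        return traction_forces(cell, P)
    lm = contacts.contact_length
    if lm <= 0:
        raise ValueError("nonempty contact set with zero contact length")
    forces = P * ln[:, None] * n_in
    idx = contacts.segment_indices
    Q = np.array([hertz_total_force(d, contacts.E_star) for d in
                  contacts.depths]) / lm
    forces[idx] = -(Q * ln[idx])[:, None] * n_in[idx]    # outward repulsion
    return PointForceSet(mid, forces, ln, tag="cell-cell")


# -- microchannel wall contact -------------------------------------------

def microtube_wall_forces(cell: CellState, tube, wall_E: float = np.inf,
                          wall_nu: float = 0.0,
                          contact_tol: float = 1e-6) -> PointForceSet:
    """Repulsion exerted on the channel walls by a compressed cell.

    For each node in wall contact the depth is d = R − ‖x_j − x_c‖ (the
    compression of the equilibrium radius); the force acts along the outward
    normal (onto the wall) with per-length magnitude (π/4) d E*/‖l_m‖.  The
    pulling traction is excluded inside the channel.
    """
    mask, n_out, _ = tube.wall_contact(cell.nodes, tol=contact_tol)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return PointForceSet.empty("wall")
    centre = cell.centre
    dist = np.linalg.norm(cell.nodes[idx] - centre, axis=1)
    d = cell.R - dist
    if np.any(d > cell.R + 1e-9):
        raise ValueError("geometry corruption: penetration depth exceeds "
                         "the cell radius")
    d = np.clip(d, 0.0, None)
    w = cell.node_weights()[idx]
    E_star = equivalent_modulus(cell.E_c_elastic, cell.nu_c, wall_E, wall_nu)
    # each contiguous contact region against one wall surface is a separate
    # contact: the Hertz normalisation length ‖l_m‖ is per patch, exactly as
    # a cell-cell contact uses the length of that contact portion only
    pts = cell.nodes[idx]
    patch_key = _wall_patch_keys(pts, tube)
    Q = np.zeros(len(idx))
    patches = []
    for key in np.unique(patch_key):
        sel = patch_key == key
        lm_g = float(w[sel].sum())
        Q[sel] = 0.25 * np.pi * d[sel] * E_star / lm_g  # per unit length
        patches.append({"indices": np.flatnonzero(sel), "lm": lm_g})
    forces = (Q * w)[:, None] * n_out[idx]
    out = PointForceSet(pts, forces, w, tag="wall", indices=idx)
    out.patches = patches
    return out


def _wall_patch_keys(points: np.ndarray, tube) -> np.ndarray:
    """Patch label per contact point: wall side × channel segment."""
    x = points[:, 0]
    side = (points[:, 1] >= tube.axis_y).astype(int)
    seg = np.zeros(len(points), dtype=int)
    seg[(x >= tube.x0) & (x <= tube.x1)] = 1
    seg[(x > tube.x1) & (x < tube.x2)] = 2
    seg[(x >= tube.x2)] = 3
    return side * 4 + seg
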