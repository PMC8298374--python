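"""Linear-Lagrange finite-element operators on a :class:`~morphocell.mesh.Mesh`.

All PDEs in the model are discretised with P1 elements and backward-Euler time
stepping.  Point sources/forces (Dirac distributions) are discretised by
direct evaluation of the test functions at the source point, which makes the
discrete load conserve the applied force exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh

__all__ = [
    "mass_matrix", "stiffness_matrix", "robin_matrix", "advection_matrix",
    "point_load_vector", "load_vector", "FemSystem",
    "viscous_operator", "elastic_strain_rhs", "l2_error",
    "estimate_convergence_order", "ConvergenceReport",
]


def _assemble(mesh: Mesh, local: np.ndarray) -> sp.csr_matrix:
    """Scatter (m,3,3) element matrices into a sparse global matrix."""
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)),
                         shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()


def mass_matrix(mesh: Mesh, lumped: bool = False) -> sp.csr_matrix:
    base = (np.ones((3, 3)) + np.eye(3)) / 12.0
    local = mesh.areas[:, None, None] * base
    M = _assemble(mesh, local)
    if lumped:
        return sp.diags(np.asarray(M.sum(axis=1)).ravel()).tocsr()
    return M


def stiffness_matrix(mesh: Mesh, coeff: np.ndarray | None = None) -> sp.csr_matrix:
    """∫ a(x) ∇φ_i·∇φ_j dΩ with an optional per-element coefficient a
    (used e.g. to make solid channel walls near-impermeable to diffusion)."""
    g = mesh.grads
    w = mesh.areas if coeff is None else mesh.areas * np.asarray(coeff)
    local = w[:, None, None] * np.einsum("kid,kjd->kij", g, g)
    return _assemble(mesh, local)


def robin_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Boundary mass matrix: ∮ φ_i φ_j ds over the outer boundary."""
    be = mesh.boundary_edges
    ln = mesh.boundary_edge_lengths
    base = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    local = ln[:, None, None] * base
    rows = np.repeat(be, 2, axis=1).ravel()
    cols = np.tile(be, (1, 2)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)),
                         shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()


def advection_matrix(mesh: Mesh, v_nodal: np.ndarray) -> sp.csr_matrix:
    """Conservative advection: A_ij = ∫ φ_i ∇·(v φ_j) dΩ with P1 velocity.

    ∇·(v φ_j) = φ_j ∇·v + v·∇φ_j; with v linear per element the integrand is
    quadratic, integrated exactly.
    """
    t = mesh.triangles
    g = mesh.grads
    A = mesh.areas
    v_el = v_nodal[t]                                  # (m,3,2)
    divv = np.einsum("kid,kid->k", g, v_el)            # constant per element
    mloc = (np.ones((3, 3)) + np.eye(3)) / 12.0
    term1 = (A * divv)[:, None, None] * mloc
    # ∫ φ_i v dΩ = (A/12) (Σ_k v_k + v_i)
    vsum = v_el.sum(axis=1)                            # (m,2)
    int_phi_v = (A[:, None, None] / 12.0) * (vsum[:, None, :] + v_el)  # (m,3,2)
    term2 = np.einsum("kid,kjd->kij", int_phi_v, g)
    return _assemble(mesh, term1 + term2)


def advection_apply(mesh: Mesh, v_nodal: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Matrix-free product of the conservative advection operator with a
    scalar field (same quadrature as :func:`advection_matrix`)."""
    t = mesh.triangles
    g = mesh.grads
    A = mesh.areas
    v_el = v_nodal[t]
    c_el = c[t]
    divv = np.einsum("kid,kid->k", g, v_el)
    csum = c_el.sum(axis=1)
    # term1_i = (A divv / 12) (c_sum + c_i); term2_i = ∫φ_i v · Σ_j c_j ∇φ_j
    term1 = (A * divv / 12.0)[:, None] * (csum[:, None] + c_el)
    gradc = np.einsum("kj,kjd->kd", c_el, g)
    int_phi_v = (A[:, None, None] / 12.0) * (v_el.sum(axis=1)[:, None, :] + v_el)
    term2 = np.einsum("kid,kd->ki", int_phi_v, gradc)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, t.ravel(), (term1 + term2).ravel())
    return out


def point_load_vector(mesh: Mesh, location, force) -> np.ndarray:
    """(n, 2) load vector for a point force: entry i = φ_i(x_s) * force.

    Only the vertices of the containing triangle receive nonzero entries, and
    each component column sums to the applied force component exactly.
    """
    force = np.asarray(force, dtype=float)
    tri_idx, lam = mesh.barycentric(np.asarray(location, dtype=float)[None, :])
    out = np.zeros((mesh.n_vertices, 2))
    verts = mesh.triangles[tri_idx[0]]
    out[verts] = lam[0][:, None] * force[None, :]
    return out


def point_loads(mesh: Mesh, locations: np.ndarray, forces: np.ndarray) -> np.ndarray:
    """Accumulate many point forces into a single (n, 2) load vector."""
    locations = np.atleast_2d(locations)
    forces = np.atleast_2d(forces)
    tri_idx, lam = mesh.barycentric(locations)
    out = np.zeros((mesh.n_vertices, 2))
    verts = mesh.triangles[tri_idx]                    # (k,3)
    contrib = lam[:, :, None] * forces[:, None, :]     # (k,3,2)
    np.add.at(out, verts.ravel(), contrib.reshape(-1, 2))
    return out


def load_vector(mesh: Mesh, f) -> np.ndarray:
    """∫ φ_i f dΩ by the edge-midpoint rule (exact for quadratic f).

    ``f`` maps (k, 2) points to (k,) scalars or (k, c) vectors.
    """
    t = mesh.triangles
    p = mesh.vertices[t]                               # (m,3,2)
    mids = 0.5 * (p + np.roll(p, -1, axis=1))          # mids[j] = edge (j, j+1)
    fv = np.asarray(f(mids.reshape(-1, 2)), dtype=float).reshape(len(t), 3, -1)
    # basis phi_i is 1/2 on the two midpoints of its adjacent edges, 0 opposite
    contrib = (mesh.areas[:, None, None] / 6.0) * (fv + np.roll(fv, 1, axis=1))
    out = np.zeros((mesh.n_vertices, fv.shape[2]))
    np.add.at(out, t.ravel(), contrib.reshape(-1, fv.shape[2]))
    return out if out.shape[1] > 1 else out[:, 0]


@dataclass
class FemSystem:
    """Pre-assembled scalar operators and time step for one mesh."""

    mesh: Mesh
    dt: float
    lumped_mass: bool = False

    def __post_init__(self):
        self.M = mass_matrix(self.mesh, lumped=self.lumped_mass)
        self.K = stiffness_matrix(self.mesh)
        self.R = robin_matrix(self.mesh)
        if self.dt <= 0:
            raise ValueError("time step must be positive")

    @property
    def domain_area(self) -> float:
        return float(np.asarray(self.M.sum(axis=1)).sum())


# -- vector-valued (velocity) system ------------------------------------

def viscous_operator(mesh: Mesh, mu1: float, mu2: float) -> sp.csr_matrix:
    """Stiffness of the Kelvin–Voigt viscous stress.

    a(v, w) = ∫ μ1 sym(∇v) : sym(∇w) + μ2 (∇·v)(∇·w) dΩ,
    on interleaved dofs [v1_0, v2_0, v1_1, v2_1, ...].
    """
    g = mesh.grads
    A = mesh.areas
    t = mesh.triangles
    m = len(t)
    # local 6x6 blocks: dof (i, a), entries from sym-grad contraction
    # sym(∇v):sym(∇w) for basis (phi_i e_a),(phi_j e_b):
    #   1/2 [ d_b phi_i d_a phi_j + delta_ab grad phi_i . grad phi_j ]
    gg = np.einsum("kid,kjd->kij", g, g)               # grad_i . grad_j
    local = np.zeros((m, 3, 2, 3, 2))
    for a in range(2):
        for b in range(2):
            term = 0.5 * mu1 * (np.einsum("ki,kj->kij", g[:, :, b], g[:, :, a])
                                + (gg if a == b else 0.0))
            term = term + mu2 * np.einsum("ki,kj->kij", g[:, :, a], g[:, :, b])
            local[:, :, a, :, b] = term
    local *= A[:, None, None, None, None]
    dof = (2 * t[:, :, None] + np.arange(2)[None, None, :]).reshape(m, 6)
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    n = 2 * mesh.n_vertices
    return sp.coo_matrix((local.reshape(m, 36).ravel(), (rows, cols)),
                         shape=(n, n)).tocsr()


def elastic_strain_rhs(mesh: Mesh, sigma_nodal: np.ndarray) -> np.ndarray:
    """-∫ σ : ∇(φ_i e_a) dΩ for a P1 symmetric stress field.

    ``sigma_nodal`` has shape (n, 3) storing (σ11, σ22, σ12) per vertex.
    Returns an (n, 2) load contribution (moved to the right-hand side of the
    momentum balance).
    """
    t = mesh.triangles
    g = mesh.grads
    A = mesh.areas
    s_el = sigma_nodal[t]                              # (m,3,3)
    s_mean = s_el.mean(axis=1)                         # exact: ∫σ = A * mean
    s11, s22, s12 = s_mean[:, 0], s_mean[:, 1], s_mean[:, 2]
    out = np.zeros((mesh.n_vertices, 2))
    fx = -(A[:, None]) * (s11[:, None] * g[:, :, 0] + s12[:, None] * g[:, :, 1])
    fy = -(A[:, None]) * (s12[:, None] * g[:, :, 0] + s22[:, None] * g[:, :, 1])
    np.add.at(out[:, 0], t.ravel(), fx.ravel())
    np.add.at(out[:, 1], t.ravel(), fy.ravel())
    return out


# -- errors and convergence ----------------------------------------------

def l2_error(mesh: Mesh, nodal: np.ndarray, exact) -> float:
    """L2 distance between a P1 field and an exact function (midpoint rule)."""
    t = mesh.triangles
    p = mesh.vertices[t]
    mids = 0.5 * (p + np.roll(p, -1, axis=1))
    vh = 0.5 * (nodal[t] + nodal[np.roll(t, -1, axis=1)])
    ve = np.asarray(exact(mids.reshape(-1, 2))).reshape(vh.shape)
    diff2 = ((vh - ve) ** 2).reshape(len(t), 3, -1).sum(axis=2)
    return float(np.sqrt((mesh.areas / 3.0 * diff2.sum(axis=1)).sum()))


@dataclass
class ConvergenceReport:
    h_values: list
    errors: list
    orders: list
    monotone: bool

    @property
    def observed_order(self) -> float:
        """Average of the orders from the finest refinement pairs."""
        tail = self.orders[-2:] if len(self.orders) >= 2 else self.orders
        return float(np.mean(tail))


def _manufactured_velocity():
    """Smooth divergence-constrained-free exact velocity and its body force
    for the quasi-static viscous momentum balance on the unit square."""
    import sympy as sy

    x, y = sy.symbols("x y")
    v1 = sy.sin(sy.pi * x) * sy.sin(sy.pi * y)
    v2 = sy.sin(sy.pi * x) * sy.sin(2 * sy.pi * y)
    return x, y, v1, v2


def estimate_convergence_order(levels: int = 4, n0: int = 8,
                               mu1: float = 33.783, mu2: float = 22.523,
                               problem: str = "manufactured") -> ConvergenceReport:
    """Uniform-refinement convergence study for the velocity solver.

    ``manufactured``: a smooth exact solution with analytically derived body
    force; the observed L2 order is ≈ 2.  ``point_force``: a static cell's
    traction point forces (reduced regularity; the order is reported as a
    diagnostic and is expected below 2, against a fine-grid reference).
    """
    import sympy as sy

    from .mesh import RectangleDomain

    if levels < 3:
        raise ValueError("need at least 3 refinement levels")

    if problem == "manufactured":
        x, y, v1, v2 = _manufactured_velocity()
        e11 = sy.diff(v1, x)
        e22 = sy.diff(v2, y)
        e12 = (sy.diff(v1, y) + sy.diff(v2, x)) / 2
        div = e11 + e22
        s11 = mu1 * e11 + mu2 * div
        s22 = mu1 * e22 + mu2 * div
        s12 = mu1 * e12
        f1 = -(sy.diff(s11, x) + sy.diff(s12, y))
        f2 = -(sy.diff(s12, x) + sy.diff(s22, y))
        f_fun = sy.lambdify((x, y), (f1, f2), "numpy")
        v_fun = sy.lambdify((x, y), (v1, v2), "numpy")

        def exact(pts):
            return np.column_stack(v_fun(pts[:, 0], pts[:, 1]))

        def body(pts):
            return np.column_stack(f_fun(pts[:, 0], pts[:, 1]))
    elif problem == "point_force":
        exact = None
        body = None
    else:
        raise ValueError(f"unknown problem kind {problem!r}")

    hs, errs, sols, meshes = [], [], [], []
    ns = [n0 * 2 ** k for k in range(levels)]
    for n in ns:
        mesh = Mesh.rectangle(RectangleDomain(1.0, 1.0), 1.0 / n)
        A = viscous_operator(mesh, mu1, mu2)
        if problem == "manufactured":
            F = load_vector(mesh, body)
        else:
            # a static circular cell pulling inward at 40 membrane points
            theta = np.linspace(0, 2 * np.pi, 41)[:-1] + np.pi / 400
            pts = 0.5 + 0.25 * np.column_stack([np.cos(theta), np.sin(theta)])
            frc = -(0.25 * 2 * np.pi / 40) * np.column_stack([np.cos(theta), np.sin(theta)])
            F = point_loads(mesh, pts, frc)
        free = np.ones(2 * mesh.n_vertices, dtype=bool)
        free[2 * mesh.boundary_vertices] = False
        free[2 * mesh.boundary_vertices + 1] = False
        sol = np.zeros(2 * mesh.n_vertices)
        Af = A[free][:, free]
        sol[free] = spla.spsolve(Af.tocsc(), F.ravel()[free])
        v_h = sol.reshape(-1, 2)
        hs.append(mesh.h)
        meshes.append(mesh)
        sols.append(v_h)
        if exact is not None:
            errs.append(l2_error(mesh, v_h, exact))
    if exact is None:
        # Richardson-style: compare each level against the finest solution
        ref_mesh, ref = meshes[-1], sols[-1]
        for mesh, v_h in zip(meshes[:-1], sols[:-1]):
            errs.append(l2_error(mesh, v_h, lambda p: ref_mesh.interpolate(ref, p)))
        hs = hs[:-1]
    orders = [float(np.log2(errs[i] / errs[i + 1])) for i in range(len(errs) - 1)]
    monotone = all(errs[i] > errs[i + 1] for i in range(len(errs) - 1))
    return ConvergenceReport(hs, errs, orders, monotone)
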