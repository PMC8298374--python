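"""Morphoelastic substrate mechanics with a Kelvin–Voigt stress.

The substrate (ECM) velocity v and effective Eulerian strain ε obey

    ρ [Dv/Dt + v (∇·v)] − ∇·σ = f,
    Dε/Dt + ε skw(L) − skw(L) ε + [tr(ε) − 1] sym(L) = −α ε,
    v = 0 on ∂Ω,

with L = ∇v and the Kelvin–Voigt stress

    σ = E/(1+ν_s) { ε + tr(ε) ν_s/(1−2ν_s) I } + μ1 sym(L) + μ2 tr(sym(L)) I.

The decay rate α encodes plasticity: with α = 0 all strain (and hence
displacement) is recovered once the forces vanish; with α > 0 part of the
deformation becomes permanent.  The default solver is quasi-static (inertia
dropped — the substrate's viscous relaxation time μ1/E is far shorter than
cell time scales and no tissue density is part of the parameter set); an
inertial mode with explicitly lagged ρ-terms is available for comparison.

Discretisation: velocity is P1, strain is stored per element (P0), which
makes the dominant strain production ε ← ε + Δt sym(∇v) exactly local.  One
backward-Euler step solves

    (A_visc + Δt A_elas) v = f + G(ε_k) + Δt A_elas v_k

inside a Picard loop, where A_elas is the linear elasticity operator of the
elastic stress and G(ε) the weak divergence of the current elastic stress;
the implicit left-hand side removes the stiff elastic coupling that a naive
fixed-point iteration cannot contract (Δt E/μ1 > 1 at the default
parameters).  The remaining Picard corrections (co-rotation, the
[tr(ε) − 1] factor, strain advection, plastic decay) are small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import mass_matrix, point_loads, viscous_operator
from .mesh import Mesh

__all__ = ["MechanicsParams", "MechanicsState", "kelvin_voigt_stress",
           "step_mechanics", "substrate_velocity_at"]


@dataclass(frozen=True)
class MechanicsParams:
    """Material parameters in the kg–μm–min unit system (table defaults)."""

    E: float = 100.0       # substrate stiffness, kg/(μm·min²)
    nu_s: float = 0.49     # substrate Poisson ratio (plane strain)
    mu1: float = 33.783    # shear viscosity
    mu2: float = 22.523    # bulk viscosity
    alpha: float = 0.1     # plasticity (strain decay) rate, min⁻¹
    rho: float = 1.0       # density; only used in the inertial mode
    quasi_static: bool = True
    picard_tol: float = 1e-8
    picard_maxit: int = 50

    def __post_init__(self):
        if abs(1.0 - 2.0 * self.nu_s) < 1e-12:
            raise ValueError("nu_s = 0.5 makes the plane-strain factor "
                             "nu/(1-2nu) diverge")

    @property
    def lame_like(self) -> tuple[float, float]:
        """(shear-like, volumetric-like) coefficients of the elastic stress."""
        fac = self.E / (1.0 + self.nu_s)
        return fac, fac * self.nu_s / (1.0 - 2.0 * self.nu_s)


def kelvin_voigt_stress(eps: np.ndarray, L: np.ndarray,
                        params: MechanicsParams) -> np.ndarray:
    """Kelvin–Voigt stress for (..., 2, 2) strain and velocity-gradient arrays."""
    eps = np.asarray(eps, dtype=float)
    L = np.asarray(L, dtype=float)
    if not np.allclose(eps, np.swapaxes(eps, -1, -2), atol=1e-10):
        raise ValueError("strain tensor must be symmetric")
    I = np.eye(2)
    fac, lam = params.lame_like
    tr_eps = np.trace(eps, axis1=-2, axis2=-1)[..., None, None]
    sig_el = fac * eps + lam * tr_eps * I
    symL = 0.5 * (L + np.swapaxes(L, -1, -2))
    tr_symL = np.trace(symL, axis1=-2, axis2=-1)[..., None, None]
    return sig_el + params.mu1 * symL + params.mu2 * tr_symL * I


def _elastic_stress(eps: np.ndarray, p: MechanicsParams) -> np.ndarray:
    """(k, 3) elastic stress components (σ11, σ22, σ12) from (k, 3) strain."""
    fac, lam = p.lame_like
    tr = eps[:, 0] + eps[:, 1]
    s = np.empty_like(eps)
    s[:, 0] = fac * eps[:, 0] + lam * tr
    s[:, 1] = fac * eps[:, 1] + lam * tr
    s[:, 2] = fac * eps[:, 2]
    return s


@dataclass
class MechanicsState:
    """Velocity, strain and accumulated displacement on a fixed mesh.

    Velocity and displacement are per vertex; strain is per element as
    (ε11, ε22, ε12) — the tensor symmetry is structural.  ``strain_nodal``
    recovers a per-vertex strain field for output and interpolation.
    """

    mesh: Mesh
    params: MechanicsParams = field(default_factory=MechanicsParams)
    v: np.ndarray = None           # (n, 2) μm/min
    eps: np.ndarray = None         # (m, 3) per element, dimensionless
    u: np.ndarray = None           # (n, 2) accumulated displacement, μm
    picard_iters: list = field(default_factory=list)

    def __post_init__(self):
        n = self.mesh.n_vertices
        m = len(self.mesh.triangles)
        if self.v is None:
            self.v = np.zeros((n, 2))
        if self.eps is None:
            self.eps = np.zeros((m, 3))
        if self.u is None:
            self.u = np.zeros((n, 2))
        self._free = np.ones(2 * n, dtype=bool)
        self._free[2 * self.mesh.boundary_vertices] = False
        self._free[2 * self.mesh.boundary_vertices + 1] = False
        self._Avisc = viscous_operator(self.mesh, self.params.mu1,
                                       self.params.mu2)
        fac, lam = self.params.lame_like
        self._Ael = viscous_operator(self.mesh, fac, lam)
        self._Mv = None
        if not self.params.quasi_static:
            Ms = mass_matrix(self.mesh, lumped=True)
            self._Mv = sp.kron(Ms, sp.eye(2), format="csr")
        self._lu = None
        self._lu_dt = None
        self._patch_w = self.mesh.vertex_patch_areas()

    # -- helpers ---------------------------------------------------------
    def _factor(self, dt: float):
        if self._lu is not None and self._lu_dt == dt:
            return self._lu
        A = self._Avisc + dt * self._Ael
        if not self.params.quasi_static:
            A = A + (self.params.rho / dt) * self._Mv
        Af = A[self._free][:, self._free].tocsc()
        self._lu = spla.splu(Af)
        self._lu_dt = dt
        return self._lu

    def element_velocity_gradient(self, v: np.ndarray) -> np.ndarray:
        """(m, 2, 2) per-element ∇v with L[a, b] = ∂v_a/∂x_b."""
        t = self.mesh.triangles
        L = np.einsum("kid,kie->kde", self.mesh.grads, v[t])
        return np.swapaxes(L, 1, 2)

    def strain_nodal(self) -> np.ndarray:
        """Area-weighted recovery of the element strain to the vertices."""
        t = self.mesh.triangles
        w = self.mesh.areas
        out = np.zeros((self.mesh.n_vertices, 3))
        for i in range(3):
            np.add.at(out, t[:, i], self.eps * w[:, None])
        return out / self._patch_w[:, None]

    def strain_tensors(self) -> np.ndarray:
        """Nodal strain as an (n, 2, 2) symmetric tensor array."""
        en = self.strain_nodal()
        e = np.empty((len(en), 2, 2))
        e[:, 0, 0] = en[:, 0]
        e[:, 1, 1] = en[:, 1]
        e[:, 0, 1] = e[:, 1, 0] = en[:, 2]
        return e

    def _element_strain_advection(self, v: np.ndarray,
                                  eps: np.ndarray) -> np.ndarray:
        """(m, 3) lagged advective transport (v·∇)ε of an element strain
        field, via nodal recovery of ε and per-element gradients."""
        mesh = self.mesh
        t = mesh.triangles
        w = mesh.areas
        en = np.zeros((mesh.n_vertices, 3))
        for i in range(3):
            np.add.at(en, t[:, i], eps * w[:, None])
        en /= self._patch_w[:, None]
        g = np.einsum("kic,kid->kcd", en[t], mesh.grads)  # ∂_d ε_c per element
        v_el = v[t].mean(axis=1)                          # (m, 2)
        return np.einsum("kcd,kd->kc", g, v_el)


def _elastic_rhs(mesh: Mesh, sigma_el: np.ndarray) -> np.ndarray:
    """-∫ σ : ∇(φ_i e_a) dΩ for a per-element (m, 3) stress; exact for P0."""
    t = mesh.triangles
    g = mesh.grads
    A = mesh.areas
    s11, s22, s12 = sigma_el[:, 0], sigma_el[:, 1], sigma_el[:, 2]
    out = np.zeros((mesh.n_vertices, 2))
    fx = -(A[:, None]) * (s11[:, None] * g[:, :, 0] + s12[:, None] * g[:, :, 1])
    fy = -(A[:, None]) * (s12[:, None] * g[:, :, 0] + s22[:, None] * g[:, :, 1])
    np.add.at(out[:, 0], t.ravel(), fx.ravel())
    np.add.at(out[:, 1], t.ravel(), fy.ravel())
    return out


def _strain_update(state: MechanicsState, eps_n: np.ndarray, v: np.ndarray,
                   dt: float, eps_ref: np.ndarray) -> np.ndarray:
    """Implicit per-element update of the strain-evolution equation.

    The co-rotation terms, the stretching production and the −αε decay are
    implicit; the advective transport uses the reference strain of the
    current Picard iterate (substrate velocities are small — the term is a
    correction)."""
    p = state.params
    L = state.element_velocity_gradient(v)
    S11 = L[:, 0, 0]
    S22 = L[:, 1, 1]
    S12 = 0.5 * (L[:, 0, 1] + L[:, 1, 0])
    w = 0.5 * (L[:, 1, 0] - L[:, 0, 1])   # skw(L) = [[0, -w], [w, 0]]
    m = len(eps_n)
    A = np.zeros((m, 3, 3))
    d = 1.0 / dt + p.alpha
    A[:, 0, 0] = d + S11
    A[:, 0, 1] = S11
    A[:, 0, 2] = 2.0 * w
    A[:, 1, 0] = S22
    A[:, 1, 1] = d + S22
    A[:, 1, 2] = -2.0 * w
    A[:, 2, 0] = S12 - w
    A[:, 2, 1] = S12 + w
    A[:, 2, 2] = d
    adv = state._element_strain_advection(v, eps_ref)
    rhs = eps_n / dt + np.column_stack([S11, S22, S12]) - adv
    return np.linalg.solve(A, rhs[:, :, None])[:, :, 0]


def step_mechanics(state: MechanicsState, force_points=None, force_vectors=None,
                   dt: float = 0.1, load: np.ndarray | None = None) -> MechanicsState:
    """One backward-Euler step of the coupled momentum/strain system.

    Cellular point forces are given either as (points, vectors) pairs or as a
    pre-assembled (n, 2) nodal ``load``.  Updates v, ε and u ← u + v Δt in
    place; raises if the Picard iteration does not converge.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    mesh = state.mesh
    p = state.params
    F = np.zeros((mesh.n_vertices, 2))
    if load is not None:
        F = F + load
    if force_points is not None and len(np.atleast_2d(force_points)):
        F = F + point_loads(mesh, np.asarray(force_points),
                            np.asarray(force_vectors))
    lu = state._factor(dt)
    free = state._free
    eps_n = state.eps.copy()
    v_n = state.v.copy()
    eps_k = eps_n.copy()
    v_k = v_n.copy()
    converged = False
    dv = de = np.inf
    for it in range(p.picard_maxit):
        rhs = (F + _elastic_rhs(mesh, _elastic_stress(eps_k, p))).ravel()
        rhs = rhs + dt * (state._Ael @ v_k.ravel())
        if not p.quasi_static:
            rhs = rhs + (p.rho / dt) * (state._Mv @ v_n.ravel())
            # explicitly lagged inertial convection ρ[(v·∇)v + v(∇·v)]
            L = state.element_velocity_gradient(v_k)
            Ln = np.zeros((mesh.n_vertices, 2, 2))
            for i in range(3):
                np.add.at(Ln, mesh.triangles[:, i],
                          L * mesh.areas[:, None, None])
            Ln /= state._patch_w[:, None, None]
            conv = (np.einsum("nab,nb->na", Ln, v_k)
                    + v_k * np.trace(Ln, axis1=1, axis2=2)[:, None])
            rhs = rhs - p.rho * (state._Mv @ conv.ravel())
        v_new = np.zeros(2 * mesh.n_vertices)
        v_new[free] = lu.solve(rhs[free])
        v_new = v_new.reshape(-1, 2)
        eps_new = _strain_update(state, eps_n, v_new, dt, eps_k)
        dv = np.max(np.abs(v_new - v_k))
        de = np.max(np.abs(eps_new - eps_k))
        v_k, eps_k = v_new, eps_new
        scale = max(1.0, np.max(np.abs(v_k)), np.max(np.abs(eps_k)))
        if max(dv, de) < p.picard_tol * scale:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Picard iteration did not converge in {p.picard_maxit} steps "
            f"(last increments dv={dv:.3e}, deps={de:.3e})")
    state.picard_iters.append(it + 1)
    state.v = v_k
    state.eps = eps_k
    state.u = state.u + v_k * dt
    return state


def substrate_velocity_at(state: MechanicsState, points: np.ndarray) -> np.ndarray:
    """Substrate velocity interpolated at arbitrary points (P1)."""
    return state.mesh.interpolate(state.v, points)
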