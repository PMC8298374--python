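"""Advection–diffusion transport of a generic signalling molecule.

The concentration c(x, t) obeys

    ∂c/∂t + ∇·(v c) − ∇·(D ∇c) = k δ(x − x_s),

with a Robin boundary condition ∂c/∂n + κ_s c = 0 (no-flux as κ_s → 0,
absorbing as κ_s → ∞) and c(x, 0) = 0.  One backward-Euler step solves

    (M + Δt [A(v) + D K + D κ_s R]) c⁺ = M c + Δt k φ(x_s),

where A is the conservative advection operator, K the stiffness matrix and R
the boundary mass matrix.  The point source is discretised by basis-function
evaluation, so with κ_s = 0 and v = 0 the total mass grows by exactly k Δt
per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .fem import (FemSystem, advection_apply, advection_matrix,
                  point_load_vector)
from .mesh import Mesh

__all__ = ["SignalField", "step_signal", "signal_gradient_at"]


@dataclass
class SignalField:
    """Concentration field with its source and transport parameters.

    Units: c in kg/μm³, D in μm²/min, k in kg/(μm³·min); κ_s is used as
    printed in the parameter tables, in mesh (μm) units.
    """

    fem: FemSystem
    D: float
    k: float
    source: np.ndarray
    kappa: float = 100.0
    active: bool = True
    c: np.ndarray = None
    #: per-element relative diffusivity (1 in the medium, ≈0 inside solid
    #: obstacles such as microchannel walls); None means uniform
    diffusivity_factor: np.ndarray = None

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=float)
        if self.c is None:
            self.c = np.zeros(self.fem.mesh.n_vertices)
        self._b_src = point_load_vector(self.fem.mesh, self.source,
                                        (1.0, 0.0))[:, 0]
        if self.diffusivity_factor is not None:
            from .fem import stiffness_matrix
            self._K = stiffness_matrix(self.fem.mesh, self.diffusivity_factor)
        else:
            self._K = self.fem.K
        self._lu0 = None  # cached factorisation for the v = 0 system

    @property
    def mesh(self) -> Mesh:
        return self.fem.mesh

    def total_mass(self) -> float:
        return float(self.fem.M @ self.c @ np.ones_like(self.c))

    def boundary_outflux(self) -> float:
        """Robin boundary loss rate  D κ_s ∮ c ds  (kg/min per μm depth)."""
        return float(self.D * self.kappa * (self.fem.R @ self.c).sum())

    def set_steady_state(self):
        """Replace c by the steady solution of the diffusion–Robin problem
        with the active source (used to warm-start long-established sources).
        Requires κ_s > 0 for a unique steady state."""
        if self.kappa <= 0:
            raise ValueError("steady state needs a positive Robin coefficient")
        A = (self.D * self._K + self.D * self.kappa * self.fem.R).tocsc()
        self.c = spla.spsolve(A, self.k * self._b_src)


def step_signal(field: SignalField, velocity: np.ndarray | None,
                dt: float, advection: str = "implicit") -> SignalField:
    """Advance the concentration by one backward-Euler step (in place).

    ``velocity`` is a per-vertex (n, 2) substrate velocity or None/zero, in
    which case a cached factorisation of the transport operator is reused.
    With ``advection="explicit"`` the (small) advective term is lagged
    (IMEX), which keeps the cached factorisation valid at any velocity —
    used by the scenario drivers, where substrate velocities are orders of
    magnitude below the diffusive scale.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    fem = field.fem
    rhs = fem.M @ field.c
    if field.active:
        rhs = rhs + dt * field.k * field._b_src
    static = velocity is None or not np.any(velocity)
    try:
        if static or advection == "explicit":
            if not static:
                rhs = rhs - dt * advection_apply(fem.mesh, velocity, field.c)
            if field._lu0 is None or field._lu0[0] != dt:
                A = (fem.M + dt * (field.D * field._K
                                   + field.D * field.kappa * fem.R)).tocsc()
                field._lu0 = (dt, spla.splu(A))
            field.c = field._lu0[1].solve(rhs)
        else:
            A = (fem.M + dt * (advection_matrix(fem.mesh, velocity)
                               + field.D * field._K
                               + field.D * field.kappa * fem.R)).tocsc()
            field.c = spla.splu(A).solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - non-physical parameters
        raise RuntimeError(
            f"singular signal-transport system (D={field.D}, "
            f"kappa={field.kappa}, dt={dt}): {exc}") from exc
    return field


def signal_gradient_at(field: SignalField, points: np.ndarray) -> np.ndarray:
    """Per-triangle-constant P1 gradient of c at the given points (k, 2)."""
    mesh = field.mesh
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.find_triangles(pts)
    nodal = field.c[mesh.triangles[tri]]               # (k,3)
    return np.einsum("ki,kid->kd", nodal, mesh.grads[tri])
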