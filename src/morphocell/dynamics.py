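"""Stochastic dynamics of the cell membrane nodes.

Each node performs an Euler–Maruyama step of

    dx_j = β ∇c/(‖∇c‖+γ) dt + E_c (x_c + B(φ̃) x̂_j − x_j) dt + v dt + σ_rw dW,

i.e. chemotaxis up the (normalised) signal gradient, spring recoil toward the
orientation-corrected equilibrium position, passive convection with the
substrate velocity, and a random walk.  The chemotactic weight

    β = β₀ μ_m (CSI/CSI₀ + A/A₀)/2

shrinks with cell deformation and compression.  Obstacles (channel walls,
other cells) remove the wall-normal displacement component, attenuate the
tangential one by friction 1 − μ_f ‖f‖ (clamped at zero so friction never
reverses motion), and finally clamp positions to the feasible region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellState, cell_csi, polygon_area

logger = logging.getLogger(__name__)

__all__ = ["MobilityParams", "mobility_beta", "step_nodes",
           "project_obstacle", "apply_friction", "engulfment_check"]


@dataclass
class MobilityParams:
    """Mobility / noise parameters of the node-displacement law.

    β₀ (min⁻¹) is the maximal membrane-point mobility, μ_m a dimensionless
    mobility-reduction factor, γ the gradient regulariser (concentration
    gradient units, kg/μm⁴), σ_rw the random-walk weight and μ_f the wall
    friction coefficient.
    """

    beta0: float = 10.0
    mu_m: float = 1.0
    gamma: float = 1e-6
    sigma_rw: float = 1.0
    mu_f: float = 0.03
    dt: float = 0.1

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gradient regulariser must be positive")
        if self.sigma_rw < 0 or self.mu_f < 0:
            raise ValueError("noise and friction weights must be non-negative")


def mobility_beta(cell: CellState, params: MobilityParams) -> float:
    """Deformation-dependent chemotactic mobility (clamped at zero)."""
    if cell.csi0 <= 0 or cell.area0 <= 0:
        raise ValueError("equilibrium CSI and area must be positive")
    ratio = (cell_csi(cell) / cell.csi0
             + polygon_area(cell.nodes) / cell.area0) / 2.0
    return max(0.0, params.beta0 * params.mu_m * ratio)


def project_obstacle(dx: np.ndarray, n_ob: np.ndarray) -> np.ndarray:
    """Remove the wall-normal component of a displacement.

    ``n_ob`` must be unit length (normalised with a warning otherwise); the
    tangential component is preserved exactly.
    """
    dx = np.asarray(dx, dtype=float)
    n = np.asarray(n_ob, dtype=float)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(np.abs(norm - 1.0) > 1e-9):
        logger.warning("non-unit obstacle normal; normalising")
        n = n / np.where(norm > 0, norm, 1.0)
    comp = np.sum(dx * n, axis=-1, keepdims=True)
    return dx - comp * n


def apply_friction(dx: np.ndarray, tau_ob: np.ndarray, f_mag,
                   mu_f: float) -> np.ndarray:
    """Attenuate tangential motion by wall friction.

    The tangential component is scaled by 1 − μ_f ‖f‖, clamped to ≥ 0
    (logged when the clamp triggers) so friction can stop but never reverse
    sliding.
    """
    dx = np.asarray(dx, dtype=float)
    tau = np.asarray(tau_ob, dtype=float)
    norm = np.linalg.norm(tau, axis=-1, keepdims=True)
    if np.any(np.abs(norm - 1.0) > 1e-9):
        logger.warning("non-unit obstacle tangent; normalising")
        tau = tau / np.where(norm > 0, norm, 1.0)
    f_mag = np.asarray(f_mag, dtype=float)
    factor = 1.0 - mu_f * f_mag
    if np.any(factor < 0):
        logger.info("friction clamp triggered (mu_f * |f| > 1)")
        factor = np.clip(factor, 0.0, None)
    comp = np.sum(dx * tau, axis=-1, keepdims=True)
    removed = (1.0 - np.atleast_1d(factor))[..., None] * comp * tau
    return dx - removed.reshape(dx.shape)


def step_nodes(cell: CellState, params: MobilityParams,
               grad_c: np.ndarray | None = None,
               substrate_v: np.ndarray | None = None,
               active_velocity: np.ndarray | None = None,
               obstacles: tuple = (),
               contact_force_mag: np.ndarray | None = None,
               rng: np.random.Generator | None = None,
               domain=None) -> CellState:
    """Advance all membrane nodes by one Euler–Maruyama step (in place).

    ``grad_c`` is the per-node signal gradient (chemotaxis mechanism);
    ``active_velocity`` replaces chemotaxis by a prescribed drift (fixed-
    velocity mechanisms).  ``contact_force_mag`` holds the per-node repelling
    force magnitude used by wall friction.  ``domain``, when given, must
    expose ``clamp(points)`` and is applied last as an outer-boundary guard.
    """
    dt = params.dt
    if dt <= 0:
        raise ValueError("time step must be positive")
    N = cell.N
    dx = np.zeros((N, 2))
    if grad_c is not None:
        beta = mobility_beta(cell, params)
        gnorm = np.linalg.norm(grad_c, axis=1, keepdims=True)
        dx += beta * grad_c / (gnorm + params.gamma) * dt
    if active_velocity is not None:
        # prescribed drift, attenuated by the same mobility reduction as
        # chemotaxis: mu_m * (CSI/CSI0 + A/A0)/2
        reduction = mobility_beta(cell, params) / params.beta0
        dx += reduction * np.asarray(active_velocity, dtype=float) * dt
    # spring recoil toward the orientation-corrected equilibrium positions
    dx += cell.E_c * (cell.equilibrium_targets() - cell.nodes) * dt
    if substrate_v is not None:
        dx += np.asarray(substrate_v, dtype=float) * dt
    if params.sigma_rw > 0:
        if rng is None:
            raise ValueError("sigma_rw > 0 requires an rng")
        # one Wiener increment per cell and step: the random walk displaces
        # the cell as a whole; independent per-node noise would roughen the
        # membrane (≈5% extra perimeter at the default parameters) and
        # depress the shape index well below its observed in-channel level
        dx += params.sigma_rw * np.sqrt(dt) * rng.standard_normal(2)
    # obstacle projection and friction on contacting nodes
    for ob in obstacles:
        mask, normals, tangents = ob.wall_contact(cell.nodes)
        if np.any(mask):
            dx[mask] = project_obstacle(dx[mask], normals[mask])
            fm = (contact_force_mag[mask]
                  if contact_force_mag is not None else np.zeros(mask.sum()))
            dx[mask] = apply_friction(dx[mask], tangents[mask], fm, params.mu_f)
    new_nodes = cell.nodes + dx
    for ob in obstacles:
        new_nodes = ob.clamp(new_nodes)
    if domain is not None:
        new_nodes = domain.clamp(new_nodes)
    cell.nodes = new_nodes
    return cell


def engulfment_check(cell: CellState, field, tol: float) -> bool:
    """Switch the signal source off permanently once the cell touches it.

    Returns the updated source-active flag (False once any membrane node is
    within ``tol`` of the source position).
    """
    if not field.active:
        return False
    dmin = float(np.min(np.linalg.norm(cell.nodes - field.source, axis=1)))
    if dmin <= tol:
        field.active = False
        logger.info("signal source engulfed (node within %.3g um)", tol)
    return field.active
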