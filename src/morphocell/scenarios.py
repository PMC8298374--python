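"""End-to-end scenario drivers and the Monte Carlo transmigration study.

Four applications are provided: chemotaxis toward a point source (with
engulfment), fibroblast→myofibroblast differentiation with shape morphing,
head-on collision of two cells, and single-cell transmigration through an
LC–SNB–LC microchannel, plus a Monte Carlo framework that samples friction
and mobility coefficients and aggregates the probability that the transit
exhibits "phase 3" (non-monotone forward motion inside the barrier).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channel import CellObstacle, TubeGeometry
from .config import ScenarioConfig, default_config, spawn_rngs
from .dynamics import MobilityParams, engulfment_check, step_nodes
from .fem import FemSystem
from .forces import (KG_UM_MIN2_TO_PA, PointForceSet, cell_cell_forces,
                     detect_cell_cell_contacts, microtube_wall_forces,
                     traction_forces)
from .geometry import CellState, ShapeTemplate, generate_equilibrium_shape
from .mechanics import MechanicsParams, MechanicsState, substrate_velocity_at
from .mesh import Mesh, RectangleDomain
from .signal import SignalField, signal_gradient_at, step_signal

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseTimeline", "MCResult", "ScenarioResult", "MicrotubeResult",
    "run_chemotaxis_scenario", "run_differentiation_scenario",
    "run_collision_scenario", "run_microtube_scenario", "detect_phases",
    "contact_pressure", "run_monte_carlo", "mc_error",
    "phase3_probability_from_error",
]


# ----------------------------------------------------------------------
# result containers
# ----------------------------------------------------------------------

@dataclass
class PhaseTimeline:
    """Per-phase [t_start, t_end] intervals of one microchannel transit.

    Phases: 1 — channel entry until the front node reaches the SNB;
    2 — squeezing into/through the SNB; 3 (optional) — non-monotone forward
    motion while occupying the SNB, ending when the rear node leaves it;
    4 — SNB exit until the rear node leaves the channel.  For a completed
    transit the intervals partition [entry, exit].
    """

    intervals: dict
    phase3_occurred: bool
    complete: bool

    @property
    def durations(self) -> dict:
        return {p: t1 - t0 for p, (t0, t1) in self.intervals.items()}

    def validate(self):
        keys = sorted(self.intervals)
        spans = [self.intervals[k] for k in keys]
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if a1 > b0 + 1e-9 or a0 > a1 + 1e-9:
                raise ValueError(f"ill-ordered phase intervals: {self.intervals}")
        return self


@dataclass
class MCResult:
    """Aggregated Monte Carlo statistics of the transmigration study."""

    mechanism: str
    n: int
    n_completed: int
    phase3_probability: float
    mc_error: float
    durations: dict                 # phase -> list of durations (min)
    samples: list = field(default_factory=list)


@dataclass
class ScenarioResult:
    """Recorded time series of a multi-cell scenario."""

    times: np.ndarray
    centres: np.ndarray             # (steps, n_cells, 2)
    csi: np.ndarray                 # (steps, n_cells)
    area: np.ndarray                # (steps, n_cells)
    cells: list
    mechanics: MechanicsState
    signal: SignalField
    extras: dict = field(default_factory=dict)

    def series(self) -> dict:
        out = {"time": self.times}
        for i in range(self.centres.shape[1]):
            out[f"x_{i}"] = self.centres[:, i, 0]
            out[f"y_{i}"] = self.centres[:, i, 1]
            out[f"csi_{i}"] = self.csi[:, i]
            out[f"area_{i}"] = self.area[:, i]
        return out


@dataclass
class MicrotubeResult:
    """Time series and phase timeline of one microchannel transit."""

    times: np.ndarray
    centres: np.ndarray             # (steps, 2)
    speed: np.ndarray
    csi: np.ndarray
    area: np.ndarray
    pressure: np.ndarray            # kPa
    front_x: np.ndarray
    rear_x: np.ndarray
    fully_in_lc: np.ndarray         # bool per step
    completed: bool
    timeline: PhaseTimeline | None
    tube: TubeGeometry
    mechanism: str
    cell: CellState = None

    @property
    def max_pressure(self) -> float:
        return float(self.pressure.max()) if len(self.pressure) else 0.0

    @property
    def speed_smoothed(self) -> np.ndarray:
        """Centre speed over a sliding 1-minute window.

        The raw per-step speed of an Euler–Maruyama path carries a noise
        floor σ_rw/√Δt that grows without bound as Δt → 0; migration speeds
        are physically defined over a finite observation interval, so peak
        speeds are reported on a 1-minute window.
        """
        if len(self.times) < 2:
            return self.speed
        dt = float(self.times[1] - self.times[0])
        h = max(1, int(round(0.5 / dt)))          # centred ±0.5 min window
        n = len(self.times)
        out = np.empty(n)
        for i in range(n):
            j0, j1 = max(0, i - h), min(n - 1, i + h)
            span = (j1 - j0) * dt
            out[i] = (np.linalg.norm(self.centres[j1] - self.centres[j0])
                      / span if span > 0 else self.speed[i])
        return out

    @property
    def max_speed(self) -> float:
        """Peak cell speed over the transit (1-minute window)."""
        return float(self.speed_smoothed.max()) if len(self.speed) else 0.0

    @property
    def pressure_smoothed(self) -> np.ndarray:
        """Contact pressure averaged over a trailing 1-minute window (the
        scale used for locating the transit's pressure maximum; brief
        single-node contact transients at first wall touch are not
        representative of the sustained load)."""
        if len(self.times) < 2:
            return self.pressure
        dt = float(self.times[1] - self.times[0])
        w = max(1, int(round(1.0 / dt)))
        w += (w + 1) % 2                          # odd length, centred
        h = w // 2
        padded = np.concatenate([np.full(h, self.pressure[0]), self.pressure,
                                 np.full(h, self.pressure[-1])])
        return np.convolve(padded, np.ones(w) / w, mode="valid")

    @property
    def mean_lc_csi(self) -> float:
        if not self.fully_in_lc.any():
            return float("nan")
        return float(self.csi[self.fully_in_lc].mean())

    def series(self) -> dict:
        return {"time": self.times, "x": self.centres[:, 0],
                "y": self.centres[:, 1], "speed": self.speed,
                "pressure_kPa": self.pressure, "csi": self.csi,
                "area": self.area, "front_x": self.front_x,
                "rear_x": self.rear_x}


# ----------------------------------------------------------------------
# shared machinery
# ----------------------------------------------------------------------

class _DomainClamp:
    """Keeps membrane nodes strictly inside the rectangular mesh."""

    def __init__(self, domain: RectangleDomain, margin: float = 1e-6):
        self.lo = np.array([domain.x0, domain.y0]) + margin
        self.hi = np.array([domain.x0 + domain.lx,
                            domain.y0 + domain.ly]) - margin

    def clamp(self, points: np.ndarray) -> np.ndarray:
        return np.clip(points, self.lo, self.hi)


def _mechanics(cfg: ScenarioConfig, mesh: Mesh) -> MechanicsState:
    params = MechanicsParams(E=cfg.E_s, nu_s=cfg.nu_s, mu1=cfg.mu1,
                             mu2=cfg.mu2, alpha=cfg.alpha,
                             quasi_static=cfg.quasi_static)
    return MechanicsState(mesh, params)


def _mobility(cfg: ScenarioConfig) -> MobilityParams:
    return MobilityParams(beta0=cfg.beta0, mu_m=cfg.mu_m, gamma=cfg.gamma,
                          sigma_rw=cfg.sigma_rw, mu_f=cfg.mu_f, dt=cfg.dt)


def _cell_forces_multicell(cells, traction_on: bool, P=None):
    """Traction plus Hertz repulsion for every cell against every other."""
    sets = []
    for i, ci in enumerate(cells):
        contact = None
        for j, ck in enumerate(cells):
            if i == j:
                continue
            c = detect_cell_cell_contacts(ci, ck)
            if not c.is_empty:
                contact = c if contact is None else ContactUnion(contact, c)
        Pi = (P[i] if P is not None else ci.P) if traction_on else 0.0
        if contact is None or contact.is_empty:
            fs = traction_forces(ci, Pi) if Pi > 0 else PointForceSet.empty()
        else:
            fs = cell_cell_forces(ci, contact, Pi)
        sets.append(fs)
    return sets


class ContactUnion:
    """Union of two contact sets of the same cell (multi-neighbour contact)."""

    def __init__(self, a, b):
        self.segment_indices = np.union1d(a.segment_indices, b.segment_indices)
        depth = max(a.depths.max(initial=0.0), b.depths.max(initial=0.0))
        self.depths = np.full(len(self.segment_indices), depth)
        lena = dict(zip(a.segment_indices, a.lengths))
        lena.update(zip(b.segment_indices, b.lengths))
        self.lengths = np.array([lena[i] for i in self.segment_indices])
        self.E_star = a.E_star
        self.is_empty = len(self.segment_indices) == 0

    @property
    def contact_length(self):
        return float(self.lengths.sum())


def _square_scene(cfg: ScenarioConfig):
    """Mesh / FEM / signal / mechanics for the square-domain scenarios."""
    cx, cy = cfg.domain_x / 2.0, cfg.domain_y / 2.0
    pad = cfg.sub_x / 2.0 + 3.0 * cfg.R
    domain = RectangleDomain(
        cfg.domain_x, cfg.domain_y,
        mandatory_x=(cx,), mandatory_y=(cy,),
        refine_x=((cx - pad, cx + pad, cfg.mesh_h_fine),),
        refine_y=((cy - pad, cy + pad, cfg.mesh_h_fine),))
    mesh = Mesh.rectangle(domain, cfg.mesh_h)
    fem = FemSystem(mesh, cfg.dt)
    source = np.array([cx, cy])
    sig = SignalField(fem, D=cfg.D, k=cfg.k, source=source, kappa=cfg.kappa_s)
    mech = _mechanics(cfg, mesh)
    return domain, mesh, fem, sig, mech


def _corner_positions(cfg: ScenarioConfig) -> np.ndarray:
    """Initial cell centres: the corners of the central subdomain."""
    cx, cy = cfg.domain_x / 2.0, cfg.domain_y / 2.0
    hx, hy = cfg.sub_x / 2.0, cfg.sub_y / 2.0
    corners = np.array([[cx - hx, cy - hy], [cx + hx, cy - hy],
                        [cx + hx, cy + hy], [cx - hx, cy + hy]])
    if cfg.n_cells == 1:
        return np.array([[cx - hx, cy]])
    return corners[:cfg.n_cells]


def _grad_at_nodes(sig: SignalField, cell: CellState) -> np.ndarray:
    return signal_gradient_at(sig, cell.nodes)


def _separate_cells(cells, iters: int = 2):
    """Mutual non-penetration pass after all cells have stepped.

    Cells are stepped sequentially, each clamped against the others'
    pre-step membranes; a moving neighbour can therefore overtake a node
    that was feasible when it moved.  A couple of mutual re-clamp passes
    restore the node-level non-penetration guarantee.
    """
    for _ in range(iters):
        moved = False
        for i, ci in enumerate(cells):
            for j, ck in enumerate(cells):
                if i == j:
                    continue
                ob = CellObstacle(ck)
                new = ob.clamp(ci.nodes)
                if not np.array_equal(new, ci.nodes):
                    ci.nodes = new
                    moved = True
        if not moved:
            break


# ----------------------------------------------------------------------
# scenario 1: chemotaxis toward a point source
# ----------------------------------------------------------------------

def run_chemotaxis_scenario(cfg: ScenarioConfig | None = None,
                            seed: int | None = None) -> ScenarioResult:
    """Cells chemotax toward a central point source, develop a "nose",
    engulf the source on contact and relax back to their equilibrium shape.

    The cellular traction stays active throughout: with plasticity α > 0 the
    substrate keeps creeping inward, leaving a persistent cell-area deficit,
    while with α = 0 the area recovers once the substrate equilibrates.
    """
    cfg = (cfg or default_config("chemotaxis")).validate()
    seed = cfg.seed if seed is None else seed
    domain, mesh, fem, sig, mech = _square_scene(cfg)
    clamp = _DomainClamp(domain)
    mob = _mobility(cfg)
    positions = _corner_positions(cfg)
    template = ShapeTemplate(kind="circle", R=cfg.R)
    cells = [CellState.from_template(template, p, N=cfg.N, E_c=cfg.E_c,
                                     E_c_elastic=cfg.E_c_elastic,
                                     nu_c=cfg.nu_c, P=cfg.P)
             for p in positions]
    rngs = spawn_rngs(seed, len(cells), "chemotaxis-rw") \
        if cfg.sigma_rw > 0 else [None] * len(cells)
    engulf_tol = cfg.mesh_h_fine

    nsteps = int(round(cfg.t_end / cfg.dt))
    rec = {"t": [], "centre": [], "csi": [], "area": []}
    for step in range(nsteps):
        t = (step + 1) * cfg.dt
        # cells pull on the ECM throughout; with alpha > 0 the sustained
        # traction keeps the substrate creeping, leaving a persistent
        # cell-area deficit that the alpha = 0 variant does not show
        force_sets = _cell_forces_multicell(cells, traction_on=True)
        pts = np.vstack([fs.points for fs in force_sets if len(fs.points)]) \
            if any(len(fs.points) for fs in force_sets) else None
        vecs = np.vstack([fs.forces for fs in force_sets if len(fs.forces)]) \
            if pts is not None else None
        from .mechanics import step_mechanics
        step_mechanics(mech, pts, vecs, cfg.dt)
        step_signal(sig, mech.v, cfg.dt, advection="explicit")
        for i, cell in enumerate(cells):
            grad = _grad_at_nodes(sig, cell)
            sv = substrate_velocity_at(mech, cell.nodes)
            obstacles = tuple(CellObstacle(c) for j, c in enumerate(cells)
                              if j != i)
            step_nodes(cell, mob, grad_c=grad, substrate_v=sv,
                       obstacles=obstacles, rng=rngs[i], domain=clamp)
            engulfment_check(cell, sig, engulf_tol)
        if len(cells) > 1:
            _separate_cells(cells)
        rec["t"].append(t)
        rec["centre"].append([c.centre.copy() for c in cells])
        rec["csi"].append([c.csi() for c in cells])
        rec["area"].append([c.area() for c in cells])
    return ScenarioResult(np.array(rec["t"]), np.array(rec["centre"]),
                          np.array(rec["csi"]), np.array(rec["area"]),
                          cells, mech, sig,
                          extras={"source_active": sig.active})


# ----------------------------------------------------------------------
# scenario 2: differentiation (ellipse -> hypocycloid morphing)
# ----------------------------------------------------------------------

def run_differentiation_scenario(cfg: ScenarioConfig | None = None,
                                 seed: int | None = None) -> ScenarioResult:
    """Elliptic fibroblasts chemotax toward a TGF-beta point source and
    differentiate into hypocycloid-shaped myofibroblasts once their local
    concentration exceeds the threshold; traction grows with the morphing
    progress up to the myofibroblast factor."""
    cfg = (cfg or default_config("differentiation")).validate()
    seed = cfg.seed if seed is None else seed
    domain, mesh, fem, sig, mech = _square_scene(cfg)
    clamp = _DomainClamp(domain)
    mob = _mobility(cfg)
    positions = _corner_positions(cfg)
    base_template = ShapeTemplate(kind="morphing", a_e=cfg.a_e, b_e=cfg.b_e,
                                  a_h=cfg.a_h, b_h=cfg.b_h,
                                  lam_w=cfg.lambda_w, t_w=math.inf)
    cells = [CellState.from_template(
        replace_template_start(base_template), p, N=cfg.N, E_c=cfg.E_c,
        E_c_elastic=cfg.E_c_elastic, nu_c=cfg.nu_c, P=cfg.P)
        for p in positions]
    rngs = spawn_rngs(seed, len(cells), "differentiation-rw") \
        if cfg.sigma_rw > 0 else [None] * len(cells)

    nsteps = int(round(cfg.t_end / cfg.dt))
    rec = {"t": [], "centre": [], "csi": [], "area": []}
    omega = np.zeros((nsteps, len(cells)))
    t_onset = [None] * len(cells)
    u_near = np.zeros((nsteps, len(cells)))
    for step in range(nsteps):
        t = (step + 1) * cfg.dt
        # morph equilibrium shapes and traction of differentiating cells
        P_eff = []
        for i, cell in enumerate(cells):
            tw = t_onset[i]
            if tw is not None:
                tmpl = replace(cell.template, t_w=tw)
                cell.template = tmpl
                w = tmpl.omega(t)
                omega[step, i] = w
                cell.set_equilibrium_offsets(
                    generate_equilibrium_shape(tmpl, cfg.N, t=t))
                cell.phenotype = ("myofibroblast" if w > 0.99
                                  else "differentiating")
                P_eff.append(cfg.P * (1.0 + (cfg.traction_factor - 1.0) * w))
            else:
                P_eff.append(cfg.P)
        force_sets = _cell_forces_multicell(cells, traction_on=True, P=P_eff)
        pts = np.vstack([fs.points for fs in force_sets if len(fs.points)])
        vecs = np.vstack([fs.forces for fs in force_sets if len(fs.forces)])
        from .mechanics import step_mechanics
        step_mechanics(mech, pts, vecs, cfg.dt)
        step_signal(sig, mech.v, cfg.dt, advection="explicit")
        for i, cell in enumerate(cells):
            grad = _grad_at_nodes(sig, cell)
            sv = substrate_velocity_at(mech, cell.nodes)
            obstacles = tuple(CellObstacle(c) for j, c in enumerate(cells)
                              if j != i)
            step_nodes(cell, mob, grad_c=grad, substrate_v=sv,
                       obstacles=obstacles, rng=rngs[i], domain=clamp)
            # differentiation trigger: concentration at the cell centre
            if t_onset[i] is None:
                c_here = float(mesh.interpolate(sig.c, cell.centre[None])[0])
                if c_here > cfg.c_diff:
                    t_onset[i] = t
                    logger.info("cell %d starts differentiating at t=%.2f "
                                "(c=%.3g)", i, t, c_here)
            u_near[step, i] = float(np.linalg.norm(
                mesh.interpolate(mech.u, cell.nodes), axis=1).mean())
        _separate_cells(cells)
        rec["t"].append(t)
        rec["centre"].append([c.centre.copy() for c in cells])
        rec["csi"].append([c.csi() for c in cells])
        rec["area"].append([c.area() for c in cells])
    return ScenarioResult(np.array(rec["t"]), np.array(rec["centre"]),
                          np.array(rec["csi"]), np.array(rec["area"]),
                          cells, mech, sig,
                          extras={"omega": omega, "t_onset": t_onset,
                                  "u_near": u_near})


def replace_template_start(template: ShapeTemplate) -> ShapeTemplate:
    """A morphing template that has not started (onset at +inf, ω = 0)."""
    return replace(template, t_w=math.inf)


# ----------------------------------------------------------------------
# scenario 3: two-cell collision
# ----------------------------------------------------------------------

def run_collision_scenario(cfg: ScenarioConfig | None = None,
                           seed: int | None = None,
                           gap: float = 6.0) -> ScenarioResult:
    """Two cells chemotax head-on toward a central source and collide.

    Both cells flank the source at a small distance; Hertz repulsion acts on
    the contacting membrane portions and the displacement projection keeps
    the membranes from interpenetrating, flattening the facing sides.
    """
    cfg = (cfg or default_config("collision")).validate()
    cfg = replace(cfg, n_cells=2)
    seed = cfg.seed if seed is None else seed
    domain, mesh, fem, sig, mech = _square_scene(cfg)
    clamp = _DomainClamp(domain)
    mob = _mobility(cfg)
    cx, cy = cfg.domain_x / 2.0, cfg.domain_y / 2.0
    offs = cfg.R + gap
    positions = np.array([[cx - offs, cy], [cx + offs, cy]])
    template = ShapeTemplate(kind="circle", R=cfg.R)
    cells = [CellState.from_template(template, p, N=cfg.N, E_c=cfg.E_c,
                                     E_c_elastic=cfg.E_c_elastic,
                                     nu_c=cfg.nu_c, P=cfg.P)
             for p in positions]
    rngs = spawn_rngs(seed, len(cells), "collision-rw") \
        if cfg.sigma_rw > 0 else [None] * len(cells)
    engulf_tol = cfg.mesh_h_fine

    nsteps = int(round(cfg.t_end / cfg.dt))
    rec = {"t": [], "centre": [], "csi": [], "area": []}
    min_gap = np.inf
    for step in range(nsteps):
        t = (step + 1) * cfg.dt
        force_sets = _cell_forces_multicell(cells, traction_on=True)
        pts = np.vstack([fs.points for fs in force_sets if len(fs.points)]) \
            if any(len(fs.points) for fs in force_sets) else None
        vecs = np.vstack([fs.forces for fs in force_sets if len(fs.forces)]) \
            if pts is not None else None
        from .mechanics import step_mechanics
        step_mechanics(mech, pts, vecs, cfg.dt)
        step_signal(sig, mech.v, cfg.dt, advection="explicit")
        for i, cell in enumerate(cells):
            grad = _grad_at_nodes(sig, cell)
            sv = substrate_velocity_at(mech, cell.nodes)
            other = cells[1 - i]
            step_nodes(cell, mob, grad_c=grad, substrate_v=sv,
                       obstacles=(CellObstacle(other),), rng=rngs[i],
                       domain=clamp)
            engulfment_check(cell, sig, engulf_tol)
        _separate_cells(cells)
        # node-level non-penetration measure (what the projection/clamp
        # guarantees): signed distance of each cell's nodes to the other
        # cell's membrane, negative when a node lies inside it
        from shapely import contains_xy, distance, make_valid
        from shapely import points as shp_points
        from shapely.geometry import Polygon
        for a, b in ((0, 1), (1, 0)):
            poly = make_valid(Polygon(cells[b].nodes))
            pts = shp_points(cells[a].nodes)
            d = distance(poly.exterior if hasattr(poly, "exterior") else
                         poly.boundary, pts)
            inside = contains_xy(poly, cells[a].nodes[:, 0],
                                 cells[a].nodes[:, 1])
            signed = np.where(inside, -d, d)
            min_gap = min(min_gap, float(signed.min()))
        rec["t"].append(t)
        rec["centre"].append([c.centre.copy() for c in cells])
        rec["csi"].append([c.csi() for c in cells])
        rec["area"].append([c.area() for c in cells])
    return ScenarioResult(np.array(rec["t"]), np.array(rec["centre"]),
                          np.array(rec["csi"]), np.array(rec["area"]),
                          cells, mech, sig, extras={"min_gap": float(min_gap)})


# ----------------------------------------------------------------------
# scenario 4: microchannel transmigration
# ----------------------------------------------------------------------

def contact_pressure(force_set: PointForceSet, contact_length: float) -> float:
    """Contact pressure in kPa: total force magnitude over the contact area
    (contact length × 1 μm out-of-plane depth)."""
    if contact_length <= 0 or len(force_set.forces) == 0:
        return 0.0
    total = float(np.linalg.norm(force_set.forces, axis=1).sum())
    return total / contact_length * KG_UM_MIN2_TO_PA / 1000.0


def wall_pressure(force_set: PointForceSet) -> float:
    """Cell pressure against the channel walls (kPa): the largest per-patch
    contact pressure, each patch normalised by its own contact length."""
    patches = getattr(force_set, "patches", None)
    if not patches:
        return contact_pressure(force_set, float(force_set.lengths.sum()))
    best = 0.0
    for p in patches:
        sel = p["indices"]
        total = float(np.linalg.norm(force_set.forces[sel], axis=1).sum())
        best = max(best, total / p["lm"] * KG_UM_MIN2_TO_PA / 1000.0)
    return best


def _parse_mechanism(mechanism: str, rng: np.random.Generator | None):
    """Mechanism → (uses_chemotaxis, active speed in μm/min or None)."""
    if mechanism == "chemotaxis":
        return True, None
    if mechanism.startswith("fixed-"):
        return False, float(mechanism.split("-")[1])
    if mechanism.startswith("uniform-"):
        _, a, b = mechanism.split("-")
        if rng is None:
            raise ValueError("uniform-velocity mechanism needs an rng")
        return False, float(rng.uniform(float(a), float(b)))
    raise ValueError(f"unknown mechanism {mechanism!r}")


def run_microtube_scenario(cfg: ScenarioConfig | None = None,
                           mechanism: str | None = None,
                           seed: int | None = None,
                           callback=None) -> MicrotubeResult:
    """One cancer cell transits the LC–SNB10–LC microchannel.

    The cell starts a short run-up before the mouth, is driven by chemotaxis
    toward a source behind the channel exit (or by a prescribed horizontal
    velocity), presses Hertzian repulsion onto the walls and feels friction
    proportional to it.  The run ends when the rear node leaves the channel
    or at the timeout (10× the ideal transit time at the reference speed).
    """
    cfg = (cfg or default_config("microtube")).validate()
    mechanism = mechanism or cfg.mechanism
    seed = cfg.seed if seed is None else seed
    rng_mech, rng_rw = spawn_rngs(seed, 2, "microtube")
    use_chem, v_active = _parse_mechanism(mechanism, rng_mech)

    cx, cy = cfg.domain_x / 2.0, cfg.domain_y / 2.0
    tube = TubeGeometry(
        entrance_x=cx - cfg.snb_length / 2.0 - cfg.lc_length,
        axis_y=cy, lc_width=cfg.lc_width, snb_width=cfg.snb_width,
        snb_length=cfg.snb_length, lc_length=cfg.lc_length)
    start_x = tube.x0 - cfg.R - cfg.runup
    # the attractant sits well past the exit so the cell clears the channel
    # before it reaches (and would engulf) the source
    source = np.array([tube.x3 + 4.0 * cfg.R, cy])
    xpad, ypad = 2.0 * cfg.R + cfg.runup + 6.0, cfg.lc_width / 2.0 + 6.0
    domain = RectangleDomain(
        cfg.domain_x, cfg.domain_y,
        mandatory_x=(tube.x0, tube.x1, tube.x2, tube.x3),
        mandatory_y=(cy - tube.lc_halfwidth, cy - tube.snb_halfwidth,
                     cy + tube.snb_halfwidth, cy + tube.lc_halfwidth),
        refine_x=((tube.x0 - xpad, tube.x3 + xpad, cfg.mesh_h_fine),),
        refine_y=((cy - ypad, cy + ypad, cfg.mesh_h_fine),))
    mesh = Mesh.rectangle(domain, cfg.mesh_h)
    fem = FemSystem(mesh, cfg.dt)
    clamp = _DomainClamp(domain)
    mech = _mechanics(cfg, mesh)
    sig = None
    if use_chem:
        # the chip material flanking the channel is impermeable: the signal
        # reaches the cell only through the channel, so its gradient funnels
        # into the openings (this is what drives the squeeze through the SNB)
        centroids = mesh.vertices[mesh.triangles].mean(axis=1)
        dfac = np.where(tube.solid_mask(centroids), 1e-6, 1.0)
        sig = SignalField(fem, D=cfg.D, k=cfg.k, source=source,
                          kappa=cfg.kappa_s, diffusivity_factor=dfac)
        if cfg.signal_warmup:
            sig.set_steady_state()
    mob = _mobility(cfg)
    template = ShapeTemplate(kind="circle", R=cfg.R)
    cell = CellState.from_template(template, (start_x, cy), N=cfg.N,
                                   E_c=cfg.E_c, E_c_elastic=cfg.E_c_elastic,
                                   nu_c=cfg.nu_c, P=0.0)

    v_ref = v_active if v_active is not None else cfg.beta0 * cfg.mu_m
    path = (tube.x3 + cfg.R) - start_x
    timeout = min(cfg.t_end, 10.0 * path / v_ref)
    nsteps = int(round(timeout / cfg.dt))

    from .mechanics import step_mechanics
    rec = {k: [] for k in ("t", "centre", "speed", "csi", "area",
                           "pressure", "front", "rear", "in_lc")}
    completed = False
    prev_centre = cell.centre.copy()
    for step in range(nsteps):
        t = (step + 1) * cfg.dt
        ws = microtube_wall_forces(cell, tube)
        fmag = np.zeros(cfg.N)
        if ws.indices is not None and len(ws.indices):
            fmag[ws.indices] = np.linalg.norm(ws.forces, axis=1)
        if len(ws.points):
            step_mechanics(mech, ws.points, ws.forces, cfg.dt)
        else:
            step_mechanics(mech, None, None, cfg.dt)
        grad = None
        active = None
        if use_chem:
            step_signal(sig, mech.v, cfg.dt, advection="explicit")
            grad = signal_gradient_at(sig, cell.nodes)
        else:
            active = np.array([v_active, 0.0])
        sv = substrate_velocity_at(mech, cell.nodes)
        step_nodes(cell, mob, grad_c=grad, substrate_v=sv,
                   active_velocity=active, obstacles=(tube,),
                   contact_force_mag=fmag,
                   rng=rng_rw if cfg.sigma_rw > 0 else None, domain=clamp)
        centre = cell.centre
        rec["t"].append(t)
        rec["centre"].append(centre.copy())
        rec["speed"].append(float(np.linalg.norm(centre - prev_centre)
                                  / cfg.dt))
        prev_centre = centre.copy()
        rec["csi"].append(cell.csi())
        rec["area"].append(cell.area())
        rec["pressure"].append(wall_pressure(ws))
        fx, rx = cell.nodes[:, 0].max(), cell.nodes[:, 0].min()
        rec["front"].append(fx)
        rec["rear"].append(rx)
        dy = np.abs(cell.nodes[:, 1] - cy)
        in_lc1 = rx >= tube.x0 and fx <= tube.x1
        in_lc2 = rx >= tube.x2 and fx <= tube.x3
        rec["in_lc"].append(bool((in_lc1 or in_lc2)
                                 and np.all(dy <= tube.lc_halfwidth + 1e-6)))
        if callback is not None:
            callback(step, t, cell, locals())
        if rx >= tube.x3:
            completed = True
            break
    times = np.array(rec["t"])
    timeline = detect_phases(times, np.array(rec["front"]),
                             np.array(rec["rear"]),
                             np.array(rec["centre"])[:, 0], tube)
    if not completed:
        logger.info("microtube transit incomplete after %.1f min", timeout)
    return MicrotubeResult(times, np.array(rec["centre"]),
                           np.array(rec["speed"]), np.array(rec["csi"]),
                           np.array(rec["area"]), np.array(rec["pressure"]),
                           np.array(rec["front"]), np.array(rec["rear"]),
                           np.array(rec["in_lc"], dtype=bool), completed,
                           timeline, tube, mechanism, cell)


def detect_phases(times: np.ndarray, front_x: np.ndarray, rear_x: np.ndarray,
                  centre_x: np.ndarray, tube: TubeGeometry,
                  mono_tol: float = 0.0) -> PhaseTimeline | None:
    """Partition a transit into the four phases.

    Events: entry (front node crosses the channel mouth), front reaches the
    SNB entrance, rear enters the SNB, rear leaves the SNB, rear leaves the
    channel.  Phase 3 is flagged when the centre's axial coordinate moves
    backward (by more than ``mono_tol``) while the cell overlaps the SNB; its
    interval runs from the first such event until the rear node leaves the
    SNB.  Returns None when the cell never entered the channel.
    """

    def first_time(mask) -> float | None:
        idx = np.flatnonzero(mask)
        return float(times[idx[0]]) if len(idx) else None

    t_entry = first_time(front_x >= tube.x0)
    t_f1 = first_time(front_x >= tube.x1)
    t_r1 = first_time(rear_x >= tube.x1)
    t_r2 = first_time(rear_x >= tube.x2)
    t_exit = first_time(rear_x >= tube.x3)
    if t_entry is None:
        return None
    overlap_snb = (front_x >= tube.x1) & (rear_x <= tube.x2)
    dc = np.diff(centre_x, prepend=centre_x[0])
    backward = (dc < -mono_tol) & overlap_snb
    occurred = bool(backward.any())
    t_back = first_time(backward)
    intervals = {}
    complete = t_exit is not None
    end = float(times[-1])
    intervals[1] = (t_entry, t_f1 if t_f1 is not None else end)
    if t_f1 is not None:
        t2_end = t_r2 if t_r2 is not None else end
        if occurred:
            t3_start = max(t_f1, min(t_back, t_r1 if t_r1 is not None else end))
            intervals[2] = (t_f1, t3_start)
            intervals[3] = (t3_start, t2_end)
        else:
            intervals[2] = (t_f1, t2_end)
        if t_r2 is not None:
            intervals[4] = (t_r2, t_exit if t_exit is not None else end)
    return PhaseTimeline(intervals, occurred, complete).validate()


# ----------------------------------------------------------------------
# Monte Carlo study
# ----------------------------------------------------------------------

def mc_error(p_hat: float, n: int) -> float:
    """Binomial Monte Carlo standard error √(p̂(1−p̂)/n)."""
    if n < 1:
        raise ValueError("need at least one sample")
    return math.sqrt(p_hat * (1.0 - p_hat) / n)


def phase3_probability_from_error(n: int, err: float) -> tuple[float, float]:
    """Invert the MC error formula: the two probabilities consistent with a
    printed sample count and error.  Raises if err²·n > 1/4 (no valid p)."""
    disc = 1.0 - 4.0 * err ** 2 * n
    if disc < 0:
        raise ValueError("error too large for any valid probability")
    root = math.sqrt(disc)
    return (0.5 * (1.0 - root), 0.5 * (1.0 + root))


def run_monte_carlo(cfg: ScenarioConfig | None = None,
                    mechanism: str = "chemotaxis", n: int = 50,
                    seed: int = 0) -> MCResult:
    """Monte Carlo transmigration study.

    Per sample, the wall friction μ_f ~ U(0.03, 0.06) and mobility reduction
    μ_m ~ U(0.6, 1) are drawn (plus the sample's active speed for the
    uniform-velocity mechanisms) and a full seeded transit is run.  The
    aggregate is the phase-3 occurrence probability over completed transits
    with its binomial standard error; incomplete transits are excluded from
    the duration statistics but counted.
    """
    if n < 1:
        raise ValueError("need at least one Monte Carlo sample")
    cfg = (cfg or default_config("microtube")).validate()
    param_rng, = spawn_rngs(seed, 1, f"mc-params-{mechanism}")
    sample_seeds = np.random.SeedSequence([seed, 777]).generate_state(n) // 2
    flags, samples = [], []
    durations = {1: [], 2: [], 3: [], 4: []}
    n_completed = 0
    for i in range(n):
        mu_f = float(param_rng.uniform(0.03, 0.06))
        mu_m = float(param_rng.uniform(0.6, 1.0))
        cfg_i = replace(cfg, mu_f=mu_f, mu_m=mu_m)
        res = run_microtube_scenario(cfg_i, mechanism,
                                     seed=int(sample_seeds[i]))
        samples.append({"mu_f": mu_f, "mu_m": mu_m,
                        "completed": res.completed,
                        "phase3": bool(res.timeline and
                                       res.timeline.phase3_occurred)})
        if res.completed:
            n_completed += 1
            flags.append(res.timeline.phase3_occurred)
            for p, d in res.timeline.durations.items():
                durations[p].append(d)
    if n_completed == 0:
        raise RuntimeError("all Monte Carlo samples incomplete")
    p_hat = float(np.mean(flags))
    return MCResult(mechanism, n, n_completed, p_hat,
                    mc_error(p_hat, n_completed), durations, samples)
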