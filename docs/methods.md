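# Model and methods

`morphocell` simulates single cells as agents — closed polygons of membrane
nodes — migrating over (and mechanically coupled to) a two-dimensional
morphoelastic extracellular matrix (ECM). This note records the governing
equations as implemented, the numerical scheme, every place where the design
was genuinely open, and what the package's synthetic scenarios do and do not
demonstrate.

Units are kg–μm–min throughout; 1 kg/(μm·min²) = 277.78 Pa.

## Governing model

**Signal transport.** A generic chemoattractant (oxygen, growth factor,
TGF-beta) is emitted by a point source at x_s with rate k and obeys

    ∂c/∂t + ∇·(v c) − ∇·(D ∇c) = k δ(x − x_s),   c(x, 0) = 0,

with a Robin condition ∂c/∂n + κ_s c = 0 on the outer boundary
(no-flux as κ_s → 0, absorbing as κ_s → ∞). The advecting velocity v is the
substrate velocity — cellular forces deform the ECM and passively convect
the dissolved signal.

**Substrate mechanics (morphoelasticity).** Velocity v and effective
Eulerian strain ε obey

    ρ [Dv/Dt + v (∇·v)] − ∇·σ = f,
    Dε/Dt + ε skw(L) − skw(L) ε + [tr(ε) − 1] sym(L) = −α ε,   L = ∇v,

with v = 0 on the outer boundary and the Kelvin–Voigt stress

    σ = E/(1+ν_s) { ε + tr(ε) ν_s/(1−2ν_s) I } + μ1 sym(L) + μ2 tr(sym L) I.

α (default 0.1 min⁻¹) is the plasticity rate: with α = 0 all deformation is
recovered once forces vanish; with α > 0 strain relaxes plastically while
the displacement it produced remains — permanent tissue deformation. The
displacement is accumulated as u ≈ ∫ v dt.

**Cellular forces** enter f as Dirac point forces:

* *Traction*: each membrane segment pulls the ECM toward the cell centre
  with magnitude P·ΔΓ_j (P per unit length, constant over the membrane).
* *Cell–cell repulsion* (linearised 2-D Hertz): total force
  Q̃ = (π/4) d E\* with penetration depth d and equivalent modulus
  1/E\* = (1−ν₁²)/E₁ + (1−ν₂²)/E₂, spread uniformly over the contacting
  membrane length ‖l_m‖; contacting segments repel, free segments keep
  pulling.
* *Channel-wall repulsion*: per contacting node, d = R − ‖x_j − x_c‖ (the
  compression of the equilibrium radius), repelling only — no pulling
  inside the channel. The wall is rigid (E₂ → ∞) by default.

**Cell shape dynamics.** Each node performs an Euler–Maruyama step of

    dx_j = β ∇c/(‖∇c‖+γ) dt + E_c (x_c + B(φ̃) x̂_j − x_j) dt + v dt
           + σ_rw dW,

i.e. chemotaxis up the normalised gradient with deformation-dependent
weight β = β₀ μ_m (CSI/CSI₀ + A/A₀)/2 (CSI = 4πA/l², evaluated once per
cell per step), spring recoil toward the orientation-corrected equilibrium
offsets, passive convection, and a random walk. The orientation φ̃ is the
closed-form Procrustes angle atan2(Σ x̂×x, Σ x̂·x) minimising
Σ‖B(φ)x̂_j − x_j‖². Obstacles (walls, other cells) remove the wall-normal
displacement component, attenuate the tangential one by 1 − μ_f‖f‖
(clamped at 0: friction stops but never reverses sliding, logged when the
clamp triggers), and positions are finally clamped to the feasible region.
Engulfment: the source switches off permanently once a node comes within
one fine-mesh length of it.

Equilibrium shape templates are circles, ellipses (a_e = 6.25, b_e = 4 μm)
and hypocycloids with base/rolling radius ratio 4 — the four-cusped
astroid, standing in for the dendritic myofibroblast. The two phenotypes
have equal area (π a_e b_e = (3/8) π a_h²). Differentiation morphs the
template with progress ω(t) = 1 − exp(−λ_ω (t − t_ω)) by linear parameter
interpolation R_a = a_h ω + a_e (1−ω) (and likewise R_b).

## Numerics

Everything is discretised with linear Lagrange (P1) triangles and backward
Euler. Meshes are tensor-product triangulations of rectangles: two monotone
coordinate arrays (with mandatory lines, e.g. channel walls, inserted
exactly, and per-box local refinement) define quads split into two
triangles. A constrained Delaunay mesher was considered and rejected: the
structured mesh satisfies every geometric requirement here (wall lines
resolved exactly, positive orientation, valid point location) with far less
machinery. Dirac loads are discretised by evaluating the P1 basis at the
load point, which conserves the applied force exactly; no mollification.

The signal step solves (M + Δt[A(v) + D K + D κ_s R]) c⁺ = M c + Δt k φ(x_s).
The scenario drivers lag the advection term (IMEX) so one factorisation of
the diffusion–Robin operator is reused at every step; substrate velocities
(≲10⁻² μm/min) are 4–6 orders below the diffusive scale, and the IMEX and
fully implicit paths agree to ~10⁻⁵ relative in tests.

The mechanics step stores ε per element (P0) and v per vertex. A naive
fixed-point iteration between the v-solve and the ε-update diverges at the
table parameters (loop gain ≈ Δt·E_eff/μ1 ≈ 5), so the elastic stress is
treated implicitly: the velocity system is (A_visc + Δt A_elas) v =
f + G(ε_k) + Δt A_elas v_k inside a Picard loop (tolerance 10⁻⁸, max 50;
typically 2–4 iterations), where A_elas is the linear-elasticity operator
of σ_elas and G its weak divergence at the current strain iterate. The
strain update is a pointwise implicit 3×3 solve per element (co-rotation,
stretching production and −αε implicit; strain advection lagged). The
default solver is quasi-static — no tissue density is part of the parameter
set and the viscous relaxation time μ1/E ≈ 0.34 min is far below cell time
scales; an inertial mode (ρ-terms explicitly lagged) exists and matches the
quasi-static solution to < 1% as ρ → 0.

The Wiener increment is one 2-D draw per **cell** per step, not per node.
Independent per-node noise at σ_rw = 1 roughens the 40-node membrane by
≈5% of perimeter, which alone depresses the shape index by ≈0.1 — far below
the CSI ≈ 0.95 observed for a cell cruising the large channel. A whole-cell
random walk reproduces the published behaviour and is the natural reading
of a cell-scale random walk.

## The microchannel scenario

The channel is a straight LC–SNB–LC run (widths 15 / 3.3 μm, SNB length
10 μm, LC segments 50 μm — the LC length is not fixed by the source
experiment and is configurable), embedded in a 400×400 μm domain with a
tapered inlet (half-width ramping 10.8 → 7.5 μm over 12 μm) that models
the funnel from the loading reservoir; an abrupt square shoulder would
impose single-node contact-pressure spikes at first touch that reflect the
discretisation, not the device.

Two modelling choices here deserve emphasis:

* **Walls are impermeable to the signal.** The chip material flanking the
  channel carries a relative diffusivity of 10⁻⁶, so the attractant reaches
  the cell only through the channel and its gradient converges into the
  openings. This is both what a PDMS device does and what makes
  transmigration possible in the model: with walls transparent to
  diffusion the gradient has no funnelling component, the membrane springs
  (E_c Δx vs. the ≲0.3 μm/min lateral chemotactic drift) win, and the cell
  jams at the barrier indefinitely — verified numerically.
* **Walls compress, they do not block.** Node projection and clamping act
  against the horizontal wall at the node's axial position (the local
  half-width); there is no axial blocking at the narrowing shoulders. With
  the printed parameters the membrane can deviate at most β₀/E_c = 2 μm
  from its equilibrium shape, so a cell blocked axially at the SNB shoulder
  could never squeeze 7.35 μm — walls that compress the passing cell are
  the only reading under which the published transits are reproducible, and
  they are what generates the several-μm penetration depths behind the
  published pressure magnitudes.

Wall contact pressure is reported per contact patch (one patch per wall
surface and channel segment, each normalised by its own contact length, as
a cell–cell contact is), converted to kPa via a 1 μm out-of-plane depth.
Peak speed and the location of the transit extrema are measured on a
centred 1-minute window: the per-step speed of an Euler–Maruyama path has a
σ_rw/√Δt noise floor (≈3.8 μm/min at Δt = 0.07) that grows without bound
as Δt → 0 and is not a physical observable; one minute is the scale of
experimental frame intervals.

Phases of a transit are operationalised from the front (max-x) and rear
(min-x) node crossings: phase 1 from channel entry until the front reaches
the SNB; phase 2 the squeeze, until the rear leaves the SNB; phase 3, if
the centre's axial motion is ever non-monotone while the cell overlaps the
SNB, runs from the first backward step to the rear's SNB exit (phase 2 is
truncated accordingly); phase 4 until the rear leaves the channel. The
intervals partition the transit. The Monte Carlo study draws
μ_f ~ U(0.03, 0.06) and μ_m ~ U(0.6, 1) per sample, runs a full seeded
transit, and aggregates the phase-3 occurrence probability with its
binomial standard error √(p̂(1−p̂)/n); incomplete transits (timeout at
min(t_end, 10× the ideal transit time)) are excluded from duration
statistics but counted.

## Parameters

Shared defaults (all scenarios): E_s = 100 kg/(μm·min²) (≈27.8 kPa),
E_c = 5, μ_f = 0.03, ν_s = 0.49, ν_c = 0.32, k = 2.5 kg/(μm³·min),
κ_s = 100, μ1 = 33.783, μ2 = 22.523, β₀ = 10 min⁻¹, N = 40 nodes,
μ_m = 1, σ_rw = 1, α = 0.1. Per scenario: chemotaxis/collision R = 5 μm,
Δt = 0.1 min, D = 200 μm²/min, domain 120×120 μm with a 40×40 central
subdomain holding the initial cells; differentiation D = 233.2 with the
ellipse/astroid template above and λ_ω = 10 min⁻¹; microchannel R = 9 μm,
Δt = 0.07 min, D = 874.5, domain 400×400.

Values the sources leave open, fixed here once:

* **P = 10 kg/min²** traction per unit membrane length. Over a ~30 μm
  perimeter this is ≈300 kg·μm/min² ≈ 100 nN total — the measured scale of
  cellular traction on soft gels. E_c appears both as a spring *rate*
  (min⁻¹) in the node law and as an elastic modulus in the Hertz contact;
  both default to the same numeral 5 and are independently configurable.
* **γ = 10⁻⁶ kg/μm⁴** gradient regulariser ("a small positive constant"):
  small against the 10⁻⁵–10⁻³ gradients occurring near active sources, so
  chemotactic drive saturates at β where there is signal and vanishes
  smoothly where there is none.
* **Differentiation threshold c_diff = 10⁻³ kg/μm³** (reached a few cell
  radii from the source) and **myofibroblast traction factor 2** (applied
  smoothly with ω); neither is quantified in the sources.
* **Morphing shapes** blend the elliptic and hypocycloid node sets
  pointwise and rescale to the ω-interpolated area: the raw blend inflates
  the mid-morph area by ≈13%, which would break the equal-volume property
  the phenotypes are constructed to have.
* Hypocycloid nodes are sampled uniformly in the curve parameter (not arc
  length), so cusp regions carry ordinary node density.
* The traction in the chemotaxis/collision scenarios stays on for the whole
  run: under sustained load an α > 0 substrate keeps creeping, which is
  what leaves the persistent cell-area deficit, while the α = 0 control
  equilibrates and recovers its area.

## Problem sizes and determinism

Default meshes resolve the source/channel neighbourhood at 2.5–3 μm and
the far field at 6–25 μm (roughly 1.5–3·10³ vertices); the Monte Carlo
study uses a coarser 4.5/40 μm mesh and a 6 μm run-up, and the convergence
study runs four nested uniform refinements of the unit square (8–64
elements per side). These sizes are the package's desk-scale defaults; all
are configurable. Every random draw descends from one integer seed through
named SeedSequence streams, so identical configuration + seed reproduces
runs bit-for-bit; σ_rw = 0 gives fully deterministic dynamics.

## What the synthetic scenarios do and do not show

The scenarios are synthetic reconstructions of published experiment-like
settings: they demonstrate that the coupled model produces the qualitative
phenomenology — nose formation and recovery, permanent plastic area loss,
mutual flattening without interpenetration, phase-structured transmigration
with SNB-localised extrema, mechanism-robust phase-3 statistics. They do
not calibrate against real trajectories: real cells have heterogeneous
traction, volume regulation, nucleus mechanics (explicitly outside the
model: there is no intracellular Poisson effect, so cell length under
compression is not meaningful here) and three-dimensional contact, none of
which are represented. Quantities sensitive to those ingredients — absolute
phase durations, absolute pressures — should be read as order-of-magnitude.

## Known limitations

* Node count N is fixed; membranes can locally self-intersect under
  extreme squeezing (the shoelace area is then algebraic and a warning is
  raised). Non-penetration between cells is enforced at node resolution;
  membrane edges may interdigitate below the ~1 μm segment scale.
* The advection of strain and the inertial convection terms are lagged
  explicitly; both are negligible at the default parameter scale but the
  scheme is first order in Δt regardless.
* Robin κ_s is used as printed, in inverse-μm mesh units, although
  dimensionally it is an inverse length.
* The fixed Eulerian mesh never moves; deformed geometry for visualisation
  is obtained by adding the accumulated displacement to vertex positions.
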