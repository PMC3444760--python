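# Methods

## Model

`ctcflow` simulates a single deformable circulating tumor cell (CTC)
carried by blood plasma through a straight microvessel segment, using the
immersed boundary (IB) method in two dimensions.

**Fluid.** Plasma is an incompressible Newtonian fluid, density
ρ = 1 g/cm³ and viscosity μ = 0.012 g/(cm·s) (≈1.2 cP), governed by the
Navier–Stokes equations with an external body-force density f:

    ρ (∂u/∂t + u·∇u) = −∇p + μ ∇²u + f,      ∇·u = 0.

For the baseline channel (height H = 30 μm, peak speed u_max = 0.6 mm/s)
the Reynolds number is ρ·u_max·H/μ ≈ 0.015: the flow is creeping and
laminar, but the solver keeps the full equations.

**Structures.** All solid structures are networks of linear Hookean
springs acting on Lagrangian material points X(l,t).  A spring with
stiffness S (dyn/cm) and rest length L exerts on its endpoint

    F = S (|X* − X| − L) (X* − X)/|X* − X|,

where X* is the partner point — a neighboring point of the same structure
(elastic), a fixed anchor (wall tether), or an adhesion partner.  The
structures are:

- **Cortex**: an annular band between radii 3 and 5 μm (10 μm cell, 2 μm
  band), discretized as two concentric rings with circumferential
  springs, radial rungs, and one diagonal per rung (a triangulated band).
- **Nuclear envelope**: a single 4 μm-diameter ring with circumferential
  springs and chordal braces every 5th point.  The nucleus interior and
  the cytoplasm between nucleus and cortex are plain fluid; no springs
  bridge the gap.
- **Endothelial wall**: two straight rows of points 30 μm apart, each
  point tethered to its initial position (zero rest length) and linked to
  its row neighbors.  The endothelium itself is passive: flow does not
  remodel it.
- **Adhesions**: transient springs between outer-cortex (membrane)
  points and wall points (next section).

All spring stiffnesses are expressed as multiples of the baseline
S₀ = 50 dyn/cm; the experiments vary the cortex multiplier κ_C and
nucleus multiplier κ_N over 1–6.

**Coupling.** Forces are spread to the fluid grid and velocities
interpolated back through the Peskin 4-point regularized delta (tensor
product of φ(r) = ⅛(3 − 2|r| + √(1+4|r|−4r²)) on |r| ≤ 1, the matching
tail on 1 ≤ |r| ≤ 2).  Spread and interpolation use the same kernel and
are exact adjoints.  Eq-form: f(x) = Σ_l F(l) δ_h(x−X(l)) Δs(l), with
F(l) the boundary **force density** (per unit arclength) and Δs the
per-point quadrature weight frozen at construction.  The per-spring
forces are converted to densities by dividing by the local Δs — the
standard discrete-IB point-force formulation.  This choice matters: with
per-spring constants, the effective cortical tension of a spring ring
scales as S₀·Δs, so the physical deformation regime is set jointly by S₀
and the boundary discretization (see Calibration).

**Adhesion.** Receptor–ligand binding is taken as always effective at
short range (no stochastic kinetics): an unlinked membrane point within
the capture radius r_on of a wall point binds to its nearest wall point
(lowest-id tie-break), creating a spring with rest length L_A; a link
stretched beyond λ_break·L_A breaks.  Both rules are deterministic, so
entire simulations are bit-reproducible.  For crawling, cortex springs
with an endpoint within r_soft of any adhered membrane point have their
stiffness multiplied by m_soft; the instant the local adhesion is gone
the base stiffness is restored.

## Numerics

- Doubly periodic collocated grid, default 128×64 nodes over a
  75 × 37.5 μm box.  The channel walls sit at y = 3.75 and 33.75 μm, so a
  7.5 μm dead band screens the cell from its periodic image in y.  The
  flow is driven by a uniform streamwise body force g = 8μu_max/H²
  (Poiseuille closed form; 640 dyn/cm³ at baseline) applied between the
  walls, with proportional weights for partially covered cells.
- Time stepping: first-order splitting — explicit skew-symmetric
  advection and forcing, implicit (backward-Euler) viscosity, and exact
  pressure projection, both diagonal in Fourier space using the symbols
  of the centered-difference operators.  The centered-difference
  divergence after projection is zero to machine round-off by
  construction.
- Boundary point spacing: walls h/2; cell h/8 (see Calibration).  The
  4-point kernel spans 4h, so both satisfy the no-leakage rule; cell area
  drift over full experiments is below 1%.
- Default dt = 1e-5 s at the default grid.  The binding stability
  constraint is the explicit spring–fluid coupling: empirically, wall
  tethers at S_w = 500 dyn/cm are stable at dt = 1e-5 while 1000 dyn/cm
  is not; the bound scales linearly with dt and with the point spacing
  (force density ∝ S/Δs).  `steady_channel_flow` therefore scales its
  default dt with h.  A spring-CFL formula of the form
  dt ≲ √(ρh³/S) is far too pessimistic for this semi-implicit scheme and
  is not used; instead `run` detects blow-ups (non-finite fields or
  |u| > 50·u_max) and restarts with dt halved, up to 3 times.
- The empty-channel solver seeds the velocity with the analytic parabola.
  A cold start excites a very slowly damped sloshing mode of the
  fluid–tether system (tens of thousands of steps to 1e-8); from the
  parabola the same fixed point is reached in a few hundred steps.
- Degenerate springs (coincident endpoints with L > 0) exert zero force
  and log a diagnostic; the event indicates too large a time step.

**Accuracy of the channel flow.** The immersed tethered wall enforces
no-slip at the point rows with an O(h) effective-boundary offset, giving
centerline speeds of 0.582, 0.591, and 0.596 mm/s at 128×64, 256×128,
and 512×256 for the 0.6 mm/s target (first-order convergence).  The
steady-flow verification therefore runs at 256×128, inside the 2% band;
cell experiments use 128×64, where the stiffness calibration below holds.

## Parameters

| parameter | symbol | default | units | origin |
|---|---|---|---|---|
| vessel width × length | H, L | 30 × 75 | μm | model geometry |
| peak plasma speed | u_max | 0.6 | mm/s | model geometry |
| viscosity, density | μ, ρ | 0.012, 1.0 | CGS | plasma constants |
| cell / nucleus / band | — | 10 / 4 / 2 | μm | model geometry |
| baseline stiffness | S₀ | 50 | dyn/cm | model baseline |
| stiffness multipliers | κ_C, κ_N | 1–6 | — | experiment axes |
| wall tether multiplier | κ_W | 10 | — | calibrated (rigidity + stability) |
| adhesion stiffness | S_A | 5 | dyn/cm | calibrated (see below) |
| capture radius / rest | r_on, L_A | 1.0 / 0.5 | μm | binding geometry |
| break strain | λ_break | 2.0 | — | break length 1 μm |
| softening factor/radius | m_soft, r_soft | 0.15 / 3 | μm | calibrated |
| snapshot unit | t | 0.0167 | s | one diameter advected |

## Calibration

Three constants are genuinely free and were fixed once, at the default
resolution, by requiring the documented regimes; they are recorded here
and never tuned per run.

1. **Cell point spacing h/8.** Because spring constants are per spring,
   the cortex tension scales with the point spacing.  h/8 places the
   sixfold sweep across the observable regime at 128×64: a κ_C = 1
   near-wall cell leaves the channel at circularity ≈ 0.75 (aspect ratio
   ≈ 2), κ_C = 3 at ≈ 0.93, κ_C = 6 at ≈ 0.975, with circularity
   monotone in κ_N at fixed κ_C ≥ 3.  Finer spacing (h/16) deepens the
   contrast but destabilizes the 6× cases at affordable dt.
2. **Wall tethers κ_W = 10** (S_w = 500 dyn/cm): the stiffest stable
   value at dt = 1e-5; maximum wall displacement in any experiment stays
   near 1e-3·h, far inside the 0.05·h rigidity budget.
3. **Adhesion S_A = 5 dyn/cm**, with m_soft = 0.15, r_soft = 3 μm: at
   this strength a near-wall cell with κ_C = 3, κ_N = 6 attaches,
   migrates about one diameter, and loses its last adhesion by the 4t
   horizon, while the same configuration with adhesion-triggered cortex
   softening keeps 20–30 active links through the full 10t crawling
   horizon and advances ≈ 16 μm.  Stronger bonds (S_A ≳ 8) pin every
   case to the wall; weaker ones (S_A ≲ 3) release every case within a
   unit.

## Locomotion-mode classifier

`classify_mode` applies deterministic threshold rules to a trajectory
window, in the order crawling → rolling → anchoring → floating
(first match; no match ⇒ floating, low confidence):

- **crawling** — remodeling active, adhesion present ≥ 90% of the
  window, turnover ≥ 2 events per unit, net advance ≥ half a diameter;
- **rolling** — adhesion present ≥ 60% of the window *and* ≥ 75% of its
  tail (the last quarter), turnover ≥ 2 per unit, stain rotation
  ≥ 1 rad, net advance ≥ half a diameter;
- **anchoring** — mean link lifetime ≥ half the horizon, adhesion ≥ 90%,
  centroid speed < 10% of the local undisturbed flow speed;
- **floating** — tail ≥ 90% adhesion-free and tail speed ≥ 50% of the
  local flow speed.

The rotation readout is the unwrapped circular-mean polar angle of a
stained cortex arc about the instantaneous centroid.  The 1 rad
threshold is calibrated against the free-rotation bound in the local
shear, ω = γ̇/2 ≈ 24 rad/s, i.e. ≈ 1.6 rad over a 4-unit window: no
trajectory at this flow can rotate by π in that window, so the threshold
is set at ~60% of the physical bound.

## Preset experiments and problem sizes

- `experiment_sweep`: κ_C × κ_N × {center, near-wall}, adhesion off,
  stop when the centroid passes 2/3 of the vessel length.  Default is
  the full 6×6×2 grid (72 runs, batch-scale); the verification suite
  runs a 5-run subset covering the trend claims.
- `experiment_rolling`: cases A (3,3), B (6,3), C (3,6), D (6,6) as
  (κ_C, κ_N); adhesion on, remodeling off, near-wall start, 4t horizon.
- `experiment_crawling`: case-C stiffness with remodeling, 10t horizon
  (2.5× the rolling horizon), plus the remodeling-off control.

All preset runs use the default 128×64 grid and dt = 1e-5 s; a rolling
case takes ≈ 7×10³ steps, the crawling run ≈ 1.7×10⁴.

## Observed regime behavior and a known limitation

With this adhesion model, contact persistence increases monotonically
with cortex *softness*: a compliant cortex conforms to the wall, which
keeps link lengths short (links never reach the break length) and keeps
membrane points inside the capture radius, whereas a stiff round cell is
torqued nose-up by its rear-biased links, its front capture starves, and
it detaches.  Consequently, in the preset rolling experiment the
stiff-cortex cases B and D attach, rotate ≈ 0.8 rad while attached
(about half of rolling without slip), and then detach, ending the 4t
window as floating — they do not sustain rolling.  No parameter region
was found (adhesion stiffness 2–50 dyn/cm, break strain 1.5–4, capture
radius 1–1.5 μm, cell spacing h/4–h/16) in which stiff cells out-persist
soft ones.  A mechanism favoring stiff-cell rolling — e.g.
membrane–wall contact repulsion limiting conformal adhesion, or
force-loaded stochastic bond kinetics — is outside the present model
(bond kinetics deliberately so).  The sweep, detachment, and crawling
regimes are unaffected.

Other limitations: two dimensions (no out-of-plane curvature or
rotation); a single cell (no red cells, leukocytes, platelets, or
emboli); linear springs (no strain stiffening, bending rigidity, or
viscoelasticity); rigid non-responsive endothelium; deterministic
adhesion without receptor–ligand kinetics; per-spring stiffness
constants that tie the elastic scale to the boundary discretization, so
stiffness multipliers are comparable only at a fixed resolution.

## What the simulations do and do not show

The package constructs all of its inputs from the geometric and material
constants above; there are no external data.  Passing its verification
suite shows that the numerical machinery (projection, coupling,
conservation, calibrated channel flow) is correct to stated tolerances
and that the calibrated model reproduces the documented deformation,
detachment, and remodeling-rescue regimes at the default resolution.  It
does not validate the model against measured CTC mechanics, and the
stiffness values should be read as relative, not absolute, cell moduli.
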