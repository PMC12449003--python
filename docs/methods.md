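# Methods

This note documents the models, numerical choices and open design decisions
behind `cortexvasc`, in the spirit of a methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic test
conditions do and do not establish about real data.

## 1. The perfusion shell

The pial arterial bed occupies a thin layer hugging the cortical surface.
We model its admissible volume as the normal extrusion of a triangulated
surface Γ: the set of points x = x_s + ξ·n(x_s) with ξ ∈ [−t_in, t_out].
Defaults: total thickness 0.2 cm, 75% outward (t_out = 0.15 cm, t_in =
0.05 cm).  Vertex normals are area-weighted averages of incident face
normals; degenerate faces produced by the extrusion are dropped and
inverted inner faces (offset exceeding the local radius of curvature) are
counted and reported.

**Containment.**  Membership is decided by the offset-distance rule: a
point is inside iff its distance to the base surface does not exceed the
admissible offset on its side of the surface, with boundary points counted
as inside (growth needs a closed admissible set).  This matches the
extrusion definition directly and is fast (KD-tree-accelerated exact
closest-point-on-triangle queries).  The independent cross-check in the
test-suite is even-odd ray casting against the extruded boundary mesh; the
two representations agree exactly away from an O(h²) skin at the faceted
offset surfaces (h = mesh edge length), and the tests assert both the
agreement and the confinement of any disagreement to that skin.

**Territories** are discrete Boolean intersections: a territory keeps the
base triangles whose centroid lies inside its (closed, user-supplied)
territorial solid.  Overlap between adjacent territories is allowed and
reported as (Σ territory volumes − shell volume)/shell volume.  Volumes are
computed from the extruded sub-shell boundary meshes, so the Boolean
consistency "sum = shell + overlap" holds to mesh accuracy (≈1%).

**Seed-network registration** composes, in order: centroid translation,
a Rodrigues rotation aligning the best-fit-plane normals of the two
landmark sets, per-axis scaling by ratios of coordinate standard deviations
(axes with vanishing spread are left unscaled — landmark sets are typically
near-planar), and projection of node coordinates onto the median offset
surface.  Collinear landmarks are rejected; long projections trigger a
warning.

**Synthetic cortex patch.**  A square height field
z = a·sin(2πx/λ + φ₁)·sin(2πy/λ + φ₂) with seed-derived phases emulates
gyral/sulcal folding; a = 0 gives a flat patch of exact area.  Defaults for
the standard demo patch: 4×4 cm, λ = 2 cm, a = 0.25 cm.  The patch
reproduces the geometric difficulty that matters for generation (curved,
folded shell; connections that can leave the domain); it does not reproduce
cortical curvature statistics, sulcal depth distributions, or a closed
hemisphere.

## 2. Constrained constructive growth

Trees grow one terminal at a time.  A candidate location is drawn uniformly
in the (sub-)shell, subject to a minimum distance to the existing tree of
ν·√(A/N) (A shell area, N current terminal count, ν = 0.01); after 2000
consecutive rejections the threshold is relaxed multiplicatively by
f_r = 0.9 (per-stage counter, reset on every committed terminal).  For each
of the f_n = 100 nearest segments, the bifurcation position is searched on
a barycentric lattice with Δv = 7 points per edge of the triangle spanned
by the candidate and the segment endpoints (lattice vertices excluded —
they are degenerate bifurcations).  A connection is admissible if all three
new segments are at least `min_length` long, the two children subtend at
least θ_min = 20°, the child-radius ratio respects the symmetry bound δ,
the out-of-plane angle respects φ_min (inactive at the default 0°), and —
for distribution vessels — all three segments lie entirely in the domain
(Δv sample points each).  Among admissible candidates the one of least cost
wins; exact ties break to the lowest segment id, then the lowest lattice
index.  Containment is screened in cost order in vectorized chunks and
capped at the 256 cheapest geometry-feasible lattice points per candidate
location; a location whose cheapest 256 connections all leave the domain is
counted as a failure.

**Costs.**  The volumetric functional is the total intravascular volume
Σπr²L after tentative insertion.  The sprouting functional is the weighted
sum C_v·V + C_p·d(x_b, root) + C_d·|x_b − candidate| with C_v = 10⁴,
C_p = 0.5, C_d = 1; within one insertion the total volume differs from the
volume *increment* by a constant, so the ranking is the same.  The exact
algebraic form of the sprouting functional in the staged-CCO literature is
not restated in our sources; this weighted sum is this package's documented
choice.

**Hemodynamics and radii.**  During generation the tree is a steady
Poiseuille network with uniform terminal outflow Q/N_T (exact, since flows
are accumulated from integer terminal counts).  Radii follow the
bifurcation power law anchored at the inlet:
r_i = r_root·(Q_i/Q_root)^{1/γ}, the Murray relation Q = ξ·rᵞ with ξ fixed
by the inlet pair.  Flow conservation then *implies* the power law at every
junction to round-off, so the Murray residual is ≈10⁻¹⁶ by construction.
This differs from classic CCO (radii from terminal resistance boundary
conditions) and is the formulation matching the inter-territory
equalization bookkeeping; it also makes radii independent of the viscosity
law, so no fixed-point iteration on μ(r) is needed — viscosity enters the
pressure field only.  Segment resistance is R = 8μ(r)L/(πr⁴) and pressures
accumulate RQ drops from the inlet (80 mmHg reference), giving monotone
pressure along every root-to-terminal path.

**Blood rheology.**  μ(r) is either Newtonian (0.032 P) or the in-vitro
relative-viscosity fit of Pries et al. at discharge hematocrit 0.45,
multiplied by a plasma viscosity of 0.01 P so that the large-diameter limit
is exactly the Newtonian value.

**Sub-domain (parallel-style) growth.**  The shell's triangles are
partitioned into K contiguous, roughly balanced parts by farthest-point
seeding and multi-source geodesic assignment on the face adjacency graph.
Each part grows its area-proportional share of the terminal budget on a
private copy of the baseline tree with a seed spawned from the stage seed;
candidate locations are restricted to the sub-domain while vessel
containment is checked against the full shell (connections near sub-domain
interfaces may cross them — merging re-validates everything globally).
Merging replays the per-sub-domain insertion journals onto the baseline; a
baseline segment split by two sub-domains is resolved by matching the
recorded attachment geometry and, failing that, attaching to the nearest
fragment.  A final global solve restores flows, radii and pressures, after
which the merged network satisfies the identical invariant suite.  K = 1
short-circuits to plain serial growth, bitwise.

**Standard demo conditions.**  The full-scale design density is
1.2 terminals/mm² (116 977 terminals over 97 500 mm²).  Desk-scale demo
networks keep the *flow per terminal* at its physiological value
(125 ml/min over 51 595 terminals ≈ 1.85·10⁻³ ml/min per penetrating
arteriole) and reduce the density, so that a 30–200-terminal patch network
carries realistic per-vessel flows, radii (tens of μm at terminals) and
pressure drops.  The feeder radius follows Murray's law from the reference
constant ξ = 1847 s⁻¹.  Consequences: direction-of-effect comparisons and
all structural invariants are meaningful at desk scale, but absolute
medians (PI, PP, damping factors) are not those of a quarter-million-vessel
hemisphere — path lengths and branching depth are far smaller, so damping
factors stay near 1 and inter-scenario gaps are compressed.

## 3. Pressure-distribution equalization

Feeder radii inherited from a seed arterial model are not calibrated
against territory inflows, so the steady pressure distributions of
different territories disagree.  Equalization scales every diameter of a
territory by a single factor f_S minimizing the quadratic error between its
pressure histogram and a reference territory's.  Histograms use the
distal-node pressure of every segment (configurable to midpoints), shifted
so the inlet sits at 80 mmHg, with 1000 uniform bins on [0, 80] mmHg;
sub-zero pressures are clipped into the first bin with a warning.  Because
binning makes the objective piecewise constant, the optimizer is a
two-stage grid scan (10⁻² then 10⁻⁴ resolution over [0.5, 1.5]) rather
than a derivative or golden-section method; an optimum at the search
boundary raises.  At fixed flows, scaling diameters by f_S scales every
pressure drop by f_S⁻⁴ (exactly, for radius-independent viscosity), so the
drop is strictly decreasing in f_S and recovery of a known scaling is
well-posed; the self-consistency test recovers f_S = 1.10 to 10⁻³.

## 4. Pulsatile 1D blood flow

State per cell: lumen area A and flow Q.  Mass and momentum balance with
convective term, pressure-gradient term −(A/ρ)∂P/∂x and friction
−8πμQ/(ρA) (Poiseuille profile; the friction factor is treated
semi-implicitly, which is exact at steady state and removes the stiffness
of small-vessel friction).  ρ defaults to 1.04 g/cm³.

**Tube law.**  P = P₀ + (πr₀h/A)[E_e ε + E_c ε_r ln(e^χ+1) +
K_m/(2√(AA₀))·∂A/∂t], ε = A/A₀ − 1, χ = (ε − ε₀)/ε_r: a linear elastin
term, a softplus collagen-recruitment term, and a Kelvin–Voigt rate term.
Defaults (the `HemoParams` set): E_e = 2·10⁶ dyn/cm² (200 kPa),
E_c = 2·10⁷ dyn/cm², ε₀ = 0.25, ε_r = 0.07, P₀ = 75 mmHg, and wall
thickness from the double-exponential fit h/r₀ = 0.2802e^{−5.053r₀} +
0.1324e^{−0.1114r₀} (h/r₀ ≈ 0.41 at arteriolar radii), giving pulse-wave
speeds of ≈9 m/s in the demo vessels.  K_m defaults to 5·10⁴ dyn·s/cm²:
matching the rate term against the standard Kelvin–Voigt wall-viscosity
form gives K_m ≈ (4/3)·η_wall, and measured arterial wall viscosities are
of order 10³–10⁴ Pa·s·10⁻¹ (1–10 kPa·s), so this sits mid-range.

**Viscoelastic reformulation.**  Substituting the mass balance
∂A/∂t = −∂Q/∂x into the rate term makes the wall-viscosity part of the
pressure gradient a diffusion of Q with coefficient
(A/ρ)·(πr₀h/A)·K_m/(2√(AA₀)).  That diffusion is integrated implicitly in
time per vessel (a tridiagonal solve; for single-cell vessels a scalar
division), which removes the parabolic time-step restriction that makes
fully explicit viscoelastic schemes so expensive, while the advective part
remains explicit under the CFL condition.  With K_m = 0 the implicit
operator is the identity and the elastic hyperbolic system is recovered
bitwise (asserted in the tests).  The recorded probe pressure is the
elastic part of the tube law.

**Scheme.**  Second-order finite volumes: minmod-limited MUSCL
reconstruction of (A, Q), midpoint (half-step) evolution, Rusanov interface
fluxes for (Q, Q²/A), and the pressure gradient applied through averaged
reconstructed interface pressures.  Boundary cells use zero slopes, so the
scheme is first-order at vessel ends; the steady Poiseuille limit is
therefore checked on a rigid-ish (stiff-wall) vessel where the residual
first-order dissipation bias is negligible (measured ≲0.1%).  Cells:
characteristic length Δx_c = 1 cm; vessels shorter than Δx_c get exactly
one cell.  Time: per-vessel steps Δt ≤ min(0.9·Δx/max|u±c|, 1 ms) on a
power-of-two hierarchy below a sync interval; junction-adjacent vessels
share common time levels, junction data are solved at the finest adjacent
level, and interface fluxes are time-integrated ("buffered") so that mass
conservation is exact across levels (asserted to round-off).  A uniform
network collapses to global time stepping; a mixed-size network agrees
with a forced global-minimum-step run to ~10⁻⁶ relative.

**Junctions.**  At each junction the unknowns are one (A, u) state per
converging vessel end; the equations are mass conservation, equality of
total pressure P + ρu²/2 across ends, and one linearized
outgoing-characteristic compatibility relation per vessel
(u* = u_b ∓ (c_b/A_b)(A* − A_b)).  Newton with the analytic Jacobian,
batched across all junctions of equal degree, normalized residuals below
10⁻¹¹.  A junction already in equilibrium is detected before the first
update, so resting states are preserved bitwise.

**Boundary conditions.**  The root takes a prescribed periodic inflow (the
stand-in for coupling to the upstream arterial tree): a smooth two-harmonic
waveform with exact period-mean and exact requested pulsatility.  Terminals
carry 3-element Windkessels integrated with explicit Euler; C = 0
degenerates algebraically to P = P_t + (R₁+R₂)Q, and network terminals are
purely resistive by default, calibrated so every outlet discharges Q/N_T
under steady conditions: R_tot = (P_root − P_t)/Q_t − R_path with
P_root = 90 mmHg, P_t = 30 mmHg, R₁ = 0.2·R_tot.

**Scenarios.**  Hypertension multiplies, relative to the normotensive
baseline: terminal Windkessel resistances ×1.47, elastin modulus ×2.0,
wall thickness ×1.4, reference lumen area ×0.81 (hence r₀ ×0.9); a feeder
Windkessel, when present, gets R ×1.40 and C ×0.85.  Scenario application
is guarded by a provenance flag (factors must not silently compound).  The
inflow is flow-driven, so both scenarios receive the same mean flow.  The
Newtonian-vs-non-Newtonian comparison holds walls and terminal boundary
conditions fixed and switches only the friction viscosity law; terminal
calibration belongs to the scenario, not to the rheology variant.

**Simulation protocol.**  Default 10 cardiac cycles of period 1 s with the
last cycle analyzed; the demo comparisons use 3 cycles (the purely
resistive terminals leave no slow time constants, and the measured
cycle-to-cycle periodicity residual is ≲10⁻³ by the second cycle).  Each
vessel is probed at its distal (and proximal) cell, 64–128 samples per
cycle.

## 5. Indices and spatial analyses

From last-cycle waveforms: systolic/diastolic/period-mean of P and Q
(uniform periodic sampling, so the trapezoidal mean is the sample mean),
PP = P_s − P_d, PI = (Q_s − Q_d)/Q_m, and damping factors
DF_Y = max(Y)/Y with the maximum over the network (the maximizing vessel
has DF = 1; a zero index yields a flagged infinity).  Indices sample the
distal end of each vessel (configurable to midpoints).  Transport-level
curves take per-distance-bin maxima (1-cm bins by default) of PI and P_m
over points of sampled root-to-terminal paths; perfusion-level statistics
take the terminal vessels against distance-to-root and diameter.  Trend
slopes are ordinary least squares — on bin maxima at the transport level,
on raw terminal points at the perfusion level.  Path sampling is uniform
over terminals without replacement, seeded.  Summary statistics are
reported as median [Q1, Q3] with equal weight per vessel.

## 6. Known limitations

- Desk-scale networks compress inter-scenario gaps (see §2); the package
  asserts directions of effect, never full-scale magnitudes.
- The junction compatibility relations are linearized about the boundary
  cell state (first order); total-pressure continuity itself is enforced
  to 10⁻¹¹.
- The recorded pressure omits the (small) wall-viscosity additive term.
- No venous side, no collateral/anastomotic loops, no autoregulation or
  flow control; terminal Windkessels stand in for everything downstream.
- The discrete Boolean territory intersection follows triangle centroids;
  territory boundaries are resolved to the surface mesh resolution.
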