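# Methods

## The model

`occlucurve` simulates how the sagittal curvature of the dental arches — the
concave mandibular *curve of Spee* and the convex maxillary *compensating
curve* — can emerge from three concurrent processes acting on two initially
flat "dental blocks":

1. **Chewing kinematics.** The mandibular block sweeps through a
   quasi-static rigid rotation stroke about a single fixed center C_ROT
   placed a distance *r* above the midpoint of the occlusal interface
   (C_ROT = (W/2, r) for blocks of width W).  The stroke runs posterior →
   anterior between two overhang positions: it starts with the mandibular
   block 3 mm behind the maxillary block (θ₀ = −asin(3/r)) and ends 3 mm
   ahead (θ_N = +asin(3/r)).  The return stroke is unloaded and
   instantaneous.  The stroke is discretized into N increments (default
   60); pressures are evaluated at mid-increment poses so the wear
   accumulated over a symmetric stroke is itself symmetric.

2. **Tooth eruption.** Each cycle the blocks advance toward each other by a
   fixed total of e_c = 0.01 mm (default split 50/50 between the blocks).
   This is the continuous eruption drive: unopposed surfaces rise
   indefinitely.

3. **Eruption inhibition as wear.** Occlusal load suppresses eruption.
   Following the Archard–Lancaster sliding-wear relationship, each surface
   node loses depth Δh = k_w·p·Δs per stroke increment (contact pressure ×
   sliding distance × wear coefficient).  The classical inhibition integral
   ∫k·F_n·dt maps onto this sum exactly with k = k_w·v/A (v sliding speed,
   A nodal tributary area): the two constants describe the same process per
   unit load-time versus per unit pressure-distance.

A cycle is: eruption advance → loaded stroke with wear accumulation on both
surfaces → wear application → interior mesh relaxation → ledger update.
Iterating cycles drives the system to a steady state in which per-cycle
wear equals the per-cycle eruption share at every contacting node: the
surfaces become stationary while material keeps flowing through them.

**Why arcs?** Surfaces in sustained sliding contact under a fixed rigid
rotation can only conform if they are *conjugate* — invariant under the
motion.  For rotation about a fixed point the conjugate surfaces are
circular arcs centered on that point.  The steady state is therefore an arc
of radius ≈ r about C_ROT on both blocks, with sagitta
d = R − √(R² − (L/2)²) over a chord L; for r = 100 mm and L = 40 mm,
d ≈ 2.02 mm (the classical curve-of-Spee depth), and for r = 400 mm,
d ≈ 0.50 mm.  The simulation's job is to show the dynamics actually find
this attractor from flat initial conditions, and the analysis layer
measures how closely (circle-fit residual, fitted center vs C_ROT,
depth-vs-radius monotonicity).

## Geometry, mesh, remeshing

Each block is a structured nx × ny grid of bilinear quadrilaterals
(defaults 40 × 20 elements over 40 mm × 20 mm, 1 mm out-of-plane thickness,
plane stress).  x increases anteriorly, y superiorly; the occlusal
interface starts at y = 0.  Occlusal surface nodes move only vertically
under wear, so profiles stay column-aligned for the whole run.

After each cycle the interiors are re-relaxed (the remeshing analog):
interior nodes take the mean of their four grid neighbors (25 Jacobi
sweeps), and lateral-edge nodes slide along their edge (1D Laplacian in y).
The edge sliding is necessary, not cosmetic: at steady state the occlusal
corner nodes sink by e_c/2 per cycle relative to the block frame, and fully
pinned lateral edges would collapse the surface element row after roughly
(element height)/(e_c/2) cycles.  Element quality is monitored as the
minimum scaled corner Jacobian (1 for rectangles); wear depths approaching
the adjacent element height abort the run with a stability error.

## Contact engines

* **Winkler (default).** Bed-of-springs surrogate with foundation modulus
  E_f = E/(2h): two h-tall columns of modulus E in series.  Pressure is
  E_f × vertical overlap of the two profiles.  Overlap is evaluated on
  *both* surfaces' node stations, reading the opposing surface through a
  cubic-spline interpolant; linear sampling is O(Δx²)-biased on curved
  surfaces, which makes the blocks wear at measurably unequal rates and the
  conforming pair drift instead of settling (the drift exceeded the
  stopping tolerance on the nx = 20 mesh).  The spline construction keeps
  per-cycle wear volumes on the two blocks equal to ≈ 0.02 %.

* **Plane-stress FE.** Full 2D solve of both blocks: bilinear quads, 2×2
  Gauss quadrature, maxillary far edge fixed, mandibular far edge rigidly
  driven by the pose, node-on-segment penalty contact with vertical springs
  (penalty stiffness 100·E_f, penetration error ≈ 1 % of interference;
  doubling the penalty changes total force by < 2 %, so results are
  discretization- not penalty-limited).  The driver uses a per-cycle cached
  sparse factorization with Woodbury low-rank contact updates; the rigid
  pose enters exactly via per-node rotation of the contact incidence
  vectors (K_world = T K_body Tᵀ for an isotropic material).

Absolute force levels are model-defined (they scale with thickness and the
contact model); the steady-state *shape* does not depend on them, which is
the reason the fast surrogate can be the default engine.  On the nx = 20
mesh the two engines' steady mandibular sagittas at r = 400 mm agree within
6 %.

Friction is omitted: the wear law consumes only normal pressure and the
kinematically exact sliding distance |x − C_ROT|·Δθ.

## Wear-update stability and the auto wear coefficient

The once-per-cycle explicit wear update is a fixed-point iteration on the
surface height field.  A node protruding by δ sees extra pressure k_c·δ
(k_c = contact stiffness per unit area of the perturbation) and hence extra
per-cycle wear k_w·k_c·δ·S, S being the slide per cycle — a feedback gain
G = k_w·k_c·S.  G < 1 gives smooth monotone decay; G > 2 diverges into
node-level chatter bounded only by the contact nonlinearity, and the run
never meets the steady tolerance.  `wear_coefficient: auto` therefore
resolves k_w = G*/(k_c·S) once per run with target gain G* = 0.5:

* winkler: every wavelength sees k_c = E_f, so G ≈ G* uniformly;
* fe: short wavelengths λ see the much stiffer elastic response
  k(λ) ≈ πE/(2λ).  The per-cycle wear field is smoothed with a 3-point
  binomial filter (which nulls the 2Δx mode and preserves constants, hence
  totals and the steady state), and k_c is evaluated at the shortest
  surviving wavelength 4Δx including the filter's ½ attenuation:
  k_c = πE/(16Δx).  This caps G near G* across the spectrum at the price
  of a slower large-wavelength transient.

Because the attractor is rate-independent, k_w only sets the timescale:
halving it changes the steady sagitta by < 0.3 % on the reference runs.
Under this stability-limited coefficient the transient is *eruption-rate
limited* (material can only flow through the interface at e_c per cycle),
so cycle counts are largely insensitive to k_w as well — a wear-limited
regime with much larger k_w would converge faster per cycle but chatters.

## Stopping rule and bookkeeping

The steady metric is the max over blocks of the RMS per-node surface height
change per cycle; a run converges when it stays below 1e−4 mm for 10
consecutive cycles (defaults; `max_cycles` 5000 caps non-converging runs,
returned with a false flag rather than raised).  The eruption ledger tracks
per-block cumulative eruption shares and wear depths; the pair-level net
eruption e_c·cycles − (wear_mand + wear_max) is the quantity whose
per-cycle change vanishes at steady state (measured < 2 % of e_c on the
reference run).

The core loop is deterministic — identical configs give bit-identical
`history.csv` files.  The config seed exists for the synthetic fixture
generators (noisy arc profiles), which are the only stochastic component.

## Problem sizes used by the tests and the acceptance script

Steady-state runs use the scaled nx = 20, ny = 10 discretization of the
same 40 × 20 mm blocks (the attractor geometry is mesh-converged at this
resolution; the r = 100 mm run converges in ≈ 1060 cycles in ~40 s).  The
printed-constant, patch-test and contact-oracle checks use the full
40 × 20 element mesh.  The FE-engine steady run is done at r = 400 mm,
whose 4× shallower curve keeps the (slower) FE transient affordable.

## Degenerate and edge cases

* `wear_coefficient: 0` disables wear entirely (eruption-only runs close
  the gap by exactly e_c per cycle and leave surfaces untouched).
* A pure-grinding degenerate path (identity poses, uniform sliding — the
  r → ∞ limit of the stroke with r·Δθ held fixed) keeps flat blocks flat to
  machine precision: flat is the fixed point of wear without rotation.
  Note that a literal horizontal ±3 mm translation stroke does *not* share
  this property: the outer 3 mm of each surface is covered for only part of
  the stroke, and the steady surface compensates with raised
  partial-coverage bands.
* Collinear profiles get a `flat` flag from the circle fit (curvature
  below 1e−6 /mm) rather than an error; end nodes that never carried load
  are excluded from steady-profile fits.

## What the synthetic fixtures do and do not cover

The fixture generators produce circular arcs with seeded Gaussian height
noise and flat/wedge interference pairs with closed-form Winkler pressure
fields.  They exercise the analysis and contact layers against exact ground
truth, but they do not emulate real dentitions: no cusps, no per-tooth
geometry, no enamel/dentin layering, no 3D (Monson-sphere) curvature, no
condylar translation or instantaneous-center migration.  Passing tests
therefore validate the model's internal mechanics and its two qualitative
predictions (flat → curved; smaller r → deeper curve), not quantitative
agreement with human cephalometric data.

## Known limitations

* 2D sagittal plane-stress idealization; out-of-plane thickness is a free
  scale factor on forces (1 mm default).
* Single fixed rotation center per run; real mastication has a migrating
  instantaneous center.
* No friction, no dynamics, no hardness contrast between the blocks (the
  two arches wear at equal rates by construction).
* Absolute pressures and cycle counts are model-defined; only the steady
  geometry is quantitatively constrained (by the conjugacy argument).
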