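# Methods

## Model

A confluent monolayer is a polygonal tiling of a flat torus.  The energy
is the standard area-elasticity-plus-line-tension vertex-model form,

    H = (K/2) Σ_α (A_α − A0)² + Λ Σ_<ij> l_ij,

with no junction-length elasticity in H itself.  Contractility is a
*force*, not an energy term: an active junction (i, j) exerts a
length-proportional tension Γ·l, i.e. it contributes −Γ (r_i − r_j) to
the force on vertex i (minimum-image displacement).  Making the active
tension proportional to length produces a stretch response independent of
the initial junction length and treats each junction as an independent
mechanical unit, unlike perimeter-contractility formulations that tie all
junctions of a cell together.

Vertices follow overdamped dynamics μ dr/dt = −∂H/∂r + F_act, integrated
with forward Euler.  Junction viscoelasticity enters through rest-length
remodeling, dl0/dt = −k_L (l0 − l); the strain ε = (l − l0)/l0 is the
quantity that drives excitability.  Rest lengths remodel in every state
(the rules never exempt active or refractory junctions).

Each junction carries a three-state automaton: inactive (Γ=0) → active
(Γ=Γ0) when ε ≥ ε_on; active → refractory (Γ=0) after τ_act; refractory →
inactive after τ_ref.  The threshold comparison is **inclusive**; at the
Δt resolution of the integrator the distinction from a strict inequality
is immaterial, but the convention is fixed and tested.  Timers decrement
by Δt and fire at ≤ 0, so realized durations are quantized to multiples
of Δt (all defaults are exact multiples).  All transitions in a step are
computed from the pre-step states and applied simultaneously, so there is
no junction-index bias and a junction leaving the refractory state can
activate at the earliest one step later.

### Per-step order

(1) forces; (2) Euler update of positions, re-reduced into the box;
(3) Euler update of rest lengths against the post-move lengths;
(4–5) automaton update using post-move strains; (6) T1 checks.  Any fixed
order is equivalent to O(Δt); this one is frozen and used everywhere
(including restarts, which are bitwise-reproducible through the snapshot
format).

### T1 transitions

A junction shorter than l_T1 = 0.01 collapses to a transient 4-fold
vertex that is resolved immediately: the junction re-opens along the
perpendicular bisector of its old direction, centered at the old
midpoint, with l = l0 = 1.5·l_T1, inactive and non-contractile.  The two
cells that shared the junction lose a side; the two cells at its
endpoints gain one; V, E, C and the Euler characteristic are conserved.
The perpendicular re-opening geometry is our choice (only the new length
and state are dictated by the model definition); the endpoint displaced
toward the cell that keeps it preserves counterclockwise loops.  A swap
that would create a 2-sided cell is skipped.

## Parameters

Simulation units: lengths in √A0, forces in K·A0^(3/2), time in
t0 = μ/(0.636·K·√A0); with K = A0 = 1 and μ = 0.636, t0 = 1.  Defaults:

| parameter | symbol | default | units |
|---|---|---|---|
| area modulus | K | 1 | K |
| preferred area | A0 | 1 | A0 |
| friction | μ | 0.636 | K·t0 |
| line tension | Λ | 0.1 | K·A0^(3/2) |
| active contractility | Γ0 | 0.5 | K·A0 |
| strain relaxation rate | k_L | 1 | 1/t0 |
| activation strain | ε_on | 0.1 | — |
| T1 threshold | l_T1 | 0.01 | √A0 |
| time step | Δt | 0.01 | t0 |

τ_act and τ_ref have no universal default; the phase-space scans set
τ_act = τ_ref = τ.  Halving Δt moves the strain transient of a seeded run
by ~1%, well inside every tolerance used in the tests.

## Tissue generators

**Ordered**: pointy-top regular hexagons of unit area (edge
a = (4/27)^(1/4) ≈ 0.6204), cols × rows with rows even for periodicity;
the box is adjusted to the nearest commensurate dimensions (e.g. 260
cells at ~14 × 18.6 realizes a 13 × 20 grid at 13.97 × 18.61).  Vertex
identification uses exact integer lattice coordinates, so the
construction is exact and is a mechanical equilibrium by the three-fold
symmetry of every vertex — verified numerically to 1e−12.

**Disordered**: seeded uniform random points → 2 Lloyd iterations →
periodic Voronoi tessellation (3×3 tiling of the generators, central
regions extracted, duplicate vertices merged by a periodic KD-tree union)
→ relaxation to mechanical equilibrium (max vertex force < 1e−6) under H
with Γ ≡ 0, T1 exchanges allowed.  Rest lengths are then set to the
relaxed lengths (zero strain).  The two Lloyd iterations are fixed a
priori: raw Poisson–Voronoi tilings contain sliver cells that slow
equilibration, while full Lloyd convergence would erase the heterogeneity
the disordered ensemble is meant to have.  The generator is a pure
function of (n_cells, box, seed).  The published disordered experiments
do not specify their generation protocol, so quantitative properties of
these ensembles (length and sidedness distributions) need not match any
particular reference tissue; the tested claims are the qualitative ones
(wave promotion, critical-k_L trend).

Equilibration satisfies the dynamical fixed-point condition
max |force| < 1e−6 (far below the Λ = 0.1 force scale).  It is reached by
L-BFGS-B minimization of H alternated with T1 sweeps — the stationary
points coincide with those of the overdamped dynamics and the quasi-Newton
route is deterministic and much faster; a pure Euler mode exists and is
tested.

## Effective three-junction model

One central junction (length l1, tension Λ1) between two outer junctions
(length l2, tension Λ2) with fixed walls: l1 + 2 l2 = 3L.  Each junction
has a spring (k, natural length L — the 1D stand-in for cell-area
elasticity), a dashpot, the constant tension, and a binary active element
with tension Γ·l.  Nondimensionalized with k = L = μ = 1; the effective
analyses use Γ0 = 1.

The wall constraint leaves one degree of freedom.  We evolve the
**constraint-reduced gradient flow** μ dl2/dt = −dH_eff/dl2 with
l1 = 3L − 2 l2 substituted, equivalently dl2/dt = (2/μ)(T1 − T2) with
per-junction tensions T_i = k(l_i − L) + Λ_i + Γ_i l_i.  (The naive
per-length equation μ dl_i/dt = −∂H_eff/∂l_i does not preserve the
constraint, and literal node dynamics carry half this rate.)  The reduced
flow is the reading under which the closed-form criteria are exact: with
the center active and k_L = 0 the outer strain is
ε2(t) = [Γ0/(3+2Γ0)] (1 − e^{−2(3+2Γ0)t}), whose ε_on-crossing is

    τ_p = [1/(2(3+2Γ0))] ln[Γ0/(Γ0 − (3+2Γ0) ε_on)],

infinite when ε_on ≥ Γ0/(3+2Γ0) (strain saturates below threshold) and
zero at ε_on = 0.  The center re-activates at the end of its refractory
period (t = 2τ, assessed with the same inclusive threshold) iff

    A e^{−6τ} − B e^{−6(2+Γ0)τ} − ε_on > 0,
    A = [2Γ0/(3+Γ0)] (1 − e^{−2(3+Γ0)τ_p}) e^{6τ_p},
    B = [2Γ0/(3+2Γ0)] (1 − e^{−2(3+2Γ0)τ_p}) e^{2(3+2Γ0)τ_p}.

The exponent of the second term is read as −6(2+Γ0)τ, which makes the
left side A·y − B·y³ with y = e^{−6τ} at Γ0 = 1 — the advertised cubic
form.  The tests integrate the model at Δt = 1e−4 and find the simulated
central strain at 2τ agrees with A e^{−6τ} − B e^{−6(2+Γ0)τ} to ~3e−5,
and that bisection of the simulated outcome over τ recovers τ_p within
two integration steps across a (Γ0, ε_on) grid — the closed forms and the
integrator validate each other through independent routes.

Numerics: forward Euler at Δt = 1e−3 (time unit μ/k) unless stated;
bisection tolerances 1e−4; the reactivation inequality is solved by dense
scanning in y plus Brent root refinement (tolerance 1e−14).  τ_1 is the
infimum of the analytic inequality's solution set at k_L = 0, and the
smallest simulated-reactivation τ (bisection) at k_L > 0.  The k_L range
for effective-model scans defaults to [0, 1].

Rest-length remodeling in the effective model applies to l1 and l2 and
feeds only the strains driving the automaton; the springs always
reference L.  The simulated horizon is τ_act + τ_ref plus a few steps, so
the center's refractory end (and hence reactivation) always falls inside
the run.

## Observables and classification

State fractions and total junction strain Σ ε_ij are sampled on a fixed
cadence.  A seeded run is classified from its active-fraction series:
quiescent if the maximum never exceeds θ_prop = 0.1 (the same threshold
for ordered and disordered tissues — one operational definition); else
wave if the final active fraction is positive, else pulse.  "Final" means
the mean over the last 10% of the horizon, so an oscillating wave state
cannot alias to zero through an unlucky point sample.  Classification
runs use t_end = 20; labels are unchanged under halving of the sampling
interval (tested).

The critical remodeling rate k_L* of a seeded junction is found by
bisection (bracket [0, 2]) on the max-active-fraction > θ_prop predicate,
the same definition as the quiescence boundary of the phase diagram.

Wavelength: the radial profile of the active-junction indicator around
the seeding point (minimum-image distances, bin width = one hexagon edge
length) is peak-detected per late-time snapshot (peaks ≥ 0.3 of the
profile maximum, ≥ 2 bins apart); the wavelength is the mean spacing of
consecutive peaks averaged over snapshots with at least two rings.  It is
undefined for pulse and quiescent runs.  The estimator recovers the
spacing of synthetic concentric ring patterns to within one bin.  No
published estimator exists to compare against, so wavelength claims are
validated by the synthetic-ring oracle and by monotonicity in
Δ = τ_ref/τ_act, not by absolute values.  The wavelength experiments use
τ_act = 2, k_L = 0.5, Δt = 0.05 on a 936-cell ordered tissue with
Δ ∈ {0.1, 0.25, 0.4}; wavelength is only defined in the wave regime, and
at these mechanics the wave-to-pulse transition lies between Δ = 0.4 and
Δ = 0.5, with Δ ≥ 0.5 giving a solitary pulse.  Per-panel refractory
times for the published wavelength figure are not available, so these Δ
values are the package's own study conditions.

## Problem sizes

All tests and scripts run at desk scale on one CPU: the ordered phase
points use the full 260-cell tissue of the published experiments, the
disordered experiments the full 208 cells (4 seeds for the
disorder-promotes-waves check, 10 seeded junctions with 5 bisection
rounds for the critical-k_L trend), and the wavelength runs a 936-cell
tissue versus 2759 in the published figure — wavelengths of 4–6 cell
diameters fit comfortably in its 27.9 × 33.5 box.  Phase diagrams are
reproduced on coarse grids via `sweep_phase_diagram` / the `sweep` CLI;
full-resolution grids are possible but slower.

## Limitations

* The synthetic disordered ensemble emulates geometric heterogeneity
  (mixed polygon classes, broad junction-length distributions) but not
  any specific experimental tissue statistics; passing tests demonstrate
  the mechanism, not a fit to data.
* The three-state automaton coarse-grains ERK/inhibitor biochemistry;
  there is no graded contractility and no explicit signaling field.
* Spiral and elliptical wavefront geometries are produced by the
  row-plus-refractory initial condition, but spiral-shape recognition is
  visual; no automated topology detection is included.
* Forward Euler only; Δt must resolve the stiffest active junctions
  (defaults validated, non-finite states abort with a diagnostic).
* No cell division, extrusion, open boundaries, or 3D.
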