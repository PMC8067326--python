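# Methods

## Model and assumptions

`chmito` integrates the dimensionless conserved phase-field (Cahn–Hilliard)
system

    ∂Ψ/∂t = −∇·J,   J = −M∇μ,   μ = Ψ³ − Ψ − γ∇²Ψ,

on bounded 2D/3D domains. Ψ is the membrane/matrix density difference
(membrane −1, matrix +1); the model contains no hydrodynamics,
electrostatics, reaction–diffusion coupling, or explicit membrane-shaping
proteins — pattern formation is driven purely by free-energy minimization
under the conservation constraint and the geometric boundary conditions.
The flux mobility is M = 1/2 in the dimensionless scaling adopted here,
exposed as `SolverConfig.mobility`.

Boundary conditions: natural zero flux for both Ψ and μ on the outer
boundary. Calcium phosphate granules are modeled by volume exclusion: each
granule ball is removed from the mesh and its boundary pins Ψ to a
constant C ∈ [−1, 1] (Dirichlet, imposed by row elimination) while μ keeps
the natural zero-flux condition. Continuum mass is conserved in granule
runs too (the flux vanishes on Γ′), but row elimination perturbs the
*discrete* balance; granule-run mass drift is therefore monitored and
reported in the time series, not asserted. Granule-free runs conserve the
discrete mass to Newton tolerance exactly, because the Ψ-equation tested
against the constant function telescopes.

## Discretization

Mixed two-field P1 formulation: the fourth-order equation is split into
two second-order equations in (Ψ, μ), discretized with piecewise-linear
simplicial elements and the theta method,

    (Ψⁿ⁺¹−Ψⁿ, u) + Δt·M·a(μ_{n+θ}, u) = 0,
    (μⁿ⁺¹, v) − (f′(Ψⁿ⁺¹), v) − γ·a(Ψⁿ⁺¹, v) = 0,

with μ_{n+θ} = (1−θ)μⁿ⁺¹ + θμⁿ. Note the convention weights μⁿ⁺¹ by
(1−θ); θ = 0.5 is the trapezoidal scheme and the default (the scheme
parameter is exposed). The coupled nonlinear system per step is solved by
Newton iteration on the stacked (Ψ, μ) unknown with a sparse direct
factorization; the Jacobian is factorized once per step and refreshed only
if the residual reduction stalls below a factor of 10 (the cubic block
changes little within one Δt at the model's step sizes). Convergence:
‖R‖₂ < max(abs_tol, rel_tol·‖R₀‖₂), defaults 1e−10 / 1e−8, at most 25
iterations; non-convergence raises with the last residual attached.

Quadrature: mass/stiffness terms are exact for P1. The quartic double-well
terms — the load vector (f′(Ψ), v), its Jacobian, and the reported bulk
energy — are integrated **exactly** using the closed-form simplex monomial
integrals ∫∏λᵢ^{aᵢ} = d!·∏aᵢ!/(d+|a|)!·|T| (precomputed 2nd/4th-order
moment tensors). This is chosen over low-order numerical rules because it
makes the Galerkin nonlinearity consistent with the reported free energy,
guarantees F ≥ 0 and F(−Ψ) = F(Ψ) at machine precision, and costs one
einsum per assembly.

Consequences verified by the test suite: granule-free mass drift at
machine precision; free energy non-increasing every step of the reference
runs (trapezoidal stepping at the model's Δt); exact trajectory negation
symmetry Ψ₀ → −Ψ₀; resumed checkpoints bit-identical to uninterrupted runs.

## Meshing

Domains (disk, ellipse, sphere, ellipsoid; ellipse/ellipsoid sizes are
FULL axis lengths, so "10 by 8" means semi-axes 5 and 4 — this keeps the
radius-5 disk and the 10×8 ellipse comparable) are meshed by a
distmesh-style force-equilibrium method over a signed distance function:
lattice seeding, edge-spring relaxation, scipy Delaunay retriangulation,
and projection of escaped points onto the boundary. Granule balls are
subtracted from the distance function, producing holes whose polygonal
boundary carries the pinned condition. Boundary facets (used by exactly
one element) are tagged outer vs. per-granule by distance to the granule
surface. The ellipse uses a scaled approximate distance function;
projection is by damped numerical-gradient descent, so boundary nodes sit
on the curved boundary to ~1e−3·h.

Default target edge length h = 0.15: the equilibrium interface width is
O(√(2γ)) ≈ 1.41 at γ = 1, giving roughly nine elements across an
interface. Discretized measures are within 2% of the analytic area/volume
at default h (in practice ~0.03% in 2D) and converge as h → 0; curved
boundaries are polygonally approximated. Granule layouts are validated
before meshing: granules must lie inside the outer shape and be pairwise
disjoint with clearance ≥ h_target, and h_target may not exceed the
smallest granule radius.

Auxiliary structured meshes (1D intervals, optionally periodic, and
rectangles) support the dispersion-rate measurements and analytic
fixtures; the periodic 1D mesh stores the wrapped element's periodic image
coordinate so the same assembly kernels apply.

## Linear analysis and the independent oracle

Closed forms: ω(k) = ½(k² − γk⁴), critical wavenumber 1/√γ, 1D interface
tanh(x/√(2γ)) with excess energy (2/3)√(2γ). The numerically measured
growth rate comes from two deliberately disjoint code paths: (a) the
production FEM solver on a periodic 1D mesh, and (b) an oracle using a
uniform periodic grid, a standard second-difference Laplacian and
semi-implicit stepping (linear part implicit, cubic explicit). Both fit
log-amplitude of the seeded FFT mode against time, skipping the first ten
steps (discrete-initialization transient) and rejecting fits with
R² < 0.999 as nonlinearly contaminated. Solver and oracle share no
spatial or temporal discretization, so their agreement (within 5% across
k ∈ [0.3, 1.5]) localizes bugs to whichever route disagrees with theory.
Default mode resolution is 64 nodes per wavelength, making the spatial
dispersion error O((kh)²/12) ≲ 1e−3 relative.

The stability discrimination of the uniform states (Ψ = 0 unstable,
Ψ = ±1 stable) seeds a 1e−4 amplitude k = 0.5 mode and integrates at
Δt = 1e−3 until the mode amplitude changes tenfold in either direction,
capped at 30000 steps: since ω(0.5) = 0.09375, tenfold growth of the
unstable state requires t = ln 10/ω ≈ 24.6, i.e. ~25000 steps; the
decaying states reach tenfold decay at t ≈ 8. The early-exit cap keeps
the check inside a couple of minutes at 1D cost.

## Morphometrics

Ψ = 0 (the double-well midpoint) is the phase boundary. Phase fractions
use exact sub-element clipping of the linear interpolant (divided-
difference formula with a deterministic 1e−12 tie-breaking jitter on mixed
elements); mixed elements partition exactly, so
matrix + membrane + interface-band residual = 1 to rounding, the residual
being only identically-zero elements. Interface length/area is extracted
by marching segments (2D) / marching tetrahedra (3D) on the interpolant's
zero level set. Connected components of a phase use facet adjacency
(edge-sharing in 2D, face-sharing in 3D — vertex adjacency would create
spurious bridges at pinch points) on elements classified by centroid
value. The characteristic pattern length is 2π/⟨k⟩ with ⟨k⟩ the first
moment of the radially averaged power spectrum of Ψ − mean, resampled on a
128² (2D) or 64³ (3D) grid over the bounding box with the exterior (and
granule holes) masked to the field mean to avoid boundary leakage.
Granule halo statistics average over elements whose centroids lie within
a shell (default width 0.5) of the granule surface.

## Synthetic initial data

The generator draws i.i.d. nodal noise uniform on
[mean − amplitude, mean + amplitude], defaults mean 0, amplitude 0.05,
with a named seeded generator (NumPy PCG64); granule nodes are overwritten
with their pinned constants. This emulates an initially homogeneous
membrane/matrix mixture with small composition fluctuations. What it does
not emulate: spatially correlated fluctuations, experimental membrane
topology, or any protein-mediated structure — so passing tests demonstrate
the model's mathematical behavior (conservation, dissipation, instability
growth, coarsening, granule exclusion effects), not agreement with imaging
data. Node-scale white noise mostly lies in the linearly decaying band
(k > 1); the unstable long-wave remnant grows at rates ≤ ω_max = γ/8·...
= 0.125, so full ±1 phase separation emerges on t = O(10–100). At the
bundled protocol horizons (t = 2.25 for the radius-4 disk) the pattern is
a coherent long-wave structure of modest amplitude whose coarsening,
composition balance and interface diagnostics are already well defined;
the acceptance checks are phrased in those terms. Granule runs reach
near-saturated halos much earlier because pinning at C = +1 is an O(1)
boundary forcing.

## Numerical choices and degenerate inputs

- Time step: bundled protocols use the stated Δt (0.001 or 0.005).
  Trapezoidal stepping is A-stable; stiff node-scale modes (|ω|Δt ≫ 1)
  decay slowly but monotonically in amplitude, and measured per-step
  energy increments stay ≤ 0 in the reference runs.
- Linear solves: sparse LU (SuperLU) on the 2N×2N block system; problem
  sizes at desk scale are ≤ ~10⁵ unknowns. An iterative solver is not
  provided.
- Ties at Ψ = 0 in morphometry are broken deterministically (see above);
  uniform fields raise an explicit undefined-spectrum error for the
  characteristic length rather than returning a number.
- Initializations with |mean| + amplitude > 1 are rejected (they would
  start outside the double-well range), as are granule layouts violating
  clearance constraints and h_target coarser than a granule radius.
- Checkpoints store mesh, both fields, step/time and the config echo;
  resuming reproduces the uninterrupted trajectory bit-compatibly (the
  dynamics consume no randomness after initialization).

## Problem sizes of the shipped checks

The test suite runs the radius-4 disk protocol at h = 0.15 (≈2600 nodes,
2250 steps), a scaled-down one-granule radius-5 disk run (600 steps at
Δt = 0.005), and a coarse 3D sphere smoke run (radius 2.5, h = 0.4, one
granule, 200 steps); these sizes were chosen so the whole suite completes
in minutes on one CPU while still exercising every code path at the
model's parameters. The acceptance script runs only 1D periodic
discretizations (64 nodes per wavelength).

## Known limitations

- The mesher is tuned for the model's convex shapes with interior holes;
  arbitrary (e.g. image-derived) boundaries and adaptive refinement are
  out of scope, and 3D element quality is adequate rather than optimized.
- No adaptive time stepping; Newton failure is reported with the residual
  and suggests reducing Δt.
- The ellipse/ellipsoid signed distance is approximate (exact projection
  only for circles/spheres), slightly degrading boundary-node placement
  on strongly eccentric shapes.
- Granule-run discrete mass drift (from Dirichlet row elimination) is
  reported, not eliminated; a Lagrange-multiplier formulation would
  restore exact discrete conservation at the cost of an indefinite system.
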