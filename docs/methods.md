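# Methods

`lutflow` models pressure-driven voiding through an idealized, two-dimensional
lower urinary tract after transurethral prostate surgery, and reproduces the
cohort-style analysis built on that model: sweep the three diameters that
surgery changes, solve the steady flow for each shape, detect and measure the
paired recirculation zones ("vortices") in the hollowed prostatic urethra
(PU), and relate vortex presence and size to the diameter ratios of the PU.

## Geometry

Each case is a closed planar outline, mirror-symmetric about the flow axis,
built from three stacked regions (all lengths in cm):

* **Bladder** (lower half): transverse diameter fixed at 10.0. The wall is a
  vertically stretched circular arc with a vertical tangent at the equator,
  reaching the bladder-neck (BN) opening (width TD-BN) at depth exactly 5.0.
  The arc meets the PU wall in a re-entrant corner: the zero-thickness neck
  forms a sharp lip. We also implemented a tangential (C1) neck as a
  sensitivity variant; it suppresses flow separation almost everywhere and
  was rejected — the corner is the modelling choice consistent with the
  observed vortex behaviour.
* **Prostatic urethra**: one parabolic arc per side spanning from the BN
  plane (half-width TD-BN/2) to the prostate-apex plane (half-width 0.3),
  vertical extent LD-PU. The third width constraint TD-PU is applied at the
  parabola's vertex (the widest station) when TD-PU ≥ TD-BN, and at the PU
  mid-height when TD-PU < TD-BN, which yields the trapezoid-like tapering
  shapes at small ratios. A parabola is the conic that admits a
  single-valued, positive solution across the whole parameter box.
* **Distal urethra** ("rest of the urethra", RU): a straight 0.6 × 15.7
  channel ending at the external urethral orifice (EUO).

The cohort is the full factorial array: LD-PU ∈ {3.6, 3.8, 4.0},
TD-BN ∈ {2.6 … 3.4}, TD-PU ∈ {2.0 … 4.6 step 0.2} — 210 cases. The index
case (LD-PU 3.8, TD-BN 3.0, TD-PU 4.2) is `geometry.cats_first()`. The two
diameter ratios are RPU-1 = TD-PU/TD-BN and RPU-2 = RPU-1/LD-PU with LD-PU
in millimetres (the mm scale is what puts RPU-2 on its conventional
0.02–0.04 range). Anterior bending of the urethra is deliberately ignored;
the outline is the maximal coronal lumen profile.

## Meshing

The lumen half-width is single-valued in the vertical coordinate, so meshing
proceeds by horizontal strips: graded rows of points across the local width,
each band triangulated by an x-ordered merge march. The generator is fully
deterministic and needs no external mesher. Sizing rules:

* nominal cell size fitted iteratively to the requested element budget
  (±15 % accepted, ±10 % targeted);
* at least 8 cells across the RU at study budgets (≥ 12k elements),
  degrading to 6 and 4 at coarse screening budgets;
* row spacing capped at aspect 1.6 and tightened where the wall slants;
* the PU band is refined ×2 with additional ×3.2 spots at the BN and apex
  lips. The lips anchor the separating shear layers; resolving them
  consistently is what keeps the computed recirculation sizes stable
  between element budgets (without it TD-V wobbled 4–8 % between the grid
  budgets; with it, < 0.5 %);
* per-element minimum angle ≥ 15° (checked in tests across the array).

Production solves use the right half-domain with a symmetry plane on the
axis; element budgets are always quoted as full-domain equivalents (a half
mesh carries half the elements at the same resolution). Full-domain meshes
remain available and are used for the mirror-symmetry cross-checks.

## Flow solver

Cell-centered finite-volume discretization of the steady incompressible
RANS equations on triangles:

* SIMPLEC pressure–velocity coupling with Rhie–Chow face-flux
  interpolation; the pressure-correction matrix uses the SIMPLEC
  denominator floored at 5 % of the momentum diagonal;
* convection: first-order upwind matrix plus a deferred second-order-upwind
  correction (blend 0.5); diffusion: over-relaxed orthogonal split with
  explicit non-orthogonal correction; least-squares cell gradients
  (Green–Gauss with boundary values for pressure);
* turbulence: RNG k–ε (Cμ = 0.0845, C1ε = 1.42, C2ε = 1.68,
  σk = σε = 0.7194, η0 = 4.38, β = 0.012) with equilibrium wall functions
  (log law, y\*-crossover 11.225); standard k–ε and a laminar mode are
  available for sensitivity and validation runs;
* boundary conditions: static gauge pressure 4958.8 Pa at the inlet (with
  the inflow direction constrained normal to the boundary, applied
  implicitly), 0 Pa at the outlet, no-slip walls, free-slip symmetry plane;
  inlet turbulence from 5 % intensity and the inlet hydraulic diameter;
* fluid: ρ = 1035 kg/m³, μ = 0.8583×10⁻³ Pa·s (urine at 37 °C); gravity
  neglected.

Steady segregated iteration on this geometry is genuinely hostile: the
outlet Reynolds number is ≈ 2×10⁴, the BN jet is bistable (Coanda), and the
pressure inlet sits on a near-stagnant reservoir. The shipped configuration
stacks the standard defensive measures:

* cosine ramp of the driving pressure over the first 120 iterations;
* pseudo-transient continuation: an implicit local-time-step term
  ρV/Δτ with Δτ = CFL·ℓ/(|u|+0.05·u_ref), CFL annealed from 5 toward 500
  and cut on residual spikes;
* a rollback guard that snapshots the best state seen and restores it
  (with deepened damping) when the scaled continuity residual spikes;
* warm starts between meshes/cases: fields are interpolated in physical
  coordinates except across the re-entrant corners, where
  lumen-normalized coordinates prevent the interpolant bridging the notch;
  warm runs begin with a damped first-order "settle" phase (250
  iterations, α_u = 0.3, α_p = 0.15) that is released smoothly;
* under-relaxation α_u = 0.7, α_p = 0.5 (raised to 0.8 after a sustained
  quiet spell), α_t = 0.6; inlet/outlet face fluxes under-relaxed by 0.5;
* linear solves by BiCGStab preconditioned with periodically refreshed
  sparse LU factorizations; each inner solve only reduces its own initial
  residual tenfold (pressure: hundredfold).

Convergence is declared at scaled residuals ≤ 10⁻⁵ (momentum and
continuity) and ≤ 10⁻⁴ (turbulence), capped at 5000 outer iterations;
non-converged runs are returned flagged, never silently used. Converged
solutions satisfy global mass balance to ≤ 10⁻³ (typically ≪ 10⁻⁶).

## Observables

* **MV-EUO**: velocity magnitude linearly interpolated at the outlet
  midpoint (nodal velocities by volume-weighted cell averaging, no-slip
  nodes pinned to zero).
* **Streamfunction**: the conservative face fluxes define ψ differences
  along every mesh edge; ψ is integrated by a least-squares graph solve.
  Walls and the symmetry axis are ψ-isolines; the inlet–outlet jump equals
  the volumetric flux.
* **Vortices**: a side recirculation zone is the connected node set inside
  the PU whose ψ lies beyond that side's wall value (past the separatrix),
  with sub-cell refinement of the region boundary by interpolating the
  separatrix crossing along mesh edges. Regions narrower than 2 local cell
  diameters are discarded as noise. TD-V/LD-V are the axis-aligned extents
  of the region; the reported values are means over the two sides (on the
  symmetric half-domain the mirror side is identical by construction).
  The transverse-velocity sign-reversal profile is available as an
  independent diagnostic (`velocity_profile`).

## Cohort statistics

Medians and IQRs use linear interpolation between order statistics. The
Mann–Whitney U test is two-sided; exact for tie-free samples with a side of
≤ 8, tie-corrected normal approximation otherwise (cross-checked against a
brute-force enumeration oracle in the tests). Vortex-size regressions are
ordinary least squares per LD-PU group. Vortex thresholds are the minima of
RPU-1/RPU-2 over the vortex-positive stratum with the nearest negative
neighbours reported for context. Non-converged cases are excluded from the
statistics but counted and reported.

## Problem sizes

The shipped studies use these resolutions, chosen as the package's own
screening/production split:

* grid-independence ladder and the index-case report: full-domain
  equivalents 2.5k → 6k → 13k → 18k → 25k → 35k elements,
  coarse-to-fine warm cascade; the headline index-case numbers are read at
  the 25k budget (the window the grid study singles out);
* the 210-case cohort sweep: 5k full-domain-equivalent elements per case
  in the shipped acceptance suite (warm-chained within each subgroup,
  settle phase replaced by a low initial pseudo-transient CFL); a 6k
  reference sweep was used to validate that the 5k flags agree except for
  the very smallest near-onset bubbles. The PU refinement keeps near-onset
  recirculation bubbles resolved at these budgets; coarser screening
  budgets (≤ 2.5k) misclassify near-onset cases as vortex-free and are
  used only for smoke tests.

## What the generator does and does not emulate

The geometry generator produces exactly the idealized study shapes — it is
the study's synthetic-data source, not a patient-imaging pipeline. Passing
tests therefore demonstrate faithful reproduction of the idealized-model
results, not validity for real urethral anatomy: real lumina are
three-dimensional, curved, elastic, and asymmetric, and voiding is
transient. Within the idealization, the known fidelity caveats are the
wall-function near-wall treatment (no boundary-layer prisms, matching the
study's meshing stance), the steady-RANS treatment of a flow with weakly
unsteady separated zones, and the unrecoverable details of the original CAD
outline (our parabolic/elliptic-arc family is one defensible
reconstruction).

## Known limitations

* The laminar mode does not converge at the physiological driving pressure
  (the flow is genuinely turbulent); it exists for low-Reynolds validation.
* Vortex onset is resolution-dependent near the threshold: budgets below
  ~4k full-domain equivalents suppress the smallest bubbles.
* The solver is 2D-planar only; no fluid–structure interaction; Newtonian
  rheology.
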