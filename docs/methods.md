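# Methods

## Physical model

The choriocapillaris is treated as a Hele-Shaw cell: a slab of thickness
`h` (10–30 µm) bounded by parallel sheets, perfused through round
arteriolar and venular openings (10–25 µm diameter) inserting
perpendicular to the plane.  At the measured in-vivo speeds the reduced
Reynolds number `Re (h/L)² ~ 1e−5` is negligible, so the depth-averaged
velocity obeys the lubrication relation `u_h = −(K/μ)∇p` with permeability
`K = h²/12`.  Openings act as point sources/sinks; superposition gives the
rational complex velocity `w(z) = Σ k_i/(z − z_i)`, whose complex
*conjugate* is the physical vector field.  The conjugation convention is
applied consistently: it makes the Jacobian at a zero of `w` symmetric and
trace-free, so every simple zero is an orthogonal-axis hyperbolic saddle
of index −1, as required for a gradient flow.

All computations are nondimensional: lengths by the mean arteriole–venule
spacing `L`, velocities by the blood speed `U`, times by `L/U`.  The
defaults (`L = 600 µm`, `h = 15 µm`, `U = 1 mm/s`, `μ = 3 mPa·s`,
`Φ = 0.3`) are configuration values, not constants baked into any
computation.  `U` is kept configurable deliberately: published in-vivo
estimates vary by a factor of a few, and only the time scale `L/U` depends
on it.  The strength convention is `w = Σ k_i/(z − z_i)` (no `1/2π`), so
the volumetric flow of opening *i* is `Q_i = 2π k_i h` and the pressure
consistent with `u_h = −(K/μ)∇p` is `p = −(μ/K) Σ k_i ln|z − z_i|`.

Intercapillary collagenous posts are never inserted as discrete obstacles.
On the sphere each post hole contributes two half-crosspoints that cancel
its Euler deficit, so the topology is post-independent; in transport the
posts enter only through the perfused fraction `1 − Φ`, which rescales
segment volume and hence every travel time.

## Stagnation points and topology

Finite saddles are the roots of the numerator polynomial
`P(z) = Σ_i k_i Π_{j≠i}(z − z_j)`.  The polynomial is assembled in a
centred, radius-normalised coordinate frame (companion matrices of
high-degree polynomials with off-centre clouds are badly conditioned — on
a 3×3 honeycomb patch the raw roots carry O(1) residuals and Newton
polishing then collapses distinct roots); roots are mapped back, polished
by Newton iteration on `w` itself, merged within `1e−9` into multiple
zeros, and accepted at residual `|w| ≤ 1e−10`.

Flux balance makes the leading coefficient vanish exactly, leaving `N − 2`
finite zeros in generic position.  Symmetric configurations (perfect
lattices, the symmetric quadrupole) also cancel low multipole moments:
each additional vanishing moment sends one saddle to the point at
infinity.  The topology report therefore computes the infinity-saddle
multiplicity from the numerically trimmed polynomial degree and records it
(`N_s_infinity`) instead of hiding it, and the counting identity
`N_a + N_v = N_s + 2` is checked with that bookkeeping: the node at
infinity is added for unbalanced sets, and saddle weight at infinity for
degenerate balanced ones.  Degenerate (multiplicity > 1) finite zeros are
reported, never silently split; a seeded jitter option (default off,
`1e−6 L`) restores genericity when wanted.

## Separatrices and segments

Separatrix branches are seeded `1e−6 L` along the saddle eigendirections
and integrated at unit speed (arclength parametrisation: the travel *time*
into a saddle diverges, the arclength does not) with an adaptive RK45
(`rtol 1e−10`, step ≤ 0.05 L) until they enter an opening's capture disc —
the opening radius `a`, inside which the continuum model is invalid
anyway — or cross the bounding circle outward.  Unstable branches run
forward into venules and form segment boundaries; stable branches run
backward toward arterioles.

Polylines are snapped to the saddle and terminal opening centres, so the
arrangement is exactly noded; shapely's `polygonize` then yields the
faces, each assigned to the arteriole it contains.  A face claimed by more
than one arteriole means part of its boundary is not a finite-saddle
manifold (it runs through a saddle at infinity, as in perfectly symmetric
benchmarks); such territories are reported unresolved rather than guessed.
An optional clip circle closes otherwise-unbounded outer territories.

Interior angles at venular vertices are measured between the tangents of
the two incident separatrices, each averaged over the last five polyline
points.  The convention measures at the opening centre; the averaging
suppresses integration noise at the tiny lever arm of the capture rim, and
the residual bias scales with boundary curvature (interior cells of a 3×3
lattice give `α = π/2` to ~3e−4 rad; their edges are very slightly curved
because a finite lattice is not its infinite limit).

Flow partition releases rays uniformly in rim angle and assigns each to
the venule its streamline reaches.  Because the finite rim radius exposes
the O(a) background field of the other openings, samples are weighted by
the actual radial rim velocity; this makes all averages exactly
flux-weighted (on an isolated source the weights are uniform).  Without
the weighting the segment-mean travel time shows a reproducible bias of
order `a` (~1 % at `a = L/60`).

## Travel times and extraction

The ensemble tracer advances all corpuscles together with classical RK4
and a per-particle step `Δt = 0.1 · d/|u|`, where `d` is the gap to the
nearest opening floored at half its radius (so trajectories cross into
capture discs instead of stalling on their rims — a Zeno trap otherwise),
additionally limited by the local strain rate `0.1/|w′|` near saddles and
by the bounding circle.  The travel-time cap defaults to 50× the
residence estimate `A₀/Q_a`; truncated samples (separatrix-adjacent
releases, whose true time diverges) enter the extraction average at the
cap value, a bias below `e^(−50)` relative for the τ regime of interest.

Extraction per corpuscle is the first-order decay `e^(−T/τ)` with
`T = (1 − Φ) T₀`; the segment extraction is the flux-weighted mean
`η = 1 − ⟨e^(−T/τ)⟩`, reported alongside the second-order expansion
`⟨T⟩/τ − ⟨T²⟩/2τ²` whose second term quantifies mechanical dispersion.
The residence identity `⟨T⟩ = (1 − Φ) A₀ h/Q_a` is the backbone linking
extraction to geometry and is verified by Monte Carlo on every closed test
segment within three standard errors (small known corrections — the
excluded source and sink discs, ~0.3 % combined at the default radius —
are far below that resolution).

`estimate_tau` inverts the single-transit relation exactly,
`τ = −⟨T⟩_measured / ln(1 − η_measured)`, returning the range in seconds
and nondimensionally via `L/U`.  With an oxygen/glucose extraction of
1–5 % per pass and a measured lobule transit of ~0.118 s this gives
`τ ≈ 2.4–12 s`; the inversion is deliberately kept to the stated
single-transit first-order model, with no hidden substance-specific
factors.

## Shape–extraction scan

Prism segments are decomposed into isosceles triangular portions of apex
angle `ω` with unit legs (the arteriole–venule distance); a regular
`n̂`-gon has `ω = 2π/n̂`, so `ω = π/2` is the square.  The scan holds the
flow through the portion and `τ` fixed, with equal (zero) venular
pressures, and varies only `ω`.

The portion flow is computed exactly by a Schwarz–Christoffel map of the
triangle onto the upper half-plane: prevertices 0 (apex) and ±1 (base
corners), `f′(ζ) = C (ζ+1)^(δ/π−1) ζ^(ω/π−1) (ζ−1)^(δ/π−1)` with
`δ = (π − ω)/2` and the closed-form normalisation
`C = 2/B(ω/2π, δ/π)` fixing unit legs.  The half-plane potential is a
boundary source at the apex preimage and half-sinks at ±1; trajectories
are integrated in the map plane, where the field is trivial, and physical
time accumulates with the Jacobian `|f′|²`.  Sharp base corners compress
the preimage of the physical capture disc below machine precision, so
capture stops at a floored map radius and the analytic corner-sink
remainder (radial inflow `q/2` through angle `δ`) completes the time —
the tracer then reproduces `⟨T⟩ = sin(ω)/2 / q` across the whole `ω`
range to within Monte-Carlo error.  Releases are stratified in angle and
the scan reuses one seed across `ω` (common random numbers), so the
argmax comparison is paired and stable at moderate sample sizes.  At
leading order `η ∝ A₀(ω) = sin(ω)/2`: the square maximises extraction,
and the simulation confirms the maximum at `ω = π/2` within grid
resolution for the whole physiological τ band.

## Dye angiography

The passive scalar obeys `∂C/∂t + u_h·∇C = D∇²C` on a regular mesh
clipped to a no-flux circle, with the analytic velocity evaluated at cell
faces and speeds capped at the rim speed of the smallest opening.  The
scheme is conservative finite-volume donor-cell upwinding plus explicit
central diffusion, operator-split, with `Δt` at 0.4× the tighter of the
advective and diffusive stability limits.  A finite-volume discretisation
replaces finite elements deliberately: the model specifies the PDE,
boundary and forcing, not the element type, and the grid-convergence test
(halving the spacing changes the 50 %-arrival map by ≤ 5 % in L1) guards
the substitution.  Arteriolar discs are Dirichlet `C = C₀` while the
double-Heaviside inlet is on and `C = 0` after switch-off; venular discs
absorb advected dye with diffusion through their faces disabled (no
diffusive re-entry).  The mesh must resolve the smallest opening with ≥ 4
cells across its diameter, or the run is refused.

The diffusivity is a configuration value: the physiological Péclet number
`UL/D` for small solutes is 10³–10⁴, and the default `D = 2e−3` (Pe 500)
sits at the diffusive end of that range so that benchmark runs at
128²–256² resolve the separatrix boundary layer.  The two-source
benchmark places equal sources at (±1, 0) and equal drains at (0, ±2):
mirror symmetry pins the inter-segment separatrix to the y-axis, which a
closed no-flux domain requires (a pure two-source configuration has no
sink to balance it).  On this benchmark the 50 %-threshold arrival time at
the separatrix exceeds the mid-segment arrival severalfold and the
latest-arrival ridge sits within half a grid cell of the traced
separatrix.

## Synthetic data

The generators stand in for histological opening maps.  The random
scatter draws positions uniformly in a disc under a minimum-separation
constraint (rejection sampling, seeded, bitwise reproducible), with equal
or randomised strengths rebalanced to zero net flux; defaults
(`min_separation = 0.4 L`, opening radius `a = L/60`) reflect the
measured opening sizes and spacings.  Lattice generators produce the
idealised square and honeycomb geometries with unit arteriole–venule
distance; venular strengths are weighted by the number of cells sharing
each vertex so a finite patch reproduces the infinite-lattice flow in its
interior, and the bulk opening ratio (venules counted by drainage share)
equals the infinite-lattice value exactly.  What the generators do not
emulate: clustering of openings, spherical curvature of the eye,
non-axisymmetric arteriolar inflow, and spatial gradients of opening
density across the fundus — so passing tests demonstrate the flow and
transport theory on idealised boundary data, not fidelity to any
particular tissue sample.

## Problem sizes and known limitations

Default test and acceptance sizes — 50 random configurations of 4–20
openings, 3×3 lattice patches, 10⁴ corpuscles per travel-time
distribution, 2×10³ per scan point, 256² dye grids — were chosen as the
smallest sizes at which the Monte-Carlo standard errors are comfortably
below the effects being measured.

Limitations: corpuscle velocities equal the mean bulk velocity (no
size-dependent slip); exchange kinetics are a single first-order constant
(no substance-specific transporters or binding); post-scale trajectory
effects are averaged into `Φ`; the planar embedding ignores the spherical
geometry of the globe; and territories bounded through saddles at
infinity in exactly symmetric configurations are reported unresolved
rather than tessellated.
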