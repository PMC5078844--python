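# chorioflow

Segmented blood flow, Lagrangian transport and simulated dye angiography in
the **choriocapillaris** — the planar capillary monolayer that sustains the
outer retina.

Unlike branched vascular trees, the choriocapillaris is a thin slab of
wide, flat capillaries fed by arterioles and drained by venules that insert
perpendicular to its plane.  `chorioflow` models this bed as a multipole
Hele-Shaw flow: each arteriolar opening is a point source of strength
`k_i > 0` and each venular opening a point sink (`k_i < 0`), giving the
complex velocity

```
w(z) = Σ_i k_i / (z − z_i),        u_h = conj(w) = −(K/μ) ∇p,   K = h²/12
```

with lengths scaled by the arteriole–venule distance `L` and velocities by
the in-vivo blood speed `U`.  From this field the package computes:

- **Topology** — stagnation (saddle) points as roots of the numerator
  polynomial of `w`, and the sphere counting identity
  `N_a + N_v = N_s + 2` (nodes have Poincaré index +1, saddles −1; a net
  flux imbalance books the point at infinity as one extra node, and
  lattice-type symmetries can place saddles *at* infinity, which the
  topology report records explicitly).
- **Functional vascular segments** — separatrices traced from each saddle
  tessellate the plane into one drainage territory per arteriole, bounded
  by surfaces joining venular openings across which no blood flows.  A
  prism (straight-sided) segment with `n̂` venular vertices obeys
  `N_a/N_v = 2/(n̂ − 2)` and partitions its inflow among the vertices in
  proportion to the interior angles, `Q_a/⟨Q_v⟩ = Σ_k α_k / 2π`.
- **Travel times and mass extraction** — corpuscles advect at the mean
  bulk velocity; flux-weighted Monte-Carlo travel times satisfy the
  residence identity `⟨T⟩ = (1 − Φ) A₀ h / Q_a` (`Φ` = collagenous-post
  volume fraction), and a first-order exchange with time constant `τ`
  gives the extraction `η = 1 − ⟨e^(−T/τ)⟩ ≈ ⟨T⟩/τ − ⟨T²⟩/2τ²`.  Scanning
  prism shapes through their apex angle `ω = 2π/n̂` at fixed flow shows
  `η` is maximal for the **square** segment (`ω = π/2`).
- **Dye angiography** — 2-D advection–diffusion of a passive tracer under
  a double-Heaviside inlet schedule reproduces the angiographic mosaic:
  segment interiors fill fast, separatrices fill last (transport there is
  diffusion-limited).

## Worked example

```python
import chorioflow as cf

cfg = cf.generate_random_openings(n_a=4, n_v=6, seed=7)
report = cf.verify_euler_relation(cfg)
print(report.to_dict())
# {'N_a': 4, 'N_v': 6, 'N_s': 8, 'chi': 2, 'n_d': 0,
#  'infinity_node': None, 'N_s_infinity': 0, 'satisfied': True}

segs = cf.build_segments(cfg)
seg = [s for s in segs if s.bounded][0]
dist = cf.travel_time_distribution(cfg, seg, n_particles=10_000, seed=22)
print(round(dist.mean, 4), round(seg.area_0 / dist.q_a, 4))
# 0.6395 0.6347   (Monte-Carlo mean travel time vs area/inflow)

res = cf.mass_extraction(dist, tau=100 * dist.mean, phi=0.3)
print(round(res.eta_exact, 6), round(res.eta_asymptotic, 6))
# 0.006969 0.006969
```

The ten openings generate exactly `N_s = N − 2 = 8` saddles; the traced
segment's mean corpuscle travel time reproduces its area divided by the
arteriolar inflow within Monte-Carlo error; and the asymptotic extraction
formula agrees with the exact flux-weighted average to well under 1 % in
the slow-exchange regime.

A command-line pipeline wraps the same library:

```bash
chorioflow segment  --config run.json --seed 7 --out out/
chorioflow dye      --config run.json --seed 7 --out out/
chorioflow report   --artifacts out/ --out figs/
```

`run.json` holds the input block (generator or opening-map CSV), the
physical block (`L`, `h`, `phi`, `mu`, `U`, `D`) and solver settings;
unknown keys are rejected.  Opening maps are plain CSV
(`id,kind,x,y,strength,radius`); segments export as GeoJSON.

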