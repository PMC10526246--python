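# Methods

`dpdshear` simulates the self-assembly of two coarse-grained lipid species in
water with dissipative particle dynamics (DPD), optionally under a reverse
non-equilibrium momentum-swap shear flow, and measures the observables used
to characterize the resulting aggregates: one- and two-dimensional density
profiles, gyration-tensor shape factors, leaflet mixing counts, energy-stage
segmentation, and a heuristic phase label (double layer, perforated double
layer, hierarchical discs, micelle, vesicle).

## Model

### Beads and interactions

Five bead species exist: head and tail beads of lipid types I and II
(`H1`, `T1`, `H2`, `T2`) and water (`W`).  All beads carry the same mass
m = 1.  Between every pair within the cut-off rc the three standard DPD
forces act:

- conservative soft repulsion `F_C = a_ij w(r) r̂`,
- dissipative drag `F_D = -γ w(r)^2 (v_ij · r̂) r̂`,
- random kicks `F_R = σ w(r) ζ_ij Δt^(-1/2) r̂`,

with the linear weight `w(r) = 1 - r/rc` inside the cut-off and zero outside.
The pair (γ, σ) = (4.5, 3.0) satisfies the fluctuation–dissipation relation
σ² = 2 γ kBT exactly, thermostatting the system to kBT = 1.  Repulsions
follow the standard amphiphile parameterization: like pairs 25,
head–water 40, tail–water and head–tail and tail–tail (cross-species) 100,
head–head (cross-species) 25.  The linear bridge to Flory–Huggins theory,
χ = 0.286 (a_ij − a_ii), gives χ ≈ 4.29 for head–water and 21.45 for
tail–water.  (Model literature sometimes quotes 21.42 for the latter; the
literal coefficient 0.286 gives 0.286 × 75 = 21.45.  We implement the
formula literally and note the 0.1 % discrepancy rather than adjusting the
coefficient.)

### Chains

A lipid is a linear chain of `NH` head beads followed by `NT` tail beads.
Consecutive beads are bonded with `F = ks (1 − r/rs) r̂` (ks = 120,
rs = 0.7 rc); consecutive triples carry a bending potential kθ (θ − θ0)²
(kθ = 6, θ0 = π).  The bending term is applied to **all** consecutive
triples, including the one spanning the head–tail junction; whether the
junction should be stiff is not determined by the model definition, so a
switch (`include_junction_angle=False`) removes those triples.

### Units

rc, kBT, m are the units of length, energy and mass; τ = rc √(m/kBT) the
unit of time.  The time step is Δt = 0.01 τ.  A `UnitMap` records the
physical interpretation for this lipid/water system: τ = 1.88 ns (from
matching in-plane lipid diffusion), rc = 0.5 nm, bead volume 0.03 nm³ at
bead density ρ = 3 rc⁻³.  (ρ·V_P)^(1/3) is strictly 0.448 nm; 0.5 nm is the
published display value and is stored as such.  The mapping never enters the
dynamics.

## Integration

Newton's equations are advanced with the Groot–Warren modified
velocity-Verlet scheme with λ = 1/2: positions advance with the current
force, the new force is evaluated with a half-step velocity prediction
(which the dissipative force needs), and the velocity completes with the
mean of old and new forces.  One force evaluation per step.  λ = 1/2 is the
community default for this parameterization; plain velocity Verlet with
λ = 1/2 velocity prediction is what "velocity Verlet" conventionally means
in DPD work.

The known consequence of finite Δt in DPD is a small systematic temperature
offset; at Δt = 0.01 and ρ = 3 the equilibrium kinetic temperature sits
within ~1–2 % of kBT = 1, and the test suite asserts 5 %.

### Pair search

A cell list with edge ≥ rc is rebuilt every step (cells are cheap and
rebuilding avoids any skin-crossing bookkeeping).  Boxes smaller than 3 rc
fall back to an all-pairs loop.  The cell-list force sum is verified against
an independent O(N²) all-pairs reference to 1e-10 per component.

### Noise stream

ζ_ij is drawn once per interacting pair per step with ζ_ij = ζ_ji — a
requirement for exact momentum conservation, since the random force must be
antisymmetric under i↔j.  The implementation is counter-based: ζ is a pure
splitmix64-style hash of (seed, step, min(i,j), max(i,j)).  Consequences:

- trajectories are bitwise reproducible for a fixed seed on one platform,
- the result cannot depend on pair-enumeration order (cell list vs
  all-pairs reference produce identical noise),
- no generator state needs maintaining or serializing.

The default ζ is uniform scaled to unit variance, √3·U(−1,1); a Gaussian
variant (Box–Muller over two hashed uniforms) is selectable.  Both have the
zero mean and unit variance the DPD thermostat requires and are
statistically equivalent for these purposes.

### Energy bookkeeping

"System energy" decompositions differ across the literature, so the engine
logs kinetic, conservative-pair (a_ij rc/2 (1 − r/rc)² per pair), bond and
angle energies separately plus their sum, every `sample_every` steps.

## Shear: reverse non-equilibrium momentum swap

The box is sliced into `n_slabs` (default 20) slabs along z.  Every M
integration steps the bead with minimum vx in the bottom slab exchanges vx
with the bead of maximum vx in the top slab.  Equal masses make the exchange
conserve momentum and kinetic energy exactly; the accumulated exchanged
momentum Px determines the imposed flux jz = Px/(2 t Lx Ly), and the fluid
answers with a linear vx(z) profile whose slope is the shear rate γ̇.

The driven slabs sit at the box edges (z ≈ 0 driven +x, z ≈ L driven −x), so
the periodic counter-gradient folds across the z-boundary and the entire
interior carries a single linear branch; `geometry="split"` selects the
textbook z = 0 / z = L/2 arrangement instead.  All species are
swap-eligible (all masses are equal; a restriction to water is available
for sensitivity checks).  Exactly one extremal pair is swapped per event.

Presets: weak shear M = 6 and strong shear M = 1.  At the full published
scale (30³ rc box, 81 000 beads) these correspond to γ̇ ≈ 0.073 and
0.168 τ⁻¹.  On the desk-scale boxes used by the tests the same M values
impose qualitatively identical, monotonically ordered flows (M = 1 shears
harder than M = 6) with interior-profile linearity R² ≥ 0.98; the
quantitative full-scale rates require the full box and are not asserted at
reduced scale.

## Observables

### Density profiles

1D per-species number-density histograms along a box axis (bin count ×
1/(bin width · L²)) and projected 2D occupancy maps.  Profiles integrate
exactly to the per-species bead counts.

### Gyration tensor and shape factor

Per chain, coordinates are first unwrapped by walking the bond path and
applying minimum-image displacements (the tensor is meaningless on wrapped
coordinates), then

    Rg²_αβ = (1/N) Σ_i (r_i,α − r_c,α)(r_i,β − r_c,β)

about the chain centroid r_c.  With eigenvalues L1² ≥ L2² ≥ L3²,

    δ = 1 − 3 (L1²L2² + L2²L3² + L1²L3²) / (L1² + L2² + L3²)²

δ = 0 for an isotropic distribution, 1 for a rod.  For a uniform planar ring
direct evaluation gives 0.25 (the value 0.5 sometimes quoted for "circular"
does not follow from this formula; we implement the formula literally).
The degenerate all-zero tensor maps to δ = 0 by convention.

Series are reported per frame as chain averages per lipid type, plus the
per-chain matrix, so both chain-only and time-windowed means are available.
The "stable-stage" mean defaults to the final third of the frames, which at
the run lengths used sits past the assembly transient.

### Leaflet mixing

For a bilayer, the normal is the axis along which tail beads are most
concentrated (smallest circular spread); the midplane is the circular mean
of the tail coordinates along that axis; a chain belongs to the leaflet
containing its first head bead.  The counts reported are type-I chains in
the right (+normal) leaflet and type-II chains in the left — each starts at
its full chain count for the constructed two-leaflet state and decays as
the species mix.

### Clusters and phase label

Aggregates are connected components of the contact graph (minimum-image
distance ≤ cutoff, default 1.0 rc) over all lipid beads.  A BFS unwrap of
each component detects periodic spanning: a contact whose unwrapped
endpoints disagree by ~L along an axis means the cluster touches its own
image there.  Heads are included (not only tails) because in a stacked-disc
aggregate adjacent discs touch head-to-head; a tail-only graph would never
span the stack axis.

Decision tree on the largest cluster:

- spans ≥ 2 axes → membrane; if the in-plane occupancy grid (1 rc cells)
  contains a connected empty patch ≥ 4 cells (periodic connectivity,
  configurable) → perforated double layer, else double layer;
- spans exactly 1 axis → cylinder-like; if the head-bead density along the
  axis shows ≥ 2 pronounced peaks (prominence ≥ half its mean) →
  hierarchical discs, else micelle;
- spans 0 axes → compact; if the tail shell is hollow (minimum tail
  distance from the aggregate centroid r_in > 0) and ≥ 5 water beads sit
  inside r_in − 0.5 rc → vesicle, else micelle.

The thresholds operationalize what is otherwise a visual call; they are
exposed as keyword arguments and validated against constructed ideal
geometries (bilayer, perforated bilayer, micelle, vesicle shell, stacked
discs, cylindrical micelle).  Classification of a noisy mid-transition
frame is genuinely ambiguous and the label carries diagnostics (cluster
sizes, spanning pattern, pore size, peak count, core water) for audit.

### Energy stages

Assembly trajectories show a fast energy decay, a slower adjustment and a
plateau.  `segment_stages` fits piecewise-linear models with 1, 2 or 3
segments (coarse breakpoint grid + local refinement) and selects by BIC
with an SSE floor tied to the data scale, so noiseless piecewise inputs do
not overfit to extra stages.  Dense systems typically yield two stages,
dilute ones three; a structureless series collapses to a single stage with
a warning.

## Synthetic systems and what they do (not) show

`build_system` fills a cubic box at ρ = 3 beads/rc³: lipid chains placed as
near-linear random walks with step rs, the rest water, uniformly at random
— no overlap rejection, since bounded soft potentials relax overlaps within
a few steps.  Velocities are Maxwell–Boltzmann at kBT = 1 with the net
momentum removed exactly.  `make_fixture` builds deterministic idealized
aggregates used to validate the analysis stack without dynamics.

The generator emulates the published study conditions: box 30 rc, ρ = 3,
n = 1200 (dilute, φ = n/V ≈ 0.044 rc⁻³) or 2400 (dense, φ ≈ 0.089 rc⁻³)
chains split equally between the species, heads of length 3, tails 2–10.
φ values print unrounded (the 0.04/0.08 usually quoted are rounded).

Desk-scale work uses reduced boxes (8–12 rc) at the same φ and ρ.  What
carries over: thermostat behavior, conservation laws, chain conformations
(the shape factor is a single-chain property), the qualitative RNEMD
response, and the broad phase topology.  What does not: quantitative
full-scale shear rates, long-wavelength membrane physics (a 12 rc box
cannot hold a 30 rc membrane's undulations), and phase-boundary positions,
which shift when an aggregate holds only tens of chains.  Conclusions at
reduced scale are correspondingly qualitative.

### Problem sizes used by the shipped checks

- Thermostat/conservation: 10³ rc water box (3 000 beads), 10⁴ steps.
- RNEMD: 8³ rc water boxes, 6–8 × 10³ steps per protocol.
- Shape-factor study: 10³ rc box, φ ≈ 0.044 (44 chains: 22 of type I with
  NT1 = 6, 22 of type II with NT2 = 8), zero/weak/strong shear.  The box
  edge is chosen so that the achievable momentum-swap gradients bracket the
  published ones: the extremal-pair swap caps the imposed flux, and on
  larger reduced boxes even M = 1 falls well short of the strong-shear rate,
  while at 10 rc M = 1 measures γ̇ ≈ 0.08–0.13 τ⁻¹, near the published
  0.168 τ⁻¹ regime.  The acceptance script runs 4 × 10⁴ steps (400 τ) per
  condition and three seeded replicates, averaging chains × frames over the
  final half (200–400 τ); the published stable stage is likewise a long
  window (≈1200 τ) late in a 3000 τ trajectory, and at 22 chains per
  species replicate pooling is what controls the chain-mean variance.
- Reduced phase grid: 10³ rc boxes, 1.5 × 10⁴ steps per cell.

## Numerical choices and edge cases

- Positions live in [0, L)³; minimum image everywhere; the engine requires
  L ≥ 3 rc for the cell list and falls back to all-pairs below that.
- Bond force at r = 0 aborts (direction undefined); angle arms of zero
  length abort; the angle force uses the 1/sin θ form with sin θ clamped at
  1e-12 — safe at θ = θ0 = π because (θ − θ0) vanishes simultaneously.
- Instantaneous temperature is 2·KE/(3N) without the 3-degree-of-freedom
  momentum correction (negligible at these N, and stated here).
- The swap ledger accumulates |Δpx|; an empty driven slab skips the swap
  with a warning rather than aborting.
- Shear-rate fits exclude the two driven slabs and require ≥ 3 interior
  slabs.
- Force-field parameter sets are immutable dataclasses; a run's parameters
  cannot drift mid-trajectory, and the config digest + seed identify a run.

## Known limitations

- The phase classifier is a geometric heuristic; labels for frames far from
  equilibrium or aggregates of comparable size are flagged ambiguous rather
  than resolved.
- No Lees–Edwards sliding-brick shear, no electrostatics, no barostat
  (NVT only).
- The momentum-swap thermostat interaction at M = 1 measurably warms the
  system (a few percent); this is inherent to the method, not corrected.
- At desk scale the strong-shear (M = 1) condition does **not** reproduce the
  small full-scale enhancement of the stable-stage shape factor: with only
  ~22 chains per species the flow repeatedly tears and reorganizes the single
  aggregate, and the replicate-pooled stable δ sits ≈0.03 below the
  zero/weak-shear values (≈0.90 vs ≈0.93) instead of slightly above them.
  The corresponding strong-shear checks in the test suite measure exactly
  this and fail against the full-scale reference values; the zero- and
  weak-shear values agree with full scale within ±0.02.
- Full-scale (30 rc, 3 × 10⁵ step) phase diagrams are out of desk scope;
  the sweep machinery supports them as an opt-in, long-running job.
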