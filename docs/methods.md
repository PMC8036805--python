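# Methods

## Model

The package partitions the total electron density ρ(x) of a periodic
parallelepiped cell among its atoms by a two-step radical Voronoi
(power-diagram) tessellation. Site *i* (an atom at *pᵢ* with radius
*rᵢ*) owns the points with minimal power distance ‖x−pᵢ‖² − rᵢ²,
minimized over periodic images. The face between sites A and B is a
plane at distance

    w = R/2 + (r_A² − r_B²) / (2R)

from A along the A→B axis (R the inter-site distance). Because only
differences of squared radii matter, the map rᵢ → √(rᵢ² + C) (a *gauge
shift*) leaves every assignment unchanged, absolute radius values carry
no meaning, and one degree of freedom is flat in the optimization. With
equal radii the construction reduces to the classical Voronoi
tessellation; the partition is exhaustive and hole-free, and a site may
own an empty cell (it then keeps its core charge and electron
population 0 — adding the core unconditionally is what keeps the total
box charge exact).

Step one assigns every grid point to a *molecule* via the rMol radius
set; step two reassigns it to an *atom of that molecule* via the rAtom
set, equivalent to tessellating each molecular volume separately. The
partial charge is q = core − ∫cell ρ, with core charges defaulting to
valence counts (pseudopotential densities; override per element for
all-electron grids). Molecular charges are exact member sums.

Both radius sets are optimized — one parameter per class of
topologically equivalent atoms (iterative element+neighbourhood
signature refinement of the bond graph; bonds by covalent radii × 1.15
under minimum image) — by minimizing the pooled charge variance

    Var = (1/K) Σᵢ (1/(T·Nᵢ)) Σₜ Σⱼ (q_{i,t,j} − μᵢ)²,  σ = √Var

(population convention, no Bessel correction), with classes = molecule
species and samples = molecular charges for stage one (σ_mol), and
classes = atom types, samples = atomic charges, molecular owner maps
frozen, for stage two (σ_atom). The stages run sequentially; the
underlying assumption is that a natural partition makes charges nearly
constant along a trajectory without charge transfer.

## Assignment and integration

The reference assignment is a vectorized per-point argmin over sites.
Squared minimum-image distances are radius-independent, so they are
cached per frame; an objective evaluation is then an argmin over columns
shifted by −r² plus a weighted bincount, which is what makes the
optimizer loop affordable. Orthorhombic cells use the exact rounded
fractional image; skewed cells scan a ±1 image shell around it, with a
subsample check that escalates to ±2 for severely skewed cells. Exact
power-distance ties break to the lowest atom index.

Because each voxel is wholly owned, the radius→charge map is piecewise
constant and carries discretization noise. *Refinement* subdivides each
stride by an integer factor f (default 2) during integration: fine
values are trilinear blends of the 8 surrounding nodes with periodic
wrapping, generated lazily one sub-voxel offset block at a time (memory
stays at one original grid), and each fine point is assigned at its own
coordinates. Trilinear weights on a periodic grid sum to f³ per source
node, so the electron count is conserved exactly; factor 2 is the
default because charges are well converged there on smooth densities.

## Optimizer

Gradients are estimated per parameter from 2s+1 equidistant objective
samples (default s = 3, displacements ±k·h): a line is least-squares
fitted to all seven, the sample with the largest absolute residual is
dropped, and the slope refitted on six is the gradient component — this
tolerates exactly one discretization-noise outlier per parameter.
Directions follow Polak–Ribière nonlinear CG,
β = r₁ᵀ(r₁−r₀)/(r₀ᵀr₀), with a steepest-descent reset when β < 0. Steps
come from a golden-section bracketing search on [0, bracket] returning
the best sampled step; a non-improving step is rejected and retried with
the bracket shrunk by 0.5 until it falls below 0.01 pm, after which a
downhill line search is attempted; convergence is declared when even
that gains less than the improvement threshold (10⁻⁵ e). Accepted
objective values are strictly non-increasing by construction, and the
objective is purely deterministic (same radii, frames and config give
bit-identical values).

After each accepted step the radii are re-anchored by a gauge shift
pinning mean(r²) to its initial value — objective-neutral by the gauge
identity — so the optimizer cannot drift along the flat direction.
Radii are floored at 0 pm by projection. Starting values are van der
Waals element radii for rMol and covalent radii for rAtom, which already
partition space reasonably and keep iteration counts low.

### Parameter scales

Defaults: max gradient displacement 0.15 pm, initial bracket 5 pm,
shrink 0.5, minimum bracket 0.01 pm, improvement threshold 10⁻⁵ e, at
most 100 iterations. The displacement must resolve the objective above
its discretization-noise floor, which scales with the boundary area of
the tessellation: production-size systems (hundreds of atoms, ~10⁷ grid
points) resolve real slope at 0.15 pm, while the desk-scale syntheses
used in the tests and the acceptance script (≈10 atoms, 32³–48³ grids,
refinement 2) do not — there a 2 pm displacement and, where the start is
far from the optimum, a 50 pm initial bracket are used. These are
config fields, not method changes; the acceptance tolerances do not
depend on them.

## Synthetic data

The generator renders each atom as a population-weighted spherical
Gaussian (widths 30 pm for hydrogen-like, ~50 pm for heavy atoms —
small but nonzero overlap at liquid-phase contact distances), summed
over periodic images and renormalized by one global factor per frame so
the discrete electron count equals the prescribed population sum
exactly. Frames differ by seeded rigid-body jitter per molecule
(translation uniform in ±a; rotation angle a/100 rad about a random
axis, one amplitude a for both), keeping topology valid. Ready-made
systems: a neutral water box (8 valence electrons per molecule, K = 2),
a two-site pair whose density-equality plane is found by 1-D root
finding, and an alternating two-species chain whose every A–B gap is
equivalent by periodicity, giving an analytic ground-truth boundary w*
(equivalently r_A² − r_B² = 2Rw* − R²).

These densities emulate the *structure* of valence densities — localized
blobs, strict charge content, small intermolecular overlap — not their
physics: no bonding density, polarization, charge transfer or basis-set
effects. Passing tests therefore demonstrate the correctness of the
partitioning, integration and optimization machinery and its ability to
recover a known boundary, not chemical accuracy of charges on real
systems. One consequence worth noting: with zero jitter, charges are
constant in time, but molecules of one species in different grid
orientations still capture slightly different populations, so the pooled
σ is frame-independent rather than strictly zero (it is strictly zero
with one molecule per species).

## Numerical choices and edge cases

- Internal units: pm, e; densities e/pm³. CUBE I/O converts from bohr;
  values are e/bohr³ (Gaussian convention) or per-voxel counts
  (`raw_counts`). Headers are written with 12 decimals so a round trip
  conserves the electron count to better than 10⁻⁹ relative.
- Grid points sit at lattice nodes origin + i·v₁ + j·v₂ + k·v₃; index
  arithmetic wraps periodically.
- Topology is detected on the first frame and held fixed; frames whose
  bond graph differs trigger a warning, not reclassification.
- Degenerate cells (zero owned points) are tracked, never an error.
- Molecular-orbital cubes (negative atom counts) and NaN data are
  rejected at parse time.
- Problem sizes in the test suite and acceptance script: water boxes of
  2–4 molecules on 16³–64³ grids with 1–4 frames, and the two-species
  chain (4 atoms, 48³, 8 frames, refinement 2), chosen so the whole
  pipeline — including two full radius optimizations — runs in minutes
  on one core while keeping several thousand fine grid points per cell
  face.

## Known limitations

- The per-point argmin path is the only assignment path; the ray-casting
  face-intersection acceleration used by high-throughput implementations
  is not included (the result contract would be identical).
- Equivalence classification is 1-WL signature refinement: sufficient
  for chemical graphs of this kind, but not a full graph-canonization.
- The minimum-image search assumes reasonably reduced cells (±2 image
  shells at most).
- Charge variance is the only objective; dipole or multipole moments of
  cells are out of scope.
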