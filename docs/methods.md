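# Methods

This note documents the models, numerical choices and study conditions behind
cuckoodock: what each component assumes, which parameters matter, what the
synthetic data does and does not emulate, and where the design was genuinely
open.

## Pose model and kinematics

A ligand conformation is the 7+τ vector (position ∈ ℝ³ in Å, scalar-first
unit quaternion, τ torsions in radians). Conventions fixed here:

- **Root anchor.** The rigid rotation acts about the reference coordinate of
  the first ROOT atom, and the pose's position places that anchor. This
  matches the PDBQT tree layout and makes the identity pose reproduce the
  input coordinates bit-for-bit.
- **Torsion semantics.** Torsion values are rotations *relative to the
  reference geometry* (identity pose = all zeros), applied root-to-leaf about
  each branch's bond axis so nested branches inherit their ancestors'
  transforms. Angles live in (−π, π]; wrapping maps both boundaries to +π.
- **Quaternions.** Scalar-first (w, x, y, z), right-handed active rotations.
  Quaternion distance is the rotation angle 2·acos(|q₁·q₂|), which is
  sign-invariant. Degenerate quaternions (norm < 1e−12) are rejected, or
  resampled uniformly where they can arise legitimately (DE updates).
- **RMSD.** All topology atoms, fixed correspondence, receptor frame, no
  superposition and no symmetry correction; reported in nm (success
  threshold 0.2 nm). Whether a united-atom benchmark RMSD should exclude
  any atoms is not decidable from first principles; all-atom is the
  package's choice and trivially configurable by filtering the topology.
- **PDBQT.** A minimal ligand-dialect reader/writer (ROOT/BRANCH/TORSDOF,
  MODEL blocks with a `REMARK ENERGY` line on output). Round trips are
  lossless at the format's 3-decimal coordinate precision. Serial numbers
  are preserved as metadata only; arrays are 0-indexed.

## Scoring contract

A scoring function maps a pose to kcal/mol and counts evaluations; a combined
value+gradient request counts once. The unit label is kept for continuity
with docking affinity reporting — the built-in objectives are not
thermodynamically calibrated.

- **Quadratic bowl** — convex sanity check; the quaternion block contributes
  a single angular term θ² weighted by the first orientation weight, since a
  4-component block has one rotation-angle distance.
- **Multifunnel landscape** — a sum of negative Gaussian wells in pose space
  with exactly one strictly deepest funnel; centers are seeded inside the box
  (15–85 % of each edge). Defaults: 5 funnels, depths 4–12 kcal/mol, width
  2.5 (mixed pose units). This is the minimal structure that reproduces
  premature convergence: optimizers that collapse early end in a shallow
  funnel.
- **Toy atomic scorer** — soft-core 12-6 wells,
  E = Σ depth·[(r₀/r)¹² − 2(r₀/r)⁶] over (ligand atom, probe) pairs within
  an 8 Å cutoff, with r capped below at 0.5 Å so clashes stay finite. All
  three objectives provide analytic pose gradients; the atomic scorer's is
  the classic force/torque construction (net force → position block, torque
  about the anchor mapped to the quaternion tangent space via the 4×3
  Jacobian of q ← δq(ω)⊗q, per-bond torques → torsions), and its evaluation
  path is JIT-compiled with numba and cross-validated in the tests against
  the pure-Python kinematics to 1e−9.

## Search algorithms

**CS–DE.** As in the README. Additional numerical decisions:

- Worse-set size ⌊k·P_worse⌋; configurations where either set would be empty
  are rejected. Ranking ties keep the earlier nest (stable sort) for
  determinism.
- The cuckoo parent is drawn uniformly from *all* k nests; only the
  replacement target is restricted to the better set. Replacement requires
  strictly lower energy; ties keep the incumbent.
- A no-op mutation lays no egg: an offspring bit-identical to its parent
  never replaces another nest. The guard is unreachable for any nonzero step
  size; it exists so that the degenerate diagnostic configuration (all step
  sizes zero, P_mutate = 0, refinement off) leaves the population exactly
  invariant instead of letting clones of good nests overwrite other nests.
- DE donors subtract quaternions component-wise (renormalizing after the
  update) because the DE move is defined element-wise; torsions subtract as
  wrapped angular differences. s = u₁/u₂ is capped at 100 (the ratio is
  otherwise unbounded) and u₂ = 0 is redrawn. The block maxima that the
  differential weights are scaled by are the largest box extent (position)
  and π (orientation and torsion) — the natural ranges of each block.
- **Cuckoo offspring are BFGS-refined before comparison; DE rebuilds are
  raw-scored by default** (`refine_de=False`, switchable). Refining the
  rebuilds drags the worse set into the same funnels the better set already
  occupies, and the population's distance sum then falls *below* PSO's —
  the opposite of the coverage behavior the worse set exists to provide.
  Raw-scored rebuilds keep the worse set wandering at box scale throughout
  the run while the better set exploits; this reproduces both signatures
  (high sustained DS, and rare worse-set "breakthroughs" that seed better-set
  bursts).
- Random-walk steps: position uniform in a 2 Å sphere then clamped to the
  box; orientation rotated about a uniform axis by a N(0, 0.25 rad) angle;
  one uniformly chosen torsion perturbed by N(0, 0.5 rad). These are small
  relative to each block's range and are config-exposed.
- Stopping: budget exhaustion only. A step interrupted by the budget counts
  its partial evaluations and leaves a consistently re-ranked population.

**Local refinement.** scipy's BFGS in the raw 7+τ coordinates, up to 100
iterations. The objective canonicalizes each trial point (unit quaternion,
wrapped torsions) and chain-rules analytic gradients through the
normalization; without a gradient, scipy's finite differences are used and
every probe is a counted evaluation. The refiner returns the best in-box
pose seen (including the start), so refinement never raises the energy and
never moves a pose outside the box. The 100-iteration cap matters: capping
at 20 truncates descents from random poses (measured native-basin hit rate
0.7 % per refinement vs 3.7 % at 100 on the toy complex, at only ~2× the
evaluations) and is the difference between recovering the native pose
reliably and stalling on decoys.

**Monte Carlo baseline.** Single chain of {random-walk mutation → BFGS
refine → Metropolis accept/revert}, acceptance scale 1.2 kcal/mol (an
exposed package choice, not a published constant). ΔE ≤ 0 is always
accepted.

**PSO baseline.** Canonical global-best PSO, N = 8, ω = 0.36,
α = β = 0.99. Orientations ride a 3-component rotation-vector chart so
velocities live in a vector space; the chart is re-projected through the
quaternion when it leaves the radius-π ball. Velocities are clamped at half
the per-block range; positions are clamped/wrapped per block. Each updated
particle position is refined and scored (updating personal/global bests),
but particles move only by velocity — refinement does not teleport them.

## Synthetic data

`make_toy_ligand` builds zig-zag carbon chains (1.5 Å bonds, small seeded
jitter so torsions genuinely move atoms) with nested BRANCH blocks;
`make_toy_complex` draws a native pose at least 20 % of the box edge away
from every face (so clamping never masks recovery failures), places one
probe 5 Å from each native atom position, and assigns every pair within the
8 Å cutoff a 12-6 well whose r₀ equals that pair's native separation. Every
interacting pair then sits at its own minimum simultaneously in the native
pose, making it the provable global minimum with energy −(number of
interacting pairs)·depth; pairs closer than 1 Å at the native pose are
dropped so no r₀ falls inside the soft core. The 5 Å probe offset sets the
well stiffness: it keeps the native basin wide enough that BFGS from a
0.5 Å perturbation falls back into it instead of over the repulsive wall.

What the fixtures emulate: a rugged multi-basin energy surface with a unique
funnel, torsional flexibility, box-bounded search, and a decoy structure
(the near-symmetric chain admits a flipped binding mode ~4 Å away at roughly
two-thirds of the native well depth). What they do not: real chemistry
(charges, heteroatoms, solvation), receptor flexibility, scoring-function
error. Passing the recovery experiment therefore demonstrates that the
*search* finds the global minimum of a frustrated landscape at a realistic
budget — not that any scoring function ranks real poses correctly.

## Study conditions and run sizes

Fixed by the algorithm's published parameterization: k = 8,
P_worse = P_mutate = 0.25; PSO N = 8, ω = 0.36, α = β = 0.99; success
threshold 0.2 nm; 22.5 Å cubic box.

Package choices (each stated where used; seeds are explicit everywhere):

- **Pose recovery**: 30 independent CS–DE runs on one seeded toy complex
  (τ = 2), 100 000 evaluations per run — roughly a thousand BFGS
  refinements, the desk-scale analogue of a production docking budget for a
  ligand of this size. Success is RMSD < 0.2 nm to the native pose.
- **Coverage comparison**: 30 seeded (CS–DE, PSO) pairs on matched
  five-funnel landscapes, 6 000 evaluations per run; end-of-run DS compared
  per pair, better-set DS checked against the all-agent DS at every sampled
  iteration; the same runs are scanned for breakthroughs (a worse-set
  important update followed by ≥ 5 better-set updates within 50 iterations).
- **Convex convergence**: budget 5 000 per algorithm, tolerance 1e−3 on the
  known minimum.
- **Metropolis closed form**: 10⁵ Bernoulli trials at ΔE = scale against
  e⁻¹ with a 3σ binomial band.

## Known limitations

- The engine searches; it does not score real complexes. Plugging in an
  empirical scoring function (and a receptor grid) is out of scope.
- DS mixes Å, quaternion components and radians in one Euclidean norm by
  construction; a block-normalized variant exists behind a flag for
  sensitivity checks but all reported numbers use the raw form.
- Single-threaded by design; "threads" are emulated as independent seeded
  runs pooled by `pool_runs`.
- The PDBQT reader covers the ligand dialect only (no receptor records, no
  flexible side chains), and reads the first MODEL of multi-model files.
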