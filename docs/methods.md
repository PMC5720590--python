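# Methods

This note states precisely what `allomsm` computes, in the order the
pipeline executes.

## Input and state-space definition

Input is a pair of labeled conformational ensembles ("wildtype",
"mutant"), each a set of replicate trajectories over one shared
topology, plus a reference structure defining the probe geometry. The
default protocol models 10 replicates × 10 000 frames saved every 10 ps
per variant (1 µs aggregate simulated time per variant).

All pairwise geometry uses minimum RMSD under proper rotations
(Kabsch/SVD with determinant sign correction, so reflections are never
used) restricted to the backbone-heavy atoms (N, CA, C, O) of the
interface region: chain A residues 425–429 and chain B residues
445–477.

## Clustering (shared microstates)

Frames of both variants are pooled in a fixed deterministic order
(variant, replicate, frame) and clustered with a hybrid scheme:

1. **k-centers**: greedy farthest-point selection starting from the
   first frame, adding the currently worst-covered frame as a new
   center until every frame lies within the 1 Å cutoff of some center.
   On termination the coverage radius is ≤ 1 Å by construction; the
   pipeline records this radius.
2. **k-medoids refinement**: 50 sweeps; each sweep proposes, per
   cluster, the member minimizing the sum of distances to its cluster's
   members (exhaustively up to 4 000 members, otherwise over a seeded
   subsample that always includes the incumbent) and accepts the swap
   only if the global objective strictly improves. The objective is
   therefore non-increasing; clusters left empty by reassignment are
   dropped. Refinement optimizes average distortion and may leave the
   worst-case radius above the k-centers cutoff.

Ties in frame assignment (equal distance to two medoids within 1e-9)
resolve to the lower cluster index.

## Markov state models

For each variant separately, transitions between microstate assignments
are counted with a sliding window at lag τ (default one frame, 10 ps),
never across replicate boundaries. The count matrix is symmetrized with
the transpose estimator

    C̃ = (C + Cᵀ) / 2,

and the transition matrix is its row normalization. No ergodic trimming
is applied: a microstate the variant never visits keeps a zero row,
receives an identity row in T, and has zero stationary weight. For this
estimator the stationary distribution is available in closed form,

    π_i = Σ_j C̃_ij / Σ_kl C̃_kl,

and satisfies detailed balance π_i T_ij = π_j T_ji exactly. The
estimator is biased for irreversible dynamics: it converges to the
row-normalized additive symmetrization of the stationary flux. Its
stationary distribution nevertheless converges to the true one; the
test suite demonstrates both facts on planted chains.

## Selection and probe readout

Per variant, microstates are ranked by stationary weight (zero-weight
states excluded from the denominator) and the top ⌈5 %⌉ are selected;
rank ties resolve to the lower microstate index. For each selected
microstate the representative conformation is its medoid frame, and the
readout is the Cα–Cα distance between probe residues A 427 and B 477,
divided by the same distance in the reference structure (d_ref). An
optional secondary readout superposes each representative onto the
reference over a chain-B anchor (residues 445–459, the stable helix
adjacent to the activation helix) and reports the displacement of the
probe Cα.

## Comparison

The two variants' normalized distances (one value per selected
microstate by default; optionally all frames assigned to selected
microstates) are compared with a two-tailed pooled-variance Student's
t test; Welch's form is available as an option. Population overlap in
the shared state space is summarized by exclusive/shared microstate
counts at an occupancy floor and by the Jensen–Shannon divergence of
the two stationary distributions (natural log; bounded by ln 2).

## Synthetic data with planted truth

The generator builds, per variant, a reversible metastable chain
T = m·I + (1 − m)·1πᵀ with chosen stationary vector π and metastability
m (default 0.85), samples state paths per replicate, and emits
coordinates as: a state-specific geometry, plus collective breathing
modes (orthonormal translation-free fields, drawn once from a fixed
internal stream so they are part of the model, not the noise), plus
isotropic atomic noise, plus a rigid-body rotation/translation jitter of
the whole frame. State geometries displace the chain-B body (residues
460–476) along tetrahedral directions and place the probe residue B 477
so the planted probe distance is exact by construction. Defaults plant
wild-type states at normalized distances (1.75, 1.60, 1.30, 1.10) with
π = (0.4, 0.4, 0.1, 0.1) and mutant states at (1.50, 1.30, 1.05, 0.90)
with π = (0.1, 0.1, 0.4, 0.4): the mutant concentrates population in
near-crystal ("engaged") geometries. All stochastic stages draw
independent substreams from one user seed, so datasets are
bit-reproducible.
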