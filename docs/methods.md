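# Methods

This note documents the models and procedures `steerkit` implements, the
parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the numerical conventions a user extending the toolkit needs
to know.

## Data model and tokenization

A complex is a flat ordered atom list with chain metadata and an explicit
bond list. Tokens are amino acids for protein chains, bases for RNA/DNA,
and individual heavy atoms for everything else; token order is chain order
then sequence order, and a residue with no resolved heavy atom still emits
a token flagged unresolved so downstream masking is explicit. Coordinates
are Å in the frame of the source file; residue indices are the
author-assigned identifiers treated as opaque ordered integers (no
renumbering). Unresolved atoms keep placeholder coordinates and are masked
out of every geometric operation. Chains with identical entity type and
sequence (polymers) or identical residue composition (nonpolymers) are
grouped into symmetric-copy entities; these groups drive both the
chain-overlap potential and symmetry-corrected scoring.

Van der Waals radii come from a single bundled element table (the
consolidated Bondi/Mantina set) with a 2.0 Å fallback for exotic elements;
the clash criteria only ever use the *sum* r_i + r_j, so any standard set
changes boundaries by a few percent at most. mmCIF/PDB I/O goes through
gemmi; on parsing, only the first alternate location is kept and
zero-occupancy atoms are flagged unresolved.

## Flat-bottom constraint potentials

Every potential is a hinge: exactly zero on any conformer satisfying the
constraint, growing linearly with the violation. This gives bounded,
scale-free gradients that are safe to inject anywhere in a diffusion
trajectory, and makes "constraint satisfied" a crisp, testable predicate.

Angular conventions. The signed dihedral lies in (−π, π], right-handed
about the central axis. Chirality uses the *signed* improper dihedral over
the quadruple (A, B, C, Z) of a center Z's three highest-CIP substituents:
R centers are feasible at ≥ +π/6, S at ≤ −π/6 (verified against
RDKit-assigned R/S centers: an embedded R center measures ≈ +38°).
Stereochemistry and planarity use the dihedral magnitude |θ| ∈ [0, π]: an
E torsion is feasible at |θ| ≥ 5π/6, Z at |θ| ≤ π/6, and a planar improper
at |θ| ≤ π/12. The magnitude form is what makes these hinges flat-bottomed:
a signed E torsion of −π is as correct as +π and must not be penalized.
Both substituent torsions (A1–A2 and B1–B2) of a stereo bond are
constrained.

Ligand internal geometry hinges on the distance-geometry bounds envelope:
for every intra-ligand pair, energy accrues above `1.2·U_ij` or below
`0.8·L_ij`, identically over the three pair classes (bonded, 1–3, and all
remaining pairs); the classes only matter for reporting, where they map to
the bond-length / bond-angle / internal-clash quality checks. Bounds can
be supplied directly, generated by the synthetic module, or derived from
an SDF via RDKit's bounds matrix (`steerkit.chem`).

Steric clash sums `max(0.725·(r_i+r_j) − d, 0)` over resolved heavy atom
pairs in distinct, non-covalently-linked chains. Chain overlap penalizes
symmetric-copy chain pairs (each with more than one atom) whose centroids
are closer than the schedule

    b_t = 1 + 4·(exp(−2(1−t)) − 1)/(exp(−2) − 1)     t ∈ [0, 1]

which runs smoothly between 1.0 and 5.0 Å; we evaluate the closed form
verbatim (its maximum, 5 Å, is attained at t = 0 under this
parameterization). Cross-chain covalent bonds hinge above 2 Å.

Weights. All α default to 1 and λ (the tilt strength) to 2; the clash term
is gated to diffusion times t < t_clash (default 0.5 in normalized time)
because early, high-noise states are all-clashing by construction and the
term would only add gradient noise there. The literature behind the sum
says only that weights are time-dependent; any schedule can be expressed
through `PotentialWeights`.

Gradients are analytic throughout (hinge subgradient 0 at the kink;
standard four-point dihedral gradient), and the test suite checks them
against central finite differences on every violation fixture.

## Feynman–Kac steering

The target distribution is the sampler's own distribution tilted by
`exp(−λE(x_0))`. Sampling uses SMC over k particles:

* **Kernel.** `GaussianAncestralSampler` implements the transition
  `x_{t−1} ~ N(x̂ + (σ_next/σ_t)(x_t − x̂), σ_next²(1 − (σ_next/σ_t)²)I)`
  with the denoised prediction x̂ first Kabsch-aligned onto the state.
  Sampling and log-density share one code path, so the guided/unguided
  density ratio in the importance weights is exact. A sampler without a
  tractable density would forfeit the ratio correction (degraded mode);
  the shipped kernel always has one.
* **Guidance.** At each checkpoint the offset Δx̂ is rebuilt by m steps
  (default 4; the toy studies use 20) of gradient descent on E(x̂ + Δx̂),
  each step's per-atom displacement capped at 0.5 Å so guidance cannot
  tear a near-feasible structure. The offset persists between checkpoints
  and biases every transition kernel mean, matching
  guidance-at-every-step with resampling every third step.
* **Weights and resampling.** Checkpoints fall every `resample_interval`
  steps (default 3) counting from the first step, where the weight is
  `exp(−λE)`. Later checkpoints use the energy *difference* against the
  previous checkpoint, so the per-step factors telescope across the
  interval, multiplied by the proposal-density ratio
  `τ(x_t|x̂, ·)/τ(x_t|x̂+Δ, ·)`. Everything is computed in log space with
  a uniform-weights fallback (and a logged warning) on total underflow.
  Resampling is multinomial with replacement; survivors get uniform
  weights and zeroed offsets.
* **Output** is the first particle's final denoised prediction plus its
  guidance offset.

With λ = 0 and m = 0 all weights are uniform and the offsets vanish, so
the marginal law of each particle equals the plain sampler's — the suite
verifies this with a two-sample Kolmogorov–Smirnov test (n = 2000 per arm,
a 6-step schedule on a 5-atom toy; sizes chosen to keep the default test
run fast while leaving the test's power ample for any real regression).

## Aligned reverse interpolation

The denoiser contract is deliberately minimal: a deterministic map
f(x, σ) → x̂. Because such denoisers are exercised under random rigid
augmentation of their input, a prediction can come back in a different
frame than the state it must be interpolated with; the sampler therefore
superposes x̂ onto x_t (Kabsch, proper rotations only) before every
interpolation step. The `dirac_pathological` toy denoiser shows why this
matters: it returns the memorized target whenever the best-rigid per-atom
RMS displacement is below 10σ and the zero structure otherwise — a model
with essentially zero *aligned* training loss. Under plain interpolation
the frame mismatch accumulates, the trigger eventually fails, and the
trajectory collapses to the origin; with alignment the trajectory stays
within the trigger for every seed tested (100). The trigger norm is
per-atom RMS (rather than an absolute norm) so the threshold is
independent of system size; typical Gaussian noise has RMS σ√3, far
inside 10σ.

## Evaluation

LDDT follows the standard published definition: reference pairs within a
15 Å inclusion radius, same-residue pairs excluded, thresholds
0.5/1/2/4 Å, score = mean over thresholds of the preserved fraction.
`LddtScorer` caches the reference distance matrix and per-threshold
preserved counts so that a candidate reassignment touching only a subset
of atoms is re-scored from the affected rows/columns alone; incremental
and full scores agree to well below 1e-9 (integer pair counts).

Greedy symmetry correction searches chain assignments (products of
permutations within symmetry groups, lexicographic, capped at 100) with
inner atom order fixed, then visits each ligand in turn and greedily
applies the bonded-graph automorphism (element-preserving, enumerated via
networkx, capped at 1000 per ligand) that most improves the global score.
Ties keep the first candidate in enumeration order. On instances small
enough to brute-force, greedy equals exhaustive search exactly (tested).

Quality checks mirror the potentials' feasible regions: bonds and 1–3
distances inside [0.8L, 1.2U], other intra-ligand pairs above 0.8L,
chirality by improper-dihedral sign, stereo by torsion magnitude
(boundary π/2), and inter-chain clash at 0.75·(r_i + r_j) between
non-bonded chains with more than one atom. A ligand without bounds makes
its geometric checks "not evaluable" (None) — reported distinctly from
failure and excluded from the overall conjunction. Pocket-aligned ligand
RMSD superposes on the backbone atoms of reference residues within 10 Å of
the ligand (the radius is our choice; it is not pinned by the metric's
users) and minimizes over ligand automorphisms.

## Data-pipeline algorithms

**MSA pairing.** Taxonomies observed in ≥ 2 distinct chains are processed
in descending unique-chain count, ties broken lexicographically by
taxonomy id (a determinism choice; the published procedure is silent).
Within a taxonomy, chain entries cycle via `i mod len(sequences)`; chains
absent from the taxonomy draw from their per-chain queue of unpaired rows
(original file order, i.e. most-similar-first from the aligner), and
remaining queue rows are appended until exhaustion or the row cap (default
16384, matching common MSA-depth limits). Consequences tested: no emitted
row is empty in every chain while rows remain; queue sequences appear at
most once per chain.

**Unified cropping.** Tokens are visited in ascending center-atom distance
from the crop center (ties by token index; unresolved tokens are skipped
as visit candidates but can enter through a window). Each visit atomically
adds its neighborhood: the whole chain if it is not larger than the
neighborhood size, otherwise a same-chain residue-index window grown ±1
per iteration around the visited token (index arithmetic ignores gaps in
the author numbering; a window that reaches both chain ends stops).
Nonpolymer tokens share one residue index, so a ligand always joins as a
unit. An addition that would exceed the token or atom budget ends the
crop — including, faithfully, a first neighborhood larger than the whole
budget. Size 0 reproduces spatial cropping exactly; size = half the token
budget on a single chain reproduces contiguous cropping exactly (both
verified against independent oracles). Training-style sampling draws the
size uniformly from {0, 2, …, 40} and the center uniformly from the named
chain or interface (tokens of either chain within 15 Å of the other — the
contact radius is our convention).

**Pocket conditioning.** With probability 0.3 per iteration, a binder is
drawn uniformly among ligand chains (any chain if there is no ligand);
candidate pocket tokens are those of other chains whose nearest resolved
heavy atom is strictly within 6 Å of the binder; N = min(|candidates|,
1 + M) of them are revealed, with M geometric (p = 0.3) on support
{1, 2, …} — so at least two residues are revealed whenever two qualify.
The inference-mode variant takes an explicit binder chain and residue
list and bypasses all sampling. The one-hot feature order is fixed as
[UNSPECIFIED, BINDER, POCKET, UNSELECTED].

## Synthetic fixtures: what they do and do not emulate

Toy polymers are idealized traces (Cα helix with 2.3 Å radius, 1.5 Å
rise, 100°/residue; one-atom-per-base strands) — enough geometry for
every potential, metric and cropping behaviour here, with no side chains,
no force-field realism, and no missing-density patterns beyond explicit
unresolved flags. Ligand templates (tetrahedral R center with four
distinct halogen/N substituents, E/Z ethylene frames, a planar frame,
trans-butane, a diatomic, CO₂, benzene) carry hand-constructed ideal
geometry; their bounds matrices are derived from that geometry — tight
(L = U = d) for bonded and 1–3 pairs, and loosened to [0.7d, 1.43d] for
torsion-dependent pairs in the stereo/planar templates so that a pure
stereo flip does not co-trigger the bounds term. Chain placement is along
one axis at a configurable separation (default 20 Å, far outside every
interaction floor), and covalently linked chains are pulled to a 1.5 Å
link distance.

Violation injection is surgical by construction: mirroring flips only
chirality (distances are preserved); rotating half a stereo frame about
the double bond flips only the torsions; rotating about a torsion bond
creates an internal clash without touching bonds or 1–3 distances;
translations create inter-chain clashes, centroid overlap (offset
perpendicular to the placement axis so atom pairs stay clear), or broken
covalent links. Each injection is verified post hoc to make exactly its
own component positive. Passing these tests shows the algorithms do what
their definitions say on clean geometry; it does not show robustness to
the correlated, partially-resolved, multi-conformer messiness of
experimental structures.

## Problem sizes and numerical choices

Default test-suite problem sizes are deliberately small — 2–30-residue
chains, 2–12-atom ligands, 6–30-step schedules, 10–100 seeds per study,
n = 2000 per arm for the distributional test — chosen so the whole suite
runs in about a minute on one core while every check retains clear
statistical margins. Bisections for boundary values run to 1e-6.
Tolerances: rigid-invariance and incremental-LDDT checks at 1e-9;
gradient versus central differences at 1e-4; Kabsch degenerate-rank
rejection at a 1e-9 relative singular-value threshold. Tie-breaks are
fixed everywhere randomness is not explicit (token index for crop
distance ties, taxonomy id for pairing ties, enumeration order for equal
LDDT); every stochastic routine takes a named seed, and identical seeds
reproduce trajectories bit for bit.

## Known limitations

* The toolkit steers *toy* denoisers; integrating a neural denoiser means
  implementing the one-callable contract, but no network code ships here.
* CIP priorities are taken from annotations or from RDKit; there is no
  built-in CIP implementation.
* The time-dependence of the potential weights beyond the clash gate is
  user-supplied; only the overlap floor b_t has a canonical schedule.
* Chain-overlap isolation in the fixtures relies on geometric headroom;
  in dense real complexes a centroid-overlap violation usually co-occurs
  with clashes (as it should).
* The mmCIF/PDB layer handles single models, first altlocs and standard
  residues; assembly expansion and chemical-component dictionaries are out
  of scope.
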