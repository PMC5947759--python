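# Methods

## Scope and data model

`mrforge` converts one protein crystal structure (PDB format, one selected
chain) into pools of molecular-replacement search models. Structures are
held as a light chain → residue → atom hierarchy with author residue
numbering as the universal key (external score files are joined on it);
extra MODEL blocks of an ensemble file are stored as coordinate arrays
sharing the first model's topology. Hydrogens are dropped on read and all
logic is heavy-atom only. Input sanitisation (`structure_io.prepare_input`)
keeps the selected chain, reverts selenomethionine to methionine (SE → SD),
keeps the highest-occupancy conformer of every alternate-location group
(ties resolved to file order) and removes waters and non-polymer
heteroatoms. Only the fixed-column PDB dialect is supported; mmCIF,
symmetry expansion and ligand chemistry are out of scope.

## Distance-geometry ensemble generation

The generator follows the classic two-step scheme: read constraints off the
input, then correct randomised coordinates until all constraints hold.

**Constraints.** Every atom pair receives at most one bound, from the
tightest applicable tier:

| tier | pairs | band around the observed distance d |
|------|-------|--------------------------------------|
| 1 | covalent bonds (residue templates, peptide links, disulfides) | ±0.5 % |
| 2 | 1-3 pairs; all pairs inside rigid/planar groups (aromatic rings, guanidinium, carboxylates, amides, peptide planes) | ±1.5 % |
| 3 | 1-4 pairs | ±5 % |
| 4 | backbone H-bond N···O partners inside helix/strand elements | ±10 % |
| 5 | all remaining heavy-atom pairs with d < 6.0 Å | lower = min(max(Σr_vdW, 0.8 d), d); upper = 1.25 d |

Unconstrained pairs must keep a distance of at least 0.8 × the sum of their
van der Waals radii (Bondi: C 1.7, N 1.55, O 1.52, S 1.8 Å); an input with
a non-bonded pair below 0.5 × that sum is rejected as clashing. The tier-5
lower bound is capped at the observed distance so that genuinely close
polar contacts (H-bond N···O ≈ 2.9 Å, below the 3.07 Å radius sum) do not
make the generating structure violate its own constraint set; without the
cap a zero-perturbation start could not converge in zero sweeps. The
tolerance tiers and the 6.0 Å contact cutoff are package choices that
preserve the qualitative contract — stronger interactions, tighter bands —
and are exposed in `DgParams`.

Secondary-structure elements for tier 4 come from a backbone H-bond
assignment in the Kabsch–Sander style: the amide hydrogen is placed 1 Å
from N opposite the preceding C=O bond, the electrostatic energy
0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) marks a bond below
−0.5 kcal/mol, consecutive i→i+4 turns define helices and bridge patterns
define strands. Only H/E membership is consumed, so the full 8-class
assignment is deliberately not reproduced; residues with incomplete
backbones are labelled coil with a warning.

**Sampling.** A conformation starts from the input coordinates displaced by
isotropic Gaussian noise (σ = 1.5 Å per atom; a perturbed start converges
at desk scale where a fully random one would not, and σ is configurable).
Sweeps then visit the violated bounds in seeded random order; for a pair at
distance d outside [l, u] both atoms move along the pair axis by (d − t)/2
each, where t is the nearest bound. Exclusion violations, re-detected each
sweep with a k-d tree, enter the sweep as lower-bound-only rows. This
pairwise Gauss–Seidel scheme was chosen over metric-matrix embedding
because it has the same fixed points (all bounds satisfied) and is simple
to verify; the inner sweep is numba-compiled. Convergence requires every
violation ≤ 0.05 Å **and** correct Cα stereochemistry:

* if the majority of Cα centres (signed volume of N, C, Cβ about Cα) are
  inverted relative to the input, the whole coordinate set is mirrored —
  distances cannot distinguish a structure from its global mirror image;
* a residue whose centre stays inverted for 10 sweeps while the remaining
  violations are small (≤ 10 × tolerance) sits in a locally mirrored,
  distance-feasible minimum — typically at a chain terminus, where the
  loose tier-5 bands genuinely admit the mirror. Reflecting Cβ alone
  oscillates, so the whole residue is rebuilt by rigidly fitting the input
  fragment onto the current positions of the neighbouring residues' atoms,
  after which ordinary sweeps re-polish. With this repair, convergence was
  observed for 100/100 seeds on both a 15-residue helix and a 30-residue
  helix-plus-tail fixture.

A run that has not converged after 500 sweeps is discarded; the caller
restarts with the next seed (child seed = root seed + attempt index, so
ensembles are bit-reproducible) within a budget of 10 × n attempts. The
default ensemble size is 500 conformations.

## Clustering, variance, subclusters

All comparisons are Cα-only; whole-atom coordinates are moved with the Cα
fit. Superposition is weighted Kabsch (proper rotation enforced via the SVD
determinant correction; collinear point sets fall back to a flagged
translation-only fit). Clustering is greedy neighbour-counting on the full
pairwise RMSD matrix: the member with most neighbours within the cutoff
seeds cluster 1, its members are removed, and the process repeats for
clusters 2 and 3 (only three clusters are ever consumed). The cutoff is
auto-tuned from 1.5 Å by ×/÷1.25 steps within [0.5, 8.0] Å until cluster 1
holds 15–85 % of the members — outside that band the top cluster is either
trivial or all-encompassing and the variance profile carries no signal.

The per-residue variance profile is an iterative reweighted superposition
to the evolving mean: residue weights 1/(var + ε) with ε = 10⁻⁶ Å², the
variance of a residue is its mean squared Cα deviation from the mean
structure, iterated to a maximal relative change < 10⁻⁴ (50 iterations
cap). This is a deliberately lightweight stand-in for full
maximum-likelihood covariance estimation; on synthetic ensembles with a
prescribed σ profile it recovers the rank order with Spearman ρ ≈ 0.99 at
100 members (the test threshold is 0.8).

Subclusters collect the members within a fixed Cα-RMSD radius of the
cluster centroid, nearest first, capped at 30 members; the centroid is
always included, so a too-small cluster still emits single-member models.
The radii default to 1, 2 and 3 Å and, like the cap, are configuration
options.

## Truncation factory and single-model mode

The truncation ladder retains ⌊n·k/20⌋ residues for k = 20…1 (floored —
the only rule consistent with all printed sizes for a 259-residue chain,
e.g. ⌊259 × 0.35⌋ = 90 — clamped to ≥ 1, duplicate sizes merged). Given a
profile, the residues kept at each level are those with the lowest scores,
ties broken toward lower residue numbers, so levels are nested by
construction and only the rank order of a score matters. Side-chain
treatments: `allatom` (unchanged), `polyala` (N, CA, C, O, Cβ, renamed ALA
except glycine) and `reliable` (side chains kept only for CYS, MET, PHE,
TRP, TYR, ILE, LEU, VAL, PRO — types with few well-occupied rotamers; the
set is configurable since no authoritative enumeration exists). Models
identical across radii are *not* deduplicated by default, so the pool-size
law |levels| × |radii| × |modes| × |clusters| holds exactly (180 per
cluster, 540 for three); a `dedupe` flag removes them.

Single-model mode applies the same ladder and treatments to one structure
per score column — 60 models per column, all columns pooled. Score files
are plain text: a header line with column titles, column 1 residue numbers,
whitespace- or comma-delimited. Higher score = removed earlier;
conservation-style scores (higher = keep) must be negated by the user.
Scores and structure must cover exactly the same residues — silent
imputation would corrupt the removal order, so any mismatch is an error.
Score smoothing is intentionally not implemented.

## Built-in metrics

* **WCN**: Σ 1/d² over Cα pairs (optionally side-chain centroids). Emitted
  negated so that poorly packed residues are removed first.
* **ASA**: Shrake–Rupley with a 1.4 Å probe and a 960-point Fibonacci
  sphere per atom (error vs a 10⁴-point reference is well under the 2 %
  test bound); optional normalisation by Gly-X-Gly maxima gives relative
  accessibility, raw Å² is the default.
* **B factor**: residue-averaged heavy-atom B.
* **Ensemble variance**: the clustering-stage profile exported as a score
  column.

## Synthetic fixtures

Test structures are grown from canonical bond lengths/angles and chosen
backbone dihedrals (NeRF construction): ideal α-helices (φ = −57°,
ψ = −47°), extended strands, helix-plus-tail chains, and a two-strand
antiparallel sheet whose inter-strand placement is grid-searched to
maximise backbone H-bonds. Synthetic ensembles displace a reference with
residue-wise Gaussian noise; this ignores chain-correlated motion of real
ensembles, which is acceptable because every consumer sees only coordinates
— passing tests therefore validate the algorithms, not the realism of any
particular protein's dynamics. Default problem sizes in the tests and the
acceptance script (30-residue chains, 30–500-member ensembles) were chosen
as the smallest sizes at which every contract — including the 500-member
default — is exercised.

## Known limitations

* The distance-geometry bands are package defaults, not a reproduction of
  any published parameter file; ensembles are geometrically plausible but
  carry no force-field energetics.
* Clustering is cutoff-based on Cα RMSD; TM-score-style metrics are not
  offered.
* The variance estimator has no hierarchical priors; for very small
  clusters (< ~5 members) the profile is noisy.
* MR itself (and hence any statement about solution rates) is outside the
  package; the recorded 0.1 Å RMSD error estimate in the run log is
  hand-off metadata only.
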