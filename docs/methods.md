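# Methods

This note records the model implemented by `decoyrank`, the numerical
choices, and what the synthetic benchmark can and cannot establish.

## Superposition and RMSD

Optimal rigid superposition uses the Kabsch SVD construction with the
standard determinant correction so only proper rotations are admitted
(mirror images of chiral point sets keep a strictly positive RMSD). RMSD is
computed from the explicitly rotated residuals rather than the trace
shortcut `sqrt((Ga+Gb-2(σ1+σ2±σ3))/n)`: the trace form loses ~8 significant
digits to cancellation near zero, which matters because several invariance
tests and the clustering radius check operate at the 1e-9 level. The
clustering hot path uses a batched SVD over all members of a cluster at
once. Degenerate inputs (rank-deficient covariance, e.g. collinear points)
are rejected rather than silently resolved.

The test suite validates RMSD against Horn's quaternion method (largest
eigenvalue of the 4×4 key matrix), an algebraically independent oracle, and
against a brute-force rotation-grid search for the chiral case.

## TM-score

`TM = max over superpositions of (1/L_target) Σ 1/(1+(di/d0)²)` with
`d0(L) = 1.24·(L-15)^(1/3) - 1.8`, floored at 0.5 Å. The maximization uses
the standard fragment-seed heuristic: contiguous seeds of lengths L, L/2 and
L/4 (minimum 4) at every start position, each refined by iterating
"superpose on the included set, re-include residues with d < max(d0+1, 4.5)"
to a fixed point (cutoff raised in 0.5 Å steps whenever fewer than three
residues qualify, since three non-collinear points are the minimum for a
well-posed superposition; 20 iteration cap). Scores are normalized by the
reference (native) length. An exhaustive-seed oracle (every contiguous
fragment of every length) bounds the heuristic's shortfall at 0.005 on
noisy-decoy test cases.

## Solvent-accessible surface area

Shrake–Rupley with a 1.4 Å probe. Instead of random sphere points, each atom
gets a deterministic golden-section spiral lattice (960 points by default,
10,242 for the fine reference; the two agree within 1% on all fixtures).
Candidate occluders come from a k-d tree query, and point–neighbor distances
are evaluated with a single matrix product per atom.

A fixed lattice is not rotation-invariant, so coordinates are first moved to
a canonical frame: principal axes of the atom cloud, with axis signs fixed
by third moments (skewness). This makes descriptors bit-reproducible and
invariant under rigid motion to ~1e-6, which the tests assert. Van der
Waals radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å.

## Descriptors and the cumulative score

- **A1**: fraction of total SASA from nonpolar residues
  (ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP, GLY).
- **A2**: fraction of total SASA from carbon and sulfur (and H) atoms.
- **A3**: Σ over residues of (Kyte–Doolittle hydropathy + 4.5) · residue
  SASA; the +4.5 offset makes all weights nonnegative.
- **A4**: total SASA in Å².
- **PH, PS**: percent of residues predicted helix (resp. strand) whose
  assigned state in the model differs from the prediction.
- **M1**: mean distance of Cα atoms from their centroid — a Euclidean
  compactness measure chosen over radius of gyration because it is the
  plain average distance and equally monotone under unfolding.

```
CS = 10·A1 + 0.1·A2 + 1e-5·A3 + 0.001·A4 + max(0.15·PH, 0.21·PS) + 0.001·M1
```

The penalty term takes the larger of the two *weighted* penalties, so a
strand mismatch outweighs a helix mismatch of equal size. Lower CS is
better; ties rank in pool order (stable sort). On synthetic pools the signal
is carried mostly by A4 and M1 (unfolded decoys expose more surface and
spread out) with PH/PS separating structured from scrambled models.

## Secondary structure assignment

Full-backbone models are assigned from (φ, ψ) windows: helix for
φ ∈ (−100, −30), ψ ∈ (−80, −5) in runs of ≥ 4; strand for φ ∈ (−170, −40),
ψ ∈ (90, 180] ∪ [−180, −170) in runs of ≥ 3; everything else coil. Window
assignment is deliberately crude compared to DSSP (no hydrogen bonds), but
it only feeds a *penalty between a prediction and a model*, where consistent
crude assignment on both sides is sufficient and keeps the package free of
external binaries. Cα-only models fall back to the i→i+3 distance rule
(helix if |Cα_i − Cα_{i+3}| within 5.0 ± 1.0 Å).

## Clustering

An RMSD-radius leader/Lloyd scheme standing in for kclust-style decoy
clustering. Deterministic by construction: members are visited in
lexicographic id order; the leader pass assigns each structure to the first
centroid within the radius; Lloyd iterations recompute each centroid as the
mean of members superposed onto it, reassign to the nearest centroid, and
spawn a new singleton cluster for any member farther than the radius from
every centroid (this keeps the "every member within radius of its centroid"
invariant exactly). Clusters are renumbered by first appearance; 10
iteration cap. The representative of a cluster is its member closest to the
centroid, first id winning ties.

The retention argument: if the best decoy in the pool has true RMSD r, its
cluster representative is within 2·radius of it in RMSD-metric terms
(triangle inequality through the centroid), so clustering at radius 1 Å can
cost at most 2 Å of best-model accuracy. The benchmark checks this bound on
every pool; in practice the loss observed is far smaller.

## Quality stand-in

Production pipelines aggregate several external assessment programs
(Molprobity-style validators, MQAPs) into one quality number. Those binaries
can't ship in a library, so the composite here is transparent:

```
quality = 100 · rama_outlier_fraction + 10 · clashes_per_residue
```

Ramachandran outliers are residues outside three generous boxes (general
φ < −20 with helical or extended ψ; left-handed helix φ ∈ (20, 120),
ψ ∈ (−60, 90)). Clashes are heavy-atom pairs under 2.0 Å between residues at
least two apart in sequence. Zero on ideal geometry; it correlates strongly
(Spearman ρ > 0.5 in tests) with true RMSD on noisy pools, which is all the
pipeline stage requires.

## Selection pipeline

cluster → representatives → CS top 10 → quality top 5 → refine the quality
best (identity hook by default) → CS-rank refined → merge with the quality
five, de-duplicating by id → CS re-rank → up to five final models. All
stage decisions are recorded in a trace for auditability.

## Evaluation

Model and native sequences are aligned globally (BLOSUM62, gap open −10,
extend −0.5; verified against an independent Gotoh dynamic program), aligned
pairs where either side lacks a Cα are dropped, and Cα RMSD plus TM-score
are computed over the mapped pairs. Multi-target summaries report
best-of-five fractions with inclusive thresholds TM ≥ 0.5, RMSD ≤ 5.0 Å.

## Synthetic generator

Natives are built by NeRF chain extension with fixed ideal geometry (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111.2°, 116.6°, 121.9°; ω = 180°)
from per-topology (φ, ψ) schedules: helix (−57, −47), strand (−120, 130),
turn (90, 0), coil (−140, 60). Topologies: helix, β-hairpin,
helix-loop-helix; default sequence alternates Leu/Lys so every residue has a
Cβ (placed with standard tetrahedral-geometry coefficients) and the
nonpolar-surface terms have signal. Decoys are the native plus isotropic
Gaussian coordinate noise, then a random rigid motion (uniform rotation,
±10 Å translation); each decoy carries ground-truth provenance (σ and true
Cα RMSD). The benchmark generator cycles topologies, draws lengths in
30–80, and includes the unperturbed native in each pool under the id
`native`.

**Limitations of the generator.** Gaussian-noise decoys are not realistic
predictor output: real decoy pools contain alternative folds, shifted
secondary structure elements, and compact-but-wrong topologies, whereas
noise moves every model radially away from one basin and destroys local
geometry (at σ = 0.5 Å most φ/ψ pairs already leave their assignment
windows, which is why PH sits near 100 even for good decoys in the worked
example). Consequently the benchmark demonstrates that the pipeline is
internally consistent and strongly enriches for low-RMSD models under known
perturbation — not that pcSM's specific coefficient values are optimal for
real decoy sets, which were fit elsewhere on predictor output against
experimental structures. A related artifact: the A1 descriptor is not
monotone in σ on these pools (the alternating Leu/Lys surface composition
barely changes under noise), so monotonicity checks are asserted on A4 and
M1 only.

## Problem sizes and numerics

Defaults are sized for a single CPU: 960-point SASA lattice, 500-decoy
pools, 10-target benchmark (about 10 minutes end to end). All randomness
flows from explicit `numpy` `default_rng` seeds; every public computation is
deterministic given its inputs. Floating-point policy: closed-form checks at
1e-12…1e-6, geometric invariances at 1e-9 (enabled by the explicit-residual
RMSD), discretization-limited quantities (SASA, TM heuristic) at their
measured convergence (1%, 0.005).
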