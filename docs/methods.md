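# Methods

This note records the scientific and numerical choices behind each module:
what is modeled, which parameters matter, what the synthetic generators do
and do not emulate, and where the design was genuinely open.

## Library standardization and filtering

Standardization keeps the largest organic fragment (salt/counter-ion
removal), clears isotope labels, neutralizes charges by protonation or
deprotonation of standard acidic/basic groups (RDKit's uncharger; zwitterions
stay neutral overall), and writes one canonical aromatic form.  The operation
is idempotent — standardizing a standardized molecule is a no-op — which the
suite checks on the full fixture library.

Property filters use inclusive bounds throughout: MW ∈ [100, 700] Da,
stereocenters ≤ 6 (assigned + unassigned), atoms ≤ 60 *including hydrogens*
(the stricter reading; configurable via `FilterConfig.count_hydrogens`),
rotatable bonds ≤ 15, elements ⊆ {C, N, S, H, O, P, B, F, Cl, Br, I}
("halogens" excludes astatine by drug-library convention).  The rotatable
bond is defined structurally — a non-ring single bond between two heavy atoms
that each carry at least one further heavy neighbor, excluding amide C–N —
and implemented directly from that definition rather than through a SMARTS
pattern, so the brute-force enumeration oracle in the tests is meaningful.

Substructure exclusion uses the published PAINS families (via RDKit's filter
catalog).  The toxicophore and medicinal-chemistry rule collections used by
screening vendors are not public; the shipped stand-ins are small, documented
SMARTS sets (nitroso, aromatic azo, acyl halide, isocyanate, Michael-acceptor
aldehyde; peroxide, thiourea, hydrazine, phosphonate ester) and are fully
configurable/replaceable.

## Binding-site flooding

The pocket is the set of unoccupied voxels reachable from a seed by
6-connected steps on a cubic lattice, truncated at a Euclidean radius from
the seed.  Conventions:

- lattice anchored to world coordinates (`voxel = floor(xyz / spacing)`), so
  a sub-voxel seed shift cannot change the result;
- a voxel is occupied when any heavy atom lies within `r_occ` of its center;
- defaults `spacing` 1 Å, `r_occ` 2.0 Å, `max_radius` 12 Å, site residues
  within `d_site` = 4.5 Å of a flooded voxel center.  The flooding literature
  this mimics gives no parameter values; these are package choices and all
  are configurable.

Seeding from a residue list (the use case for a binding site known only as
"surrounded by residues …") floods from the unoccupied voxel nearest the
centroid of the named residues' atoms.

## Pose generation

Rigid-body placement of a fixed input conformer: rotations uniform on SO(3)
(normalized-quaternion method), translation to a uniformly drawn flooded
voxel center, accepted when the minimum heavy-atom distance to the protein is
at least `clash_cutoff` (default 2.2 Å; the synthetic benchmark uses 1.0 Å
because its "ligands" are bare point clouds).  No torsional sampling — the
original screen's docking engine is not disclosed, and rigid placement is the
minimal model that exercises the scoring machinery.  Sampling fails with
`pocket_too_small` when the acceptance rate falls below 1/10,000.

## Voxel featurization

Binary presence occupancy ("is an atom of this class in this cube"), not
Gaussian densities.  Voxels are half-open cubes `[x, x + spacing)`; the
default grid spans [−15, +15) Å per axis.  Channels are
(entity ∈ {protein, ligand}) × (element class ∈ {C, N, O, S, P, B, halogen,
other}); a 2-channel entity-only scheme exists for cheap training runs.  The
original atom-type vocabulary is not disclosed; the scheme is configurable
and fingerprinted, and a model refuses grids whose spec differs from the one
it was built against.  Augmentation applies one uniform rotation about the
site center plus a translation uniform in [−2, 2]³ Å (t_max unstated in the
source method; 2 Å keeps typical complexes inside the grid).

## Scoring network

Default architecture: conv 32×3³ (stride 1), 64×3³ (2), 64×3³ (2), 64×3³ (2),
64×2³ (1), valid padding, ReLU after every convolution, FC-256 ReLU, linear
scalar output — strides chosen so a 30³ input collapses to 1³ before the
dense head (340,257 parameters at 16 input channels; verified in closed form).
Pose scores are combined by weighted Boltzmann averaging
`S = Σ sᵢ e^{βsᵢ} / Σ e^{βsᵢ}` (max-shifted for overflow safety), the natural
reading of "Boltzmann averaging" over pose scores: β = 0 gives the arithmetic
mean, β → ∞ the maximum.  β defaults to 1.0 (score units⁻¹) and is part of
the model.  Aggregation sits inside the training loss (it is differentiable),
so training sees exactly the quantity that is reported at screening time.
Loss is MSE on the pKi/pIC50 scale, optimizer Adam, minibatch 64, seeded
shuffling; with single-threaded BLAS a run is bit-reproducible.

Implementation is pure NumPy: im2col gather indices are precomputed per layer
and the col2im backward pass uses a precomputed inverse gather, which keeps
everything as BLAS matmuls.  Two training-only devices improve desk-scale
behavior and are on by default (both can be disabled in `TrainConfig`):

- decoupled weight decay (1e-4) on weight matrices;
- data augmentation by the 24 proper cube rotations of the grid, drawn per
  example per step — exact for binary occupancy grids, free of
  re-rasterization cost, and the discrete analogue of the rotational
  augmentation used at featurization time.  Without it the small network
  memorizes the 400-complex training set (train MSE below the label noise
  floor) and held-out rank correlation stalls near 0.5; with it the same
  budget reaches ≈ 0.95.

`NetworkConfig.reduced()` (3 conv layers, 8/16/16 filters, FC-32) is the
desk-scale stack used with 16³ two-channel grids; the full 30³ architecture
is exercised functionally in the suite but not trained to convergence there.

## Ranking and diversity selection

Higher score = better (pK scale); ties broken by compound id so ranking is
input-order invariant.  The 5000 → 89 triage in the original campaign was
partly manual ("diverse chemical scaffolds"); here it is greedy max-min
selection on Tanimoto distance over Morgan fingerprints (radius 2, 2048
bits), seeded at the top-ranked candidate.  Greedy max-min is per-step
optimal (each pick attains the exhaustive maximum of the minimum distance to
the already-selected set — verified against exhaustive search at small n) but
not globally subset-optimal; no polynomial method is.

## Degron scanning

Motif classes default to Φ = {A,V,L,I,M,F,P,G,W,Y,C} and
π = {S,T,N,Q,D,E,H,K,R,Y,C} with positions [Φ][π][S][S/T][S/T], following the
canonical SPOP-degron consensus; the published evidence for VTSSS is an
alignment, not a consensus definition, so the classes are an interpretation
and fully configurable.  Coordinates are 1-based; `X` is tolerated in input
and never matches.

## TMT post-processing

Channel normalization scales each reporter channel to the mean of all channel
sums (equal-loading assumption); it is idempotent and rank-preserving within
channels.  Differential abundance uses a two-sided Welch t-test on log2
intensities (the original analysis names only spreadsheet-level tools; the
unequal-variance form is the conservative default, pooled variance is an
option) with log2fc = log2(mean +Tet / mean −Tet).  Thresholds: raw p < 0.05
(no multiple-testing correction, matching the stated criterion; an FDR option
would be easy but is deliberately not the default) and |log2fc| ≥ 0.5 — the
boundary is inclusive because the published down-regulated list contains
−0.5 exactly.  The published tables carry a header ("−Tet vs +Tet") whose
literal reading contradicts the sign of their entries; the package follows
the biology (negative = down upon depletion) and records the discrepancy.
Proteins with missing channels or a zero group mean are flagged and excluded
from thresholding; imputation is out of scope.

## Synthetic generators: what a green test establishes

The generators produce the *mechanistic* structure of each input, not its
physics or biology:

- **Pockets** are hollow atom shells with atoms on voxel centers; flooding
  them with `r_occ = 0.9·spacing` makes the flooded count exactly
  `cavity_edge³`.  The default pocket is sealed: an opening would let the
  flood reach the exterior and destroy the closed form (an optional `mouth`
  exists for pose experiments).  Real pockets have irregular shapes, partial
  enclosure, and chemistry; none of that is represented.
- **The affinity oracle** is `a0 + a1·contacts − a2·clashes + noise`
  (defaults a0 = 4 pK, a1 = 0.2 pK/contact, contact cutoff 4 Å, label noise
  0.1 pK): deliberately simple so a small CNN can recover it in CPU-minutes.
  Recovery (held-out Spearman ≥ 0.7) demonstrates that grids carry the
  contact information and that training/aggregation are wired correctly — it
  says nothing about real binding affinity.
- **The screen benchmark** uses 500 complexes (400/100 split by compound, no
  pose leakage), 8 poses each rather than the production 64, 16³ two-channel
  grids — pure CPU-budget scaling; the complex label is the Boltzmann
  aggregate (same β) of noise-free per-pose oracle values plus noise.
- **The filter fixture** plants hand-verified single-rule violators (each
  SMILES breaks exactly one filter) so per-reason rejection counts can be
  checked by equality.
- **The TMT fixture** draws log-normal intensities (log2 base N(20, 1.5),
  within-group SD 0.1), plants 50 of 1000 proteins at log2fc = −1 in the
  +Tet channels, and multiplies per-channel loading factors that
  normalization must remove.  With n = 3 vs 3 and normal noise the null
  p-values are exactly uniform, which the suite checks by a
  Kolmogorov–Smirnov test.

## Known limitations

- No torsional/flexible docking, no protonation/tautomer enumeration, no
  conformer generation for real molecules (a conformer must be supplied).
- The NumPy network trains small models only; there is no GPU path.
- The diversity step models, but cannot reproduce, a partly manual selection.
- Vendor toxicophore/medchem rule sets are stand-ins.
- Proteomics assumes the post-search protein×channel table as input; no
  peptide-level processing, isotope-impurity correction, or imputation.
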