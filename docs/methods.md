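# Methods

## Confidence filtering

Predicted models carry a per-residue confidence (pLDDT, 0–100) in the
PDB temperature-factor column. A chain's confidence is the plain
arithmetic mean over **all** residues (no trimming), and retention is
strict: kept iff mean pLDDT > threshold (default 80), so a mean of
exactly 80 is removed. Files whose confidences all lie in [0, 1] are
assumed to be on a fractional scale and rescaled ×100 with a logged
warning. Alternate locations resolve to the highest occupancy (ties: the
first occurrence); without an explicit chain id the first chain in the
file is used. Consecutive Cα–Cα distances outside (2.0, 4.5) Å are
logged but never fatal — synthetic coils and noisy models legitimately
stray outside the band.

## Superposition and TM-score

Rigid superposition is the closed-form Kabsch solution: SVD of the
cross-covariance of the centered point sets, with the smallest singular
direction sign-flipped when the raw solution is a reflection, so the
rotation is always proper. Point sets of rank < 2 (collinear) are solved
but logged, since the rotation about the line is then arbitrary.

TM-score uses the standard normalization
`d0(L) = 1.24 (L − 15)^(1/3) − 1.8`, clamped below at 0.5 Å (the formula
goes negative for short chains). Because the two chains of a pair
generally differ in length, the score is computed under both
normalizations; the **symmetric TM** (their mean) feeds the similarity
matrix, which must be symmetric for UPGMA. The per-chain normalizations
remain available in the pair table, and the pipeline can be switched to
the shorter-chain normalization (`tm_normalization="shorter"`).

## Sequence-independent alignment

The aligner is a deliberately simple, auditable take on iterative
structural alignment:

1. **Seeding.** Gapless threading of the shorter chain onto the longer
   at every offset (configurable stride, default 1). Each seed is scored
   by superposing on its correspondence and evaluating symmetric TM.
2. **Refinement.** The best `max_refined` seeds (default 5) are refined:
   superpose on the current correspondence, build the score matrix
   `S_ij = 1/(1 + (d_ij/d0)^2)` (d0 of the shorter chain), run global
   affine dynamic programming (gap-open −0.6, free extension, traceback
   ties prefer diagonal, then up, then left), and repeat until the
   correspondence repeats (convergence or a cycle) or 30 iterations.
3. **Selection.** The correspondence with the highest symmetric TM seen
   anywhere wins; its RMSD and transform come from a final least-squares
   superposition.

Refining only the top-scoring seeds, and terminating a refinement as soon
as a correspondence recurs, are the two performance choices; both are
deterministic, and the all-offset seed scan is retained in full.
Symmetry is exact by construction: the pair is reordered internally to a
canonical (length, id) order, so `align(A, B)` and `align(B, A)` return
identical scores. There is no secondary-structure seeding and no
fragment-rotation search — unrelated folds score low (~0.1–0.2), which
is all downstream clustering needs.

## Combined similarity

`S = w_tm · TM_sym + (1 − w_tm) · (1 − min(RMSD/r_max, 1))`, with
defaults `w_tm = 0.7` and `r_max = 10 Å`. TM-score carries most of the
weight because it is bounded and length-normalized, whereas raw RMSD over
the aligned subset is scale-dependent; the linear RMSD term saturates at
`r_max`, beyond which pairs are simply "different". The per-pair
saturating form was chosen over dataset-level min–max rescaling of RMSD
(the other plausible reading of a "normalized RMSD") because it keeps the
score a pure function of the pair — adding a structure to the dataset
cannot change existing similarities. Dataset-level scaling is
deliberately not implemented.

## UPGMA and the tree

UPGMA operates on `D = 1 − S` (it is defined on dissimilarities; the
conversion is the standard bounded complement). Merge heights are the
minimal average inter-cluster distances themselves, so the cophenetic
distance of two leaves equals the height of their lowest common merge,
and `cophenetic(upgma(D)) = D` exactly when D is ultrametric. Newick
output places nodes at half the merge height (leaf-to-leaf path length
through the tree then reproduces the cophenetic distance), with 6-decimal
branch lengths and single-quoting of labels containing reserved
characters. Ties in the minimal distance are broken by the
lexicographically smallest (min leaf label, min leaf label) pair, which
makes the tree invariant to input row order and reproducible across
platforms. Flat clusters cut the k−1 highest merges and index the
resulting components by smallest member label. Alternative linkages and
bootstrap support are out of scope.

## Sequence baseline and concordance statistics

The sequence tree is built from pairwise global alignment identity
(match +1, mismatch 0, linear gap −1, deterministic traceback
diagonal > up > left; identity = matches / alignment columns;
distance = 1 − identity) followed by the same UPGMA — a transparent,
self-contained baseline that keeps both trees ultrametric and therefore
directly comparable. It is *not* a maximum-likelihood phylogeny; it
stands in for one as a grouping baseline only.

Concordance is reported as: Robinson–Foulds distance by explicit
bipartition enumeration (maximum 2(n−3) for binary trees); adjusted Rand
index of each tree's k-cut against reference labels (computed from the
contingency table, with the degenerate zero-denominator case defined as
1 if the partitions' co-membership is identical, else 0); Pearson
correlation of the two cophenetic matrices; and the list of leaves whose
set of cluster co-members differs between the two k-cuts. Note the
discordant set is intentionally *transitive*: swapping one member's
sequence also perturbs the co-membership of the clusters it leaves and
joins, so the planted swap ids are a subset — not the entirety — of the
reported discordant ids. No single published statistic exists for this
comparison; the report's composition is this package's own definition.

## Synthetic data

The generator emulates a structure-prediction run over a protein family:

* **Template folds** — per family, alternating ideal α-helices (rise
  1.5 Å/residue, radius 2.3 Å, twist 100°/residue; consecutive Cα ≈
  3.83 Å) and self-avoiding random-walk coils with 3.8 Å steps, segments
  joined under random rigid placements rejected when any non-bonded Cα
  pair falls below 3.0 Å (bounded retries, then an error).
* **Members** — template + i.i.d. Gaussian coordinate noise (sd `sigma`
  per coordinate), a random rigid displacement, and with probability
  `indel_rate` a terminal truncation of up to 10 % of the chain.
  Two independently noised copies superpose at RMSD ≈ σ√6.
* **Confidence** — core residues ~ Normal(`plddt_core`, 3), 10-residue
  termini ~ Normal(`plddt_tail`, 3), clipped to [0, 100]; members chosen
  as low-confidence are shifted until their mean hits a target drawn in
  [70, 79], guaranteeing removal by the strict >80 filter.
* **Sequences** — a random 20-letter consensus per family, per-member
  substitutions at `seq_mut_rate`; a `swap_fraction` of members instead
  receive the *next* family's consensus (mutated the same way), planting
  structure-vs-sequence discordance with recorded ids.

Defaults (chosen once as a realistic desk-scale family study): 5 families
× 6 members, 200 residues (the low end of the 200–500-residue single-chain
range typical of the enzyme families this targets), σ = 0.5 Å (the
backbone spread of repeated predictions of close homologs), indel rate
0.1, substitution rate 0.05, pLDDT core/tail 90/70 (mean ≈ 88, safely
above the filter), no swaps. `members_per_family` accepts a per-family
list so totals such as 82 = 17+17+16+16+16 with five planted
low-confidence members are expressible.

All randomness flows from one integer seed through numpy's PCG64
(`default_rng`) via spawned `SeedSequence` children (one per fold, member
and confidence profile), so a spec reproduces bit-for-bit.

What the generator does **not** emulate: real side-chain packing,
Ramachandran statistics, β-sheets, domain motions, or the correlated
error structure of real predictors. Passing tests therefore demonstrate
the pipeline's correctness and discriminative behaviour on controllable
fold families, not predictor-specific accuracy on any real proteome.

## Numerical and design notes

* The two dynamic-programming inner loops (structural DP, sequence NW)
  are numba-compiled; everything else is numpy/scipy. Results are
  independent of compilation.
* Pipeline artifacts use fixed-precision text formats (6 decimals for
  matrices and branch lengths) and contain no timestamps, so identical
  config + seed gives byte-identical files; the manifest records SHA-256
  checksums.
* An all-pairs run is O(n²) alignments; a `max_structures` guard
  (default 200) protects interactive use.
* Test and acceptance runs use 60–200-residue chains and 12–82-member
  sets — sizes at which every stage's behaviour (recovery, degradation
  with noise, discordance) is already fully expressed.
* Robinson–Foulds on two UPGMA trees of the same leaves is usually large
  even for concordant flat clusters, because within-cluster fine
  structure differs; the ARI/discordant-id statistics, not RF alone,
  carry the subfamily-level signal.
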