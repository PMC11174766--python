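# foldclust

Structure-based clustering of predicted protein models — for protein-family
studies where structure predictions (AlphaFold-style single-chain models with
per-residue pLDDT in the B-factor column) are available for every family
member and the question is *how the family organizes by fold*, and whether
that organization agrees with sequence-based grouping.

The pipeline:

1. **Confidence filter.** A model is retained only if its mean per-residue
   pLDDT is strictly greater than 80 (low-confidence predictions are not
   meaningful inputs to geometric comparison).
2. **Pairwise comparison.** Every retained pair is aligned
   sequence-independently (gapless threading seeds + iterated Kabsch
   superposition / dynamic programming on TM-score terms), yielding a
   TM-score

   $$\mathrm{TM} = \frac{1}{L}\sum_{i\in\text{aligned}} \frac{1}{1+(d_i/d_0(L))^2},
   \qquad d_0(L) = 1.24\,(L-15)^{1/3} - 1.8 \;(\ge 0.5\,\text{Å}),$$

   reported under both chain-length normalizations (symmetric TM = their
   mean), and an RMSD over the aligned Cα pairs.
3. **Combined similarity.** TM-score and normalized RMSD are fused into
   one bounded similarity,
   $S = w\,\mathrm{TM} + (1-w)\,\bigl(1 - \min(\mathrm{RMSD}/r_{\max},\,1)\bigr)$
   with defaults $w = 0.7$, $r_{\max} = 10$ Å.
4. **Clustering.** UPGMA on $D = 1 - S$ produces a rooted ultrametric tree,
   exported as iTOL-compatible Newick; flat clusters come from cutting the
   tree at a chosen cluster count *k*.
5. **Structure vs sequence.** A transparent sequence baseline (pairwise
   global-alignment identity → UPGMA) is compared with the structure tree
   via Robinson–Foulds distance, adjusted Rand index against reference
   subfamily labels, cophenetic correlation, and an explicit list of the
   proteins that the two groupings place differently.

A first-class synthetic generator builds fold families (ideal α-helices
joined by self-avoiding coils) with tunable coordinate noise, terminal
truncations, simulated pLDDT profiles, and deliberately *discordant*
sequences (members whose sequence comes from another family), so every
stage of the pipeline can be validated against planted ground truth.

## Worked example

```python
import foldclust as fc

spec = fc.SyntheticFamilySpec(n_families=3, members_per_family=4,
                              length=60, sigma=0.3, seed=11)
dataset = fc.generate_dataset(spec)

tree, pairs = fc.structure_tree(dataset.structures)
partition = fc.cut_tree(tree, k=3)
print(fc.adjusted_rand_index(partition, dataset.labels))
```

prints `1.0`: at 0.3 Å coordinate noise the structure tree, cut at the
family count, recovers the three planted families exactly. A typical
within-family pair scores `TM-score (sym) = 0.930, RMSD = 0.90 Å,
combined similarity = 0.924`, while a between-family pair scores
`TM = 0.215, RMSD = 6.67 Å, combined = 0.251` — the gap that makes the
clustering clean. The scripts in `examples/` walk through each capability
(confidence filtering, pairwise alignment, clustering, structure-vs-sequence
comparison) and print annotated output.

The same analysis is available from the shell:

```bash
foldclust simulate --families 3 --members 4 --length 60 --sigma 0.3 --seed 11 --out data/
foldclust run --in data/ --out results/
```

which writes the filter report, pair-score table, similarity/distance
matrices, both Newick trees, the comparison report, and a checksummed
manifest (identical config + seed ⇒ byte-identical artifacts).

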