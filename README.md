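# kmerphylo

Alignment-free phylogenies from CG/TA-classified 8-mer rank signatures.

Vertebrate and invertebrate genomes deplete the CpG and TpA dinucleotides,
and the strength of that depletion tracks evolutionary divergence. This
package turns the idea into a reproducible pipeline for whole genomes, with
no alignment and no ortholog calling:

1. **Count** every 8-mer of a genome with a sliding window (step 1 bp,
   forward strand, ambiguous windows skipped). The universe has
   4⁸ = 65,536 words.
2. **Partition** the universe by the number of occurrences of an ordered
   dinucleotide XY in each 8-mer (overlaps counted): XY0 (none), XY1
   (exactly one), XY2 (two or more). For X ≠ Y the sizes are
   40,545 / 21,468 / 3,523, for X = Y they are 44,631 / 14,931 / 5,974.
3. **Locate** each subset's occurrence spectrum relative to the *random
   center* x̄ = total windows / 4⁸ by the separability
   δ_XYi = x̄ / x̄_XYi (δ > 1 ⇒ subset sits at the low-frequency end).
   CG- and TA-containing 8-mers are the ones whose spectra separate from
   the background, so **CG1 ∪ CG2** (N = 24,991 8-mers) and its TA
   counterpart are the evolution-bearing feature sets.
4. **Rank-transform** the feature set's counts: members are sorted by
   actual frequency from small to large and the 1-based order (the
   *relative frequency*) is the feature value — robust to genome size and
   to any monotone distortion of the counts.
5. **Distance**: for genomes *a*, *b* over a feature set of size N,

   D_ab = √( Σᵢ (x_ai − x_bi)² / N )

   the root-mean-square rank difference (a scaled Euclidean metric).
6. **Tree**: neighbor joining (Saitou–Nei) on the distance matrix, written
   as Newick; deterministic tie-breaking makes runs byte-reproducible.

A first-order Markov simulator with tunable CG/TA suppression plus
Jukes–Cantor evolution along a known tree provides download-free,
ground-truthed validation of the whole pipeline.

## Worked example

Simulate eight genomes (200 kb each) along a balanced tree with CG
suppression λ_CG = 0.3, then rebuild the tree from CG1+CG2 ranks:

```bash
kmerphylo simulate --n-taxa 8 --length 200000 --lambda-cg 0.3 --seed 1 --out-dir sim
kmerphylo pipeline --fasta-dir sim --set CG12 --out-dir run --true-tree sim/true_tree.nwk
```

prints (log lines elided):

```
T8: 200000 bp, 199993 windows
wrote run/distances.phy and run/tree.nwk
RF distance to true tree: 0
```

`199993` is the number of counted windows (200,000 − 8 + 1). The
Robinson–Foulds distance of 0 means the neighbor-joining tree built from
rank distances has exactly the unrooted topology the genomes were
simulated on. `run/` also holds per-genome count, δ and rank TSVs, the
PHYLIP distance matrix, and a `manifest.json` recording k, the feature
set (`CG12`, 24,991 members), and the tie policy, e.g.:

```
"feature_set": "CG12", "feature_set_size": 24991, "rf_to_true_tree": 0
```

The same steps are available as library functions
(`count_kmers`, `partition_by_dinucleotide`, `separability_table`,
`relative_frequency`, `distance_matrix`, `neighbor_joining`) for use on
real FASTA genomes — one file per taxon, multi-record files welcome.

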