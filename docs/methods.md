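# Methods

## The statistic and the model behind it

Genomes are compared through the composition of their 8-mer vocabulary,
not through alignments. Three ingredients matter.

**The dinucleotide partition.** For an ordered dinucleotide XY, every
8-mer is assigned the class min(2, number of XY occurrences), overlapping
occurrences counted (so `AAAAAAAA` holds seven `AA`s). The classification
is purely combinatorial — it depends on k and XY, never on data — and the
class-0 sizes admit closed-form checks: the number of k-mers free of a
non-self-overlapping pair (X ≠ Y) obeys g(n) = 4·g(n−1) − g(n−2), and
free of a self-overlapping pair (X = Y) obeys f(n) = 3·f(n−1) + 3·f(n−2),
both with g(0) = 1, g(1) = 4. The test suite checks the enumerating code
against these recurrences and against brute force at small k. By symmetry
of the alphabet, all 12 unequal pairs share one size triple and all 4
equal pairs the other; this is also asserted.

**Separability.** With total windows W, the random center is
x̄ = W/4⁸ — the count every 8-mer would have if the genome were a random
word. A subset's location is its mean count x̄_XYi with absent members
counted as zero; δ_XYi = x̄/x̄_XYi. Including zero-count members in the
denominator is what keeps all 48 δ values defined on every genome; a
subset whose members are all absent yields δ = undefined (reported as an
empty cell with a warning, never ∞). Two identities are property-tested:
Σᵢ sizeᵢ·x̄_XYi = W for every XY (mass conservation), and consequently
Σᵢ sizeᵢ/δᵢ = 4⁸ (the size-weighted mean of 1/δ is 1). δ is invariant
under duplicating the genome, since numerator and denominator scale
together.

**Ranks and the distance.** Within a feature set (default CG1 ∪ CG2,
N = 24,991), counts are replaced by their ascending 1-based order. The
default **ordinal** policy breaks count ties by ascending k-mer index:
deterministic, and the ranks are an exact permutation of 1..N. The
**average** policy (mean rank within a tie group) is available for users
who prefer tie-symmetric vectors; with low-coverage genomes many 8-mers
tie at small counts, and the two policies can differ noticeably there.
Ranks for union sets are computed jointly over the union
(`rank_scope="union"`); per-class ranking is kept as an option for the
alternative reading where each class is ordered separately. The distance
D_ab is the RMS rank difference — Euclidean distance scaled by 1/√N,
hence a true metric; its maximum over ordinal rank vectors is
√((N² − 1)/3), attained by a permutation and its reversal (verified
exhaustively through N = 6).

Because ranks are invariant under any strictly increasing transformation
of counts, the method is insensitive to genome size and to multiplicative
count distortions — the main motivation for preferring ranks over raw
frequencies.

## Neighbor joining

Classic Saitou–Nei agglomeration on the Q criterion, implemented in-repo
so tree construction is scriptable and deterministic end to end
(the distance matrix interchanges with MEGA and other tools via square
PHYLIP format for anyone who prefers an external NJ engine). Numerical
choices:

- Q-ties are broken by the lexicographically smallest (row, column) pair
  of the current matrix, so identical inputs give identical Newick.
- A negative branch length at a join is clamped to zero and the deficit
  moved to the sister branch, preserving the pair's path length (common
  practice; only arises off the additive cone).
- The last three lineages are joined by the three-point closed form with
  lengths clamped at zero; the seed node is the resulting trifurcation,
  i.e. the tree is unrooted.

On any matrix that is additive on a binary tree with positive branch
lengths, NJ provably returns that tree; the suite checks RF = 0 and
path-length agreement to 1e-9 on random trees with 5–12 leaves and
branch lengths in [0.1, 2], and cross-checks topology against
scikit-bio's independent NJ implementation.

## The synthetic generator

`synthetic` exists so the pipeline can be validated against a known
history without downloading genomes. It emulates exactly two features of
real genomes: dinucleotide suppression and tree-structured divergence.

- **Root sequence**: first-order Markov chain started from its stationary
  distribution. The transition matrix is the independence matrix for a
  target GC content with the C→G entry multiplied by λ_CG and T→A by
  λ_TA, rows renormalized. λ = 1 means no suppression; mammal-like CpG
  depletion corresponds to λ_CG around 0.2–0.3, which is why 0.3 is the
  default. Default root length 200 kb keeps mean 8-mer coverage near 3,
  enough for stable ranks over 25k features while staying fast.
- **Evolution**: Jukes–Cantor, i.i.d. per site — along a branch of length
  b (expected substitutions/site) each site substitutes with probability
  (3/4)(1 − e^(−4b/3)), uniformly to another base. The closed-form
  saturation limit (3/4 differing sites) and the b = 0 identity serve as
  oracles. JC substitution slightly erodes the dinucleotide bias along
  branches; acceptable because recovery is judged on topology, not on δ.
- **Seeding**: one master seed; the root and each branch draw from
  numpy streams derived from (seed, preorder node id), so outputs are
  byte-reproducible and independent of leaf labels.

What the generator does *not* model: methylation–deamination mechanisms,
rate heterogeneity, indels, context-dependent substitution, isochores,
repeats. Passing recovery tests therefore show that the statistical
machinery is sound under controlled dinucleotide bias — not that the
feature set resolves any particular real clade.

## Validation conditions and problem sizes

The stochastic end-to-end check uses an 8-taxon balanced tree, all
branches 0.05 substitutions/site, 200 kb roots, λ_CG = 0.3, and requires
the CG12-rank pipeline to recover the true topology (RF = 0) in at least
9 of 10 seeds; the δ response check averages 5 seeds of 500 kb sequences
per λ_CG ∈ {0.2, 0.5, 1.0} and requires δ_CG1 to decrease strictly as
suppression weakens, reaching ≈1 (±0.05 across all 48 subsets) at λ = 1.
These sizes give comfortable margins (observed: 10/10 recovery;
δ ≈ 3.0 → 1.5 → 1.0) while keeping the suite quick on a laptop.

## Degenerate inputs and edge cases

- Windows containing any non-ACGT IUPAC code are skipped deterministically
  (never randomly resolved); a genome with no countable window is an
  error, as is an empty FASTA.
- Counting is forward-strand only: CG and TA are reverse-complement
  palindromes, so the targeted signal is strand-robust by construction.
- Multi-record files are one taxon; windows never span record boundaries,
  so counts are exactly the per-record sums.
- `minimum_k(L) = ceil(0.7·log₄ L)` reads the k-selection rule as a
  minimum, hence the ceiling; a 1e-9 back-off keeps exact powers of 4
  from being rounded up by float error.
- Empty subsets (possible only at small k, e.g. CG2 at k ≤ 3) raise a
  specific error rather than returning vacuous spectra.

## Known limitations

- Dense 4^k count vectors make k ≤ 12 practical; no canonical
  (strand-collapsed) k-mers.
- No bootstrap support, rooting, or tree visualization — Newick output is
  meant for downstream tools.
- The published-scale analyses (hundreds of real genomes) require bulk
  sequence downloads and are out of scope here; the simulator-based
  checks substitute controlled ground truth for them.
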