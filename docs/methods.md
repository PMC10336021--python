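# Methods

## The ranking statistic

`taumark` treats marker selection as a rank-agreement problem. Let
`D_g` be the pairwise distance matrix induced by locus *g* over the
genome collection and `D_ref` a genome-wide reference matrix over the
same genomes. Both matrices are flattened into paired vectors over the
genome pairs defined in both (labels sorted lexicographically, upper
triangle in row-major order, pairs masked in either matrix dropped),
and the locus is scored by Kendall's tau-b:

    tau_b = (C − D) / sqrt((n0 − n1)(n0 − n2))

with `C`/`D` the concordant/discordant pair counts, `n0 = n(n−1)/2`,
and `n1`, `n2` the tie terms `Σ t(t−1)/2` over tied groups of each
vector. Tau-b is the deliberate choice of variant: distance matrices of
closely related genomes contain many exact ties (identical sequences),
and the tie-free variants coincide with tau-b when ties are absent.
Spearman's rho (Pearson on midranks, via scipy) and Pearson's r²
(signed r retained in the result metadata) are alternatives; tau and
rho are invariant under strictly increasing transforms of either
matrix, r² is not.

The C(n,2) genome pairs are treated as exchangeable observations for
ranking purposes only. No Mantel-style permutation p-value is computed:
the coefficient is a ranking heuristic, not a test statistic, and the
non-independence of matrix entries would invalidate naive p-values
anyway.

Degenerate comparisons never abort a run: fewer than `min_pairs`
(default 3) common unmasked pairs, or a zero-variance vector, yield a
flagged result (`too_few_pairs` / `zero_variance`) that sorts to the
bottom of the ranked table with its flag preserved.

## Distances

All sequence comparisons use pairwise deletion: a column counts for a
pair only when both characters are in `{A,C,G,T}` (gaps, N and other
IUPAC codes are excluded per pair, not per column). Transitions are
A↔G and C↔T; everything else is a transversion.

- **identity**: `d = p`, the raw mismatch proportion. Identities and
  ANI are similarities; everything is converted to distance so all
  matrices share a monotone orientation and expected correlations are
  positive.
- **jc69**: `d = −(3/4) ln(1 − 4p/3)`, undefined for `p ≥ 3/4`.
- **k80**: `d = −(1/2) ln(1 − 2P − Q) − (1/4) ln(1 − 2Q)` from the
  transition/transversion proportions, undefined when either log
  argument is ≤ 0.

Saturated (out-of-domain) corrections are **masked**, not capped:
capping would manufacture tied distances at the cap and bias the rank
correlation. A `saturation_cap` option exists for users who need a
finite matrix. Pairs with fewer than `min_sites` (default 1) comparable
columns are likewise masked, since a handful of sites produces noisy
ranks.

The **core-gene ANI** reference is the length-weighted mean identity
over loci where both genomes are present:
`identity(a,b) = Σ_g (1 − p_g)·n_g / Σ_g n_g`, reported as
`1 − identity`. When every locus covers every genome this equals the
identity distance on the concatenated super-alignment exactly (an
algebraic identity the tests check to 1e-12). The **concat** reference
applies the chosen model to the concatenation of all core loci;
concatenation appends loci in ascending `locus_id` order and gap-fills
missing taxa.

Trees supplied as references are converted to **patristic** distances
(sum of branch lengths along the leaf-to-leaf path). Patristic rather
than topological distance is the documented choice: branch lengths are
where a recombination-corrected or coalescent reference tree carries
its information.

## Trees

Newick I/O is restricted to unquoted labels over `[A-Za-z0-9_.-]` (the
same alphabet sample sheets allow), with internal node names tolerated
and ignored; parse errors report a character offset. Written Newick is
canonical — children ordered by smallest descendant leaf label, branch
lengths with 6 decimals — so equal trees serialize identically and
byte-level determinism of outputs is meaningful.

Per-locus trees (optional output) are built by Saitou–Nei neighbor
joining on the locus matrix. Ties in the Q-criterion are broken by the
lexicographically smallest pair of node keys (a node's key is its
smallest descendant leaf label), making the algorithm deterministic.
Negative branch lengths, which NJ can produce on non-additive input,
are clamped to 0 — common practice; on additive input no clamping
occurs and NJ reproduces the input matrix exactly (tested to 1e-9 via
patristic round-trip). The NJ tree is left unrooted (trifurcating
root): distances, not rooting, drive the method. NJ requires a fully
observed matrix; masked entries raise an error pointing at
`core_fraction`.

## Core filtering and inputs

Loci arrive as per-locus FASTA alignments (the taxon label is the
header token before the first whitespace; sequences are uppercased and
`U`→`T` on read). The genome universe is declared either by the union
of taxa across loci or by a `sample,fasta` CSV sample sheet; when a
sheet is given, alignments are additionally restricted to its taxa so
labels stay joinable. A locus is kept when it covers at least
`core_fraction` (default 1.0, strict core) of the universe; soft-core
thresholds are allowed because the correlation step tolerates missing
pairs via masking. Dropped loci are logged, never silently discarded.

## Ranking, tie groups, gene sets

The ranked table orders loci by (flag ok first, coefficient descending,
`n_pairs` descending, id ascending) — a deterministic total order.
Near-ties are grouped greedily from the top with `tie_delta` = 0.05 by
default: differences that small are unlikely to outweigh wet-lab
criteria (primer sites, amplicon length) when choosing markers.

Gene sets are built from the top `top_k` loci (default 10). The default
mode is **nested** prefixes {top-2}, …, {top-K} — linear in K and
usually what a user scanning for "how few loci suffice" wants.
**exhaustive** mode enumerates all subsets of size 2..`max_size`,
guarded to `top_k ≤ 15` against 2^K blowup. Each set is concatenated
into a super-alignment and re-scored with the *same* distance model as
single loci, so set and locus coefficients are directly comparable;
re-computing distances from the concatenation (rather than averaging
per-locus matrices) is what makes complementary loci show a boost.

## The simulator

`simulate_dataset` emulates the target regime: conspecific genomes with
one shared history.

- **Tree**: Yule-style random joins, exponential waiting times (rate =
  lineage count), rescaled so root-to-tip height equals `tree_height`.
  Default height 0.05 substitutions/site puts maximal pairwise
  divergence near 0.1 (~90–96% identity), bracketing the 95–99.9% ANI
  band where the method is recommended.
- **Loci**: JC69 site-wise evolution; per-branch substitution
  probability `(3/4)(1 − e^{−(4/3)·rate·t})`, substitutions uniform
  over the other three bases. Defaults: 20 loci × 1000 bp, rate
  multiplier 1.0.
- **Decoys**: evolved on a leaf-label-permuted copy of the true tree —
  rate and marginal composition preserved, phylogenetic signal
  destroyed. This emulates loci whose gene tree contradicts the genome
  tree (e.g. via recombination or horizontal transfer) without
  simulating recombination mechanics, which the analysis side makes no
  attempt to correct for either.
- **Dropout**: each (locus, taxon) pair removed with probability
  `dropout_prob` after evolution (never below 2 taxa per locus),
  recorded in the truth manifest.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configs give bit-identical
datasets.

What the simulator does **not** emulate — indels and alignment error,
within-locus rate heterogeneity, selection, base-composition bias,
explicit recombination tracts, assembly/annotation artifacts. Passing
recovery tests therefore demonstrates that the statistic ranks loci
correctly when the model assumptions hold; on real data, alignment
quality and recombination remain the user's responsibility (a corrected
reference tree can be supplied for the latter).

## Numerical and design notes

- Matrices are symmetrized on load by averaging; asymmetry beyond 1e-6
  is an error, the diagonal is forced to 0, `NA` cells are masked.
- Self-correlation of any non-constant unmasked matrix is exactly 1.0:
  `C − D` and the tie-corrected denominator are equal integers, so the
  quotient is exact in floating point.
- tau-b is computed by vectorized sign-product enumeration, O(n²) in
  the number of genome pairs — exact, and fast for the matrix sizes
  (≤ a few thousand pairs) this tool sees.
- The identity track computes alignment-column identity and the model
  track closed-form JC69/K80 distances: deterministic, self-contained
  replacements for external aligner-based identity and ML distance
  estimation, preserving the structure of both analysis tracks.
- CLI runs are pure functions of (inputs, config); fatal errors remove
  partial outputs and exit nonzero with a single-line cause.
- Validation scale: recovery properties are checked at 12 genomes,
  5 true + 15 decoy loci × 1000 bp × 100 replicates, estimator
  consistency at 100 kb two-taxon alignments; these sizes give tight
  binomial error on the reported rates while keeping the whole suite
  fast on one CPU.

## Known limitations

- No recombination detection or correction; decoy-style loci are
  *ranked down*, not flagged as recombinant.
- p-distance/JC69/K80 only; no codon, protein or among-site-variation
  models.
- Exhaustive set search is intentionally bounded; beyond `top_k` = 15
  a heuristic (nested) scan is the supported path.
- The tau of a gene set is recomputed from its super-alignment; with
  heavy missing data the set's pair mask can differ from its members'.
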