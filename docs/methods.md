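# Methods

## Model and assumptions

`corebin` assumes that reads from the same organism form separable clusters:
locally, reads from overlapping genome positions share long exact substrings;
globally, genomes differ in short-word (tetranucleotide) usage. Both
assumptions degrade gracefully — a missed overlap splits a group (recoverable
at the merge stage), and compositionally similar genomes merge into one
cluster (the label then falls to their LCA rather than to a wrong leaf).

The labeling stage assumes that reads of one cluster share a taxon, so hit
evidence can be pooled across a cluster's core: a taxon supported by most
core reads is trustworthy even when each individual read's hits are
ambiguous, which is the common failure mode of per-read LCA assignment on
short reads.

## Pipeline and parameters

**Overlap detection.** Two reads overlap when they share ≥ *m* distinct
*l*-mers. Defaults *l* = 30, *m* = 5: for 100 bp reads this demands ≈ 34 bp
of true overlap, long enough that chance 30-mer collisions between unrelated
genomes are negligible (4⁻³⁰), short enough to tolerate ~1 % substitution
errors. Matching is reverse-complement-canonical by default because shotgun
reads come from both strands; the switch exists (off) for strand-pure
fixtures. *l*-mers containing N are never indexed. The graph is built from an
inverted *l*-mer index; candidate pairs are exactly the pairs co-listed under
shared *l*-mers, so bucketing changes work, not results.

**Grouping and tiny groups.** Groups are connected components of the overlap
graph, numbered by smallest member read id for determinism. Groups smaller
than `min_group_size` (default 3) carry too little sequence for a reliable
composition vector; they skip merging and become standalone clusters whose
core is the whole group.

**Composition vectors.** Per group, word counts are pooled over member reads
(within-read windows only), default word size 4 with reverse-complement
canonical merging (136 features), normalised to frequencies. Word size 4 is
the standard genome-signature choice; size is configurable.

**Merging and automatic k.** Groups are merged by k-means
(k-means++ initialisation, `n_init=10`, fixed seed; ties and label order
stabilised by relabeling clusters in order of smallest member group). The
number of clusters uses the f(k) evaluation function of Pham, Dimov & Nguyen
(2005): f(1) = 1, f(k) = S_k / (α_k S_{k−1}) with S_k the k-means distortion,
α_2 = 1 − 3/(4d), α_k = α_{k−1} + (1 − α_{k−1})/6. Candidate k are those with
f(k) < 0.85; among candidates the k minimising f(k) is chosen, else k = 1.
Selecting the *minimum* rather than the first sub-threshold k matters: with
three well-separated clusters, f(2) already dips below the threshold, but
f(3) is lower.

Two refinements stabilise k detection on grouped read data (both are about
*which vectors vote*, not about the function): only groups with
≥ `k_detect_min_reads` (default 10) reads participate, because small-group
vectors are noisy enough to flatten the f(k) curve; and the participating
vectors are weighted by read count, keeping the distortion on the scale of
reads represented. The subsequent partition runs unweighted over all kept
groups at the detected k.

**Cores.** A cluster's core is a greedy maximal independent set of its
overlap subgraph, visiting reads in ascending id order — deterministic and
independent of graph construction order. Greedy MIS on interval-like overlap
graphs retains most of the cluster's genomic span (tested: ≥ 80 % of covered
positions at ≥ 5× coverage), which is why discarding non-core reads from the
similarity search costs little label information.

**Two-level filtering and LCA.** Defaults s_min = 35 bits, p_top = 10 %,
o_max = 50 %. Read level: drop hits < s_min, then keep hits with score
≥ (1 − p_top/100) × best remaining score (score-relative cutoff, the
MEGAN-style convention). Cluster level: over the core's hit lists L, taxon t
survives iff it occurs in ≥ (o_max/100)·|L| lists, counted at most once per
list, compared in exact real arithmetic. If the threshold empties every list
while hits existed, o_max is halved exactly once and the filter recomputed;
still-empty clusters stay unlabeled. |L| counts core reads with ≥ 1 raw hit:
a read the search returned nothing for says nothing about hit consensus, so
it does not dilute the denominator. The label is the LCA of all surviving
taxa. Post-processing merges same-label clusters (surviving id = smallest)
and marks reads of unlabeled or root-labeled clusters unassigned.

## Evaluation

`classify_at_level` resolves the truth lineage at the queried rank and calls
an assignment *exact* (equal to that node), *under* (strictly below it — e.g.
the wrong species within the right genus), or *neither*; lineages lacking the
rank count as neither, keeping the metrics strict. Metric A counts
exact + under; metric B counts only exact-at-evidence-level, where each
read's evidence level (the lowest rank of its lineage present in the
reference) is supplied alongside the truth labels, since the package cannot
inspect the reference database itself. By construction
sensitivity_A = precision_A × A/N.

## Synthetic data

The generator emulates the target regime: a few genomes with genome-specific
composition bias, uniform-coverage 80–100 bp reads from both strands with 1 %
substitution errors, and a mock hit table. Genomes are order-2 Markov chains
with Dirichlet(1) transition rows — distinct in tetranucleotide usage roughly
the way unrelated bacteria are. Hits per read: none with probability 0.05,
else 1 + Poisson(mean 2); each hit points at the true species with
probability `hit_signal` (default 0.7), otherwise a uniform species;
bit-scores are N(80, 10) for signal and N(45, 10) for noise, truncated at 0,
straddling the default s_min = 35 so both filter levels are exercised. The
toy taxonomy gives each genome a full class→species lineage under one shared
class, so cross-genome LCAs land at class level.

What the generator does *not* model: indels and quality-correlated errors,
GC/coverage bias, repeats shared between genomes, paired ends, and real
bit-score structure (mock scores are independent of sequence). Passing tests
therefore demonstrate the machinery — grouping, k selection, core validity,
filter semantics, LCA, metrics — under clean assumptions, not performance on
real communities, where overlap detection and composition separation are
strictly harder.

## Numerical and design choices

- Distinct-set l-mer semantics (not multiset) for overlap counting; the
  simplest reading of "shared l-mers" and invariant to repeat copy number
  within a read.
- Occurrence threshold compared as f(t) ≥ (o_max/100)·|L| without rounding;
  a 60 % threshold over 5 lists means exactly 3.
- k-means ties in nearest-centroid assignment are resolved by scikit-learn's
  deterministic argmin; all stochastic steps take one integer seed, and
  identical inputs + seed give byte-identical output files.
- Empty survivor sets, empty hit tables, clusters with hitless cores, and
  reads shorter than *l* all degrade to "unassigned"/zero rather than errors.
- Hit-table lines whose taxid is missing from the loaded taxonomy are dropped
  with a warning; reference databases routinely outpace taxonomy dumps.

## Problem sizes

The bundled study conditions are 3 genomes × 10 kb at 5× coverage
(1,500 reads, ≈ 4,000 mock hits) — large enough that grouping, k detection
and the occurrence filter operate in their intended regime, while the whole
pipeline, test suite and acceptance script run in seconds.

## Known limitations

- Composition k-means cannot split genomes with near-identical signatures;
  occasionally (≈ 1 random data set in 8 at these sizes) two of the three
  simulated genomes are close enough that f(k) prefers k = 2. The labels then
  fall to the shared ancestor for the merged cluster rather than to wrong
  species.
- The cluster-level filter assumes clusters are mostly genome-pure; in a
  badly mixed cluster the majority taxon suppresses the minority's evidence.
- No merged-taxid remapping (`merged.dmp`) and no per-read LCA fallback for
  unassigned clusters.
- Mate pairs are treated as independent reads.
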