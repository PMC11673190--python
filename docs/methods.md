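# Methods

## Distances

Protein distances are computed on aligned sequences with **pairwise
deletion**: a site enters the comparison of a pair only if neither sequence
has a gap (`-`) or ambiguity (`X` for proteins, `N` for nucleotides) there.
The uncorrected-*p* distance is the mismatch proportion over those sites;
the Poisson-corrected distance is d = −ln(1 − p), which compensates for
multiple substitutions at one site under a uniform-rate model. Pairs with
no comparable sites, or with p = 1 under the Poisson model, are recorded as
undefined — they hold NaN in the matrix and are listed per pair, never
silently zeroed (strict mode raises instead).

Nucleotide divergence between LTR copies uses the Kimura two-parameter
model, d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with P and Q the transition
and transversion mismatch proportions. When a log argument is non-positive
the pair is **saturated**: it is flagged, excluded from divergence summaries
and counted in `n_saturated`, because clamping it to any finite value would
distort the age histogram.

## Similarity network and clustering

The network has a candidate edge for every sequence pair; the weight is
w = 1/d, capped at `w_cap` (default 10³) for near-identical pairs, and an
edge is kept iff w ≥ τ. The default τ = 0.666 keeps pairs with d ≤ 1.5.
With the Poisson model that corresponds to p ≲ 0.777; under uncorrected-*p*
every distance is ≤ 1 and the filter would keep everything, which is why
the distance model feeding the network is an explicit parameter
(default `poisson`). Isolated nodes are kept and become singleton clusters —
dropping them would change n and both Rand variants.

**CC** clustering is plain connected components. **MC** clustering is
Louvain-style greedy modularity maximization (resolution 1, weighted by
default): local moving — each node greedily joins the neighboring community
with the largest modularity gain, visiting nodes in a seeded random order,
until no move improves — followed by aggregation of communities into
super-nodes, repeated until the graph stops shrinking. Because modularity
maximization is NP-hard and a single greedy pass stalls in local optima
(we observed random 7-node graphs whose optimum no singleton-start greedy
run reaches), the optimizer runs `n_restarts` = 16 seeded restarts — the
first from the classical all-singletons start, the rest from random initial
assignments — and finishes each with a node-level pass on the original
graph, so the returned partition admits no improving single-node move. The
best-modularity restart is returned; everything is deterministic for a
fixed seed. Modularity itself is the Newman–Girvan form
M = Σ_c [l_c/m − (d_c/2m)²] with the standard weighted generalization.

Partition labels are canonical (clusters numbered by decreasing size, ties
by smallest member identifier) so outputs are diffable. Rand agreement is
exposed in both the unadjusted and the Hubert–Arabie adjusted form; the two
can rank methods differently, so reports always carry both. Comparing
partitions over different identifier sets is an error, never a silent
intersection.

## Neighbor-joining baseline

The taxonomy baseline is classical Saitou–Nei neighbor joining on the same
distance matrix, with lexicographic tie-breaking in the Q-matrix
minimization for determinism and negative branch lengths clamped to zero
(count reported on `tree.n_clamped`). On additive matrices NJ recovers the
generating topology and branch lengths exactly, which the tests verify by
path-sum reconstruction. Trees are rooted at the midpoint by default or on
a named outgroup leaf. `taxonomy_from_tree` cuts all branches longer than a
threshold and reads the connected leaf groups as clusters — an explicit,
reproducible surrogate for annotating taxonomy on a tree by eye. The
default cut of 1.0 substitutions/site sits between typical within-family
branches (~0.1) and the long stems separating families in the synthetic
data.

## LTR detection and proliferation dynamics

The detector assumes the biology of intact elements: two same-orientation
terminal repeats, one at each end. It indexes exact k-mers (k = 20) of a 5ʹ
window (first `max_len` + 200 nt) against a 3ʹ window of the same size,
keeps one seed per diagonal, extends each seed ungapped in both directions
with X-drop scoring (match +1, mismatch −2, drop 20, trimmed back to the
best-scoring endpoints), and accepts the longest candidate with length in
[`min_len`, `max_len`] = [100, 1000] and identity ≥ 0.80. K2P divergence is
computed on the accepted pair and is exactly reproducible from the reported
coordinates. There is no dynamic-programming alignment, no target-site
duplication and no TG…CA box requirement: the detector targets indel-free
repeat pairs, which is what the generator emits and the common case for
recent insertions. At these defaults a random 5-kb sequence essentially
never yields a hit (0/200 in the tests), because a shared exact 20-mer
between the two windows has probability ≈ 10⁻⁶.

A population's divergence profile is the histogram of per-element K2P
values (bin width 0.01). The activity call is "active" iff the fraction of
pairs with divergence below `recent_cutoff` (default 0.01) is at least
`min_recent_fraction` (default 0.05); both cutoffs are explicit
configuration, since "actively proliferating" has no canonical numeric
criterion, and the underlying fraction is always reported next to the call.

## Synthetic data generator

The generator emulates the statistical structure the two analyses assume,
with every stochastic choice drawn from one seeded `numpy` generator so a
fixed seed reproduces byte-identical output.

**RT families.** Each of `n_groups` superfamily ancestors is an independent
uniform-random protein sequence; members receive Poisson(`within_rate` × L)
substitutions at uniform sites, each substitution resampling the site from
the 19 alternative residues (multiple hits allowed). Independent ancestors
mean between-group divergence sits at mutational saturation (expected
p ≈ 0.95, Poisson distance ≈ 3, weight ≈ 0.33), well below the τ = 0.666
edge cutoff, while within-group pairs (p ≈ 0.1 at the default
`within_rate` = 0.05) sit far above it. This is deliberate: the generator
models the regime where superfamilies are unambiguous, so clustering
failures in tests indicate implementation defects rather than borderline
separability. `between_rate` is validated (it must exceed `within_rate`)
and recorded with the run, but a finite ancestor divergence scale is not
simulated in v1 — a root-derived construction with the default rates would
put between-group weights exactly at the edge cutoff and make every result
a coin flip. Consequently the defaults say nothing about how the pipeline
behaves when families are genuinely marginal; that regime can be probed by
raising `within_rate` toward the cutoff instead.

**Elements.** Each element is 5ʹ-LTR + random internal region + 3ʹ-LTR,
with total length uniform in 5000–6000 nt and LTR length uniform in
200–500 nt. The 3ʹ copy receives substitutions at a proportion drawn from a
mixture of uniform components (default 0.5 × U[0, 0.01] + 0.3 × U[0.01, 0.08]
+ 0.2 × U[0.08, 0.15], i.e. half the insertions recent — the regime of an
actively proliferating population), at sites chosen **without** replacement
so the realized mismatch proportion is exact and checkable by counting,
with a 2:1 transition:transversion bias so K2P estimation has nontrivial P
and Q components. Because sites are hit at most once, the raw mismatch
proportion is the true divergence and the K2P estimate exceeds it slightly
(the correction assumes multiple hits); the default mixture keeps
divergences ≤ 0.15, where this bias is well inside sampling noise at
n = 200. The upper mixture bound also stays below the detector's
1 − `min_identity` = 0.20, so detection failures in tests are defects, not
saturation. No indels, no ORFs, no target-site duplications, no nested
insertions are simulated; tests passing on this generator show the pipeline
is correct on clean repeat structure, not that it matches specialized
annotation tools on real genomes.

## Pipelines and reproducibility

`run_classify` wires alignment + taxonomy → distance matrix (PHYLIP out) →
network (edge list out) → MC, CC and tree-cut partitions → a report with
cluster counts, MC modularity and both Rand variants, plus a cluster ×
group contingency table. `run_dynamics` wires elements → detector → GFF3 +
divergence table + histogram + activity call. Both echo the resolved
configuration to JSON, log to stderr and `run.log`, and write a manifest of
SHA-256 checksums; identical configuration and seed give identical
checksums. CLI subcommands (`simulate`, `classify`, `dynamics`, `ssn`,
`tree`, `ltr`, `motif`) are thin wrappers over the library functions, which
remain the primary interface.

## Problem sizes

The shipped checks run at: 100 random graphs of ≤ 8 nodes against
exhaustive modularity enumeration (Bell(8) = 4140 partitions), 100 random
partition pairs of ≤ 30 items against pair-counting Rand, 1000 label
permutations for chance calibration, 50 random additive matrices of ≤ 12
taxa for NJ, 20 seeds × 80 sequences for end-to-end cluster recovery, and
200 elements for LTR recovery. These sizes make every oracle exact or
tightly bounded while keeping the whole suite under a minute of compute.

## Known limitations

- The SSN weight filter is only meaningful with a corrected distance; with
  uncorrected-*p* all weights exceed 1 and the default τ removes nothing.
- The LTR detector requires an exact shared 20-mer; repeat pairs more than
  ~20% diverged, or with indels, are invisible to it.
- NJ is a surrogate for likelihood-based phylogenetics; it shares the
  distance matrix with the network analysis and is not an independent
  taxonomy source on real data.
- Modularity restarts guarantee a partition stable under single-node moves,
  not a global optimum; exhaustive agreement is verified only at ≤ 8 nodes.
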