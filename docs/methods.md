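# Methods

## The model

`ebwtphylo` reconstructs an unrooted phylogenetic tree for ℓ taxa directly
from their raw sequence collections — reads, contigs or whole genomes —
without alignment, assembly, a reference genome, or a distance matrix.  The
signal it exploits is combinatorial: if a substring is shared by the
sequences of some taxa but not others, the suffixes starting with that
substring sit contiguously in the lexicographically sorted suffix list of
the whole collection, and the colors (taxon indices) observed in that block
identify the sharing group.  Groups that share many such maximal contexts
are interpreted as clades.

### Data structures

Every string carries its own end-marker; markers sort below the DNA letters
and among themselves by global string index ($_i < $_j iff i < j).  Because
markers never match anything in common-prefix computations, any fixed total
order yields the same interval structure downstream; the restriction of the
arrays to a color subset is obtained by one left-to-right scan (dropping the
foreign rows and taking running minima of the LCP values over the dropped
spans), never by rebuilding.

The three parallel arrays over the N suffixes are

* `ebwt` — the symbol circularly preceding each suffix (the multi-string
  BWT); all end-markers are stored as one class symbol `#`, since their
  identity is never consumed,
* `lcp` — N+1 entries, zero at both ends; entry i is the longest common
  prefix of suffixes i−1 and i,
* `cda` — the color document array: the taxon index owning each suffix.

Construction is a desk-scale suffix sort: prefix doubling over numpy
`lexsort` (O(N log² N)) followed by Kasai's LCP recurrence.  Efficient
external-memory construction is deliberately out of scope; the arrays are
also read/written in a small declared binary dialect (one byte per eBWT
symbol, little-endian uint32 LCP/CDA, JSON sidecar) so an external builder
can be substituted.

### Positional clusters

A *local minimum* of the LCP array is the first index p of an equal-valued
run that is strictly below its left neighbour and strictly below the value
just past the run; the run may not touch the array boundary.  On
`[2,1,3,3,5,4,2,2,7]` the minima are positions 2 and 7.  (The run length is
allowed to be 1 — the published worked array requires it, although the prose
definition it accompanies says otherwise.)

An *eBWT positional cluster* at minimum context length k_m is a maximal
interval [i, j], j > i, with all internal LCP values ≥ k_m and no internal
local minimum.  Clusters are disjoint, their internal LCP profile is
unimodal, and the shared-context length is therefore min(lcp[i+1], lcp[j]).
Single-suffix blocks are suppressed: a lone suffix can never witness a
context shared *between* groups.  Clusters refine the classical
LCP-intervals of value k when k_m = k, which is the validation hook the
tests use.

### Refinement and tree growth

The tree is a *partition tree*: each node is a taxon set, the children of
every node partition it, the root is everything, the leaves are singletons.
Starting from the star, the driver keeps a FIFO queue of non-final nodes.
For a dequeued node X with children C_1..C_h (h ≥ 3):

1. restrict the arrays to the colors of X (one streaming pass);
2. enumerate positional clusters; a cluster is *relevant* when (i) its eBWT
   slice is not a one-symbol run (all end-markers count as one class),
   (ii) its γ-coloring — the set of C_k whose colors occur in the cda slice
   — has between 2 and h−1 members, and (iii) every member C_k shows at
   least τ·|C_k| of its *distinct* colors in the slice;
3. each relevant cluster votes +1 for its γ-subset; subsets are then
   visited by score descending and the union U = ∪γ is appended to the
   output list L when it is a subset of, superset of, or disjoint from
   everything already in L and duplicates neither an existing entry, a
   single C_k, nor X.  Selection stops at h−2 accepted sets, when the score
   falls two orders of magnitude below the best, or after min{2h, 100}
   consecutive rejections.

Each accepted set becomes a new internal node (absorbed siblings are
reparented beneath it).  Nodes left with ≤ 2 children are final; others are
re-enqueued, X included.  An empty L finalizes X.  Since every insertion
strictly reduces the total excess child count and at most ℓ−2 strict
intermediate sets exist, the loop reaches quiescence after O(ℓ) refinement
calls; the whole run is O(Nℓ) time and O(N + ℓ²) space.

The rooted result is emitted as Newick without re-rooting: a root with ≥ 3
children is the standard unrooted encoding, and a 2-child root encodes the
same unrooted topology.  No branch lengths are computed, so none are
written.

## Parameters

* `k_m` (minimum context length, default 16) — suppresses short random
  shared contexts.  Working regimes: ≥ 16 for reads and genomes, 23–45 for
  assemblies.  The index does not depend on k_m, so parameter sweeps reuse
  the same files.
* `τ` (support threshold in (0, 1], default 0.6) — the minimum fraction of
  an element's distinct colors that must appear in a cluster for the
  element to count.  Near 1 it demands the whole subgroup share the
  context; near 0 a single representative suffices.
* `score_drop_ratio` (default 100) — the "two orders of magnitude" cutoff
  of the greedy selection, exposed because the constant is a convention.
* Tie-breaks among equal scores: larger union first, then lexicographic on
  the sorted color lists — chosen purely for cross-platform determinism.
* Sanitization: non-ACGT characters split a record into maximal ACGT runs;
  `min_run_length` (default 1, i.e. keep everything) can be raised — for
  noisy read sets twice k_m is a sensible floor, since shorter runs cannot
  contain a scoring context.

## The synthetic generator

`simulate_collection` evolves an i.i.d.-uniform root sequence (default
20 kb) down a given binary topology, substituting each site independently
with probability `sub_prob` (default 0.02) per branch, uniformly over the
three alternative bases.  Optional fragmentation draws error-free reads of
fixed length with uniform random starts to a target coverage; optional
reverse-complement augmentation interleaves each string with its reverse
complement.  All randomness flows from one explicit `numpy` generator.

What it does **not** emulate: indels, rate heterogeneity, recombination,
sequencing errors, paired-end structure, or genome-scale repeat content.
Passing recovery tests on this generator therefore demonstrates that the
cluster-vote machinery extracts clade signal from substitution patterns at
desk scale; it does not certify performance on real sequencing data, where
genome length, repeats and error rates change the score margins.

### Problem sizes used by the test suite

Unit and property tests run on collections of at most a few kilobases,
cross-checked against two independent oracles (an enumerate-decorate-sort
index builder and a quadratic literal-definition cluster finder).  The
recovery tests use 8 taxa, 20 kb genomes, 2% per-branch divergence,
k_m = 16, τ = 0.6, ten seeded replicates — whole genomes, and the same
collections fragmented into 100 bp reads at 10× with reverse complements.

## Numerical and degenerate-input choices

* All public positions are 1-based with inclusive intervals, matching the
  conventions of the worked examples; storage is 0-based internally.
* Support comparisons in condition (iii) are real-valued (no rounding).
* Condition (iii) counts distinct colors, not occurrences — the set reading
  of the cardinality; with occurrence counting, high-coverage taxa would
  dominate mixed clusters.
* ℓ = 2 collections return the final 2-star immediately; empty score
  tables, empty selections and incompatible candidates are all defined,
  non-error outcomes of the corresponding stages.
* Restriction to the full color set returns the index unchanged.

## Known limitations

* The suffix sorter holds several int64 arrays of length N in memory;
  practical desk-scale inputs are tens of millions of symbols, not
  billions.  External-memory builders can feed the binary dialect instead.
* On fragmented input (reads), read boundaries inject end-marker rows and
  truncated contexts that split multi-taxon clusters; the surviving
  sub-clusters keep only part of the γ-coloring, which systematically
  inflates the vote counts of small subsets relative to large ones.  At
  desk scale (20 kb genomes, 2% divergence) this thins the margin between
  true clades and spurious pairs enough that read-based runs recover the
  topology noticeably less often than genome-based runs on the same
  collections; longer genomes widen the margin again.  See the recovery
  tests for the exact protocol.
* Weighted scoring (by cluster size or context length) and weakly
  compatible splits / network output are deliberate non-goals.
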