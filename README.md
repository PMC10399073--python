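# ebwtphylo

Alignment-, assembly- and reference-free phylogeny reconstruction from the
extended Burrows–Wheeler Transform.

`ebwtphylo` infers an unrooted phylogenetic tree for ℓ taxa directly from
their raw sequence collections — short reads, contigs, or whole genomes —
with no alignment against a reference, no de novo assembly, and no pairwise
distance matrix.  It is aimed at anyone who wants a tree straight from
FASTA files: population genomicists comparing strain sequencing runs,
virologists clustering outbreak genomes, or method developers who need a
k-mer-free baseline.

## The method in brief

All suffixes of all strings (each terminated by its own end-marker) are
sorted lexicographically; three parallel arrays describe the result: the
multi-string BWT `ebwt(S)`, the LCP array `lcp(S)`, and the color document
array `cda(S)` mapping each suffix to its taxon.  Substrings shared by a
group of taxa appear as *eBWT positional clusters*: maximal intervals
[i, j] with internal LCP ≥ k_m and no internal local minimum of the LCP
array, sharing a context of length min(lcp[i+1], lcp[j]) — variable-length
contexts, unlike fixed-k k-mer methods, and the arrays are independent of
k_m, so one index serves every parameter choice.

Reconstruction refines a partition tree, starting from the star over all
taxa.  For a node with children C_1,…,C_h, a cluster is *relevant* when its
eBWT slice is not a single-symbol run, its γ-coloring (the set of C_k
whose colors occur in `cda[i,j]`) has 2 … h−1 members, and every member C_k
shows at least τ·|C_k| of its distinct colors in the slice.  Each relevant
cluster votes for its γ-subset; the highest-scoring, mutually compatible
unions U = ∪γ (subset / superset / disjoint against everything inserted so
far) become new internal nodes.  Nodes with two children are final; the
loop ends at quiescence and emits Newick.  The whole run costs O(Nℓ) time
and O(N + ℓ²) space for total input length N.

## Worked example

Simulate six taxa that diverged along a known tree (10 kb genomes, 3%
per-branch substitutions), index them, and reconstruct:

```
$ ebwtphylo simulate --n-leaves 6 --sub-prob 0.03 --length 10000 --seed 42 --output data
taxa=6 strings=6 N=60006
$ cat data/truth.nwk
((t2,(t1,t5)),(t6,(t3,t4)));
$ ebwtphylo build-index --manifest data/manifest.tsv --index-prefix idx
N=60006 ell=6
$ ebwtphylo reconstruct --index-prefix idx --kmin 16 --tau 0.6 --output tree.nwk
((t2,(t1,t5)),(t6,(t3,t4)));
iterations=1 log=tree.nwk.log.json
```

`N=60006` is the total symbol count (six 10 kb genomes plus one end-marker
each).  A single refinement iteration recovers the generating topology; the
Robinson–Foulds distance to the truth is 0:

```python
>>> from ebwtphylo import rf_distance
>>> rf_distance(open("tree.nwk").read(), open("data/truth.nwk").read())
0
```

The same objects are available as a library.  On the classic three-string
collection {GGCGTACCA, ACGAGTACGACT, GGGGCGTATT}:

```python
>>> from ebwtphylo import fig1_fixture, build_index, enumerate_clusters, reconstruct
>>> idx = build_index(fig1_fixture())
>>> [(c.i, c.j, c.context_length) for c in enumerate_clusters(idx, 1)]
[(4, 10, 1), (11, 14, 1), (15, 17, 1), (18, 19, 2), (20, 21, 5),
 (22, 23, 6), (24, 25, 3), (26, 28, 3), (29, 34, 1)]
>>> reconstruct(idx, k_m=1, tau=1.0).to_newick()
'((t1,t2),t3);'
```

Two of those clusters ([11,14] and [22,23]) are relevant under the
singleton partition — contexts shared by exactly two of the three taxa —
and their votes produce the (t1,t2) cherry.

## Input formats

Per-taxon FASTA files listed in a two-column TSV manifest
(`taxon<TAB>path`; repeated taxon names accumulate files).  Non-ACGT
characters split records into maximal ACGT runs.  `--add-rc` appends each
string's reverse complement.  Prebuilt eBWT/LCP/CDA arrays are accepted in
the package's declared binary dialect (see `docs/methods.md`), so external
index builders can be substituted for the built-in suffix sorter.

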