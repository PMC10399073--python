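"""Synthetic collections evolved along a known tree, plus an RF comparator.

The generator emulates the situation the reconstructor targets: taxa that
diverged from a common ancestor by point substitutions, optionally observed
only through fixed-length error-free reads.  A uniform random root sequence
evolves down a binary tree; every branch substitutes each site independently
with a fixed probability (uniform choice among the three alternatives).
Leaves become taxa; fragmentation draws read start positions uniformly to a
target coverage.  Everything is driven by an explicit numpy generator, so a
seed pins the output bit-for-bit across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .sequence_io import Collection, collection_from_strings

__all__ = [
    "SimulatedPhylogeny",
    "random_binary_topology",
    "simulate_collection",
    "fig1_fixture",
    "rf_distance",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# The three-string collection used throughout the worked examples.
FIG1_STRINGS = ("GGCGTACCA", "ACGAGTACGACT", "GGGGCGTATT")


@dataclass
class SimulatedPhylogeny:
    """A generating binary tree with per-branch substitution probability.

    topology       Newick text of the generating tree (leaf names = taxa)
    sub_prob       per-site substitution probability applied on every branch
    root_length    length of the i.i.d.-uniform root sequence (bp)
    seed           seed for the explicit numpy generator
    """

    topology: str
    sub_prob: float = 0.02
    root_length: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_prob <= 0.25:
            raise ValueError("sub_prob must be in [0, 0.25]")
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        tree = self._tree()
        if len(tree.leaf_nodes()) < 3:
            raise ValueError("generating tree needs at least 3 leaves")

    def _tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.topology, schema="newick")

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree().leaf_node_iter()]


def random_binary_topology(
    n_leaves: int, seed: int, names: list[str] | None = None
) -> str:
    """Random rooted binary topology by repeated random joins."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"t{i + 1}" for i in range(n_leaves)]
    if len(names) != n_leaves:
        raise ValueError("names must match n_leaves")
    forest: list[str] = list(names)
    while len(forest) > 1:
        i, j = sorted(rng.choice(len(forest), size=2, replace=False))
        b = forest.pop(j)
        a = forest.pop(i)
        forest.append(f"({a},{b})")
    return forest[0] + ";"


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < p
    n = int(mask.sum())
    if n:
        # shift by 1..3 mod 4: uniform over the three alternative bases
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_collection(
    phylo: SimulatedPhylogeny,
    read_length: int | None = None,
    coverage: float | None = None,
    add_rc: bool = False,
) -> tuple[Collection, str]:
    """Evolve sequences down the generating tree; return (Collection, truth).

    With ``read_length`` set, each leaf genome is replaced by error-free
    fixed-length reads whose starts are drawn uniformly, ceil(n*coverage/
    read_length) of them.  The truth tree is returned as Newick text.
    """
    if coverage is not None and read_length is None:
        raise ValueError("coverage requires read_length")
    if read_length is not None:
        if read_length < 1:
            raise ValueError("read_length must be positive")
        if coverage is None:
            coverage = 1.0
        if coverage <= 0:
            raise ValueError("coverage must be positive")

    rng = np.random.default_rng(phylo.seed)
    tree = phylo._tree()
    root_seq = rng.integers(0, 4, size=phylo.root_length, dtype=np.uint8)

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        child_seq = _mutate(parent_seq, phylo.sub_prob, rng)
        seqs[id(node)] = child_seq
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = child_seq

    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    colored: list[tuple[int, str]] = []
    for color, name in enumerate(taxa, start=1):
        genome = leaf_seqs[name]
        if read_length is None:
            colored.append((color, _BASES[genome].tobytes().decode()))
        else:
            n = len(genome)
            if read_length > n:
                raise ValueError("read_length exceeds the leaf sequence length")
            n_reads = math.ceil(n * coverage / read_length)
            starts = rng.integers(0, n - read_length + 1, size=n_reads)
            for s in np.sort(starts):
                frag = genome[int(s) : int(s) + read_length]
                colored.append((color, _BASES[frag].tobytes().decode()))

    collection = collection_from_strings(taxa, colored, add_rc=add_rc)
    truth = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return collection, truth


def fig1_fixture() -> Collection:
    """The three printed example strings as three single-string taxa."""
    return Collection(
        taxa=["t1", "t2", "t3"],
        colors=[1, 2, 3],
        strings=list(FIG1_STRINGS),
    )


def rf_distance(tree_a: str, tree_b: str) -> int:
    """Robinson-Foulds distance between two Newick trees (unrooted).

    Counts the non-trivial bipartitions present in exactly one of the two
    trees; both trees must be over the same leaf set.
    """
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=tree_a, schema="newick", taxon_namespace=tns)
    try:
        tb = dendropy.Tree.get(data=tree_b, schema="newick", taxon_namespace=tns)
    except dendropy.utility.error.TaxonNamespaceError as exc:
        raise ValueError(f"leaf sets differ: {exc}") from exc
    leaves_a = {lf.taxon.label for lf in ta.leaf_node_iter()}
    leaves_b = {lf.taxon.label for lf in tb.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError(
            f"leaf sets differ: {sorted(leaves_a ^ leaves_b)} not shared"
        )
    for t in (ta, tb):
        t.is_rooted = False
        t.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
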