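"""Gamma-coloring, relevance, subset scoring and greedy compatible selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebwtphylo import (
    Collection,
    PositionalCluster,
    ScoreTable,
    SelectionPolicy,
    SiblingFamily,
    build_index,
    enumerate_clusters,
    gamma_coloring,
    is_relevant,
    refine,
    restrict,
    score_subsets,
    select_compatible,
)
from conftest import random_collection

# the four-element family of the worked gamma-coloring example
FAMILY_1346 = SiblingFamily(elements=[{1, 3, 4}, {2}, {5}, {6}], tau=0.5)
SLICE_CDA = np.array([1, 2, 1, 1, 3, 3], dtype=np.int32)
SLICE_EBWT = np.frombuffer(b"ACAAGT", dtype=np.uint8)
CLUSTER = PositionalCluster(i=1, j=6, context_length=20)


class TestGammaColoring:
    def test_worked_example(self):
        g = gamma_coloring(FAMILY_1346, SLICE_CDA)
        assert g.members == frozenset({0, 1})  # {{1,3,4},{2}}
        assert g.support[0] == 2  # distinct colors {1,3}
        assert g.support[1] == 1

    def test_single_repeated_color(self):
        g = gamma_coloring(FAMILY_1346, np.array([5, 5, 5]))
        assert g.members == frozenset({2})
        assert g.support[2] == 1

    def test_full_coloring(self):
        g = gamma_coloring(FAMILY_1346, np.array([1, 2, 5, 6]))
        assert g.members == frozenset({0, 1, 2, 3})


class TestIsRelevant:
    def test_worked_example_tau_half(self):
        g = gamma_coloring(FAMILY_1346, SLICE_CDA)
        assert is_relevant(CLUSTER, SLICE_EBWT, g, FAMILY_1346)

    def test_single_symbol_run_never_relevant(self):
        fam = SiblingFamily(elements=[{1, 3, 4}, {2}, {5}, {6}], tau=0.5)
        g = gamma_coloring(fam, SLICE_CDA)
        run = np.frombuffer(b"AAAAAA", dtype=np.uint8)
        assert not is_relevant(CLUSTER, run, g, fam)

    def test_end_markers_are_one_symbol_class(self):
        fam = SiblingFamily(elements=[{1}, {2}, {3}], tau=1.0)
        g = gamma_coloring(fam, np.array([1, 2]))
        markers_only = np.frombuffer(b"##", dtype=np.uint8)
        assert not is_relevant(CLUSTER, markers_only, g, fam)
        mixed = np.frombuffer(b"#G", dtype=np.uint8)
        assert is_relevant(CLUSTER, mixed, g, fam)

    def test_tau_one_requires_full_support(self):
        fam = SiblingFamily(elements=[{1, 3, 4}, {2}, {5}, {6}], tau=1.0)
        g = gamma_coloring(fam, SLICE_CDA)
        # element {1,3,4} shows only 2 of its 3 colors: 2 < 1.0 * 3
        assert not is_relevant(CLUSTER, SLICE_EBWT, g, fam)

    def test_all_or_one_element_rejected(self):
        fam = SiblingFamily(elements=[{1}, {2}, {3}], tau=0.5)
        g_all = gamma_coloring(fam, np.array([1, 2, 3]))
        assert not is_relevant(CLUSTER, SLICE_EBWT, g_all, fam)
        g_one = gamma_coloring(fam, np.array([1, 1]))
        assert not is_relevant(CLUSTER, SLICE_EBWT, g_one, fam)


class TestScoreSubsets:
    def test_fig1_singleton_partition(self, fig1_index):
        fam = SiblingFamily(elements=[{1}, {2}, {3}], tau=1.0)
        table = score_subsets(fig1_index, fam, 1)
        # exactly the two relevant clusters [11,14] (colors 1,2) and
        # [22,23] (colors 1,3)
        assert dict(table) == {(0, 1): 1, (0, 2): 1}

    def test_single_colored_clusters_give_empty_table(self):
        col = Collection(taxa=["a", "b"], colors=[1, 2], strings=["AAAA", "CCCC"])
        idx = build_index(col)
        fam = SiblingFamily(elements=[{1}, {2}], tau=0.5)
        assert score_subsets(idx, fam, 1) == {}

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 5_000))
    def test_matches_per_cluster_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        col = random_collection(rng, max_taxa=5, max_len=40)
        idx = build_index(col)
        colors = sorted(set(col.colors))
        if len(colors) < 3:
            return
        # a family over all colors: first two grouped, rest singletons
        elements = [set(colors[:2])] + [{c} for c in colors[2:]]
        fam = SiblingFamily(elements=elements, tau=0.5)
        got = score_subsets(idx, fam, 2)

        sub = restrict(idx, fam.X)
        expected = ScoreTable()
        for c in enumerate_clusters(sub, 2):
            g = gamma_coloring(fam, sub.cda_slice(c.i, c.j))
            if is_relevant(c, sub.ebwt_slice(c.i, c.j), g, fam):
                expected.vote(g.members)
        assert dict(got) == dict(expected)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 5_000))
    def test_invariant_under_taxon_permutation(self, seed):
        rng = np.random.default_rng(seed)
        col = random_collection(rng, max_taxa=4, max_len=30)
        colors = sorted(set(col.colors))
        perm = list(rng.permutation(colors))
        relabel = {c: colors[i] for i, c in enumerate(perm)}
        order = np.argsort([relabel[c] for c in col.colors], kind="stable")
        permuted = Collection(
            taxa=[col.taxa[c - 1] for c in perm],
            colors=sorted(relabel[c] for c in col.colors),
            strings=[col.strings[int(k)] for k in order],
        )
        fam_a = SiblingFamily(elements=[{c} for c in colors], tau=0.5)
        table_a = score_subsets(build_index(col), fam_a, 2)
        table_b = score_subsets(build_index(permuted), fam_a, 2)
        # relabel table_a's keys: color c becomes relabel[c]
        inv_elem = {c: i for i, c in enumerate(colors)}
        mapped = {
            tuple(sorted(inv_elem[relabel[colors[k]]] for k in key)): v
            for key, v in table_a.items()
        }
        assert mapped == dict(table_b)


class TestSelectCompatible:
    def fam(self, h):
        return SiblingFamily(elements=[{i} for i in range(1, h + 1)], tau=0.5)

    def test_union_of_members_is_added(self):
        fam = SiblingFamily(elements=[{1, 3, 4}, {2}, {5}, {6}], tau=0.5)
        table = ScoreTable({(0, 1): 7})
        assert select_compatible(table, fam) == [frozenset({1, 2, 3, 4})]

    def test_empty_table(self):
        assert select_compatible(ScoreTable(), self.fam(4)) == []

    def test_partial_overlap_rejected_greedily(self):
        # AB:5 accepted; BC:4 overlaps AB; AC:1 overlaps AB; no cap reached
        fam = self.fam(4)
        table = ScoreTable({(0, 1): 5, (1, 2): 4, (0, 2): 1})
        assert select_compatible(table, fam) == [frozenset({1, 2})]

    def test_h_minus_2_cap(self):
        fam = self.fam(4)
        table = ScoreTable({(0, 1): 5, (2, 3): 4, (0, 1, 2): 3})
        L = select_compatible(table, fam)
        assert len(L) == 2  # h-2 = 2: the compatible third subset is not taken

    def test_score_drop_cutoff(self):
        fam = self.fam(6)
        table = ScoreTable({(0, 1): 1000, (2, 3): 9})
        L = select_compatible(table, fam)
        assert L == [frozenset({1, 2})]  # 9 < 1000/100

    def test_failure_cap_stops_scanning(self):
        fam = self.fam(5)
        # highest accepted, then a long chain of incompatible subsets ahead
        # of a compatible one; failure cap f = min(2h, 100) = 10
        table = ScoreTable({(0, 1): 50})
        for k, other in enumerate(((0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4))):
            table[other] = 40 - k
        table[(2, 3)] = 2
        L = select_compatible(table, fam, SelectionPolicy(failure_cap=3))
        assert L == [frozenset({1, 2})]  # stopped before reaching (2,3)
        L2 = select_compatible(table, fam)
        assert frozenset({3, 4}) in L2  # default cap is generous enough

    def test_duplicates_of_structure_count_as_failures(self):
        fam = self.fam(4)
        # gamma covering h-1 elements whose union equals an existing C_k? not
        # possible; but a union equal to one already in L must be rejected
        table = ScoreTable({(0, 1): 5, (0, 1, 2): 4, (0, 1, 3): 3})
        L = select_compatible(table, fam)
        assert L == [frozenset({1, 2}), frozenset({1, 2, 3})] or L == [
            frozenset({1, 2}),
            frozenset({1, 2, 4}),
        ]
        assert len(L) == 2

    def test_tie_break_larger_union_then_lexicographic(self):
        fam = self.fam(5)
        table = ScoreTable({(3, 4): 5, (0, 1, 2): 5, (0, 1): 5})
        L = select_compatible(table, fam)
        # all tie at 5: the triple wins by size, then {1,2} < {4,5} lexicographically
        assert L[0] == frozenset({1, 2, 3})
        assert L[1] == frozenset({1, 2})


class TestRefine:
    def test_fig1_cap_limits_to_one_cherry(self, fig1_index):
        fam = SiblingFamily(elements=[{1}, {2}, {3}], tau=1.0)
        L = refine(fig1_index, fam, 1)
        # both subsets score 1; h-2 = 1 keeps only the tie-break winner
        assert L == [frozenset({1, 2})]

    def test_no_shared_context_gives_empty_list(self):
        col = Collection(
            taxa=["a", "b", "c"],
            colors=[1, 2, 3],
            strings=["AAAAAAAA", "CCCCCCCC", "GGGGGGGG"],
        )
        L = refine(build_index(col), SiblingFamily([{1}, {2}, {3}], tau=0.5), 2)
        assert L == []

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 5_000))
    def test_output_contract(self, seed):
        rng = np.random.default_rng(seed)
        col = random_collection(rng, max_taxa=6, max_len=40)
        colors = sorted(set(col.colors))
        if len(colors) < 3:
            return
        fam = SiblingFamily(elements=[{c} for c in colors], tau=0.5)
        L = refine(build_index(col), fam, 2)
        assert len(L) <= fam.h - 2
        for u in L:
            assert 2 <= len(u) <= fam.h - 1
            assert u < fam.X
        for a in range(len(L)):
            for b in range(a + 1, len(L)):
                u, v = L[a], L[b]
                assert u < v or v < u or not (u & v)


class TestSiblingFamilyValidation:
    def test_overlapping_elements_rejected(self):
        with pytest.raises(ValueError):
            SiblingFamily(elements=[{1, 2}, {2, 3}], tau=0.5)

    def test_tau_out_of_range_rejected(self):
        for tau in (0.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                SiblingFamily(elements=[{1}, {2}], tau=tau)
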