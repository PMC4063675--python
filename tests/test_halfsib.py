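import itertools

import numpy as np
import pytest

from pedrecon.halfsib import (
    PolygamyGraph,
    TwoColoring,
    filter_redundant_edges,
    filter_redundant_sib_edges,
    merge_half_sib_parents,
    two_color_clique_cover,
)
from pedrecon.pedigree import Individual, Pedigree
from pedrecon.sibassembly import add_parent_couples
from tests.conftest import make_pedigree


def pgraph(n, weighted_edges, groups=None):
    groups = [(f"g{k}",) for k in range(n)] if groups is None else groups
    return PolygamyGraph(groups=[tuple(g) for g in groups],
                         edges={tuple(sorted(e)): w for e, w in weighted_edges.items()})


# ---------------------------------------------------------------------------
# Coloring
# ---------------------------------------------------------------------------


def chain_of_cliques(weights):
    """Cliques Q_k = {2k, 2k+1, 2k+2} sharing one articulation vertex each."""
    edges = {}
    for k, w in enumerate(weights):
        verts = (2 * k, 2 * k + 1, 2 * k + 2)
        for a, b in itertools.combinations(verts, 2):
            edges[(a, b)] = w / 3.0  # clique weight == w
    return pgraph(2 * len(weights) + 1, edges)


class TestTwoColoring:
    def test_single_triangle_one_color(self):
        G = pgraph(3, {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0})
        col = two_color_clique_cover(G)
        col.validate()
        assert len(col.cliques) == 1
        assert col.cliques[0][0] == frozenset({0, 1, 2})

    def test_adjacency_order_colors_whole_chain(self):
        # weights chosen so heaviest-first coloring strands the middle
        # clique between two same-colored neighbors
        G = chain_of_cliques([6.0, 10.0, 7.0, 8.0, 9.0])
        col = two_color_clique_cover(G, order="adjacency")
        col.validate()
        assert len(col.cliques) == 5
        e1, e2 = col.edge_sets()
        assert len(e1) + len(e2) == len(G.edges)

    def test_naive_order_leaves_a_clique_uncolored(self):
        G = chain_of_cliques([6.0, 10.0, 7.0, 8.0, 9.0])
        col = two_color_clique_cover(G, order="naive")
        col.validate()
        assert len(col.cliques) < 5

    def test_adjacency_beats_naive_on_chains(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            G = chain_of_cliques(list(rng.uniform(1, 10, size=5)))
            w_adj = two_color_clique_cover(G, "adjacency").colored_weight(G.edges)
            G2 = chain_of_cliques(list(np.random.default_rng(seed).uniform(1, 10, size=5)))
            w_naive = two_color_clique_cover(G2, "naive").colored_weight(G2.edges)
            assert w_adj >= w_naive - 1e-9

    def test_coloring_legality_random_graphs(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 8))
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        edges[(i, j)] = float(rng.uniform(0.5, 5.0))
            G = pgraph(n, edges)
            for order in ("adjacency", "naive"):
                col = two_color_clique_cover(G, order)
                col.validate()
                e1, e2 = col.edge_sets()
                assert (e1 | e2) <= set(G.edges)


def _all_cliques(n, edge_set):
    adj = {v: set() for v in range(n)}
    for a, b in edge_set:
        adj[a].add(b)
        adj[b].add(a)
    out = []
    for size in range(2, n + 1):
        for verts in itertools.combinations(range(n), size):
            if all(b in adj[a] for a, b in itertools.combinations(verts, 2)):
                out.append(frozenset(verts))
    return out


def _best_two_coloring(n, edges):
    """Exhaustive oracle: maximum total weight over all legal two-colorings."""
    cliques = _all_cliques(n, set(edges))
    weights = {c: sum(edges[tuple(sorted(p))] for p in itertools.combinations(sorted(c), 2))
               for c in cliques}

    def families(avail_cliques, used_vertices):
        """All vertex-disjoint clique families from the candidate list."""
        if not avail_cliques:
            yield []
            return
        head, rest = avail_cliques[0], avail_cliques[1:]
        yield from families(rest, used_vertices)
        if not (head & used_vertices):
            for fam in families([c for c in rest if not (c & head)],
                                used_vertices | head):
                yield [head] + fam

    best = 0.0
    for fam1 in families(cliques, frozenset()):
        used_edges = {tuple(sorted(p)) for c in fam1
                      for p in itertools.combinations(sorted(c), 2)}
        w1 = sum(weights[c] for c in fam1)
        remaining = [c for c in cliques
                     if not any(tuple(sorted(p)) in used_edges
                                for p in itertools.combinations(sorted(c), 2))]
        best2 = 0.0
        for fam2 in families(remaining, frozenset()):
            w2 = sum(weights[c] for c in fam2)
            best2 = max(best2, w2)
        best = max(best, w1 + best2)
    return best


def test_greedy_coloring_near_optimal_on_random_instances():
    """Greedy two-coloring reaches >= 80% of the exhaustive optimum over
    random graphs of <= 7 vertices."""
    rng = np.random.default_rng(7)
    ratios = []
    trials = 0
    while len(ratios) < 200 and trials < 1000:
        trials += 1
        n = int(rng.integers(4, 8))
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    edges[(i, j)] = float(rng.uniform(0.5, 5.0))
        if len(edges) < 2 or len(edges) > 9:
            continue
        G = pgraph(n, edges)
        got = two_color_clique_cover(G, "adjacency").colored_weight(G.edges)
        opt = _best_two_coloring(n, edges)
        if opt > 0:
            ratios.append(got / opt)
    assert len(ratios) == 200
    assert np.mean(ratios) >= 0.8


# ---------------------------------------------------------------------------
# Redundant-edge rules
# ---------------------------------------------------------------------------


@pytest.fixture
def polygamous_partial():
    """Reconstruction state after one generation: founders a, b, c, d, w at
    generation 1; a had children with both b and c; d is truly a's
    half-sibling (their link is above generation 1 and not yet built)."""
    return make_pedigree([
        ("a", "male", 1, None, None), ("b", "female", 1, None, None),
        ("c", "female", 1, None, None), ("d", "male", 1, None, None),
        ("w", "female", 1, None, None),
        ("e1", "male", 0, "a", "b"), ("e2", "female", 0, "a", "b"),
        ("e3", "male", 0, "a", "c"), ("e4", "female", 0, "a", "c"),
        ("e5", "male", 0, "d", "w"), ("e6", "female", 0, "d", "w"),
    ])


class TestRedundantEdgeRules:
    def test_two_mate_containment_removes_spurious_edges(self, polygamous_partial):
        """An individual with two descendant-contained mates: edges between
        the mates and from each mate to the true half-sib are removed; the
        true edge survives."""
        groups = [("a",), ("b",), ("c",), ("d",), ("w",)]
        G = pgraph(5, {(0, 3): 5.0, (1, 2): 3.0, (1, 3): 2.0, (2, 3): 2.0},
                   groups=groups)
        filter_redundant_edges(G, polygamous_partial)
        assert set(G.edges) == {(0, 3)}
        assert {(r[0], r[1]) for r in G.removed} == {(1, 2), (1, 3), (2, 3)}
        assert all(r[2] == "R1" for r in G.removed)

    def test_no_containment_leaves_graph_unchanged(self):
        P = make_pedigree([
            ("a", "male", 1, None, None), ("b", "female", 1, None, None),
            ("x", "male", 1, None, None), ("y", "female", 1, None, None),
            ("e1", "male", 0, "a", "b"), ("e2", "male", 0, "x", "y"),
        ])
        G = pgraph(4, {(0, 2): 1.5}, groups=[("a",), ("b",), ("x",), ("y",)])
        before = dict(G.edges)
        filter_redundant_edges(G, P)
        assert G.edges == before and not G.removed

    def test_rules_idempotent(self, polygamous_partial):
        groups = [("a",), ("b",), ("c",), ("d",), ("w",)]
        G = pgraph(5, {(0, 3): 5.0, (1, 2): 3.0, (1, 3): 2.0, (2, 3): 2.0},
                   groups=groups)
        filter_redundant_edges(G, polygamous_partial)
        removed_once = list(G.removed)
        filter_redundant_edges(G, polygamous_partial)
        assert G.removed == removed_once

    def test_mates_of_full_sibs_edge_removed(self):
        """Mates of two full siblings (Fig 8C/8D style): the half-sib edge
        between the mates is redundant once the sibship is established."""
        P = make_pedigree([
            ("a1", "male", 1, None, None), ("a2", "male", 1, None, None),
            ("b", "female", 1, None, None), ("c", "female", 1, None, None),
            ("e1", "male", 0, "a1", "b"), ("e2", "male", 0, "a2", "c"),
        ])
        groups = [("a1", "a2"), ("b",), ("c",)]
        G = pgraph(3, {(1, 2): 2.0}, groups=groups)
        filter_redundant_edges(G, P)
        assert not G.edges
        assert G.removed[0][2] == "R3"  # containment case

    def test_fullsib_edge_rule_on_contracted_graph(self, polygamous_partial):
        """R2: the same containment logic drops spurious full-sib super-edges."""
        classes = [("a",), ("b",), ("c",), ("d",), ("w",)]
        desc = [polygamous_partial.extant_descendants(c[0]) for c in classes]
        edges = {(1, 2): 4.0, (0, 3): 6.0}
        removed = filter_redundant_sib_edges(edges, classes, desc, polygamous_partial)
        assert (1, 2, "R2") in removed
        assert (0, 3) in edges


# ---------------------------------------------------------------------------
# Parent merging
# ---------------------------------------------------------------------------


class TestMergeParents:
    def test_two_clique_shares_one_parent(self, halfsib_pedigree):
        P = halfsib_pedigree.copy()
        for anc in ("F", "M1", "M2"):
            P.remove(anc)
        for e in P.individuals.values():
            e.father_id = e.mother_id = None
        groups = [("h1", "h1b"), ("h2",)]
        parents = add_parent_couples(P, groups, gen=1)
        coloring = TwoColoring(cliques=[(frozenset({0, 1}), 1)])
        merge_half_sib_parents(P, groups, parents, coloring)
        fathers = {P.individuals[m].father_id for g in groups for m in g}
        mothers = {P.individuals[m].mother_id for g in groups for m in g}
        assert len(fathers) == 1 and len(mothers) == 2
        for m in ("h1", "h1b", "h2"):
            assert len(P.individuals[m].parent_ids()) == 2
        P.validate()

    def test_empty_coloring_no_change(self, halfsib_pedigree):
        P = halfsib_pedigree.copy()
        for anc in ("F", "M1", "M2"):
            P.remove(anc)
        for e in P.individuals.values():
            e.father_id = e.mother_id = None
        groups = [("h1", "h1b"), ("h2",)]
        parents = add_parent_couples(P, groups, gen=1)
        n_before = len(P)
        merge_half_sib_parents(P, groups, parents, TwoColoring())
        assert len(P) == n_before

    def test_group_in_both_colors_shares_both_parents(self):
        P = make_pedigree([(f"x{k}", "male", 0, None, None) for k in range(3)])
        groups = [("x0",), ("x1",), ("x2",)]
        parents = add_parent_couples(P, groups, gen=1)
        coloring = TwoColoring(cliques=[(frozenset({0, 1}), 1),
                                        (frozenset({0, 2}), 2)])
        merge_half_sib_parents(P, groups, parents, coloring)
        # x0 shares its father with x1 and its mother with x2
        assert P.individuals["x0"].father_id == P.individuals["x1"].father_id
        assert P.individuals["x0"].mother_id == P.individuals["x2"].mother_id
        assert P.individuals["x1"].mother_id != P.individuals["x2"].mother_id
        P.validate()
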