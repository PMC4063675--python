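"""Half-sibling detection via a two-color clique cover of the polygamy graph.

Full-sibship is an equivalence relation; half-sibship is a relation between
its classes.  The polygamy graph has one vertex per full-sibling group and
a weighted edge wherever group-level composite-likelihood scoring favours
the half-sibling hypothesis.  All children of one shared parent form a
clique, and each group has two parents, so the true half-sib structure is a
two-coloring of edges where each color class is a union of vertex-disjoint
cliques (one color per parental slot).  Maximizing the colored weight is
NP-hard; the greedy heuristic colors the heaviest clique adjacent to the
already-colored region first, which resolves the color forced by adjacency
and colors chain-of-clique subgraphs optimally.

Before coloring, parsimony rules remove edges that are explained by
previously reconstructed matings rather than by a distinct shared parent
(containment of descendant sets signals such redundancy).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from pedrecon.pedigree import Pedigree
from pedrecon.scoring import GROUP_HYPOTHESES, ObservedFeatures, RelationshipScorer

logger = logging.getLogger(__name__)

#: maximum clique size searched during coloring
MAX_CLIQUE = 12


@dataclass
class PolygamyGraph:
    """Weighted half-sib evidence between full-sibling groups."""

    groups: List[Tuple[str, ...]]
    edges: Dict[Tuple[int, int], float] = field(default_factory=dict)
    removed: List[Tuple[int, int, str]] = field(default_factory=list)  # (i, j, rule)

    def remove_edge(self, i: int, j: int, rule: str) -> bool:
        key = (min(i, j), max(i, j))
        if key in self.edges:
            del self.edges[key]
            self.removed.append((key[0], key[1], rule))
            return True
        return False


@dataclass
class TwoColoring:
    """Edge two-coloring into per-color vertex-disjoint clique systems."""

    cliques: List[Tuple[FrozenSet[int], int]] = field(default_factory=list)  # (vertices, color 1|2)

    def edge_sets(self) -> Tuple[Set[Tuple[int, int]], Set[Tuple[int, int]]]:
        out: Tuple[Set[Tuple[int, int]], Set[Tuple[int, int]]] = (set(), set())
        for verts, color in self.cliques:
            for a, b in itertools.combinations(sorted(verts), 2):
                out[color - 1].add((a, b))
        return out

    def colored_weight(self, edges: Mapping[Tuple[int, int], float]) -> float:
        e1, e2 = self.edge_sets()
        return sum(edges.get(e, 0.0) for e in e1 | e2)

    def validate(self) -> None:
        e1, e2 = self.edge_sets()
        if e1 & e2:
            raise ValueError("an edge received both colors")
        for color in (1, 2):
            seen: Set[int] = set()
            for verts, c in self.cliques:
                if c != color:
                    continue
                if seen & verts:
                    raise ValueError(f"color {color} cliques are not vertex-disjoint")
                seen |= verts


def build_polygamy_graph(P: Pedigree, groups: Sequence[Tuple[str, ...]],
                         scorer: RelationshipScorer, obs: ObservedFeatures,
                         founder_gen: int) -> PolygamyGraph:
    """Score group pairs under {unrelated, half-sib, cousin}."""
    desc_sets = []
    for members in groups:
        desc: Set[str] = set()
        for m in members:
            desc |= P.extant_descendants(m)
        desc_sets.append(frozenset(desc))
    edges = {}
    for i, j, w in scorer.score_groups(P, desc_sets, founder_gen, obs, GROUP_HYPOTHESES):
        edges[(i, j)] = w
    return PolygamyGraph(groups=list(map(tuple, groups)), edges=edges)


# ---------------------------------------------------------------------------
# Redundant-edge rules
# ---------------------------------------------------------------------------


def _group_index(groups: Sequence[Tuple[str, ...]]) -> Dict[str, int]:
    return {m: gi for gi, members in enumerate(groups) for m in members}


def filter_redundant_edges(G: PolygamyGraph, P: Pedigree,
                           mates: Optional[Mapping[str, Set[str]]] = None,
                           ) -> PolygamyGraph:
    """Remove half-sib edges explained by already-reconstructed matings.

    Rules (applied in order, idempotent, removals tagged):

    * R1 — an individual ``a`` with two mates ``b, c`` whose descendant sets
      are both contained in ``a``'s: the edge between the groups of b and c,
      and edges between each mate's group and any group half-sib-linked to
      a's group, are redundant (the sharing flows through ``a``).
    * R3 — mates ``b`` of a1 and ``c`` of a2 with (a1, a2) full siblings and
      desc(b) in desc(a1), desc(c) in desc(a2): the edge (b, c) reflects the
      a1-a2 sibship, not a shared parent of b and c.
    * R4 — any half-sib edge between mates of two full siblings is removed
      once the full-sib relation of their partners is established: the
      descendant similarity is already explained.

    (The R2 analogue for full-sib edges on the contracted graph is exposed
    as :func:`filter_redundant_sib_edges`.)
    """
    mates = P.mate_map() if mates is None else mates
    gidx = _group_index(G.groups)
    desc = {m: P.extant_descendants(m) for members in G.groups for m in members}

    # R1: two mates of one individual, both descendant-contained
    for members in G.groups:
        for a in members:
            ms = sorted(mates.get(a, ()))
            for b, c in itertools.combinations(ms, 2):
                if b not in gidx or c not in gidx:
                    continue
                if not (desc[b] <= desc[a] and desc[c] <= desc[a]):
                    continue
                G.remove_edge(gidx[b], gidx[c], "R1")
                ga = gidx[a]
                linked = [x if y == ga else y for (x, y) in list(G.edges) if ga in (x, y)]
                for x in (b, c):
                    for other in linked:
                        if other != gidx[x]:
                            G.remove_edge(gidx[x], other, "R1")

    # R3 / R4: mates of two full siblings
    for members in G.groups:
        for a1, a2 in itertools.combinations(sorted(members), 2):
            for b in sorted(mates.get(a1, ())):
                for c in sorted(mates.get(a2, ())):
                    if b == c or b not in gidx or c not in gidx:
                        continue
                    if gidx[b] == gidx[c]:
                        continue
                    if desc[b] <= desc[a1] and desc[c] <= desc[a2]:
                        if G.remove_edge(gidx[b], gidx[c], "R3"):
                            continue
                    G.remove_edge(gidx[b], gidx[c], "R4")
    return G


def filter_redundant_sib_edges(edges: Dict[Tuple[int, int], float],
                               classes: Sequence[Tuple[str, ...]],
                               desc_sets: Sequence[FrozenSet[str]],
                               P: Pedigree,
                               mates: Optional[Mapping[str, Set[str]]] = None,
                               ) -> List[Tuple[int, int, str]]:
    """R2: the R1 containment rule applied to full-sib super-edges.

    Mutates ``edges`` in place and returns the removals (i, j, "R2").
    """
    mates = P.mate_map() if mates is None else mates
    cidx = {m: ci for ci, members in enumerate(classes) for m in members}
    desc = {m: P.extant_descendants(m) for members in classes for m in members}
    removed: List[Tuple[int, int, str]] = []

    def drop(i: int, j: int) -> None:
        key = (min(i, j), max(i, j))
        if key in edges:
            del edges[key]
            removed.append((key[0], key[1], "R2"))

    for members in classes:
        for a in members:
            ms = sorted(mates.get(a, ()))
            for b, c in itertools.combinations(ms, 2):
                if b not in cidx or c not in cidx:
                    continue
                if not (desc[b] <= desc_sets[cidx[a]] and desc[c] <= desc_sets[cidx[a]]):
                    continue
                drop(cidx[b], cidx[c])
                ca = cidx[a]
                linked = [x if y == ca else y for (x, y) in list(edges) if ca in (x, y)]
                for x in (b, c):
                    for other in linked:
                        if other != cidx[x]:
                            drop(cidx[x], other)
    return removed


# ---------------------------------------------------------------------------
# Two-color clique cover
# ---------------------------------------------------------------------------


def _clique_weight(verts: Sequence[int], edges: Mapping[Tuple[int, int], float]) -> float:
    return sum(edges[(a, b)] for a, b in itertools.combinations(sorted(verts), 2))


def _legal_cliques(active: nx.Graph, blocked: Set[int]):
    """Maximal cliques of the active graph avoiding blocked vertices."""
    H = active.subgraph([v for v in active if v not in blocked])
    for Q in nx.find_cliques(H):
        if len(Q) >= 2:
            yield tuple(sorted(Q))[:MAX_CLIQUE]


def two_color_clique_cover(G: PolygamyGraph, order: str = "adjacency") -> TwoColoring:
    """Greedy maximum-weight two-coloring of the polygamy graph.

    ``order="adjacency"`` repeatedly colors the heaviest clique touching the
    already-colored region (its color forced by which color's vertices it
    touches), falling back to the globally heaviest clique (color 1) when no
    adjacent clique of two or more vertices is colorable.  This order
    propagates color constraints outward and colors chains of cliques
    optimally.  ``order="naive"`` is the baseline: all maximal cliques by
    decreasing weight, first legal color.
    """
    active = nx.Graph()
    active.add_nodes_from(range(len(G.groups)))
    for (a, b), w in G.edges.items():
        active.add_edge(a, b, weight=w)
    coloring = TwoColoring()
    V: Tuple[Set[int], Set[int]] = (set(), set())

    def commit(verts: Tuple[int, ...], color: int) -> None:
        coloring.cliques.append((frozenset(verts), color))
        V[color - 1].update(verts)
        active.remove_edges_from(itertools.combinations(verts, 2))

    if order == "naive":
        cliques = sorted(
            ((tuple(sorted(Q))[:MAX_CLIQUE]) for Q in nx.find_cliques(active) if len(Q) >= 2),
            key=lambda q: (-_clique_weight(q, G.edges), q),
        )
        for q in cliques:
            if not all(active.has_edge(a, b) for a, b in itertools.combinations(q, 2)):
                continue
            for color in (1, 2):
                if not (set(q) & V[color - 1]):
                    commit(q, color)
                    break
        return coloring

    if order != "adjacency":
        raise ValueError(f"unknown coloring order {order!r}")

    while True:
        best_adj = None  # (-w, q, color)
        best_any = None
        for color in (1, 2):
            for q in _legal_cliques(active, V[color - 1]):
                w = _clique_weight(q, G.edges)
                cand = (-w, q, color)
                if set(q) & (V[0] | V[1]):
                    if best_adj is None or cand < best_adj:
                        best_adj = cand
                elif color == 1:  # untouched cliques are color-symmetric
                    if best_any is None or cand < best_any:
                        best_any = cand
        if best_adj is not None:
            _, q, color = best_adj
            commit(q, color)
        elif best_any is not None:
            _, q, color = best_any
            commit(q, 1)
        else:
            break
    coloring.validate()
    return coloring


# ---------------------------------------------------------------------------
# Parent merging
# ---------------------------------------------------------------------------


def merge_half_sib_parents(P: Pedigree, groups: Sequence[Tuple[str, ...]],
                           parents: Dict[int, Tuple[str, str]],
                           coloring: TwoColoring) -> None:
    """Merge one parent slot per colored clique into a single shared parent.

    Color 1 merges the father slot, color 2 the mother slot (gender labels
    are arbitrary — parental sex is unidentifiable from autosomes).  The
    merged parent replaces each member group's slot parent and inherits the
    union of mates; every child keeps exactly two parents.
    """
    for verts, color in coloring.cliques:
        slot = 0 if color == 1 else 1
        members = sorted(verts)
        keep = parents[members[0]][slot]
        for gi in members[1:]:
            old = parents[gi][slot]
            for child in list(P.children_of(old)):
                ind = P[child]
                if slot == 0:
                    P.set_parents(child, keep, ind.mother_id)
                else:
                    P.set_parents(child, ind.father_id, keep)
            P.remove(old)
            pair = list(parents[gi])
            pair[slot] = keep
            parents[gi] = tuple(pair)
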