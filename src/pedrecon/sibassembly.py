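"""Contracted sibling graph and greedy clique-cover edge assignment.

Founders with identical extant-descendant sets (e.g. a monogamous parent
couple) are indistinguishable from descendant evidence alone, so they are
contracted into super-vertices.  Potential full-sibling relations are then
weighted super-edges between classes, and each super-edge must be assigned
to a single individual-level sibling edge such that the assigned edges form
a union of vertex-disjoint cliques (full-sibship is transitive).  Finding
the maximum-weight assignment is NP-hard; a greedy traversal by decreasing
weight is used, preferring assignments that grow existing cliques (fewer
parents — the parsimonious choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from pedrecon.pedigree import FEMALE, MALE, Individual, Pedigree
from pedrecon.scoring import COUPLE_HYPOTHESES, ObservedFeatures, RelationshipScorer

logger = logging.getLogger(__name__)


@dataclass
class ContractedSiblingGraph:
    """Super-vertices (classes of founders) and weighted potential-sib edges."""

    classes: List[Tuple[str, ...]]  # sorted member ids per class
    desc_sets: List[FrozenSet[str]]
    edges: Dict[Tuple[int, int], float] = field(default_factory=dict)  # (i<j) -> weight

    def edge_weight(self, i: int, j: int) -> Optional[float]:
        return self.edges.get((min(i, j), max(i, j)))

    def neighbors(self, i: int) -> Set[int]:
        out = set()
        for (a, b) in self.edges:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out


@dataclass
class AssignedSiblingGraph:
    """Result of the edge assignment: vertex-disjoint cliques of individuals."""

    cliques: List[Set[str]]
    assignments: Dict[Tuple[int, int], Tuple[str, str]]  # super-edge -> individual edge
    dropped: List[Tuple[int, int]]

    def clique_of(self) -> Dict[str, int]:
        out = {}
        for k, cl in enumerate(self.cliques):
            for m in cl:
                out[m] = k
        return out

    def validate(self) -> None:
        seen: Set[str] = set()
        for cl in self.cliques:
            if seen & cl:
                raise ValueError("individual appears in two cliques")
            seen |= cl


def contract(P: Pedigree, founders: Optional[Sequence[str]] = None,
             ) -> Tuple[List[Tuple[str, ...]], List[FrozenSet[str]]]:
    """Partition founders into classes with identical extant-descendant sets.

    Founders with no extant descendants carry no evidence and are excluded
    with a warning.  Classes and members are ordered deterministically.
    """
    founders = P.founders() if founders is None else list(founders)
    by_desc: Dict[FrozenSet[str], List[str]] = {}
    for f in founders:
        desc = P.extant_descendants(f)
        if not desc:
            logger.warning("founder %s has no extant descendants; excluded", f)
            continue
        by_desc.setdefault(desc, []).append(f)
    items = sorted(by_desc.items(), key=lambda kv: sorted(kv[1])[0])
    classes = [tuple(sorted(members)) for _, members in items]
    desc_sets = [desc for desc, _ in items]
    return classes, desc_sets


def build_contracted_graph(P: Pedigree, classes: List[Tuple[str, ...]],
                           desc_sets: List[FrozenSet[str]],
                           scorer: RelationshipScorer, obs: ObservedFeatures,
                           founder_gen: int,
                           hypotheses: Tuple[str, ...] = COUPLE_HYPOTHESES,
                           ) -> ContractedSiblingGraph:
    """Score every class pair; add a weighted super-edge on a full-sib win."""
    edges = {}
    for i, j, w in scorer.score_groups(P, desc_sets, founder_gen, obs, hypotheses):
        edges[(i, j)] = w
    return ContractedSiblingGraph(classes=classes, desc_sets=desc_sets, edges=edges)


def assign_edges(G: ContractedSiblingGraph) -> AssignedSiblingGraph:
    """Greedy maximum-weight disjoint-clique-cover edge assignment.

    Super-edges are traversed by decreasing weight.  For super-edge (U, V)
    the candidate individual pairs (a, b), a in U, b in V, are those whose
    current cliques (a free individual counts as a singleton clique) can be
    merged: every implied cross pair must be supported by an existing,
    still-unassigned super-edge between distinct classes.  The candidate
    maximizing the resulting clique size wins, ties broken lexicographically
    by (class id, individual id); committing an edge auto-assigns every
    implied super-edge to the corresponding implied individual edge.
    Unassignable super-edges are dropped — the cover maximizes weight, not
    coverage.
    """
    class_of: Dict[str, int] = {}
    for ci, members in enumerate(G.classes):
        for m in members:
            class_of[m] = ci
    clique_id: Dict[str, int] = {}
    cliques: List[Set[str]] = []
    assigned: Dict[Tuple[int, int], Tuple[str, str]] = {}
    dropped: List[Tuple[int, int]] = []

    def ekey(i: int, j: int) -> Tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def supports(ci: int, cj: int, current: Tuple[int, int]) -> bool:
        """Is the implied pair (class ci, class cj) backed by a usable super-edge?"""
        if ci == cj:
            return False
        e = ekey(ci, cj)
        return e in G.edges and (e == current or e not in assigned)

    order = sorted(G.edges.items(), key=lambda kv: (-kv[1], kv[0]))
    for (U, V), w in order:
        if (U, V) in assigned:
            continue
        best = None
        for a in G.classes[U]:
            for b in G.classes[V]:
                K_a = cliques[clique_id[a]] if a in clique_id else {a}
                K_b = cliques[clique_id[b]] if b in clique_id else {b}
                if K_a is K_b:
                    continue
                ok = all(
                    supports(class_of[x], class_of[y], (U, V))
                    for x in K_a for y in K_b
                )
                if not ok:
                    continue
                size = len(K_a) + len(K_b)
                cand = (-size, (G.classes[U].index(a), a, G.classes[V].index(b), b), a, b)
                if best is None or cand < best:
                    best = cand
        if best is None:
            dropped.append((U, V))
            continue
        _, _, a, b = best
        K_a = cliques[clique_id[a]] if a in clique_id else {a}
        K_b = cliques[clique_id[b]] if b in clique_id else {b}
        # assign every implied cross edge (the traversed one included)
        for x in K_a:
            for y in K_b:
                e = ekey(class_of[x], class_of[y])
                assigned[e] = (x, y) if e[0] == class_of[x] else (y, x)
        merged = K_a | K_b
        if a in clique_id:
            cliques[clique_id[a]] = merged
            target = clique_id[a]
            if b in clique_id:
                cliques[clique_id[b]] = set()
        elif b in clique_id:
            cliques[clique_id[b]] = merged
            target = clique_id[b]
        else:
            cliques.append(merged)
            target = len(cliques) - 1
        for m in merged:
            clique_id[m] = target
    result = AssignedSiblingGraph(cliques=[c for c in cliques if len(c) >= 2],
                                  assignments=assigned, dropped=dropped)
    result.validate()
    return result


def sibling_groups(G: ContractedSiblingGraph, A: AssignedSiblingGraph,
                   ) -> List[Tuple[str, ...]]:
    """Full-sibling groups: assignment cliques plus singletons, sorted."""
    in_clique = {m for cl in A.cliques for m in cl}
    groups = [tuple(sorted(cl)) for cl in A.cliques]
    for members in G.classes:
        for m in members:
            if m not in in_clique:
                groups.append((m,))
    groups.sort()
    return groups


def add_parent_couples(P: Pedigree, groups: Sequence[Tuple[str, ...]], gen: int,
                       ) -> Dict[int, Tuple[str, str]]:
    """Create a new (father, mother) couple for every full-sibling group.

    Sexes of constructed ancestors are arbitrary but consistent within a
    couple; true parental sex is unidentifiable from autosomal evidence.
    Returns group index -> (father_id, mother_id).
    """
    parents: Dict[int, Tuple[str, str]] = {}
    for k, members in enumerate(groups):
        fa = f"anc{gen}_{k}f"
        mo = f"anc{gen}_{k}m"
        P.add(Individual(fa, sex=MALE, generation=gen))
        P.add(Individual(mo, sex=FEMALE, generation=gen))
        for m in members:
            P.set_parents(m, fa, mo)
        parents[k] = (fa, mo)
    return parents
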