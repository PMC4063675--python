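"""Pedigree data model.

A pedigree is a DAG of individuals linked by parentage.  Extant individuals
are the observed leaves (generation 0 in the synchronized-generation model);
all ancestors are unobserved.  The module provides the relatedness
primitives the reconstruction and evaluation stages are built on:

* extant descendant sets (the evidence base of every unobserved founder),
* least-common-ancestor (LCA) vectors of meiosis distances, used both as
  relationship descriptors and as cache keys for simulated IBD-feature
  distributions,
* minimal meiosis distances between individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

#: (d_i, d_j) meiosis distances from a pair up to one least common ancestor.
LCAEntry = Tuple[int, int]
LCAVector = Tuple[LCAEntry, ...]


@dataclass
class Individual:
    """One pedigree member.

    ``generation`` counts upwards from the extant generation (0); parents of
    a generation-g individual sit at generation g+1 in the synchronized
    model.  Age-structured populations carry ``generation=None`` and mark
    observed individuals with the explicit ``extant`` flag instead.
    """

    id: str
    sex: str = UNKNOWN
    generation: Optional[int] = None
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    extant: bool = False

    def parent_ids(self) -> Tuple[str, ...]:
        return tuple(p for p in (self.father_id, self.mother_id) if p is not None)


class Pedigree:
    """A mutable pedigree: a DAG of :class:`Individual` keyed by id."""

    def __init__(self, individuals: Iterable[Individual] = ()):
        self.individuals: Dict[str, Individual] = {}
        self._children: Dict[str, Set[str]] = {}
        for ind in individuals:
            self.add(ind)

    # -- construction ---------------------------------------------------

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise ValueError(f"duplicate individual id {ind.id!r}")
        self.individuals[ind.id] = ind
        for p in ind.parent_ids():
            self._children.setdefault(p, set()).add(ind.id)

    def set_parents(self, child_id: str, father_id: Optional[str], mother_id: Optional[str]) -> None:
        ind = self.individuals[child_id]
        for p in ind.parent_ids():
            self._children.get(p, set()).discard(child_id)
        ind.father_id = father_id
        ind.mother_id = mother_id
        for p in ind.parent_ids():
            self._children.setdefault(p, set()).add(ind.id)

    def remove(self, ind_id: str) -> None:
        ind = self.individuals.pop(ind_id)
        for p in ind.parent_ids():
            self._children.get(p, set()).discard(ind_id)
        self._children.pop(ind_id, None)

    def copy(self) -> "Pedigree":
        return Pedigree(replace(ind) for ind in self.individuals.values())

    # -- basic queries --------------------------------------------------

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    def children_of(self, ind_id: str) -> Set[str]:
        return self._children.get(ind_id, set())

    def founders(self) -> List[str]:
        """Ids of individuals with no recorded parents, in insertion order."""
        return [i.id for i in self.individuals.values() if not i.parent_ids()]

    def extant_ids(self) -> List[str]:
        return [i.id for i in self.individuals.values() if i.extant]

    def mate_map(self) -> Dict[str, Set[str]]:
        """Map each parent to the set of co-parents of its children."""
        mates: Dict[str, Set[str]] = {}
        for ind in self.individuals.values():
            if ind.father_id is not None and ind.mother_id is not None:
                mates.setdefault(ind.father_id, set()).add(ind.mother_id)
                mates.setdefault(ind.mother_id, set()).add(ind.father_id)
        return mates

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and acyclicity; raise ValueError."""
        for ind in self.individuals.values():
            for p in ind.parent_ids():
                if p not in self.individuals:
                    raise ValueError(f"{ind.id}: unknown parent {p!r}")
        color: Dict[str, int] = {}

        def dfs(start: str) -> None:
            stack = [(start, iter(self.individuals[start].parent_ids()))]
            color[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if color.get(p, 0) == 1:
                        raise ValueError(f"parentage cycle through {p!r}")
                    if color.get(p, 0) == 0:
                        color[p] = 1
                        stack.append((p, iter(self.individuals[p].parent_ids())))
                        advanced = True
                        break
                if not advanced:
                    color[node] = 2
                    stack.pop()

        for i in self.individuals:
            if color.get(i, 0) == 0:
                dfs(i)

    # -- relatedness primitives -----------------------------------------

    def extant_descendants(self, ind_id: str) -> FrozenSet[str]:
        """Extant individuals reachable from ``ind_id`` via child links.

        An extant individual is its own (reflexive) extant descendant.
        """
        if ind_id not in self.individuals:
            raise KeyError(f"unknown individual {ind_id!r}")
        out: Set[str] = set()
        stack = [ind_id]
        seen = {ind_id}
        while stack:
            v = stack.pop()
            if self.individuals[v].extant:
                out.add(v)
            for c in self._children.get(v, ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return frozenset(out)

    def ancestor_distances(self, ind_id: str) -> Dict[str, int]:
        """Minimal meiosis count from ``ind_id`` up to each ancestor.

        Includes ``ind_id`` itself at distance 0.  With inbreeding an
        ancestor may be reachable along several paths; the minimum is kept.
        """
        if ind_id not in self.individuals:
            raise KeyError(f"unknown individual {ind_id!r}")
        dist = {ind_id: 0}
        frontier = [ind_id]
        while frontier:
            nxt: List[str] = []
            for v in frontier:
                dv = dist[v]
                for p in self.individuals[v].parent_ids():
                    if p not in dist or dist[p] > dv + 1:
                        dist[p] = dv + 1
                        nxt.append(p)
            frontier = nxt
        return dist

    def _ancestor_set(self, ind_id: str) -> Set[str]:
        return set(self.ancestor_distances(ind_id))

    def lca_vector(self, i: str, j: str) -> LCAVector:
        """LCA vector of a pair: one ``(d_i, d_j)`` entry per least common
        ancestor, canonically sorted.

        A least common ancestor is a common ancestor none of whose proper
        descendants is also a common ancestor of the pair.  Full siblings
        have vector ``((1, 1), (1, 1))`` — both parents, one meiosis each
        side; an unrelated pair has the empty vector.
        """
        if i == j:
            raise ValueError("lca_vector requires two distinct individuals")
        di = self.ancestor_distances(i)
        dj = self.ancestor_distances(j)
        common = set(di) & set(dj)
        if not common:
            return ()
        anc_of = {c: self._ancestor_set(c) for c in common}
        # c is an LCA unless another common ancestor is a proper descendant
        # of c (i.e. has c among its own ancestors).
        lcas = [c for c in common if not any(o != c and c in anc_of[o] for o in common)]
        entries = [tuple(sorted((di[c], dj[c]))) for c in lcas]
        return tuple(sorted(entries))

    def min_meiosis_distance(self, i: str, j: str) -> float:
        """Minimal number of meioses separating i and j; inf if unrelated."""
        if i not in self.individuals or j not in self.individuals:
            raise KeyError("unknown individual")
        if i == j:
            return 0
        di = self.ancestor_distances(i)
        dj = self.ancestor_distances(j)
        best = math.inf
        for c, d in di.items():
            if c in dj:
                best = min(best, d + dj[c])
        return best

    # -- truncation ------------------------------------------------------

    def truncate(self, k: int) -> "Pedigree":
        """First ``k`` generations: extant plus ``k - 1`` ancestor levels.

        Individuals at generation >= k are dropped and dangling parent links
        cleared.  Requires synchronized generation labels.
        """
        out = Pedigree()
        keep = {i for i, ind in self.individuals.items() if ind.generation is not None and ind.generation < k}
        for i in keep:
            ind = replace(self.individuals[i])
            if ind.father_id not in keep:
                ind.father_id = None
            if ind.mother_id not in keep:
                ind.mother_id = None
            out.add(ind)
        return out


def canonical_lca_key(vec: LCAVector) -> str:
    """Serialize an LCA vector into the cache-key string."""
    return ";".join(f"{a},{b}" for a, b in vec)
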