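"""Generation-by-generation reconstruction loop.

Starting from the extant individuals, each iteration contracts the current
founders into descendant-equivalence classes, scores class pairs for
full-sibship, assigns super-edges to a disjoint clique cover, and creates a
new parent couple per sibling group; in polygamous mode a half-sibling
detection pass then merges single parents across groups.  All evidence
flows through observed extant-pair IBD features — ancestors are never
observed directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from pedrecon.genome import GenomeModel, IBDFeatures, default_genome
from pedrecon.halfsib import (
    build_polygamy_graph,
    filter_redundant_edges,
    filter_redundant_sib_edges,
    merge_half_sib_parents,
    two_color_clique_cover,
)
from pedrecon.pedigree import Individual, Pedigree
from pedrecon.scoring import (
    COUPLE_HYPOTHESES,
    COUPLE_HYPOTHESES_POLY,
    ObservedFeatures,
    RelationshipScorer,
    ScoringConfig,
)
from pedrecon.sibassembly import (
    add_parent_couples,
    assign_edges,
    build_contracted_graph,
    contract,
    sibling_groups,
)

logger = logging.getLogger(__name__)

MONOGAMOUS = "monogamous"
POLYGAMOUS = "polygamous"


def _dump_generation(debug_dir: str, t: int, G, A, H, coloring) -> None:
    """Debug TSVs: contracted edges with assignments, removed half-sib
    edges with rule tags, and the coloring, one file set per generation."""
    from pathlib import Path

    d = Path(debug_dir)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / f"gen{t}.sib_edges.tsv", "w") as fh:
        fh.write("class_i\tclass_j\tmembers_i\tmembers_j\tweight\tassigned_to\n")
        for (i, j), w in sorted(G.edges.items()):
            a = A.assignments.get((i, j))
            fh.write(f"{i}\t{j}\t{','.join(G.classes[i])}\t{','.join(G.classes[j])}"
                     f"\t{w:.4f}\t{','.join(a) if a else '-'}\n")
    if H is not None:
        with open(d / f"gen{t}.halfsib.tsv", "w") as fh:
            fh.write("kind\tgroup_i\tgroup_j\tinfo\n")
            for (i, j), w in sorted(H.edges.items()):
                fh.write(f"edge\t{i}\t{j}\t{w:.4f}\n")
            for i, j, rule in H.removed:
                fh.write(f"removed\t{i}\t{j}\t{rule}\n")
            for verts, color in coloring.cliques:
                fh.write(f"clique\t{','.join(map(str, sorted(verts)))}\t-\tcolor{color}\n")


@dataclass(frozen=True)
class RunConfig:
    mode: str = MONOGAMOUS
    generations: int = 5
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    coloring_order: str = "adjacency"
    debug_dir: Optional[str] = None  # per-generation graph dumps (TSV)

    def __post_init__(self):
        if self.mode not in (MONOGAMOUS, POLYGAMOUS):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.generations < 2:
            raise ValueError("need at least 2 generations")


@dataclass
class GenerationStats:
    generation: int
    n_classes: int = 0
    n_super_edges: int = 0
    n_cliques: int = 0
    n_groups: int = 0
    n_polygamy_edges: int = 0
    n_removed_edges: Dict[str, int] = field(default_factory=dict)
    n_colored_cliques: int = 0


def reconstruct(extant_ids: Sequence[str],
                observed: Mapping[Tuple[str, str], IBDFeatures],
                cfg: RunConfig,
                genome: Optional[GenomeModel] = None,
                scorer: Optional[RelationshipScorer] = None,
                stats_out: Optional[List[GenerationStats]] = None,
                ) -> Pedigree:
    """Reconstruct a ``cfg.generations``-generation pedigree.

    ``observed`` maps sorted extant-id pairs to IBD features (absent pairs
    share nothing).  A caller-supplied ``scorer`` allows distribution-cache
    reuse across runs; results are independent of cache state because
    per-key simulation seeds derive from the scoring config alone.
    """
    if not extant_ids:
        raise ValueError("empty extant set")
    genome = default_genome() if genome is None else genome
    scorer = RelationshipScorer(cfg.scoring, genome) if scorer is None else scorer
    obs = ObservedFeatures(extant_ids, observed)

    P = Pedigree(Individual(i, generation=0, extant=True) for i in extant_ids)
    for t in range(1, cfg.generations):
        st = GenerationStats(generation=t)
        founders = P.founders()
        classes, desc_sets = contract(P, founders)
        st.n_classes = len(classes)
        couple_hyps = COUPLE_HYPOTHESES_POLY if cfg.mode == POLYGAMOUS else COUPLE_HYPOTHESES
        G = build_contracted_graph(P, classes, desc_sets, scorer, obs,
                                   founder_gen=t - 1, hypotheses=couple_hyps)
        if cfg.mode == POLYGAMOUS and t >= 2:
            removed = filter_redundant_sib_edges(G.edges, classes, desc_sets, P)
            for i, j, rule in removed:
                st.n_removed_edges[rule] = st.n_removed_edges.get(rule, 0) + 1
        st.n_super_edges = len(G.edges)
        A = assign_edges(G)
        st.n_cliques = len(A.cliques)
        groups = sibling_groups(G, A)
        st.n_groups = len(groups)
        coloring = None
        H = None
        if cfg.mode == POLYGAMOUS:
            H = build_polygamy_graph(P, groups, scorer, obs, founder_gen=t - 1)
            if t >= 2:
                filter_redundant_edges(H, P)
            for i, j, rule in H.removed:
                st.n_removed_edges[rule] = st.n_removed_edges.get(rule, 0) + 1
            st.n_polygamy_edges = len(H.edges)
            coloring = two_color_clique_cover(H, order=cfg.coloring_order)
            st.n_colored_cliques = len(coloring.cliques)
        if cfg.debug_dir is not None:
            _dump_generation(cfg.debug_dir, t, G, A, H, coloring)
        parents = add_parent_couples(P, groups, gen=t)
        if coloring is not None:
            merge_half_sib_parents(P, groups, parents, coloring)
        logger.info(
            "generation %d: %d classes, %d super-edges, %d cliques, %d groups, "
            "%d polygamy edges, %d colored cliques, removed %s",
            t, st.n_classes, st.n_super_edges, st.n_cliques, st.n_groups,
            st.n_polygamy_edges, st.n_colored_cliques, st.n_removed_edges or {},
        )
        if stats_out is not None:
            stats_out.append(st)
    P.validate()
    return P
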