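"""Quality scores for reconstructed pedigrees.

A reconstructed pedigree is compared with the ground truth through the
minimal meiosis distances it implies between extant pairs:

* sensitivity — fraction of truly related extant pairs whose minimal
  meiosis distance is reproduced exactly;
* PPV — fraction of reconstructed related pairs whose distance is correct;
* consensus accuracy — fraction of ALL extant pairs (unrelated matches
  included) with equal distance; dominated by unrelated pairs, kept for
  comparability;
* RMSE-IBD — root-mean-square difference between observed total IBD length
  per pair and the total obtained by gene-dropping the reconstructed
  pedigree (averaged over several drops), in Mbp.

Scores with an empty denominator are reported as ``None`` (serialized as
null), never as 0 — an all-unrelated reconstruction has zero sensitivity
and *undefined* PPV.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from pedrecon.genome import GenomeModel, gene_drop, pairwise_ibd_features
from pedrecon.pedigree import Pedigree

Pair = Tuple[str, str]


def extant_pair_distances(P: Pedigree, k: Optional[int] = None) -> Dict[Pair, int]:
    """Minimal meiosis distance for every related extant pair.

    ``k`` truncates the pedigree to its first k generations (extant plus
    k - 1 ancestor levels) before measuring.  Unrelated pairs are absent.
    """
    if k is not None:
        P = P.truncate(k)
    extant = sorted(P.extant_ids())
    per_anc: Dict[str, List[Tuple[str, int]]] = {}
    for e in extant:
        for anc, d in P.ancestor_distances(e).items():
            per_anc.setdefault(anc, []).append((e, d))
    out: Dict[Pair, int] = {}
    for anc, lst in per_anc.items():
        if len(lst) < 2:
            continue
        for x in range(len(lst)):
            ex, dx = lst[x]
            for y in range(x + 1, len(lst)):
                ey, dy = lst[y]
                if ex == ey:
                    continue
                key = (ex, ey) if ex < ey else (ey, ex)
                dist = dx + dy
                if key not in out or out[key] > dist:
                    out[key] = dist
    return out


def _check_same_extant(P_R: Pedigree, P_O: Pedigree) -> List[str]:
    er, eo = set(P_R.extant_ids()), set(P_O.extant_ids())
    if er != eo:
        raise ValueError("reconstructed and true pedigrees observe different extant sets")
    return sorted(er)


def sensitivity_ppv(P_R: Pedigree, P_O: Pedigree, k: Optional[int] = None,
                    max_distance: Optional[int] = None,
                    ) -> Tuple[Optional[float], Optional[float]]:
    """Distance-exact sensitivity and PPV over related extant pairs.

    ``max_distance`` restricts each rel-set to pairs within that minimal
    meiosis distance (e.g. 4 covers siblings and first cousins).  Undefined
    scores (empty denominators) are returned as None.
    """
    _check_same_extant(P_R, P_O)
    dR = extant_pair_distances(P_R, k)
    dO = extant_pair_distances(P_O, k)
    rel_O = {p: d for p, d in dO.items() if max_distance is None or d <= max_distance}
    rel_R = {p: d for p, d in dR.items() if max_distance is None or d <= max_distance}
    sens = None
    if rel_O:
        sens = sum(1 for p, d in rel_O.items() if dR.get(p) == d) / len(rel_O)
    ppv = None
    if rel_R:
        ppv = sum(1 for p, d in rel_R.items() if dO.get(p) == d) / len(rel_R)
    return sens, ppv


def consensus_accuracy(P_R: Pedigree, P_O: Pedigree, k: Optional[int] = None) -> float:
    """Fraction of all extant pairs with matching minimal meiosis distance
    (infinite distances match each other)."""
    extant = _check_same_extant(P_R, P_O)
    n = len(extant)
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    dR = extant_pair_distances(P_R, k)
    dO = extant_pair_distances(P_O, k)
    mismatch = sum(1 for p in set(dR) | set(dO)
                   if dR.get(p, math.inf) != dO.get(p, math.inf))
    return (total - mismatch) / total


def halfsib_pairs(P: Pedigree) -> set:
    """Extant pairs sharing exactly one parent."""
    extant = P.extant_ids()
    by_parent: Dict[str, List[str]] = {}
    for e in extant:
        for p in P.individuals[e].parent_ids():
            by_parent.setdefault(p, []).append(e)
    shared: Dict[Pair, int] = {}
    for p, kids in by_parent.items():
        kids = sorted(kids)
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                shared[(kids[a], kids[b])] = shared.get((kids[a], kids[b]), 0) + 1
    return {pair for pair, cnt in shared.items() if cnt == 1}


def halfsib_sensitivity_ppv(P_R: Pedigree, P_O: Pedigree,
                            ) -> Tuple[Optional[float], Optional[float]]:
    """Sensitivity/PPV of half-sibling pairs (exactly one shared parent)."""
    _check_same_extant(P_R, P_O)
    true_hs = halfsib_pairs(P_O)
    rec_hs = halfsib_pairs(P_R)
    sens = len(true_hs & rec_hs) / len(true_hs) if true_hs else None
    ppv = len(true_hs & rec_hs) / len(rec_hs) if rec_hs else None
    return sens, ppv


def rmse_ibd(P_R: Pedigree, observed_totals: Mapping[Pair, float],
             genome: GenomeModel, n_runs: int = 5,
             rng: Optional[np.random.Generator] = None,
             min_len_cm: float = 1.0) -> float:
    """RMSE (Mbp) between observed and pedigree-simulated total IBD length.

    Per run, one gene drop on the reconstructed pedigree yields a simulated
    total IBD length for every extant pair; the per-run RMSE over all pairs
    is averaged over ``n_runs``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    extant = sorted(P_R.extant_ids())
    n = len(extant)
    total_pairs = n * (n - 1) // 2
    if total_pairs == 0:
        return 0.0
    obs = {tuple(sorted(p)): v for p, v in observed_totals.items()}
    scores = []
    for _ in range(n_runs):
        haps = gene_drop(P_R, genome, rng)
        sim = {p: f.total_length_mbp
               for p, f in pairwise_ibd_features(haps, extant, genome, min_len_cm).items()}
        sq = 0.0
        for p in set(obs) | set(sim):
            sq += (obs.get(p, 0.0) - sim.get(p, 0.0)) ** 2
        scores.append(math.sqrt(sq / total_pairs))
    return float(np.mean(scores))
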