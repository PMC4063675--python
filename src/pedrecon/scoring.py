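"""Relationship scoring from IBD features.

For a candidate pair of unobserved founders (or full-sibling groups) the
method decides among a small set of hypothesized relationships — e.g.
{unrelated, full siblings, first cousins} — by comparing the observed IBD
features (segment count, total length in Mbp) of their extant descendant
pairs against simulated feature distributions.

Every extant descendant pair is characterized by its LCA vector: the
multiset of meiosis-distance pairs to its least common ancestors in the
hypothesis pedigree, i.e. the ancestry already reconstructed in the partial
pedigree plus the entries contributed by the hypothesized link.  For each
distinct vector a minimal pedigree realizing it is gene-dropped ``n_sim``
times, the sampled feature cloud is smoothed with a Gaussian product kernel
(features scaled to unit variance per axis, bandwidth ``kde_h``), and the
resulting density is cached under the canonical vector key.  Conditioning
on the reconstructed ancestry is what keeps already-explained sharing (e.g.
between in-law families) from masquerading as fresh sibling evidence.

The composite log likelihood of a hypothesis is the sum of per-pair log
densities over all *informative* cross pairs of extant descendants: a pair
lying entirely inside one candidate's descendant set relates through that
candidate itself, making the hypothesized ancestors non-least common
ancestors, so its density is hypothesis-independent and the pair is
excluded.  An edge is emitted only when the positive relationship strictly
beats both alternatives; its weight is the composite log-likelihood ratio
``log L_pos - log max(L_alt1, L_alt2)``.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.special import logsumexp

from pedrecon.genome import GenomeModel, IBDFeatures, extract_ibd, gene_drop, ibd_features
from pedrecon.pedigree import (
    FEMALE,
    MALE,
    Individual,
    LCAVector,
    Pedigree,
    canonical_lca_key,
)

UNRELATED = "unrelated"
FULL_SIB = "full_sib"
HALF_SIB = "half_sib"
COUSIN = "cousin"

#: hypothesis sets: the positive hypothesis comes second, the rest are
#: alternatives.  In polygamous mode the couple-level test adds half_sib as
#: an alternative so that half-sibling pairs do not masquerade as full
#: siblings (their features sit between the full-sib and cousin clouds).
COUPLE_HYPOTHESES = (UNRELATED, FULL_SIB, COUSIN)
COUPLE_HYPOTHESES_POLY = (UNRELATED, FULL_SIB, HALF_SIB, COUSIN)
GROUP_HYPOTHESES = (UNRELATED, HALF_SIB, COUSIN)


@dataclass(frozen=True)
class ScoringConfig:
    n_sim: int = 50
    kde_h: float = 2.0
    min_len_cm: float = 1.0
    density_floor: float = 1e-300
    scale_floor: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_sim < 2:
            raise ValueError("n_sim must be >= 2")


def hypothesis_extra_entries(founder_gen: int, relationship: str) -> LCAVector:
    """LCA-vector entries the hypothesized link adds for an extant cross pair.

    The candidates sit at generation ``founder_gen``; their extant
    descendants are ``founder_gen`` meioses below, so e.g. shared parents of
    the candidates sit ``founder_gen + 1`` meioses from each leaf.
    """
    t = founder_gen + 1
    if relationship == FULL_SIB:
        return ((t, t), (t, t))
    if relationship == HALF_SIB:
        return ((t, t),)
    if relationship == COUSIN:
        return ((t + 1, t + 1), (t + 1, t + 1))
    if relationship == UNRELATED:
        return ()
    raise ValueError(f"unknown relationship {relationship!r}")


def merge_lca_entries(existing: LCAVector, extra: LCAVector) -> LCAVector:
    return tuple(sorted(tuple(existing) + tuple(extra)))


# ---------------------------------------------------------------------------
# Hypothesis pedigrees
# ---------------------------------------------------------------------------


def realize_lca_vector(entries: LCAVector) -> Tuple[Pedigree, str, str]:
    """Build a minimal pedigree in which an extant pair (p, q) has exactly
    the given LCA vector.

    Two identical entries form a shared ancestor couple, an unpaired entry a
    single shared ancestor (a half link).  Connections are attached in
    ascending depth through chains of intermediate ancestors, each chain
    step mating with an unrelated founder; chain spouses provide attachment
    points for deeper connections.  Raises if the vector is unrealizable
    (cannot occur for vectors produced by LCA computation on a pedigree).
    """
    P = Pedigree()
    P.add(Individual("p", sex=MALE, generation=0, extant=True))
    P.add(Individual("q", sex=MALE, generation=0, extant=True))
    # open[side] = list of (depth, node_id) whose parents are unassigned
    open_nodes = {"p": [(0, "p")], "q": [(0, "q")]}
    counter = itertools.count()

    def new_id(prefix: str) -> str:
        return f"{prefix}{next(counter)}"

    def extend_to(side: str, depth: int) -> str:
        """Return a parentless node at ``depth`` on ``side``."""
        avail = [n for n in open_nodes[side] if n[0] <= depth]
        if not avail:
            raise ValueError("unrealizable LCA vector")
        d0, node = max(avail)
        open_nodes[side].remove((d0, node))
        while d0 < depth:
            chain = new_id(f"{side}a")
            spouse = new_id(f"{side}s")
            P.add(Individual(chain, sex=MALE, generation=d0 + 1))
            P.add(Individual(spouse, sex=FEMALE, generation=d0 + 1))
            P.set_parents(node, chain, spouse)
            open_nodes[side].append((d0 + 1, spouse))
            node, d0 = chain, d0 + 1
        return node

    # group entries: pairs of identical entries -> couples, leftovers -> singles
    counts: Dict[Tuple[int, int], int] = {}
    for e in entries:
        counts[tuple(e)] = counts.get(tuple(e), 0) + 1
    connections: List[Tuple[int, int, bool]] = []  # (d_p, d_q, is_couple)
    for (a, b), c in sorted(counts.items()):
        connections.extend([(a, b, True)] * (c // 2))
        if c % 2:
            connections.append((a, b, False))
    connections.sort()

    for a, b, couple in connections:
        cp = extend_to("p", a - 1)
        cq = extend_to("q", b - 1)
        if couple:
            fa, mo = new_id("cf"), new_id("cm")
            P.add(Individual(fa, sex=MALE, generation=a))
            P.add(Individual(mo, sex=FEMALE, generation=a))
            P.set_parents(cp, fa, mo)
            P.set_parents(cq, fa, mo)
        else:
            shared = new_id("h")
            P.add(Individual(shared, sex=MALE, generation=a))
            sp_p, sp_q = new_id("ps"), new_id("qs")
            P.add(Individual(sp_p, sex=FEMALE, generation=a))
            P.add(Individual(sp_q, sex=FEMALE, generation=a))
            P.set_parents(cp, shared, sp_p)
            P.set_parents(cq, shared, sp_q)
            open_nodes["p"].append((a, sp_p))
            open_nodes["q"].append((a, sp_q))
    return P, "p", "q"


def hypothesis_pedigree(founder_gen: int, relationship: str) -> Tuple[Pedigree, str, str]:
    """Minimal pedigree for an otherwise-unrelated candidate pair at
    ``founder_gen`` under a hypothesized relationship.

    Returns (pedigree, extant_leaf_u, extant_leaf_v).
    """
    return realize_lca_vector(hypothesis_extra_entries(founder_gen, relationship))


def build_hypothesis_pedigree(P: Pedigree, u: str, v: str, relationship: str) -> Pedigree:
    """Hypothesis ancestry added above founders ``u, v`` of a partial pedigree.

    Returns a copy of ``P`` extended with the hypothesized structure:
    full siblings share a new parent couple, half siblings one new parent
    (plus distinct co-parents), cousins two new shared grandparents through
    full-sibling linking parents, unrelated two disjoint new couples.
    """
    if relationship not in (UNRELATED, FULL_SIB, HALF_SIB, COUSIN):
        raise ValueError(f"unknown relationship {relationship!r}")
    for x in (u, v):
        if P.individuals[x].parent_ids():
            raise ValueError(f"{x} is not a founder")
    gen_u, gen_v = P[u].generation, P[v].generation
    if gen_u is None or gen_v is None or gen_u != gen_v:
        raise ValueError("hypothesis pairs must share a synchronized generation")
    out = P.copy()
    g = gen_u

    def add(i, sex, gen, fa=None, mo=None):
        out.add(Individual(i, sex=sex, generation=gen, father_id=fa, mother_id=mo))

    if relationship == FULL_SIB:
        add("hypF", MALE, g + 1)
        add("hypM", FEMALE, g + 1)
        out.set_parents(u, "hypF", "hypM")
        out.set_parents(v, "hypF", "hypM")
    elif relationship == HALF_SIB:
        add("hypS", MALE, g + 1)
        add("hypMu", FEMALE, g + 1)
        add("hypMv", FEMALE, g + 1)
        out.set_parents(u, "hypS", "hypMu")
        out.set_parents(v, "hypS", "hypMv")
    elif relationship == COUSIN:
        add("hypGF", MALE, g + 2)
        add("hypGM", FEMALE, g + 2)
        for side, x in (("u", u), ("v", v)):
            add(f"hypA{side}", MALE, g + 1, "hypGF", "hypGM")
            add(f"hypB{side}", FEMALE, g + 1)
            out.set_parents(x, f"hypA{side}", f"hypB{side}")
    else:
        for side, x in (("u", u), ("v", v)):
            add(f"hypA{side}", MALE, g + 1)
            add(f"hypB{side}", FEMALE, g + 1)
            out.set_parents(x, f"hypA{side}", f"hypB{side}")
    return out


# ---------------------------------------------------------------------------
# KDE over simulated features
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalDensity:
    """Gaussian-kernel-smoothed 2-D empirical density of IBD features.

    The kernel standard deviation on each axis is ``h * scale`` where
    ``scale`` is the sample standard deviation on that axis (floored for
    degenerate samples).  At a lone sample point the density equals the
    kernel normalization constant ``1 / (2 pi h1 h2)``.
    """

    samples: np.ndarray  # (n, 2)
    h: float
    scales: np.ndarray  # (2,)

    @classmethod
    def fit(cls, samples: np.ndarray, h: float, scale_floor: float = 1e-3) -> "EmpiricalDensity":
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 1:
            raise ValueError("need an (n, 2) sample array")
        scales = np.maximum(samples.std(axis=0), scale_floor)
        return cls(samples=samples, h=h, scales=scales)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Log density at points ``x`` of shape (m, 2) (or (2,))."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        bw = self.h * self.scales  # per-axis kernel std in raw units
        z = (x[:, None, :] - self.samples[None, :, :]) / bw[None, None, :]
        d2 = np.sum(z * z, axis=2)  # (m, n)
        log_norm = -np.log(2.0 * np.pi * bw[0] * bw[1])
        return logsumexp(-0.5 * d2, axis=1) - np.log(len(self.samples)) + log_norm

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))


class DistributionCache:
    """LCA-vector-keyed store of simulated feature densities.

    ``simulations`` counts distributions actually simulated; cache hits
    perform zero gene drops.
    """

    def __init__(self):
        self._store: Dict[str, EmpiricalDensity] = {}
        self.simulations: Dict[str, int] = {}
        self.hits = 0

    def get(self, key: str) -> Optional[EmpiricalDensity]:
        d = self._store.get(key)
        if d is not None:
            self.hits += 1
        return d

    def put(self, key: str, density: EmpiricalDensity) -> None:
        self._store[key] = density
        self.simulations[key] = self.simulations.get(key, 0) + 1

    def __contains__(self, key: str) -> bool:
        return key in self._store

    def __len__(self) -> int:
        return len(self._store)

    def save(self, path) -> None:
        """Persist the cached densities to a JSON key-value file."""
        import json

        payload = {k: {"samples": d.samples.tolist(), "h": d.h,
                       "scales": d.scales.tolist()}
                   for k, d in self._store.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DistributionCache":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        cache = cls()
        for k, d in payload.items():
            cache._store[k] = EmpiricalDensity(
                samples=np.asarray(d["samples"], dtype=float),
                h=float(d["h"]), scales=np.asarray(d["scales"], dtype=float))
        return cache


def _derived_seed(seed: int, key: str) -> int:
    digest = hashlib.sha256(f"{seed}|{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def simulate_feature_distribution(P_r: Pedigree, leaf_u: str, leaf_v: str, key: str,
                                  cfg: ScoringConfig, genome: GenomeModel,
                                  cache: Optional[DistributionCache] = None,
                                  ) -> EmpiricalDensity:
    """Simulate (or fetch) the IBD-feature density of a hypothesis pair.

    On a cache miss the pedigree is gene-dropped ``n_sim`` times and the
    pair's features recorded; the fitted KDE is stored under ``key``.  The
    RNG seed derives from (scoring seed, key), so cached and uncached runs
    score identically.
    """
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    rng = np.random.default_rng(_derived_seed(cfg.seed, key))
    feats = np.empty((cfg.n_sim, 2))
    for k in range(cfg.n_sim):
        haps = gene_drop(P_r, genome, rng)
        segs = extract_ibd(haps, leaf_u, leaf_v, genome, cfg.min_len_cm)
        f = ibd_features(segs)
        feats[k] = (f.n_segments, f.total_length_mbp)
    density = EmpiricalDensity.fit(feats, cfg.kde_h, cfg.scale_floor)
    if cache is not None:
        cache.put(key, density)
    return density


# ---------------------------------------------------------------------------
# Observed features
# ---------------------------------------------------------------------------


class ObservedFeatures:
    """Indexed view of observed extant-pair IBD features.

    ``features`` maps sorted extant-id pairs to :class:`IBDFeatures`; pairs
    absent from the map share nothing.
    """

    def __init__(self, extant_ids: Sequence[str],
                 features: Mapping[Tuple[str, str], IBDFeatures]):
        self.ids = list(extant_ids)
        self.index = {v: k for k, v in enumerate(self.ids)}
        rows = []
        for (a, b), f in features.items():
            if a not in self.index or b not in self.index:
                raise KeyError(f"feature pair ({a}, {b}) outside the extant set")
            if f.n_segments > 0:
                i, j = self.index[a], self.index[b]
                rows.append((min(i, j), max(i, j), f.n_segments, f.total_length_mbp))
        rows.sort()
        self.pair_i = np.array([r[0] for r in rows], dtype=np.int64)
        self.pair_j = np.array([r[1] for r in rows], dtype=np.int64)
        self.X = np.array([[r[2], r[3]] for r in rows], dtype=float).reshape(-1, 2)
        self._lookup = {(min(a, b), max(a, b)): (f.n_segments, f.total_length_mbp)
                        for (a, b), f in features.items() if f.n_segments > 0}

    def __len__(self) -> int:
        return len(self.ids)

    def n_pairs(self) -> int:
        return len(self.pair_i)

    def pair_features(self, a: str, b: str) -> Tuple[float, float]:
        key = tuple(sorted((a, b)))
        return self._lookup.get(key, (0, 0.0))


# ---------------------------------------------------------------------------
# Scorer
# ---------------------------------------------------------------------------


class RelationshipScorer:
    """Composite-likelihood relationship scorer with distribution caching."""

    def __init__(self, cfg: ScoringConfig, genome: GenomeModel,
                 cache: Optional[DistributionCache] = None):
        self.cfg = cfg
        self.genome = genome
        self.cache = cache if cache is not None else DistributionCache()

    # -- densities ------------------------------------------------------

    def density_for_entries(self, entries: LCAVector) -> EmpiricalDensity:
        key = canonical_lca_key(entries)
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        P_r, p, q = realize_lca_vector(entries)
        return simulate_feature_distribution(P_r, p, q, key, self.cfg,
                                             self.genome, self.cache)

    def density(self, founder_gen: int, relationship: str) -> EmpiricalDensity:
        """Feature density for an otherwise-unrelated pair at founder_gen."""
        return self.density_for_entries(hypothesis_extra_entries(founder_gen, relationship))

    def _floored_logpdf(self, density: EmpiricalDensity, X: np.ndarray) -> np.ndarray:
        return np.maximum(density.logpdf(X), np.log(self.cfg.density_floor))

    # -- single-pair scoring (reference path; used by tests, small runs) --

    def score_pair(self, P: Pedigree, u: str, v: str, obs: ObservedFeatures,
                   hypotheses: Tuple[str, ...] = COUPLE_HYPOTHESES,
                   desc_u: Optional[FrozenSet[str]] = None,
                   desc_v: Optional[FrozenSet[str]] = None,
                   ) -> Optional[Tuple[str, float]]:
        """Score one founder pair; return (positive relationship, weight)
        when the positive hypothesis strictly beats both alternatives.

        The composite log likelihood sums, over informative cross pairs of
        extant descendants, the log density of the observed features under
        the pair's conditioned LCA vector (reconstructed ancestry plus
        hypothesized link).
        """
        du = P.extant_descendants(u) if desc_u is None else desc_u
        dv = P.extant_descendants(v) if desc_v is None else desc_v
        if not du or not dv:
            raise ValueError("both candidates need at least one extant descendant")
        gen = P[u].generation
        if gen is None:
            raise ValueError("scoring requires synchronized generations")
        pairs = [(p, q) for p in sorted(du - dv) for q in sorted(dv - du)]
        logL = {r: 0.0 for r in hypotheses}
        for p, q in pairs:
            existing = P.lca_vector(p, q)
            x = np.array(obs.pair_features(p, q), dtype=float)
            for r in hypotheses:
                entries = merge_lca_entries(existing, hypothesis_extra_entries(gen, r))
                density = self.density_for_entries(entries)
                logL[r] += float(self._floored_logpdf(density, x)[0])
        positive = hypotheses[1]
        alts = [r for r in hypotheses if r != positive]
        best_alt = max(logL[r] for r in alts)
        if logL[positive] > best_alt:
            return positive, logL[positive] - best_alt
        return None

    # -- batch scoring over a partition (driver path) -------------------

    def _existing_vectors(self, P: Pedigree, obs: ObservedFeatures,
                          contrib: np.ndarray) -> List[Optional[LCAVector]]:
        """Conditioned (reconstructed-ancestry) LCA vector per nonzero pair."""
        ancd = {e: P.ancestor_distances(e) for e in obs.ids}
        ancself_memo: Dict[str, FrozenSet[str]] = {}

        def ancself(x: str) -> FrozenSet[str]:
            s = ancself_memo.get(x)
            if s is None:
                s = frozenset(P.ancestor_distances(x))
                ancself_memo[x] = s
            return s

        out: List[Optional[LCAVector]] = [None] * obs.n_pairs()
        for k in range(obs.n_pairs()):
            if not contrib[k]:
                continue
            di = ancd[obs.ids[obs.pair_i[k]]]
            dj = ancd[obs.ids[obs.pair_j[k]]]
            if len(dj) < len(di):
                di, dj = dj, di
            common = [c for c in di if c in dj]
            if not common:
                out[k] = ()
                continue
            if len(common) == 1:
                lcas = common
            else:
                lcas = [c for c in common
                        if not any(o != c and c in ancself(o) for o in common)]
            out[k] = tuple(sorted(tuple(sorted((di[c], dj[c]))) for c in lcas))
        return out

    def score_groups(self, P: Pedigree, desc_sets: Sequence[FrozenSet[str]],
                     founder_gen: int, obs: ObservedFeatures,
                     hypotheses: Tuple[str, ...] = COUPLE_HYPOTHESES,
                     ) -> List[Tuple[int, int, float]]:
        """Score all pairs of descendant sets at once.

        Equivalent to :meth:`score_pair` on a representative of every class
        pair, but vectorized: per-pair log densities are evaluated once per
        (hypothesis, conditioned key) and composite sums are assembled by
        sparse matrix algebra with inclusion-exclusion to drop uninformative
        (contained) cross pairs.  Returns (i, j, weight) with i < j for class
        pairs where the positive hypothesis wins.
        """
        n_cls = len(desc_sets)
        n_ext = len(obs.ids)
        if n_cls < 2 or obs.n_pairs() == 0:
            return []
        rows, cols = [], []
        classes_of: Dict[int, Set[int]] = {}
        for ci, dset in enumerate(desc_sets):
            for ind in dset:
                e = obs.index[ind]
                rows.append(ci)
                cols.append(e)
                classes_of.setdefault(e, set()).add(ci)
        M = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_cls, n_ext))
        Md = np.asarray(M.todense())

        # a nonzero pair is informative for some class pair iff each end has
        # a class the other end is outside of
        contrib = np.zeros(obs.n_pairs(), dtype=bool)
        for k in range(obs.n_pairs()):
            ci = classes_of.get(int(obs.pair_i[k]), set())
            cj = classes_of.get(int(obs.pair_j[k]), set())
            contrib[k] = bool(ci - cj) and bool(cj - ci)
        idx = np.nonzero(contrib)[0]
        existing = self._existing_vectors(P, obs, contrib)

        d = np.asarray(M.sum(axis=1)).ravel()
        overlap = (M @ M.T).toarray()
        n_pairs = np.maximum(d[:, None] - overlap, 0) * np.maximum(d[None, :] - overlap, 0)

        ii = obs.pair_i[idx]
        jj = obs.pair_j[idx]
        sym_i = np.concatenate([ii, jj])
        sym_j = np.concatenate([jj, ii])

        def bilinear(values: np.ndarray) -> np.ndarray:
            """Sum of per-pair values over informative cross pairs, for every
            class pair: T1 - T2 - T2' (+ overlap correction below)."""
            vals = np.concatenate([values, values])
            D = csr_matrix((vals, (sym_i, sym_j)), shape=(n_ext, n_ext))
            T1 = (M @ D @ M.T).toarray()
            B = (D @ M.T).toarray()  # (n_ext, n_cls)
            C = Md.T * B  # elementwise: membership of i in V times B[i, V]
            T2 = M @ C
            return T1 - T2 - T2.T

        def overlap_correction(values: np.ndarray, out: np.ndarray) -> None:
            """Add back pairs double-subtracted when both ends sit in the
            overlap of the two descendant sets."""
            pair_val: Dict[Tuple[int, int], float] = {}
            for k_local, k in enumerate(idx):
                pair_val[(int(obs.pair_i[k]), int(obs.pair_j[k]))] = float(values[k_local])
            cls_u, cls_v = np.nonzero(np.triu(overlap >= 2, k=1))
            for U, V in zip(cls_u.tolist(), cls_v.tolist()):
                shared = desc_sets[U] & desc_sets[V]
                members = sorted(obs.index[s] for s in shared)
                corr = 0.0
                for a_i in range(len(members)):
                    for b_i in range(a_i + 1, len(members)):
                        v = pair_val.get((members[a_i], members[b_i]))
                        if v is not None:
                            corr += 2.0 * v
                out[U, V] += corr
                out[V, U] += corr

        # interaction pattern: any informative nonzero cross pair at all
        ones = np.ones(len(idx))
        pattern = bilinear(ones)
        overlap_correction(ones, pattern)
        interacting = pattern > 0.5

        S: Dict[str, np.ndarray] = {}
        zero = np.zeros((1, 2))
        for r in hypotheses:
            extra = hypothesis_extra_entries(founder_gen, r)
            c0 = float(self._floored_logpdf(self.density_for_entries(extra), zero)[0])
            lf = np.empty(len(idx))
            by_key: Dict[LCAVector, List[int]] = {}
            for k_local, k in enumerate(idx):
                by_key.setdefault(merge_lca_entries(existing[k], extra), []).append(k_local)
            for entries, members in sorted(by_key.items()):
                density = self.density_for_entries(entries)
                lf[members] = self._floored_logpdf(density, obs.X[idx[members]])
            delta = lf - c0
            T = bilinear(delta)
            overlap_correction(delta, T)
            S[r] = n_pairs * c0 + T

        positive = hypotheses[1]
        alts = [r for r in hypotheses if r != positive]
        weight = S[positive] - np.max(np.stack([S[r] for r in alts]), axis=0)
        out = []
        a_idx, b_idx = np.nonzero(np.triu(interacting, k=1) & (weight > 0))
        for a, b in zip(a_idx.tolist(), b_idx.tolist()):
            out.append((a, b, float(weight[a, b])))
        return out
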