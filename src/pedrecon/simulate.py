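"""Forward population simulators.

Two generators produce ground-truth pedigrees with founder-labeled
haplotypes:

* :func:`simulate_wf` — a Wright-Fisher model with genders, optional
  polygamy, and geometrically interpolated dynamic population size over T
  synchronized generations.  Each child draws its mother's couple uniformly
  from the previous generation; with probability ``polygamy_prob`` the
  father is redrawn uniformly from all males, so a parent may have children
  with several mates.
* :func:`simulate_async` — an age-structured model running in 5-year
  iterations: individuals mature at 20, die at a capped-exponential age
  (mean 50, cap 90), join a pool of unmated mature singles, marry a
  uniformly drawn mate with a fixed success probability, and mated couples
  give birth with a probability steered in +/-0.2 steps toward a target
  population size.  Polygamy arises through remarriage after widowhood.

The default ``polygamy_prob`` is calibrated (scripts/calibrate_polygamy.py)
so that about one third of extant sibling pairs are half-siblings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from pedrecon.genome import GenomeModel, Haplotypes, gene_drop
from pedrecon.pedigree import FEMALE, MALE, Individual, Pedigree

#: Calibrated so ~33% of extant sibling pairs are half-siblings
#: (see scripts/calibrate_polygamy.py).
DEFAULT_POLYGAMY_PROB = 0.11


@dataclass(frozen=True)
class WFConfig:
    initial_size: int = 1000
    final_size: int = 1000
    generations: int = 5
    polygamy_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.initial_size < 2 or self.final_size < 2:
            raise ValueError("population sizes must be >= 2")
        if self.generations < 2:
            raise ValueError("need at least 2 generations")
        if not 0.0 <= self.polygamy_prob <= 1.0:
            raise ValueError("polygamy_prob must be in [0, 1]")


def wf_generation_sizes(cfg: WFConfig) -> List[int]:
    """Geometric interpolation from initial (oldest) to final (extant)."""
    T = cfg.generations
    ratio = cfg.final_size / cfg.initial_size
    return [int(round(cfg.initial_size * ratio ** (s / (T - 1)))) for s in range(T)]


def wf_pedigree(cfg: WFConfig, rng: Optional[np.random.Generator] = None) -> Pedigree:
    """Sample a Wright-Fisher pedigree (no haplotypes)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    T = cfg.generations
    sizes = wf_generation_sizes(cfg)
    P = Pedigree()
    prev_ids: List[str] = []
    prev_sexes: Dict[str, str] = {}
    for s, size in enumerate(sizes):
        gen = T - 1 - s  # oldest generation first; extant is generation 0
        ids = [f"g{gen}_{i}" for i in range(size)]
        sexes = {i: (MALE if rng.random() < 0.5 else FEMALE) for i in ids}
        if s == 0:
            for i in ids:
                P.add(Individual(i, sex=sexes[i], generation=gen, extant=(gen == 0)))
        else:
            males = [i for i in prev_ids if prev_sexes[i] == MALE]
            females = [i for i in prev_ids if prev_sexes[i] == FEMALE]
            if not males or not females:
                raise ValueError(f"generation {gen + 1} has zero males or females")
            # primary couples: random matching of females to males
            fperm = rng.permutation(len(females))
            mperm = rng.permutation(len(males))
            n_pairs = min(len(males), len(females))
            couples = [(males[mperm[k]], females[fperm[k]]) for k in range(n_pairs)]
            for i in ids:
                fa, mo = couples[int(rng.integers(n_pairs))]
                if cfg.polygamy_prob > 0 and rng.random() < cfg.polygamy_prob:
                    fa = males[int(rng.integers(len(males)))]
                P.add(Individual(i, sex=sexes[i], generation=gen,
                                 father_id=fa, mother_id=mo, extant=(gen == 0)))
        prev_ids, prev_sexes = ids, sexes
    return P


def simulate_wf(cfg: WFConfig, genome: GenomeModel) -> Tuple[Pedigree, Haplotypes]:
    """Sample a WF pedigree and gene-drop founder-labeled haplotypes."""
    rng = np.random.default_rng(cfg.seed)
    P = wf_pedigree(cfg, rng)
    haps = gene_drop(P, genome, rng)
    return P, haps


def halfsib_fraction(P: Pedigree) -> float:
    """Fraction of extant sibling pairs (>=1 shared parent) sharing exactly one.

    Returns NaN when the extant generation contains no sibling pairs.
    """
    extant = P.extant_ids()
    by_parent: Dict[str, List[str]] = {}
    for i in extant:
        for p in P.individuals[i].parent_ids():
            by_parent.setdefault(p, []).append(i)
    shared: Dict[Tuple[str, str], int] = {}
    for p, kids in by_parent.items():
        kids = sorted(kids)
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                shared[(kids[a], kids[b])] = shared.get((kids[a], kids[b]), 0) + 1
    if not shared:
        return float("nan")
    half = sum(1 for v in shared.values() if v == 1)
    return half / len(shared)


# ---------------------------------------------------------------------------
# Asynchronous, age-structured simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AsyncConfig:
    founder_count: int = 100
    target_size: int = 1000
    years: int = 200
    iteration_years: int = 5
    maturity_age: float = 20.0
    mean_death_age: float = 50.0
    death_age_cap: float = 90.0
    match_success_prob: float = 0.5
    birth_prob_init: float = 1.0
    birth_prob_step: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for p in (self.match_success_prob, self.birth_prob_init, self.birth_prob_step):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.founder_count < 2 or self.target_size < 2:
            raise ValueError("population sizes must be >= 2")


@dataclass
class AsyncPopulation:
    """An age-annotated pedigree produced by :func:`simulate_async`."""

    pedigree: Pedigree
    birth_year: Dict[str, float]
    death_year: Dict[str, float]
    final_year: float

    def alive_at_end(self) -> List[str]:
        return [i for i in self.pedigree.individuals
                if self.death_year[i] > self.final_year]

    def age_at_end(self, ind_id: str) -> float:
        return self.final_year - self.birth_year[ind_id]


def _draw_death_age(cfg: AsyncConfig, rng: np.random.Generator) -> float:
    return min(float(rng.exponential(cfg.mean_death_age)), cfg.death_age_cap)


def simulate_async(cfg: AsyncConfig, genome: Optional[GenomeModel] = None,
                   ) -> Tuple[AsyncPopulation, Optional[Haplotypes]]:
    """Run the age-structured simulator; optionally gene-drop haplotypes.

    Raises RuntimeError naming the year reached if the population dies out.
    """
    rng = np.random.default_rng(cfg.seed)
    P = Pedigree()
    birth_year: Dict[str, float] = {}
    death_year: Dict[str, float] = {}
    sex_of: Dict[str, str] = {}
    next_id = 0

    def new_individual(sex, year, mother=None, father=None) -> str:
        nonlocal next_id
        ind_id = f"a{next_id}"
        next_id += 1
        P.add(Individual(ind_id, sex=sex, mother_id=mother, father_id=father))
        birth_year[ind_id] = year
        death_year[ind_id] = year + _draw_death_age(cfg, rng)
        sex_of[ind_id] = sex
        return ind_id

    # founders: balanced sexes, ages spread over [0, 40) at year 0
    for k in range(cfg.founder_count):
        sex = MALE if k % 2 == 0 else FEMALE
        age = float(rng.uniform(0.0, 40.0))
        new_individual(sex, -age)

    couples: List[Tuple[str, str]] = []
    birth_prob = cfg.birth_prob_init
    year = 0.0
    while year < cfg.years:
        year += cfg.iteration_years
        alive = {i for i in P.individuals if death_year[i] > year}
        if not alive:
            raise RuntimeError(f"population extinct at year {year:g}")
        couples = [(a, b) for a, b in couples if a in alive and b in alive]
        mated = {i for c in couples for i in c}
        pool = [i for i in alive if i not in mated
                and year - birth_year[i] >= cfg.maturity_age]
        pool_m = [i for i in pool if sex_of[i] == MALE]
        pool_f = [i for i in pool if sex_of[i] == FEMALE]
        rng.shuffle(pool_m)
        rng.shuffle(pool_f)
        for m in pool_m:
            if not pool_f:
                break
            k = int(rng.integers(len(pool_f)))
            if rng.random() < cfg.match_success_prob:
                couples.append((m, pool_f.pop(k)))
        for fa, mo in list(couples):
            if rng.random() < birth_prob:
                sex = MALE if rng.random() < 0.5 else FEMALE
                new_individual(sex, year, mother=mo, father=fa)
        size = sum(1 for i in P.individuals if death_year[i] > year)
        if size < cfg.target_size:
            birth_prob = min(1.0, birth_prob + cfg.birth_prob_step)
        else:
            birth_prob = max(0.0, birth_prob - cfg.birth_prob_step)

    pop = AsyncPopulation(P, birth_year, death_year, float(cfg.years))
    haps = gene_drop(P, genome, rng) if genome is not None else None
    return pop, haps


def extant_stratum(pop: AsyncPopulation, age_range: Tuple[float, float] = (0.0, 20.0),
                   ) -> List[str]:
    """Select the observed age stratum and mark it extant.

    Returns the ids of individuals alive at the end of the run whose age
    falls inside ``age_range`` (closed), marking them ``extant`` in the
    population's pedigree (cross-generation relationships outside the
    stratum are thereby excluded from the observed set, while the full
    ancestry is retained as ground truth).
    """
    lo, hi = age_range
    if hi < lo:
        raise ValueError("invalid age range")
    chosen = [i for i in pop.alive_at_end() if lo <= pop.age_at_end(i) <= hi]
    if not chosen:
        raise ValueError("empty age stratum")
    for ind in pop.pedigree.individuals.values():
        ind.extant = False
    for i in chosen:
        pop.pedigree.individuals[i].extant = True
    return chosen
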