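"""Genome model, meiosis simulation, and IBD extraction.

Haplotypes are represented as founder-label mosaics: per chromosome, an
ordered list of half-open physical intervals (in Mbp), each carrying the
integer label of the founder haplotype it descends from.  Gene dropping
assigns two globally unique labels to every founder and recombines mosaics
down the pedigree; two individuals are IBD over an interval exactly where
any of their haplotypes carry the same founder label.

The default genome is a 22-autosome, GRCh37-like physical map (~2881 Mbp
total) with a uniform 1 cM/Mbp genetic map.  Crossovers are Poisson
(no interference), with positions uniform in physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from pedrecon.pedigree import Pedigree

# One haplotype mosaic on one chromosome: (segment end positions, labels).
# Segment k covers [ends[k-1], ends[k]) with ends[-1] == chromosome length.
Mosaic = Tuple[np.ndarray, np.ndarray]
# Per individual: list over chromosomes of the two parental mosaics.
Haplotypes = Dict[str, List[Tuple[Mosaic, Mosaic]]]


@dataclass(frozen=True)
class GenomeModel:
    """Physical and genetic chromosome lengths."""

    chromosomes: Tuple[Tuple[str, float, float], ...]  # (name, Mbp, Morgans)

    def __post_init__(self):
        for name, mbp, morgans in self.chromosomes:
            if mbp <= 0 or morgans < 0:
                raise ValueError(f"invalid lengths for chromosome {name}")

    @property
    def total_length_mbp(self) -> float:
        return sum(c[1] for c in self.chromosomes)

    def cm_per_mbp(self, idx: int) -> float:
        name, mbp, morgans = self.chromosomes[idx]
        return 100.0 * morgans / mbp


#: GRCh37-like autosome physical lengths in Mbp.
_GRCH37_MBP = (
    249.25, 243.20, 198.02, 191.15, 180.92, 171.12, 159.14, 146.36,
    141.21, 135.53, 135.01, 133.85, 115.17, 107.35, 102.53, 90.35,
    81.20, 78.08, 59.13, 63.03, 48.13, 51.30,
)


def default_genome() -> GenomeModel:
    """22 autosomes, GRCh37-like lengths, uniform 1 cM/Mbp map."""
    return GenomeModel(
        tuple((f"chr{i + 1}", mbp, mbp / 100.0) for i, mbp in enumerate(_GRCH37_MBP))
    )


def uniform_genome(n_chrom: int, mbp: float, cm_per_mbp: float = 1.0) -> GenomeModel:
    """Small equal-length test genome."""
    return GenomeModel(
        tuple((f"chr{i + 1}", mbp, mbp * cm_per_mbp / 100.0) for i in range(n_chrom))
    )


@dataclass(frozen=True)
class IBDSegment:
    chromosome: str
    start_mbp: float
    end_mbp: float

    def __post_init__(self):
        if self.end_mbp <= self.start_mbp:
            raise ValueError("IBD segment must have end > start")

    @property
    def length_mbp(self) -> float:
        return self.end_mbp - self.start_mbp


@dataclass(frozen=True)
class IBDFeatures:
    """The 2-D IBD feature: segment count and total shared length (Mbp)."""

    n_segments: int
    total_length_mbp: float

    def __post_init__(self):
        if (self.n_segments == 0) != (self.total_length_mbp == 0):
            raise ValueError("n_segments == 0 iff total_length == 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_segments, self.total_length_mbp], dtype=float)


@dataclass(frozen=True)
class SegmentNoise:
    """Optional detection-noise model for IBD segments.

    Segments are dropped with probability ``exp(-length_cM / drop_scale_cm)``
    (short segments are missed most often) and surviving boundaries are
    jittered by centred Gaussian noise.
    """

    drop_scale_cm: float = 4.0
    jitter_sd_mbp: float = 0.5


def meiosis(parent: Tuple[Mosaic, Mosaic], phys_len: float, gen_len: float,
            rng: np.random.Generator) -> Mosaic:
    """Produce one gamete mosaic for a single chromosome.

    Crossover count ~ Poisson(genetic length in Morgans); positions uniform
    in physical coordinates; the starting parental haplotype is chosen
    fairly and sources alternate at each crossover.
    """
    start = int(rng.integers(2))
    k = int(rng.poisson(gen_len))
    if k == 0:
        ends, labels = parent[start]
        return ends.copy(), labels.copy()
    cuts = np.sort(rng.uniform(0.0, phys_len, size=k))
    bounds = np.concatenate(([0.0], cuts, [phys_len]))
    out_ends: List[float] = []
    out_labels: List[int] = []
    s = start
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi > lo:
            ends, labels = parent[s]
            i = int(np.searchsorted(ends, lo, side="right"))
            pos = lo
            while pos < hi:
                e = min(float(ends[i]), hi)
                lab = int(labels[i])
                if out_labels and out_labels[-1] == lab:
                    out_ends[-1] = e
                else:
                    out_ends.append(e)
                    out_labels.append(lab)
                pos = e
                i += 1
        s ^= 1
    return np.asarray(out_ends), np.asarray(out_labels, dtype=np.int64)


def _founder_mosaics(genome: GenomeModel, label0: int) -> List[Tuple[Mosaic, Mosaic]]:
    out = []
    for name, mbp, _ in genome.chromosomes:
        h0 = (np.array([mbp]), np.array([label0], dtype=np.int64))
        h1 = (np.array([mbp]), np.array([label0 + 1], dtype=np.int64))
        out.append((h0, h1))
    return out


def _topological_order(P: Pedigree) -> List[str]:
    """Parents before children."""
    order: List[str] = []
    state: Dict[str, int] = {}
    for start in P.individuals:
        if state.get(start, 0) == 2:
            continue
        stack = [start]
        while stack:
            v = stack[-1]
            if state.get(v, 0) == 2:
                stack.pop()
                continue
            state[v] = 1
            pending = [p for p in P.individuals[v].parent_ids() if state.get(p, 0) != 2]
            if pending:
                stack.extend(pending)
            else:
                state[v] = 2
                order.append(v)
                stack.pop()
    return order


def gene_drop(P: Pedigree, genome: GenomeModel, rng: np.random.Generator) -> Haplotypes:
    """Simulate inheritance down the pedigree from uniquely labeled founders.

    Every founder receives two globally unique haplotype labels; every
    non-founder receives one meiosis-derived gamete from each parent.
    Individuals with exactly one recorded parent are rejected.
    """
    haps: Haplotypes = {}
    next_label = 0
    for ind_id in _topological_order(P):
        ind = P.individuals[ind_id]
        parents = ind.parent_ids()
        if len(parents) == 1:
            raise ValueError(f"{ind_id} has exactly one recorded parent; gene drop requires full couples")
        if not parents:
            haps[ind_id] = _founder_mosaics(genome, next_label)
            next_label += 2
            continue
        fa, mo = ind.father_id, ind.mother_id
        per_chrom = []
        for ci, (name, mbp, morgans) in enumerate(genome.chromosomes):
            g_pat = meiosis(haps[fa][ci], mbp, morgans, rng)
            g_mat = meiosis(haps[mo][ci], mbp, morgans, rng)
            per_chrom.append((g_pat, g_mat))
        haps[ind_id] = per_chrom
    return haps


def _match_mosaics(h1: Mosaic, h2: Mosaic) -> List[Tuple[float, float]]:
    """Intervals where two mosaics carry the same founder label."""
    ends1, lab1 = h1
    ends2, lab2 = h2
    i = j = 0
    pos = 0.0
    out: List[Tuple[float, float]] = []
    while i < len(ends1) and j < len(ends2):
        e = min(float(ends1[i]), float(ends2[j]))
        if lab1[i] == lab2[j] and e > pos:
            if out and out[-1][1] == pos:
                out[-1] = (out[-1][0], e)
            else:
                out.append((pos, e))
        pos = e
        if float(ends1[i]) <= e:
            i += 1
        if float(ends2[j]) <= e:
            j += 1
    return out


def _merge_intervals(intervals: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        mlo, mhi = merged[-1]
        if lo <= mhi:
            if hi > mhi:
                merged[-1] = (mlo, hi)
        else:
            merged.append((lo, hi))
    return merged


def extract_ibd(haps: Haplotypes, i: str, j: str, genome: GenomeModel,
                min_len_cm: float = 1.0) -> List[IBDSegment]:
    """Unphased IBD segments between two labeled individuals.

    Matches over all four haplotype pairings are merged into their union;
    segments shorter than ``min_len_cm`` are dropped.
    """
    if i == j:
        raise ValueError("IBD extraction requires two distinct individuals")
    segs: List[IBDSegment] = []
    for ci, (name, mbp, morgans) in enumerate(genome.chromosomes):
        matches: List[Tuple[float, float]] = []
        for hi in haps[i][ci]:
            for hj in haps[j][ci]:
                matches.extend(_match_mosaics(hi, hj))
        min_len_mbp = min_len_cm / genome.cm_per_mbp(ci) if morgans > 0 else 0.0
        for lo, hi_ in _merge_intervals(matches):
            if hi_ - lo >= min_len_mbp:
                segs.append(IBDSegment(name, lo, hi_))
    return segs


def ibd_features(segs: Iterable[IBDSegment]) -> IBDFeatures:
    """Collapse a segment list into the (count, total Mbp) feature."""
    n = 0
    total = 0.0
    for s in segs:
        n += 1
        total += s.length_mbp
    return IBDFeatures(n, total)


def _apply_noise(pair_segs, genome_idx_cm, noise: SegmentNoise, rng: np.random.Generator):
    """Drop/jitter segments in-place per the noise model."""
    out = []
    for chrom_idx, lo, hi in pair_segs:
        length_cm = (hi - lo) * genome_idx_cm[chrom_idx]
        if rng.random() < np.exp(-length_cm / noise.drop_scale_cm):
            continue
        lo2 = lo + rng.normal(0.0, noise.jitter_sd_mbp)
        hi2 = hi + rng.normal(0.0, noise.jitter_sd_mbp)
        if hi2 > lo2:
            out.append((chrom_idx, lo2, hi2))
    return out


def pairwise_ibd_segments(haps: Haplotypes, ids: Sequence[str], genome: GenomeModel,
                          min_len_cm: float = 1.0,
                          noise: Optional[SegmentNoise] = None,
                          rng: Optional[np.random.Generator] = None,
                          ) -> Dict[Tuple[str, str], List[IBDSegment]]:
    """IBD segments for every sharing pair among ``ids``.

    Uses an inverted index from founder labels to carrier intervals, so cost
    scales with actual sharing rather than with the number of pairs.  Pairs
    with no segment above the length threshold are absent from the result.
    Keys are sorted id pairs.
    """
    idset = list(ids)
    per_pair: Dict[Tuple[str, str], List[Tuple[int, float, float]]] = {}
    for ci, (name, mbp, morgans) in enumerate(genome.chromosomes):
        by_label: Dict[int, List[Tuple[float, float, str]]] = {}
        for ind in idset:
            for ends, labels in haps[ind][ci]:
                pos = 0.0
                for e, lab in zip(ends, labels):
                    by_label.setdefault(int(lab), []).append((pos, float(e), ind))
                    pos = float(e)
        for lab, carriers in by_label.items():
            if len(carriers) < 2:
                continue
            carriers.sort()
            for a in range(len(carriers)):
                lo_a, hi_a, id_a = carriers[a]
                for b in range(a + 1, len(carriers)):
                    lo_b, hi_b, id_b = carriers[b]
                    if lo_b >= hi_a:
                        break
                    if id_a == id_b:
                        continue
                    lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
                    if hi > lo:
                        key = (id_a, id_b) if id_a < id_b else (id_b, id_a)
                        per_pair.setdefault(key, []).append((ci, lo, hi))
    cm_rates = [genome.cm_per_mbp(ci) if genome.chromosomes[ci][2] > 0 else 0.0
                for ci in range(len(genome.chromosomes))]
    out: Dict[Tuple[str, str], List[IBDSegment]] = {}
    for key, raw in per_pair.items():
        if noise is not None:
            if rng is None:
                raise ValueError("noise model requires an rng")
            raw = _apply_noise(raw, cm_rates, noise, rng)
        by_chrom: Dict[int, List[Tuple[float, float]]] = {}
        for ci, lo, hi in raw:
            by_chrom.setdefault(ci, []).append((lo, hi))
        segs: List[IBDSegment] = []
        for ci, intervals in sorted(by_chrom.items()):
            min_len_mbp = min_len_cm / cm_rates[ci] if cm_rates[ci] > 0 else 0.0
            for lo, hi in _merge_intervals(intervals):
                if hi - lo >= min_len_mbp:
                    segs.append(IBDSegment(genome.chromosomes[ci][0], lo, hi))
        if segs:
            out[key] = segs
    return out


def pairwise_ibd_features(haps: Haplotypes, ids: Sequence[str], genome: GenomeModel,
                          min_len_cm: float = 1.0,
                          noise: Optional[SegmentNoise] = None,
                          rng: Optional[np.random.Generator] = None,
                          ) -> Dict[Tuple[str, str], IBDFeatures]:
    """IBD features for every sharing pair among ``ids`` (sorted-pair keys).

    Pairs absent from the map share nothing, i.e. have feature (0, 0).
    """
    segs = pairwise_ibd_segments(haps, ids, genome, min_len_cm, noise, rng)
    return {k: ibd_features(v) for k, v in segs.items()}
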