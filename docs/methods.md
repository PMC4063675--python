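# Methods

`pedrecon` reconstructs the historical pedigree of a set of *extant*
(observed, contemporaneous) individuals from their pairwise
identity-by-descent (IBD) sharing alone.  All ancestors are unobserved;
the method infers them generation by generation, going back in time.

## Problem setting and model assumptions

The population model is synchronized-generation: every observed individual
belongs to generation 0, its parents to generation 1, and so on.  Evidence
consists of one 2-D feature per extant pair — the number of IBD segments
and their total length in Mbp.  A pair absent from the input shares
nothing.  Inheritance is modeled as Poisson recombination (no crossover
interference) on a fixed genome: 22 autosomes with GRCh37-like physical
lengths (2881 Mbp total) and a uniform 1 cM/Mbp genetic map.  Mutation,
genotyping error and phasing are outside the model; an optional
segment-noise model (exponential-in-length segment dropping plus Gaussian
boundary jitter) emulates IBD-detection error when desired.

## The reconstruction loop

Each iteration `t` takes the partial pedigree (extant individuals plus
`t - 1` reconstructed ancestor generations) and adds generation `t`:

1. **Contraction.**  Current founders with *identical* extant-descendant
   sets are indistinguishable from descendant evidence (the two members of
   a monogamous couple are the canonical case) and are contracted into one
   super-vertex.
2. **Couple-level scoring.**  Every super-vertex pair is scored for full
   sibship against alternatives (unrelated, first cousins; in polygamous
   mode also half siblings — see below).  A super-edge is added when the
   sib hypothesis strictly wins; its weight is the composite
   log-likelihood ratio.
3. **Edge assignment.**  Each super-edge must be mapped to one
   individual-level sibling edge such that the assigned edges form
   vertex-disjoint cliques (full sibship is an equivalence relation).
   Maximum-weight assignment is NP-hard; a greedy traversal in decreasing
   weight order is used.  For the edge under consideration, every
   candidate pair of members is evaluated by merging the members' current
   cliques (a free individual is a singleton clique); a merge is legal
   only if *every* implied cross pair is supported by a distinct, existing,
   still-unassigned super-edge.  The candidate yielding the largest clique
   wins (parsimony: fewer parents), ties break lexicographically, and all
   implied super-edges are assigned in the same step.  Unassignable edges
   are dropped — the cover maximizes weight, not coverage.
4. **Parent creation.**  Every sibling group (cliques plus leftover
   singletons) receives a fresh parent couple.
5. **Half-sibling detection (polygamous mode).**  Full-sib groups are the
   vertices of a polygamy graph whose weighted edges carry half-sib
   evidence from a group-level test (unrelated / half sib / cousin).
   Because all children of one parent form a clique, and each group has
   two parent slots, the true structure is a two-coloring of edges where
   each color class is a union of vertex-disjoint cliques.  The greedy
   cover repeatedly colors the heaviest clique *adjacent to the
   already-colored region* (its color forced by the vertices it touches),
   falling back to the globally heaviest clique when no adjacent clique of
   two or more vertices is colorable; this propagates constraints outward
   and colors chains of cliques optimally, unlike a heaviest-first order.
   Before coloring, parsimony rules remove edges explained by
   already-reconstructed matings: two descendant-contained mates of one
   individual (R1; the same containment logic is applied to full-sib
   super-edges as R2), descendant-contained mates of two full siblings
   (R3), and any residual half-sib edge between mates of full siblings
   (R4).  Finally, one parent slot per colored clique is merged into a
   single shared parent (color 1 = father slot, color 2 = mother slot;
   parental sex is unidentifiable from autosomes, so the labels are pure
   convention).

## Relationship scoring

For a hypothesized relationship between two founders (or groups) at
generation `g`, every extant cross pair `(p, q)` of their descendant sets
is characterized by its **LCA vector** — the multiset of meiosis-distance
pairs `(d_p, d_q)` to its least common ancestors in the *hypothesis
pedigree*, i.e. the partial pedigree plus the hypothesized link (shared
parent couple for sibs at `(g+1, g+1)` twice; one shared parent for half
sibs; two shared grandparents through full-sib linking parents for
cousins; nothing for unrelated).  Conditioning on reconstructed ancestry
is essential: sharing already explained by an earlier generation (e.g.
between the two in-law couples of one family) must not be read as fresh
sibling evidence.

Cross pairs contained in either candidate's descendant set are excluded
from every hypothesis: for such a pair the candidate itself is a common
ancestor, so the hypothesized ancestors are not *least* common ancestors,
the pair's density is hypothesis-independent, and it cancels from the
likelihood ratio.

For each distinct LCA vector, a minimal pedigree realizing it is
constructed (paired entries become shared couples, unpaired entries single
shared ancestors, attached through chains whose spouses provide deeper
attachment points) and gene-dropped `n_sim = 50` times; the pair's
features are recorded each time.  Fifty draws suffice — relationship
calls are stable against a 500-draw reference on fixtures.  The sampled
cloud is smoothed by a Gaussian product kernel: features are scaled to
unit variance per axis (scales floored at 1e-3 for degenerate samples,
e.g. the all-zero unrelated cloud) and the kernel standard deviation is
`kde_h = 2` on the scaled axes.  Larger bandwidths (h = 4 and above)
over-smooth: the normalization constant of a tighter alternative density
then dominates the exponential term, and deep sib edges are lost to the
cousin hypothesis.  Densities are cached under the canonical vector key;
per-key RNG seeds are derived from the scoring seed and the key, so
results are bit-identical whether or not the cache is warm, and one cache
serves all generations and replicate runs.

The composite log likelihood of hypothesis `r` is the sum of per-pair log
densities (floored at 1e-300 to avoid zero-collapse of long products) over
informative cross pairs.  An edge is added only when the positive
hypothesis strictly beats every alternative, with weight
`log L_pos − log max_alt L_alt` — positive exactly when the positive
hypothesis wins.  In the batch path the per-pair log densities are
evaluated once per (hypothesis, key) and composite sums for all class
pairs are assembled by sparse matrix algebra with an inclusion–exclusion
correction implementing the containment rule; zero-sharing pairs enter
through a count-times-baseline term using the unconditioned key (pairs
with reconstructed common ancestors essentially never share zero, so the
approximation is negligible).

In polygamous mode the couple-level test carries half sibship as a fourth,
*alternative* hypothesis: half-sib features lie between the full-sib and
cousin clouds, and without this alternative nearly every half-sib pair is
absorbed into a full-sib clique, which the later group-level stage cannot
undo.

## Simulators

**Wright–Fisher with genders, polygamy and dynamic size.**  Generation
sizes interpolate geometrically from an initial (oldest) to a final
(extant) size.  The parent generation is paired into random primary
couples; each child picks a couple uniformly, and with probability
`polygamy_prob` its father is redrawn uniformly from all males.  The
default `polygamy_prob = 0.11` was calibrated once by sweep
(`scripts/calibrate_polygamy.py`) so that about one third of extant
sibling pairs are half siblings; it was not revisited afterwards.
Founder haplotypes receive globally unique labels and are gene-dropped;
true IBD is read off the label mosaics (an inverted label index makes
all-pairs extraction scale with actual sharing, not with the number of
pairs).

**Age-structured asynchronous simulator.**  Time advances in 5-year
iterations.  Individuals mature at 20, die at a capped-exponential age
(mean 50, cap 90 — the cap is ours; the model needs boundedness), and
join a pool of unmated mature singles.  Pool members marry a uniformly
drawn mate with success probability 0.5 (a neutral default; the value is
configurable).  Each couple
has a child per iteration with probability `p_birth`, steered by ±0.2
toward a target population size.  Widowed individuals rejoin the pool, so
polygamy arises through remarriage.  Observation uses an age stratum
(default ages 0–20) to exclude cross-generation relationships, which the
synchronized reconstruction model does not represent.

What the generators do *not* emulate: linkage-map heterogeneity, crossover
interference, genotyping and phasing error, IBD-detection noise (unless
the segment-noise model is switched on), mutation, migration and
selection.  Passing tests therefore demonstrate correctness of the
method's logic under its own inheritance model, not robustness to
real-data IBD callers.

## Evaluation

Reconstruction quality is measured on extant pairs via minimal meiosis
distances: **sensitivity** (fraction of truly related pairs whose distance
is reproduced exactly), **PPV** (fraction of reconstructed related pairs
that are correct), **consensus accuracy** (fraction of all pairs with
matching distance, infinity included — dominated by unrelated pairs and
kept only for comparability), and **RMSE-IBD** (root-mean-square
difference, in Mbp, between observed and pedigree-simulated total IBD per
pair, averaged over 5 gene drops).  Truncation to depth `k` (extant plus
`k − 1` ancestor levels) localizes the scores per generation.  Scores
with empty denominators are `None`/null, never 0: an all-unrelated
reconstruction has zero sensitivity but *undefined* PPV, and a high
consensus accuracy — the pathology that motivates the sensitivity/PPV
pair.  Half-sibling sensitivity/PPV compare pairs sharing exactly one
parent.

## Numerical and design choices

* Coordinates are physical Mbp, 0-based half-open, everywhere; cM appear
  only at I/O boundaries and in the minimum segment length
  (`min_len_cm = 1` by default).
* Unphased IBD: matches over all four haplotype pairings are merged into
  their union.  Under this convention full siblings share 3/4 of the
  genome in expectation (some sharing on at least one haplotype), not the
  phased 1/2 — the closed form the tests check.
* LCA vectors canonicalize each entry as (min, max) and sort entries; with
  inbreeding an ancestor reachable along multiple path lengths contributes
  its minimal meioses per side, one entry per distinct LCA individual.
* Tie-breaks everywhere are lexicographic on (class id, individual id) for
  bit-reproducibility; equal seeds give byte-identical CLI outputs.
* Heaviest-clique search enumerates maximal cliques of the remaining
  graph (positive weights make the heaviest clique maximal), capped at 12
  vertices; polygamy graphs at any generation are group-level and small.
* Degenerate inputs: founders with no extant descendants carry no
  evidence and are excluded from contraction with a warning; empty
  feature maps reconstruct everyone as unrelated; an empty extant set is
  an error.

## Problem sizes used in validation

The acceptance experiments run at the study scales — constant-size 1000
(monogamous and polygamous), size 200–300 polygamous for the coloring
comparison, and 100 → 500 expansion — with 2–3 replicates each; these
full-scale experiments complete in a few minutes in total because
scoring is vectorized over class pairs and the distribution cache is
shared across replicates.  Unit tests use a 4 × 100 Mbp toy genome.

## Known limitations

* Inbred structures: the hypothesis sets contain no inbreeding options,
  and composite likelihoods double-count overlapping-descent evidence in
  heavily inbred class pairs.
* The distribution cache keys on the LCA vector only; pairs with equal
  vectors but different full ancestry structure share a distribution (an
  approximation the original efficiency argument also makes).
* Deep generations (5 and beyond) lose most of their signal: distributions
  of distant relationships overlap strongly, which no amount of smoothing
  can undo.
* Maternal/paternal labels on reconstructed ancestors are arbitrary;
  autosomal data cannot identify parental sex.
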