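# pedrecon

Reconstruction of multi-generation historical pedigrees — including
polygamous matings — from identity-by-descent (IBD) sharing among the
*extant* individuals of a population.  All ancestors are unobserved: the
package infers them generation by generation from the pairwise IBD
features (segment count, total shared length in Mbp) of the observed
generation alone.  It is aimed at population and statistical geneticists
studying relatedness in isolated or founder populations, and ships with
the forward simulators and quality metrics used to validate it.

## The method in brief

Going one generation back at a time, the current founders are first
*contracted*: founders with identical extant-descendant sets (such as the
two members of a monogamous couple) are indistinguishable from descendant
evidence and become one super-vertex.  For every super-vertex pair, the
observed IBD features of their descendant cross pairs are compared —
via a composite likelihood

&nbsp;&nbsp;&nbsp;&nbsp;L<sub>r</sub> = ∏<sub>(p,q)</sub> f̂<sub>r</sub>(x<sub>pq</sub>)

— against Gaussian-kernel-smoothed feature distributions simulated by
gene dropping under each hypothesized relationship r ∈ {unrelated, full
sib, cousin} (plus half sib in polygamous mode).  Each descendant pair is
conditioned on its vector of meiosis distances to its least common
ancestors in the hypothesis pedigree, and simulated distributions are
cached by that vector, so inheritance is simulated only when a new
ancestry configuration appears.  Winning full-sib super-edges, weighted
by log L<sub>sib</sub> − log max(L<sub>alt</sub>), are then assigned to
individual sibling edges under the constraint that assigned edges form
vertex-disjoint cliques — full sibship is transitive — by a greedy
maximum-weight disjoint-clique-cover heuristic (the exact problem is
NP-hard).  Every sibling group receives a fresh parent couple.  In
polygamous mode, a second pass detects groups sharing a *single* parent:
half-sib evidence between full-sib groups forms a polygamy graph whose
edges are two-colored into vertex-disjoint cliques (one color per
parental slot), preferring cliques adjacent to the already-colored
region, after parsimony rules strip edges already explained by
reconstructed matings.

Quality is scored on extant pairs by minimal meiosis distance:
sensitivity (true related pairs reconstructed at the exact distance), PPV
(reconstructed related pairs that are correct), consensus accuracy, and
the RMSE (Mbp) between observed and pedigree-simulated total IBD length.
See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from pedrecon import (WFConfig, simulate_wf, default_genome, pairwise_ibd_features,
                      RunConfig, reconstruct, sensitivity_ppv)
from pedrecon.scoring import ScoringConfig

genome = default_genome()          # 22 autosomes, 2881 Mbp, 1 cM/Mbp
truth, haplotypes = simulate_wf(
    WFConfig(initial_size=200, final_size=200, generations=4, seed=7), genome)
extant = truth.extant_ids()
observed = pairwise_ibd_features(haplotypes, extant, genome)
recon = reconstruct(extant, observed,
                    RunConfig(mode="monogamous", generations=4,
                              scoring=ScoringConfig(seed=7)), genome)
for k in (2, 3, 4):
    sens, ppv = sensitivity_ppv(recon, truth, k=k)
    print(f"depth {k}: sensitivity={sens:.3f}  ppv={ppv:.3f}")
```

prints

```
depth 2: sensitivity=1.000  ppv=1.000
depth 3: sensitivity=0.999  ppv=0.985
depth 4: sensitivity=0.846  ppv=0.889
```

i.e. in a 200-individual Wright–Fisher population every sibling pair is
recovered exactly (depth 2), 99.9% of pairs are still placed at their
correct minimal meiosis distance when grandparents are added (depth 3),
and 84.6% when great-grandparents are added (depth 4), with 88.9% of the
depth-4 reconstructed relationships being correct.

The same pipeline is available from the shell:

```sh
pedrecon simulate --model wf --initial-size 200 --final-size 200 \
    --generations 4 --seed 7 --out-prefix sim
pedrecon reconstruct --ibd sim.match.tsv --samples sim.samples.txt \
    --generations 4 --seed 7 --out-prefix run
pedrecon evaluate --truth sim.ped.tsv --recon run.recon.ped.tsv \
    --ibd sim.match.tsv --max-generations 4
```

IBD input is a tab-separated GERMLINE-style match file
(`id1 id2 chrom start_mbp end_mbp length_cm`); pedigrees are PLINK
.fam-style TSV.

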