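# synergynet

Phenotype-specific gene-cooperation networks from information synergy.

## The problem

Single-gene screens find genes whose expression individually tracks a
phenotype. They are blind to *cooperating* pairs: two genes whose joint
expression separates phenotype classes while each marginal distribution
looks uninformative — for example a pair whose *difference* G1 − G2 is
discriminative (a "gap" configuration), whose *sum* is (a "substitute"),
or whose joint silent/active state is (an "on/off" pair). This package
implements a pipeline for reconstructing such cooperation networks from
a phenotype-labelled expression matrix — the motivating setting is
hepatocyte cultures under free-fatty-acid treatments (BSA control,
palmitate, oleate), where palmitate-treated samples carry a cytotoxic
phenotype — together with the downstream pathway analyses and a
differential-correlation baseline for comparison.

## The statistic

For genes G1, G2 and a binary phenotype P, the information synergy is

    Syn(G1, G2; P) = I(G1, G2; P) − I(G1; P) − I(G2; P)

where I(·;P) is mutual information between discretized expression states
and the phenotype, normalized by the phenotype entropy H(P) so that
every term lies in [0, 1] and Syn in [−1, 1]. Positive synergy means the
pair jointly carries more phenotype information than its parts
(cooperation); negative synergy means redundancy. Marginal states come
from an exact minimum-variance 1-D partition (3 states by default);
joint states from seeded k-means on the standardized pair (9 clusters),
or a 3×3 grid variant. Significance is assessed by permuting phenotype
labels (the same permutations for every pair) and Benjamini–Hochberg
control across pairs; edges of the cooperation network are the
significant positive-synergy pairs.

The surrounding pipeline: metabolite-trend-guided gene selection
(strict per-condition mean orderings + pairwise Welch t-tests),
hypergeometric pathway enrichment over the network genes, a
hypergeometric pathway–neighbor association test for network genes
connected to ≥ 3 pathway members, a degree-distribution contrast with an
Erdős–Rényi graph, and a Fisher-z differential-correlation baseline.
A seeded synthetic-data generator plants all three cooperative
configurations, metabolite trends, redundant genes and pathway
annotations, so every stage is testable without external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort (40 genes × 60 samples; a planted pathway whose hub
gene cooperates with three members, two further planted gap pairs,
redundant genes, and a trend-structured background):

```sh
python analysis/01_simulate.py        # write the cohort fixture
python analysis/02_select_genes.py    # trend matching + DE filter
python analysis/03_synergy_network.py # synergy scan -> network
python analysis/04_topology.py        # degree law vs Erdos-Renyi
python analysis/05_pathway_enrichment.py
python analysis/06_neighbor_association.py
python analysis/07_diffcorr_comparison.py
```

Output of the chain (seed 0):

```
kept 32 / 40 genes; by trend: {'I': 11, 'II': 10, 'III': 6, 'IV': 5}
tested 496 pairs -> network of 8 genes, 5 edges; patterns: {'gap': 5}
PLANTED: 5/6 in network, p=0.00151, p_adj=0.00303 [significant]
PLANTED neighbor G0015: 3/5 pathway links at degree 3, p=0.179, rank 1
  method  edges  planted_recovered  planted_total
 synergy      5                  5              5
diffcorr     46                  0              5
```

Reading this: selection keeps the 32 genes with condition structure; the
synergy scan recovers exactly the five planted cooperative pairs (all
gap-configured) and nothing else; the planted pathway is the only
enriched gene set; the planted hub is the top-ranked (and only) neighbor
connected to ≥ 3 pathway genes. The differential-correlation baseline
misses all five planted pairs — they leave within-class correlations
untouched — while flagging 46 pairs of trend genes whose correlation
differs between classes only because the nontoxic class mixes two
treatment conditions.

The same pipeline runs from a shell via the `synergynet` command
(subcommands `simulate`, `select`, `synergy`, `network`, `enrich`,
`associate`, `diffcorr`, `run`), or in one call as
`synergynet run --config config.yaml`.

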