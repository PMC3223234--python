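# Methods

## Model and score

The pipeline treats a phenotype-labelled expression matrix (genes ×
samples, log2 scale) as draws from a joint distribution of per-gene
expression and a binary phenotype P. For a gene pair (G1, G2) the
information synergy

    Syn(G1, G2; P) = I(G1, G2; P) − I(G1; P) − I(G2; P)

is estimated by plug-in mutual information over discretized expression
states, with every MI divided by the phenotype entropy H(P). For binary
P this normalization is what makes the advertised [−1, 1] synergy scale
tight: each normalized MI lies in [0, 1], a perfectly informative pair
has I12 = 1, and a duplicated perfectly-informative gene attains
Syn = −1. Positive synergy = cooperation, negative = redundancy, zero =
unrelated contributions.

## Discretization

* **Marginal (1-D) states.** Exact minimum within-cluster-variance
  partition of the gene's values into at most `n_states` (default 3)
  contiguous bins, found by dynamic programming over the sorted values.
  Deterministic, scale- and order-invariant; constant genes collapse to
  one state.
* **Joint (2-D) states, `cluster` method (default).** k-means with
  `n_states**2` = 9 clusters on the per-gene standardized pair, 10
  seeded random restarts, best inertia wins. A batched Lloyd
  implementation clusters every pair of a scan in a few vectorised numpy
  passes; the restart draws depend on the scan's seed and batch
  composition, so scans are reproducible given (data, pair set, seed).
* **Joint states, `grid` method.** The product of the two marginal
  partitions (≤ 9 cells). Fully deterministic; exposed via
  configuration and used where an RNG-free discretization is preferable.
* **Degenerate pairs.** If the two vectors are exactly collinear
  (|r| = 1, e.g. duplicated genes) the joint support is one-dimensional
  and is partitioned at *marginal* resolution (`n_states` bins along the
  principal axis). This yields I12 = I1 = I2 and Syn = −I1 exactly for
  duplicates; a 9-cluster partition of a line would instead inflate I12
  by finite-sample bias and could push a duplicated noise gene to
  spuriously positive synergy.

## Finite-sample bias

Plug-in MI is biased upward by roughly (K−1)(L−1)/(2N ln 2) bits for K
states and L classes, so under the null E[Syn] ≈ bias(9 states) − 2 ×
bias(3 states) ≈ +0.06 at N = 60 samples. The permutation test is built
on discretizations that are fixed before labels are permuted, so the
null distribution carries exactly the same bias and the test is
calibrated despite it (measured null rate of p < 0.05: 0.056 across
1000 null pairs). Raw synergy values should therefore be read relative
to their permutation null, not against literal zero.

## Permutation significance

Phenotype labels are permuted B times (default 1000; the recovery and
calibration suites use 200), with the *same* permutations applied to
every pair, and each pair's synergy recomputed from its fixed states.
Two p-value modes:

* `pooled` (default): the null scores of all P pairs are pooled;
  p = (1 + #{pooled ≥ observed}) / (P·B + 1). Pairs are exchangeable
  under the global null because the discretization adapts per pair, and
  pooling gives resolution 1/(P·B+1) ≈ 4·10⁻⁶ at P = 1225, B = 200.
  This matters because BH at level α over P pairs can only ever reject
  when some p ≤ α·k/P: with per-pair granularity 1/(B+1), B must exceed
  P/(α·k) before *any* discovery is possible — at hundreds of
  permutations and ≥ 10³ pairs the per-pair test is structurally unable
  to reject, while the pooled null retains the documented behaviour of
  a shared-permutation design.
* `per_pair`: the classic smoothed empirical tail
  p = (1 + #{b: syn_b ≥ syn_obs}) / (B + 1), with ties counted
  conservatively. Used for calibration checks and available throughout.

BH (Benjamini–Hochberg step-up, via statsmodels) is applied once across
all tested pairs; network edges are pairs with Syn > 0 and adjusted
p < α (default 0.05). Negative-synergy pairs are redundancy, not
cooperation, and never become edges.

## Pattern taxonomy

Significant pairs are classified on per-gene z-scores by comparing
phenotype separation (absolute Welch t) along three axes: difference
(z1 − z2)/√2, sum (z1 + z2)/√2, and radius √(z1² + z2²). A dominant
radial separation is called **on/off** (silent vs dispersed joint
state). Otherwise **gap** requires r ≥ 0, a dominant difference axis and
Welch p < 0.05 on it; **substitute** requires r < 0 and a dominant,
discriminating sum axis; anything else is on/off. The p < 0.05 guard
exists because for genuine on/off pairs both linear-axis t statistics
are near zero and their ordering is a coin flip; the guard leaves
gap/substitute calls (dominant-axis |t| ≈ 20 at the reference
conditions) untouched. Agreement with generator truth: 40/40 per
pattern over 40 seeds.

## Gene selection

Genes are first log2-transformed (when requested) and probe-averaged.
Selection keeps a gene iff (i) its per-condition mean expression follows
one of four strict orderings across BSA/palmitate/oleate — palmitate
peak (I), palmitate trough (II), monotone increase (III), monotone
decrease (IV) — and (ii) at least one of the three pairwise Welch
t-tests between conditions has p < α (default 0.05). Welch rather than
pooled-variance t because expression variance is rarely equal across
treatment groups; strict inequalities on arithmetic means of log2
values, ties match nothing. An optional caller-supplied blacklist
handles annotation-dependent removals (e.g. ESTs).

## Pathway statistics

Both pathway tests use the upper hypergeometric tail
Σ_{i≥x} C(n,i)·C(N−n,k−i)/C(N,k) (scipy, log-space). Enrichment:
N = background universe (default: the selected genes entering the
synergy scan — the universe actually at risk of appearing in the
network; configurable), n = pathway ∩ background, k = network genes,
x = pathway ∩ network; BH across pathways. Association: for each
enriched pathway, tested neighbors are non-pathway network genes
adjacent to ≥ 3 pathway members (the threshold is exposed);
N = network size, n = pathway genes in the network, k = neighbor
degree, x = adjacent pathway genes; BH per pathway across its tested
neighbors; deterministic (p_adj, p, gene-id) ranking.

## Differential-correlation baseline

Within-phenotype Pearson correlations (Spearman optional) compared by
Fisher z: z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided
normal p, BH across all pairs. Correlations are clipped to 1 − 10⁻¹⁵
before atanh and p-values floored at the smallest positive double so
reports never contain 0 or ±∞. The baseline sees only second-moment
differences between classes; planted cooperative pairs shift the joint
phenotype geometry while preserving within-class correlations, so the
synergy route recovers them and the baseline cannot — the package's
head-to-head property. Conversely, on cohorts whose "nontoxic" class
mixes two treatment conditions, shared condition structure induces
genuine within-class correlation differences that the baseline flags
and the synergy scan ignores; both behaviours are visible in the
analysis scripts.

## Synthetic cohorts

The generator emulates the assumed study design: three treatment
conditions (BSA control, palmitate, oleate), palmitate samples toxic,
the nontoxic samples split between BSA and oleate; per-gene baselines
uniform on 6–10 log2 units; measurement noise N(0, 0.3²) log2 units; 30
samples per phenotype by default. Planted structure:

* **gap**: shared latent C ~ N(0, σc²); G1 = C + sδ/2 + ε,
  G2 = C − sδ/2 + ε′ with s = ±1 the phenotype sign. Defaults δ = 2,
  σc² = δ² = 4, chosen so each marginal's class shift is ≈ 1
  within-class SD — marginals near-uninformative, difference axis
  decisive, which is the defining geometry of a cooperative pair.
* **substitute**: G2 = −C + sδ/2 + ε′ (negative correlation, phenotype
  on the sum axis).
* **on/off**: nontoxic samples ~ N(0, 0.1·I) around the joint baseline,
  toxic samples uniform on an annulus of radius 2–3.
* **redundant genes**: a marginal mean shift δ between phenotypes.
* **trends**: per-condition mean offsets (1 log2 unit by default)
  realising the four orderings.
* **pathways**: named member sets; a pathway may designate a hub gene
  that shares one latent level with its first three members, making
  every hub–member pair gap-cooperative.

All randomness flows from one root seed through named substreams per
gene role, so a configuration is bit-reproducible. Conflicting explicit
role assignments are rejected with the offending gene named.

What the generator does **not** emulate: probe-level microarray
artifacts, normalization or dye effects, correlated background
structure, heavy-tailed noise, or metabolite flux values themselves
(only the trend codes). Passing tests therefore demonstrate the
statistical machinery under the assumed generative geometry, not
robustness to microarray-specific artifacts.

## Problem sizes and numerics

The test and acceptance suites run at the reference conditions the
package is designed around: 5 planted gap pairs among 40–60 genes,
30+30 samples, 200 permutations, 10–20 replicate seeds per property —
sizes at which every suite completes in minutes on one CPU while the
BH-feasibility arithmetic above still holds. Tolerances: MI agrees with
the direct double-sum to 1e-12 relative; hypergeometric tails agree
with exhaustive enumeration to 1e-12 absolute for N ≤ 12; bounds are
asserted with 1e-12 slack for floating summation order. k-means ties
are broken by lowest cluster index (numpy argmin); 1-D partitions label
bins in value order; empty clusters keep their centroid and simply drop
out of the label set.

## Limitations

* The MI estimator's cluster counts (3 marginal states, 9 joint
  clusters) are fixed design choices, not fitted; very small cohorts
  (< ~20 samples per class) leave too few samples per joint state.
* The pooled null assumes pairs are exchangeable under the global null;
  strong heterogeneity in discretization geometry across pairs would
  miscalibrate individual p-values (the per-pair mode is immune, at the
  cost of resolution).
* The synergy score is symmetric and pairwise; higher-order cooperation
  is out of scope.
* With phenotype confounded with treatment (palmitate = toxic),
  condition effects and phenotype effects are not separable by design;
  the trend filter operates on conditions, the synergy scan on
  phenotype, and both views of the same genes can disagree.
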