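# Methods

This note records the statistical model behind `ercov`, the defaults and
why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect reproducibility.

## The quantity being estimated

For gene g and branch k of the species phylogeny, let b_gk be the amount
of amino-acid divergence assigned to that branch (substitutions/site).
Genes differ enormously in overall rate, and all genes share the species
tree's branch-length profile, so raw b vectors of unrelated genes are
strongly positively correlated. ERC is meaningful only after both
nuisance signals are removed. Per unique species set S (genes are
compared on the intersection of their species coverage):

1. every background gene covering S is pruned to S (branch lengths summed
   along suppressed paths),
2. u_g = b_g / ‖b_g‖ removes gene-wide rate (scale invariance is exact:
   multiplying a gene's raw vector by any positive constant leaves its
   residual unchanged),
3. m = mean_g u_g is the expected tree for S,
4. the default residual is the centred relative rate
   r_gk = u_gk/m_k − mean_k(u_gk/m_k); a gene evolving exactly
   proportionally to the expected tree has residual zero,
5. each branch column of the residual table is winsorized (clamped) at
   its mean ± 2 SD to bound outlier influence.

The ERC of a pair is the Pearson correlation of their residual vectors
over the 2|S|−3 branches of the shared set.

### Why relative rates rather than orthogonal projection

An alternative residual removes the component along the mean direction,
r_g = u_g − ((u_g·m)/(m·m)) m, which makes every raw residual exactly
orthogonal to m. Both variants are implemented (`method="ratio"` |
`"projection"`); the ratio form is the default because dividing by m_k
puts branches on a comparable scale. Under the orthogonal projection the
residual variance of a branch tracks its expected length, so an
unweighted Pearson correlation is dominated by a few long branches: on
the 12-taxon calibration tree the null ERC SD is ≈ 0.37 versus ≈ 0.22
for relative rates (close to the 1/√(B−1) expected for B = 21
exchangeable branches), roughly halving the effective branch count and
substantially reducing power to detect planted covariation. The
projection variant's orthogonality invariant (r_g·m = 0 before
winsorization) is still tested against that variant.

### Winsorization

Clamping is per branch column, after the residual transformation, at
exactly mean ± 2 SD (sample SD, ddof = 1) of the column. Column-wise
clamping is used because outliers are branch-specific rate excursions
(a burst on one branch of one gene); clamping rather than exclusion keeps
the gene comparable across all its pairs. The bound is a parameter
(`winsor_bound`, default 2).

## Empirical p-values

The distribution of pairwise correlations depends on the species set:
fewer species mean fewer branches and a wider null (the package's tests
assert SD(5-species null) > SD(12-species null)). Observed ERC values are
therefore converted to empirical p-values against the observed ERC
distribution of background gene pairs *from the same species set*: up to
10,000 unordered background pairs sampled uniformly without replacement
(all pairs when fewer exist), p = (1 + #{null ≥ r}) / (1 + n). One-sided
by default — only elevated ERC is interpreted as evidence of shared
pressure — with a two-sided option; the add-one rule keeps p > 0 under
finite nulls, and ties count toward the tail (conservative).

## Species-matched permutation test

The test statistic for a gene set is the arithmetic mean of ERC over all
admissible pairs. Each of n_perm (default 10,000) replicates rebuilds the
mean by replacing every observed pair slot with a value drawn uniformly
from background pairs of that slot's species set; p is add-one, so its
granularity is 1/(n_perm+1). Values are drawn independently across slots
and replicates (no within-replicate exclusivity); a whole-set resampling
mode exists for sensitivity analysis. If a slot's species set has no
background pairs, the nearest-size species-matched pool substitutes with
a warning and the fallback count is reported. Under the null the test's
size is calibrated: across 400 null gene sets the rejection rate at
α = 0.05 stays inside the exact binomial 99% interval (asserted in the
acceptance suite).

## Screening rule

A candidate is nominated when it shows empirical p < 0.05 with at least
two query proteins, or p < 0.01 with at least one. "Multiple" is
operationalized as ≥ 2 — the minimal reading — and both thresholds are
parameters recorded in the report header. No multiple-testing correction
is applied: the screen prioritizes candidates for follow-up rather than
controlling a family-wise error rate, and the expected false-nomination
rate under the null (~6.3% with five queries) follows directly from the
rule's combinatorics, which the tests verify by brute-force Monte-Carlo.
Untestable candidates (no admissible query pair) are always listed.

## Branch-length estimation

The built-in estimator is deliberately simple: p-distances with pairwise
deletion (gap and `X` columns removed per pair), Poisson correction
d = −ln(1−p), and nonnegative ordinary least squares of path lengths on
the pruned topology. It is exact on additive distance matrices and,
against the generator's 20-state equal-rates sequences, recovers total
tree length with a median relative error of ~3% at 2,000 sites (the
acceptance bound is 15%). No among-site rate variation or empirical
exchangeability matrix is modelled; users wanting maximum-likelihood
branch lengths under a richer model can compute them externally and
ingest the TSV branch tables — downstream modules are agnostic to the
vectors' provenance, and the relative-rate transformation absorbs
systematic scale differences. Saturated pairs (p = 1) cause the gene to
be excluded rather than silently capped; an opt-in cap (p ≤ 0.95) exists
for exploratory use. A pair sharing zero ungapped columns makes the
distance undefined and likewise excludes the gene from that species set.

## Tree handling

Trees are unrooted throughout (rate correlations are root-invariant); a
rooted Newick is unrooted on read by suppressing the degree-2 root and
summing its incident branch lengths. Branch identity is by leaf
bipartition — the frozenset of leaves on the side away from the
lexicographically smallest leaf — never by node index, so branch tables,
prunings and re-read trees align unambiguously. Pruning suppresses
degree-2 nodes, sums their incident lengths, and returns the mapping from
each pruned branch to the original branches merged into it; leaf-to-leaf
path lengths among retained species are preserved exactly. Projections
and nulls are cached per frozen species set (LRU bound configurable),
since heterogeneous coverage can generate on the order of a couple of
thousand distinct sets in a genome-scale run.

## Synthetic data

The generator draws, for gene g and branch k with base length t_k:

    b_gk = s_g · t_k · exp(σ·e_gk − σ²/2),

with s_g lognormal (gene-wide rate), σ the branch-level log-rate noise,
and e_gk standard normal. A planted group with strength λ shares a
per-branch factor f_k: e_gk = √λ·f_k + √(1−λ)·z_gk, so λ is the
variance-partition coefficient and the expected log-rate correlation of
two same-group genes is exactly λ — verified by pooling over many
independent groups. The −σ²/2 offset makes the multiplicative noise
mean-one so the expected branch length is s_g·t_k for every σ, keeping
the expected tree well defined. Sequences evolve under a 20-state
equal-rates model whose per-branch substitution probability
p(ℓ) = (19/20)(1 − e^{−(20/19)ℓ}) is the exact transition kernel, so
composing branches is consistent. Missingness masks each species
independently per gene; genes falling below the 5-species floor are
dropped and counted, mirroring the analysis threshold.

Defaults (12-taxon fixed tree with Exponential(0.1) branch lengths drawn
once under a frozen seed, σ = 0.5, lognormal gene-rate σ_s = 0.5, a few
hundred genes) are the calibration conditions for the whole test suite.
What the generator does **not** emulate: realistic amino-acid
exchangeabilities (JTT/LG), among-site rate variation, indels, alignment
error, correlated missingness (e.g. clade-wise gene loss), and selection
regimes that change a gene's rate on one branch only. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the assumed model, not that real alignments satisfy that model.

## Numerical and degenerate-input choices

Pair correlations are computed in a canonical gene order so results are
bit-identical regardless of input order. Constant residual vectors make
the correlation undefined; such pairs are skipped and counted, as are
pairs whose shared species fall below the minimum (default 5, the
analysis floor). Zero-norm branch vectors are dropped from a projection
with a warning; expected-tree branches that are not strictly positive are
dropped table-wide and recorded. Branch tables and Newick output are
written with 17 significant digits so write → read round-trips reproduce
floats exactly. Every stochastic stage takes an explicit seed, and
per-species-set null seeds are derived from the analysis seed plus a hash
of the sorted species names, so nulls do not depend on the order in which
species sets are first visited.

## Problem sizes used in the validation suite

Oracle checks use 100 random instances per statistic (tolerance 1e−12);
tree-signal removal uses 300 genes; null calibration uses a 600-gene
universe, 2,000 fresh pairs for the KS test and 400 permutation runs at
999 replicates; planted-group detection uses 50 runs of a 7-gene λ = 0.6
group among 500 background genes; the screen check pools 10 replicate
screens (5 queries, 7 hidden members, 100 null candidates each). These
sizes keep the full suite and the acceptance script to seconds on one CPU
while leaving the binomial/KS acceptance intervals meaningfully tight.
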