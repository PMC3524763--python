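# Methods

This note records the statistical model behind `siteclust`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer should know.

## Model and assumptions

An alignment is an M x N array of symbols over the 20 amino acids plus a
gap symbol. Each column (site) is treated as a categorical random variable
and the rows as an i.i.d. sample from the family's joint distribution.
This is the standard working assumption for alignment-column statistics
and it is knowingly wrong in one respect: rows are related by phylogeny,
so shared ancestry inflates apparent interdependency. No tree-based
correction or sequence weighting is applied; deduplication of identical
rows is the only relatedness control. Results on real families should be
read with that in mind.

All probabilities are plug-in maximum-likelihood relative frequencies with
no pseudocounts: the dependency test is a G-test, whose asymptotics assume
raw counts. Entropies are computed in nats internally because the test
compares 2nI against a chi-square quantile; the redundancy R = I/H itself
is base-free, and a property test asserts the nat/bit paths agree.

### Degenerate cases

- Both columns constant: H = 0, and R is defined as 0 with the pair marked
  uninformative — a pair with no variation carries no interdependency
  signal either way.
- A constant column in a pair: degrees of freedom (G_i-1)(G_j-1) = 0 and
  the dependency test reports "not testable" rather than a decision.
- Mutual information is clipped at 0 and at H to absorb floating-point
  noise at the exact-independence and exact-dependence boundaries.

### Gaps and alphabet

Columns more than (or exactly) 20% gapped are removed before any
statistics, so gaps are rare in what remains; the gap symbol then counts
as an ordinary 21st symbol in frequency estimates. The alternative —
dropping rows pairwise — would make the sample size n vary per pair and
break the single-n form of the test. Ambiguity codes (B, Z, X, U, O) map
to gap on input by default (`keep_ambiguous` retains them), since the
working alphabet is the 20 standard residues. Degrees of freedom use the
*observed* symbol support per site by default; a fixed-alphabet variant
(`df_mode="full"`) exists but is wildly conservative for sparse columns.

## k-modes clustering

Parameters: `k` (cluster count), `seed`, `max_iter` (default 100, a cap
that in practice is never reached — convergence on structured data takes
well under 20 iterations), `restarts` (default 1).

Tie-breaking and edge rules, all deterministic:

- assignment tie (equal R to several modes): keep the current cluster if
  it is among the best, otherwise the mode with the lowest site label;
- mode tie (equal SR): lowest site label;
- emptied cluster: reseeded with the site worst served by the current
  modes (lowest maximal R to any mode).

The iteration is initialization-sensitive by construction: if two starting
modes land in the same strongly coupled block, the block cannot split
later. This is intrinsic to mode-based partitioning, and the remedy is the
usual one — restarts scored by the total within-cluster redundancy of
members to their mode. The recovery and stability guarantees in the test
suite are therefore stated for the restarted search; a single run is only
guaranteed to be deterministic given its seed.

SR(mode) is normalized by the number of pairs involving the mode
(|cluster| - 1), so a pair's score equals its R and all scores live on the
same [0, 1] scale; normalization by all C(|cluster|, 2) pairs is available
(`normalization="all_pairs"`) for sensitivity checks.

## Pattern discovery

Candidates are the residue combinations actually observed among the rows
projected onto the cluster's sites, not the full |G|^m lattice — the
search is meant to explain observed co-occurrence, and this keeps the cost
linear in the number of distinct row projections. The adjusted residual
uses the Haberman variance generalized to order-m events,
v = e * prod_j (1 - p_j), which reduces exactly to the classical two-way
contingency form at m = 2 (and is tested against an independent two-way
oracle at 1e-9).

Significance calls additionally require the expected count e to reach a
validity floor, `min_expected` (default 5, the classical rule of thumb for
residual-based tests in sparse tables; 0 disables). Without the floor the
normal approximation fails catastrophically for high-order events: over a
20-letter alphabet, any combination observed even once has e near
n/20^m and a huge, meaningless residual, and a null alignment would
"discover" every row. With the floor, false-positive calibration on null
alignments holds at the advertised level (verified over 200 seeded
replicates in the test suite). The cost is reduced sensitivity for rare
genuine patterns at small n: a pattern must be frequent enough that its
marginal product reaches the floor before it can be called.

The cutoff is strict (`gamma > cutoff`), default 3.29 (99.9% two-sided);
`confidence_to_cutoff` converts any confidence level. By default only
full-order events (spanning every site of the cluster) are enumerated;
`span="sub"` adds all sub-order events of size >= 2.

## Cluster tree

Clusters recurring identically at several k values are one tree node.
A cluster's parent is sought in the configuration at the next k below its
last appearance and must have strictly larger order and contain a strict
majority (> 50%) of the child's sites; among candidates the largest
overlap wins, ties going to the smaller parent, then the lower mode label.
Clusters with no qualifying parent stay unattached — they are retained
because locally coherent clusters that never merge can still be
structurally or functionally meaningful. Singletons are kept as isolated
nodes but take no part in nesting: branches begin at second-order
clusters.

Branch typing compares a branch's *exclusive* clusters against other
branches: a convergence node belongs to every branch that reaches it, so
clean convergence leaves branches Type I, while straddling membership
(a site sitting in different branches' clusters at different k) makes the
affected branches Type II. One shared site suffices (`min_interlace=1`).

Modules are connected groups of branches reaching a common node; branches
that never converge are grouped into a declared module when they pairwise
share at least `module_min_shared` sites (default 2). The declared-module
rule is a formalization of a judgment call and is the loosest part of the
pipeline; both thresholds are configurable.

Representative selection uses a *relative* tolerance (default 5%): any
cluster within 5% of the branch's best SR(mode) competes, and the largest
such cluster wins because it covers more sites and is therefore more
informative to inspect.

## Synthetic generator

The generator emulates exactly the statistical structure the pipeline
detects: blocks of sites copying a per-block latent symbol stream through
site-specific bijective relabelings with probability rho (so rho = 1 gives
pairwise R = 1 and rho = 0 gives independence, with mutual information
monotone in between), optional weak second-level coupling of blocks
through a shared stream (planting a nested hierarchy for the tree to
recover), explicit residue combinations overwritten into a chosen fraction
of rows, and per-column gaps at a rate capped below the 20% filtering
threshold. The background is i.i.d. uniform over a configurable alphabet
(default all 20 residues), keeping marginal entropies high and degrees of
freedom stable.

Default conditions: 200 rows, three blocks of four sites at rho = 0.8 —
enough rows for the G-test asymptotics and for pattern expectations to
clear the validity floor, with coupling well short of perfect copies.

What the generator does *not* emulate: phylogenetic correlation between
rows, compositional biases of real residue distributions, indel structure
beyond i.i.d. gaps, and alignment error. Passing recovery tests on this
generator therefore demonstrates the statistical machinery under its own
assumptions; it does not certify performance on real families, where
shared ancestry inflates interdependency.

## Problem sizes and determinism

The test suite and acceptance checks run at desk scale: oracle comparisons
on columns of length 4-50, recovery on 200 x 12 alignments, null
calibration on 200 replicates of 50 x 4, and a full k-sweep end-to-end
determinism check on a 200 x 70 alignment — sizes chosen so each property
is measured where its asymptotics are already informative while the whole
suite stays fast. All randomness flows from explicit seeds
(`numpy.random.default_rng`); restart seeds derive deterministically from
the master seed via `SeedSequence`, so identical inputs give byte-identical
artifacts (timestamps live only in the run log).

## Known limitations

- No phylogenetic correction; interdependency on real families mixes
  structural signal with shared ancestry.
- No multiple-testing correction beyond the fixed cutoff; the 99.9%
  cutoff plus the validity floor controls but does not eliminate
  family-wise error across many clusters.
- The declared-module rule approximates a manual judgment; different
  `module_min_shared` values can regroup non-converging branches.
- k-modes finds a local optimum; guarantees hold for the restarted search.
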