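# Methods

This note documents the statistical models implemented in `bioprofile`,
their assumptions, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where more
than one reading was defensible.

## Data model

The unit of raw data is an activity record: one binary outcome (active /
inactive) for a compound against a sequence-level protein target in one
assay. Records merge into a sparse trinary matrix (0 = untested,
1 = inactive, 2 = active) whose columns may be individual targets or
sequence-similarity clusters. Merging applies active-over-inactive
precedence: any active record makes the merged cell active, since screens
differ in sensitivity and a reproducible active anywhere is the signal of
interest. Merging is idempotent and order-independent. Records with
non-binary outcome strings (e.g. inconclusive) are dropped with a logged
count. Targets missing from a supplied cluster map become singleton columns
with a warning rather than an error, since cluster maps produced by external
sequence clustering are often incomplete.

Compound-level analyses are restricted to "highly screened" compounds
(≥ 10 distinct sequence-level targets by default, configurable), because
selectivity statistics computed over a handful of screened targets are
dominated by participation, not biology.

## Replicate error model

Assumptions: a single aggregate flip probability *e* applies symmetrically
to false positives and false negatives, measurements of the same pair in
different assays are independent given the true state, and the true-active
fraction *p* among twice-measured pairs matches the rest of the data. Under
these, for pairs measured in exactly two assays,

    P(disagree) = 2e(1 − e)
    P(agree active) = p(1 − e)² + (1 − p)e²

The estimator takes the smaller root e = (1 − √(1 − 2d))/2 (an error rate,
so e ≤ 1/2), then p = (a − e²)/(1 − 2e), and reports
ppv = p(1 − e)/(p(1 − e) + (1 − p)e), the fraction of observed actives that
are truly active. A disagreement fraction d ≥ 1/2 has no real root and is
reported as a model violation; a negative implied p (possible under sampling
noise when actives are very rare) is clamped to zero with a warning. The
estimator is an exact algebraic inverse of the forward model: expected
counts at any (e, p) ∈ (0, 0.4) × (0.001, 0.5) are inverted to machine
precision, which the test suite verifies on a grid. Per-assay error rates
are deliberately out of scope — the estimate is an aggregate over
heterogeneous assays.

## Selectivity at three grouping depths

Domain selectivity is computed as the number of connected components of the
graph whose nodes are a compound's active targets and whose edges join
targets sharing at least one Pfam domain (union–find; equivalent to BFS
component counting, which the tests use as the oracle). Active targets
without any domain annotation count as isolated components — dropping them
would silently deflate selectivity. Because the generator (and real
sequence clustering) makes same-cluster targets share a domain, the nesting
domain ≤ cluster ≤ target ≤ screened holds and is asserted by the
`SelectivityProfile` constructor.

Domains are summarised by binning on the median domain selectivity of each
domain's active compounds (default bins 2–4, 5–7.5, …, 23.5–25.5; medians of
even-sized sets are the mean of the central order statistics, hence the
half-integer edges). Domains with fewer than 10 active compounds are
excluded as unstable.

The tail of a selectivity distribution is fitted with the stretched
exponential P(x) = exp(−(x/x₀)^c). The objective is unweighted least squares
on ln P (distributions of this kind are inspected on semi-log axes, and the
choice of log-space fitting is the natural reading); a log-log linearisation
seeds a nonlinear refinement, and two-parameter exponential and power-law
comparators are fitted for reference, all scored by R² in log space. Points
with P ≥ 1 carry no information about the decay and are dropped; at least
three informative points are required.

Group comparisons use the one-sided Mann–Whitney–Wilcoxon test (W equals
pairwise wins with ½ per tie; p by normal approximation with tie
correction). Participation-normalised comparisons remove random tested
outcomes from the currently most-screened compound of the larger group until
its median participation falls to the smaller group's, deterministically per
seed.

## Beta-binomial hit-ratio model

The hit ratio θ is modelled per compound as n ~ Binomial(N, θ) with a
Beta(α, β) prior estimated by the method of moments from the empirical hit
ratios n/N of active compounds screened against at least 20 targets
(sample standard deviation, ddof = 1). The moment equations require
σ² < μ(1−μ); violations raise rather than silently producing an invalid
prior. Conjugacy gives Beta(α+n, β+N−n), and the promiscuity probability is
the posterior tail P(θ ≥ 0.25). The binomial assumption treats a compound's
screened targets as an unbiased sample of the target space; it is weakest
for little-screened compounds, so compounds with N < 10 are not scored
(avoiding overfit posteriors), and the threshold is a parameter.

Compound-set comparisons pool an equal number of posterior draws per
compound and subsample a fixed pool without replacement — an equally
weighted mixture unbiased by participation — and distances between pooled
distributions use the two-sample Kolmogorov–Smirnov statistic. External
promiscuity labels (PAINS-like substructure flags, aggregator assays) are
evaluated on a cutoff sweep (0.01–0.9999) where "sensitivity" is the
fraction of promiscuous-classified compounds carrying the label and
"specificity" the fraction of non-promiscuous-classified compounds without
it; empty classes report missing values, never zero.

## Biclustering

The score of an m × n submatrix with k ones against background density p is
the negative exponent of the multiplicative Chernoff bound,
E = μ((1+δ)ln(1+δ) − δ), μ = mnp, δ = k/μ − 1, normalised to
E / (m^α n^β). Submatrices at or below background (δ ≤ 0) score zero — only
enrichment is rewarded. The normalisation exponents α = β = 0.6 are the
no-bias default; the normalisation is isolated in `chernoff_score` so an
alternative convention is a one-function change.

Search alternates two exact half-steps: given a column set, rows are ranked
by in-set active count and every prefix is scored in one vectorised pass
(for a fixed row count the best selection is always such a prefix, because
the score increases with k); then roles swap; iteration stops at a fixed
point. The best result over seeded random column-subset restarts (default
50) is returned. When the restart budget covers every non-empty column
subset (small matrices), all subsets are enumerated, which makes the search
provably exact — the test suite checks equivalence with exhaustive
enumeration on 4 × 4 matrices. Extraction is iterative: each accepted
bicluster's cells are zeroed before the next search; clusters smaller than
2 × 2 are discarded but still zeroed; extraction stops at the configured
maximum or when the best score drops below the score of the smallest
admissible all-ones block at background density.

For drug–target biclustering, the binary input matrix is the OR of assay
activity and externally annotated drug–target pairs, so annotation-only
pairs count as activity evidence.

## Annotation comparison and enrichment

Every compound–target pair falls into exactly one of six cells,
{untested, inactive, active} × {unannotated, annotated}; actives without
annotation are emitted as candidate novel pairs. Term enrichment
(GO slim, Pfam — the implementation is term-agnostic) uses the upper-tail
hypergeometric test P(X ≥ k). No multiple-testing correction is applied by
default, matching the convention of displaying raw p ≤ 0.05 for these
exploratory summaries; callers can correct downstream.

## Target-protein network

Column similarity is the Tanimoto of active-compound sets restricted to
mutually tested compounds, gated to zero for pairs with fewer than 12
mutually screened compounds or fewer than 3 actives. The 3-actives gate is
applied to the union of the two active sets by default; a stricter per-side
scope is available (`min_actives_scope="each"`) since either reading is
defensible. Edges require similarity ≥ 0.50; isolated targets are excluded
from the node set. Compounds with promiscuity probability strictly above
0.5 are removed before computing similarities (promiscuous binders inflate
spurious co-activity), while unscored, infrequently screened compounds are
retained — they carry usable evidence here even though they are excluded
from compound-level analyses. All pairwise similarities are computed with
three matrix products (mutually-tested, co-active, active-on-mutual counts),
so the construction scales quadratically in targets and linearly in
compounds.

## Structure vs bioactivity comparison

Compound structure is represented by externally computed binary fingerprints
(e.g. atom-pair descriptors); the package deliberately does not compute
chemical descriptors — the fingerprint matrix is an input contract, and the
synthetic generator emits group-correlated random bit vectors instead.
Structural distance is 1 − Tanimoto (zero-vector pairs are assigned distance
1 with a warning). Classical (Torgerson) MDS — double centering of squared
distances plus eigendecomposition — is implemented directly because the
common SMACOF-style MDS implementations solve a different optimisation;
classical MDS reproduces Euclidean-realisable configurations exactly.
Discrete structural clusters come from complete-linkage hierarchical
clustering cut at k groups (k = 11 by default, matching the number of
bioactivity clusters when each compound is assigned to its lowest-numbered
bicluster). Agreement between clusterings is the Jaccard index over
co-clustered pairs; compounds outside every bicluster are excluded from pair
counting (treated as singletons), since their pairing status is undefined.
The null reassigns compounds to clusters independently with probabilities
proportional to the structural cluster sizes; the permutation p-value uses
the add-one correction (1 + #{J_null ≥ J_obs})/(1 + n_perm), so the minimal
attainable p at n permutations is 1/(n + 1).

## Synthetic worlds

The generator emulates the statistical structure of public screening
corpora: heterogeneous participation (default log-uniform over
[1, n_targets], mimicking the irregular participation profiles of real
repositories), compound classes with different hit behaviour (selective
θ = 0.02, promiscuous θ = 0.6, inactive θ = 0.0005, and family-cross-reactive
compounds hitting 0.7 of their assigned family and 0.02 outside it), targets
partitioned into sequence families whose members share a family-core domain
plus extras from a family pool, a symmetric flip error applied independently
to every measurement (default e = 0.698%), a fraction of tested pairs
measured in two assays (default 16%), optional planted dense biclusters
(cells forced tested, with enough cells set active to guarantee the
requested block density), label sets enriched by class (an approved-drug-like
set, a PAINS-like set strongest in the middle promiscuity range, an
aggregator-like set concentrated among the most promiscuous), and
group-correlated fingerprints keyed to planted biclusters. The default class
mix (35% selective, 5% cross-reactive, 1% promiscuous, 59% inactive) puts
the implied true-active fraction among tested pairs near 1–2%, the regime of
large public screening matrices; `SyntheticConfig.implied_active_fraction()`
reports the value implied by any configuration. All randomness flows from a
single seed through per-stage spawned substreams, so worlds are byte-stable
across calls and insensitive to the order in which stages consume
randomness.

What the generator does **not** emulate: real chemistry (no structures or
SMILES; fingerprints are synthetic bit vectors), per-assay heterogeneity in
error rates, correlated errors within an assay, biased target selection
conditioned on prior results, or hierarchical family structure beyond one
level. Passing tests therefore demonstrate correct recovery of the model's
own generative structure — parameter recovery, gate behaviour, ranking
separation — not performance on any real screening corpus.

## Numerical choices and degenerate inputs

- Error model: smaller quadratic root only; d ≥ 0.5 raises; p clamped to
  [0, 1] with a warning.
- Prior estimation: requires two qualifying compounds and valid moments.
- Stretched-exponential fit: curve-fit failure falls back to the
  linearised solution; R² of a zero-variance log response is 1 when the
  residual is zero, else 0.
- Biclustering: background density clipped away from {0, 1}; an all-zero
  matrix returns no bicluster; ties in row/column ranking break by index
  (stable sort) for determinism.
- Clique de-duplication: exact maximum-clique enumeration up to 2000 nodes,
  greedy heuristic beyond (logged); ties break by total screened count, then
  lexicographically smallest member set.
- Representative selection: precedence classes (annotated human drug
  target → human with UniProt id → any UniProt id → rest), ties
  lexicographic.
- Jaccard between clusterings: computed from contingency-table pair counts;
  an empty pair union reports missing rather than zero.

## Problem sizes used in the test suite

The suites run on worlds of 300–1000 compounds × 60–200 targets, one
million simulated replicate pairs for error-rate recovery, 2000 permutations
for the structure-bioactivity null, and exhaustive oracles on instances
small enough to enumerate (4 × 4 matrices for biclustering, n ≤ 8 samples
for rank statistics, ≤ 12 nodes for graph oracles). These sizes make the
full suite complete in about a minute while leaving every statistical check
at least three standard errors of headroom.
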