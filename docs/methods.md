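# Methods

This note documents the models, estimators, null models and numerical
choices behind each analysis stage, the design decisions taken where
more than one convention exists, and what the synthetic-data generator
does and does not emulate.

## Trees and per-species metrics

Trees are rooted, with finite non-negative branch lengths in time units
(Myr throughout); ultrametricity is *not* assumed or enforced, and no
rescaling is applied on input. Tip names are normalized by collapsing
whitespace runs to underscores so Newick labels and CSV species columns
match; unmatched species are dropped from tree-dependent stages only,
with logged counts. Polytomies are legal for ED, BL and distances;
only the D statistic requires a strictly bifurcating tree (below).
Zero-length branches are permitted and contribute zero everywhere.

* **BL** (terminal branch length): the pendant edge above each tip —
  a species' "recent evolutionary age".
* **ED** (fair-proportion evolutionary distinctiveness): each edge's
  length divided equally among its descendant tips and summed along
  each tip's root path. The identity Σ_tips ED = total branch length
  holds exactly and is asserted across random trees at 1e-9 relative
  tolerance (measured error is ~1e-15).
* **Cophenetic distances** are computed by a single sweep over internal
  nodes using `d(i,j) = depth(i) + depth(j) − 2·depth(lca)`; the
  per-pair patristic API of dendropy serves as the independent oracle
  in the tests.

## Taxon selectivity

With `n` prohibited among `N` species, each taxon's observed statistic
is `100·(prohibited in taxon)/N`. The null draws `n_reps` (default
1000) assemblages of `n` distinct species uniformly from the pool and
recomputes the same proportion; the interval is the empirical 2.5–97.5
percentile, and a taxon is `over`/`under` only when the observed value
falls strictly outside it. The denominator choice (total species, not
taxon size) makes the per-taxon null count exactly hypergeometric with
mean `n·m/N`, which the tests verify by exhaustive enumeration at small
size and within Monte-Carlo error at study scale.

Two consequences of discreteness are worth knowing. First, when a
taxon's maximum attainable count carries more than 2.5% of the null
mass, the strict rule can never flag it even if every prohibited
species sits inside it (this occurs at very small datasets, e.g.
N=10, m=4, n=3). Second, the ~5% nominal flag rate under random labels
is only meaningful when both tails of the interval are reachable; a
family so small that `P(count=0) > 2.5%` can never be
under-represented. The calibration test therefore uses 5 families of
16 species with prevalence 25, a regime where measured per-taxon flag
rates are 0.03–0.04. No multiple-testing correction is applied across
taxa.

## D statistic

Nodal trait values are estimated by unweighted post-order child
averaging; `Σd` is the sum over all edges of the absolute parent–child
difference. Branch lengths deliberately do not enter the nodal
estimation; they act only through the Brownian simulation, making D
invariant to rescaling the tree (tested). The Brownian null simulates
a unit-rate Brownian character (per-edge normal increments with
variance equal to edge length), ranks the tip values, and assigns
state 1 to the top `k` tips, `k` being the observed number of 1s; ties
at the threshold are broken uniformly at random. The random null
shuffles the observed states across tips. Defaults: 1000 simulations
per null, fully seeded.

Both p-values are one-tailed in the conservation direction:
`p_random = #{Σd_rand ≤ Σd_obs}/n_sims` (small = more conserved than a
random arrangement) and `p_brownian = #{Σd_BM ≥ Σd_obs}/n_sims`
(small = less conserved than Brownian). The published quantity cited
for this statistic does not pin down its tail conventions; these were
chosen so that a trait with D near 1 reads "not different from random,
departs from Brownian", and the interpreter also reports
overdispersion when `1 − p_random < α` with D > 1.

Polytomies are refused by default because silent resolution changes
Σd; an explicit flag resolves them randomly with zero-length edges
under a stated seed. Calibration (by construction of the two nulls):
the mean D over replicates of shuffle-generated traits is ≈1 and of
Brownian-threshold-generated traits ≈0; the acceptance test runs 200
replicates on 100-tip Yule trees with 200 simulations each and
requires the means in [0.85, 1.15] and [−0.15, 0.15].

## NRI / NTI

MPD is the mean over unordered member pairs of patristic distance;
MNTD the mean nearest-member distance. Null communities are uniform
draws of the same size, without replacement, from all tree tips — in
the pipeline the pool is the full analyzed assemblage, so each
category is tested against the whole alien pool. Indices are minus
the standardized effect size, so clustering is positive, and p-values
use the add-one rank rule `(1 + r)/(n_reps + 1)`, one-tailed toward
clustering (an overdispersed set shows p near 1). On trees small
enough to enumerate every subset, the Monte-Carlo null mean and SD
match exhaustive enumeration; under the null itself the rejection rate
at α = 0.05 is 0.04–0.05 with 199 null draws per test (the add-one rule
makes the achievable rate 9/200 = 0.045). Other null models
(independent swap, label shuffles within subsets) and abundance
weighting are out of scope.

## Rank-sum comparisons

W is the Mann–Whitney U of the first sample over the second
(`W ∈ [0, n1·n2]`, `W(x,y) + W(y,x) = n1·n2`), two-sided by default.
For `n1 + n2 ≤ 12` the p-value is computed by exhaustively enumerating
all C(n1+n2, n1) assignments of the pooled midranks — this handles
ties exactly and gives p = 1 for identical samples, and the two-sided
value is `min(1, 2·min(P≤, P≥))`. Larger samples use the normal
approximation with midranks, tie correction and continuity correction.
Medians of both groups are reported alongside.

## GLMM screen

Each predictor is screened in its own univariate model (per-predictor
models keep collinear predictors — e.g. three latitude variants —
individually interpretable; a multivariate mode is deliberately not
offered). The model is binomial with logit link and a family-level
random intercept. The marginal likelihood integrates the random
effect by adaptive Gauss–Hermite quadrature: per group, the
conditional mode is found by Newton iteration (the integrand is
log-concave), the quadrature grid is centered there and scaled by the
curvature, and 15 Hermite nodes are applied — accurate to ~1e-6
against an external adaptive-quadrature reference (lme4::glmer,
nAGQ=15) on the frozen test fixture. Optimization is L-BFGS-B over
(β₀, β₁, log σ) with log σ bounded in [−8, 3] and two starts for the
variance parameter; standard errors come from the numerical Hessian of
the negative marginal log-likelihood, dropping the variance row when
σ̂ sits on the boundary (the model has then collapsed to plain
logistic regression, and only there does the slope coincide with the
IRLS logistic estimate — a boundary equivalence the tests assert
conditionally on σ̂ < 0.01). Predictors enter on their raw scale, so
estimates are per predictor unit on the logit scale; p-values are
two-sided normal tails of z = estimate/SE. Complete cases are taken
per predictor; predictors with fewer than 10 usable rows (default), a
constant value, or a single response class are skipped with a logged
reason. Suspected separation (|β̂₁| > 30 or SE > 1000) clears the
converged flag.

The redundancy filter is deterministic: among significant predictors,
while any retained pair has |Pearson r| ≥ 0.7 on pairwise-complete
data, the member of any offending pair with the largest p is dropped,
ties broken alphabetically. Thresholds α and |r| are configurable.

## Synthetic data

The generators exist so every stage can be exercised against known
ground truth. Trees are Yule (ultrametric) or Kingman coalescent via
dendropy, rescaled to a maximum root-to-tip depth of 100 Myr-like
units. Families are monophyletic: the largest clade is split
repeatedly until the requested number of groups exists, and contiguous
families are grouped into orders — this coupling of taxonomy to
topology is what lets taxonomic and phylogenetic structure be set
independently. Status modes: `random` (uniform, D ≈ 1 by
construction), `bm_threshold` (identical construction to the D
statistic's Brownian null, D ≈ 0), and `taxon_clustered` (selection
odds multiplied inside designated families via weighted sampling
without replacement — taxonomic selectivity with only the mild
tree-signal that clade-aligned families induce). Every mode yields an
exact prohibited count. Trait tables are standard normal per species;
effects can either regenerate the response from the logistic
random-intercept model (making the slopes the estimand truth for
recovery tests) or, keeping the input status fixed, act as
standardized mean shifts in the prohibited class. Missing cells are
inserted completely at random and written with the −999 sentinel.

The bundled fixture (seed 20140430) has 77 species, 20 families, 9
orders, a 19/7/51 prohibited/permitted/invasive split, taxon-clustered
status (boost 8 in the largest family), and six traits with a
negative gestation-length-like shift and a positive group-size-like
shift. What the generator does *not* emulate: realistic life-history
covariance between traits, non-random missingness, taxonomic
non-monophyly, supertree polytomies, or measurement error — so green
tests demonstrate correctness of the estimators and their calibration
under the stated generating processes, not robustness to those real-
data complications.

## Pipeline and reproducibility

A master seed spawns one child stream per stochastic stage
(`numpy.random.SeedSequence`), so disabling a stage never perturbs
another's draws; reruns with the same configuration are byte-identical
(the run log carries no timestamps for this reason). Default null
sizes are 1000 replicates/simulations per stage. The acceptance
script re-runs the bundled fixture end-to-end and re-measures each
calibration at the sizes stated above (100 trees for ED conservation,
200 × 200 for D, 1000 × 199 for NRI, 100 replicates of 50 × 40 for
GLMM recovery, 1000 × 1000 for selectivity), which together take
roughly half a minute on one CPU.

## Known limitations

* The D statistic requires a bifurcating tree; random resolution is
  available but changes Σd, so results on heavily polytomous trees
  depend on the resolution seed.
* The GLMM is univariate by design; confounding among predictors is
  only addressed by the post-hoc correlation filter.
* Wald p-values from the observed information can be optimistic at
  small group counts or near-boundary variance estimates.
* One-tailed conventions for the D and NRI/NTI p-values are stated
  choices among defensible alternatives; compare tail definitions
  before benchmarking against other implementations.
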