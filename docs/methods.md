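# Methods

## Life-table demography

A `LifeTable` holds a species' annual survival probabilities s(x) on an
ascending integer age grid, built either directly from survival columns or
from cohort counts via s(x) = n(x+1)/n(x).  Counts must be non-increasing;
trailing extinct classes are dropped; at least three age classes are required.
Survivorship is accumulated from age 1 (juvenile survival between birth and
age 1 is too heterogeneous across field studies to compare), l(1) = 1,
l(x+1) = l(x)·s(x).

**Median lifespan** is the age at which l(x) crosses 0.5, linearly
interpolated between the bracketing age classes — linear interpolation is the
minimal assumption between annual censuses.  When l never reaches 0.5 within
the observed ages the median is a flagged missing value rather than an error,
so batch runs retain such species for aging-rate analyses while excluding
them from lifespan analyses.

**Survival smoothing.**  Annual survival is smoothed on age with a cubic
smoothing spline (the penalised criterion Σ(y−f)² + λ∫f″², whose solution is
a natural cubic spline through its own fitted values).  By default the
penalty is chosen by generalized cross-validation, so precise life tables
(large cohorts) are tracked closely while noisy ones are smoothed hard; a
fixed effective-degrees-of-freedom interface (`df=4` reproduces the classical
GAM default of the historical local-scoring software) is retained and tested
— the penalty weight is then calibrated so that trace of the smoother matrix
equals the requested df, capped at n (interpolation) and collapsing to the
least-squares line as df → 2.  GCV was made the default because a fixed df=4
smears the knee of a plateau-then-decline schedule over several age classes,
which makes the onset of senescence (below) undetectable at the ±1-age-class
precision the recovery experiments demand.

**Onset of senescence.**  The onset is the age at which the smoothed survival
trajectory enters a *sustained decline*: the earliest grid age at which the
fitted derivative stays below half the curve's mean decline rate
((max−min)/age span) for at least 0.5 years.  For a strictly declining curve
this is the first observed age; for a rise-then-fall curve it is the peak (up
to the smoother's shoulder, ≲0.5 yr); for a flat plateau followed by decline
it is the plateau's end.  A bare "age of the fitted maximum" rule was
rejected: a plateau-then-decline schedule is globally non-increasing, so any
smoothed fit has its maximum pinned at the first age and the rule cannot
recover a plateau-end onset at all.  The relative-rate threshold also makes
the rule immune to noisy terminal age classes (tiny cohorts can put spurious
bumps at the end of the fitted curve) and scale-free across fast- and
slow-aging species.  When no sustained decline exists (flat or rising
curves) the earliest age of the fitted maximum is returned.

**Aging rate** is the unweighted OLS slope of *observed* annual survival on
age from the onset onward; the smoother is used only to locate the onset (a
config switch regresses the fitted values instead).  Consumers take
log |slope|; an exactly zero slope is legal here and flagged downstream.

## Phylogeny and covariance structure

Trees are read from Newick (dendropy), branch lengths required, duplicate
tips rejected, unlabelled internal nodes allowed.  Pruning takes the induced
subtree with degree-2 nodes collapsed and lengths summed, so patristic
distances among retained tips are unchanged.  The Brownian covariance matrix
accumulates each edge's length over the tip pairs descending from it:
V[i,j] is the shared root-to-MRCA path length, V[i,i] the tip depth.
Pagel's λ multiplies the off-diagonal entries, leaving the diagonal fixed;
for ultrametric trees the transformed matrix stays positive semi-definite on
all of [0, 1].  Non-ultrametric trees are accepted with a warning (their
observed tip depths are kept).  Species names are matched between tree and
tables after underscore/space normalisation and case folding; unmatched
species are reported and dropped.  Polytomies pass through unchanged.

## PGLS and model selection

Conditional on λ, GLS is solved in whitened coordinates via the Cholesky
factor of V(λ): β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² = rᵀV⁻¹r/n (ML), and
logL = −½[n·ln(2πσ̂²) + ln|V| + n].  Standard errors and t statistics use the
(n−p)-denominator variance estimate — the dual ML/small-sample convention of
mainstream PGLS implementations — with two-sided p from t(n−p).  A condition
number above 1e12 on XᵀV⁻¹X raises a singularity error naming the collinear
columns.  A residual sum of squares below 1e−12 of the response's whitened
norm is flagged as a perfect fit (σ̂² = 0, infinite likelihood) rather than
reported as a numeric likelihood.

λ is profiled by bounded Brent search on [0, 1] (tolerance 1e−6) with
explicit endpoint evaluation; a tie between an interior optimum and an
endpoint resolves to the endpoint, 0 before 1, so phylogeny-free data report
λ̂ = 0 (on a star tree every λ is equivalent and 0 is returned).

AICc uses k = (#coefficients incl. intercept) + 2, counting σ² and λ as
estimated parameters — this reproduces the conventional k of 3 for an
intercept-only PGLS and 4 for a one-slope model.  Akaike weights are
w_i = exp(−Δᵢ/2)/Σexp(−Δⱼ/2).  Selection retains, among all models within
2 AICc units of the best, the one with smallest k (ties: smaller AICc, then
listing order); "simplest" is defined by parameter count, nesting is not
checked.  Adjusted R² is computed in the V(λ̂)-whitened space against the
intercept-only GLS fit at the same λ̂; intercept-only models report 0 by
convention.  Shapiro–Wilk screening (scipy) flags variables for log
transform at p < 0.05; no multiple-testing correction is applied anywhere,
matching standard practice for this design.

The two candidate sets mirror the study design: the testes-mass set
{Constant; AFR; BM; TM+BM; AFR+TM+BM; AFR×TM+BM} (body mass accompanies
testes mass everywhere, so relative testes investment is modelled without
residual regressors), and the multiple-paternity set {Constant; AFR; MP; LS;
MP+LS; MP×LS; AFR+MP; AFR+MP+LS; AFR+MP×LS} (litter size as a detectability
covariate; MP also appears alone, following the published layout).
Interactions are products of the two log-scale, uncentred variables and
always include both main effects — hence the interaction-only MP×LS model
has k = 6, not the 5 printed in the source table, whose own convention
elsewhere implies 6.  All logs are natural; the base shifts coefficients by
a constant factor only.

## Pipeline

`assemble` inner-joins the per-species metrics with the trait table on
normalised names, applies the log transforms (aging rate as log |slope|),
keeps species with undefined median lifespan for aging-rate analyses only,
excludes zero-aging-rate species from log analyses with a flag, and prunes
the tree to the joined set.  Joins are order-independent: shuffling input
rows changes no numeric output.  `run_block` fits one candidate set on one
taxonomic subset, with every model fitted on the same completed-case species
so AICc values are comparable, and skips blocks whose n is too small for the
largest model.  Sensitivity reruns drop species or substitute single trait
values and diff the selected models and headline slopes against the
baseline.  Sample sizes are always computed from the data actually supplied,
never hard-coded.

## Synthetic data

`simulate_tree` draws a crown Yule tree (lineages split at unit rate,
splitting lineage uniform) rescaled to unit root-to-tip depth.
`simulate_traits` evolves predictors as unit-rate Brownian motion and draws
the response y = Xβ + ε with ε ~ N(0, σ²·V(λ_true)); columns are returned
exponentiated so the pipeline's log transforms recover the linear model
exactly.  `simulate_life_table` realises a plateau-then-linear-decline
annual-survival schedule as binomial cohort counts
n(x+1) ~ Bin(n(x), p(x)) from n(1) = cohort₀ — binomial rather than Gaussian
noise so small cohorts show realistic irregularity.  Tables end once fewer
than 2 individuals remain: a class followed by a single survivor yields an
annual-survival ratio of exactly 0 or 1 (pure noise with high leverage in
the aging-rate regression), and published life tables likewise stop when the
cohort is exhausted.

The default **study fixture** (51 species) ties both mortality metrics to
the pace of life with no testes-mass effect — the null result the analysis
is designed to reproduce.  Calibration choices, in the package's own
judgment of what is realistic for this clade and design:

* log AFR = 1.0 + 0.45·BM-motion (AFR ≈ 1–8 yr); log body mass
  10.8 + 1.6·BM-motion (grams); log testes mass allometric on body mass with
  slope 0.7 plus phylogenetically correlated deviations — so the fixture
  satisfies the collinearity precondition (testes mass independent of AFR).
* log median lifespan = 1.1 + 1.0·log AFR + ε and log |aging rate| =
  −2.3 − 1.2·log AFR + ε, effect sizes near the published comparative
  estimates (a calibration choice, not ground truth from the study's raw
  data), with residual sd 0.35 and **zero residual phylogenetic signal**:
  all tree structure in the mortality metrics is inherited through AFR,
  consistent with the near-zero fitted λ of retained pace-of-life models in
  this literature.  Feasibility clips (median ≥ 1.9 yr, |rate| ≤ 0.25/yr,
  decline span ≥ 3 age classes) almost never bind, so the log-linear
  generative relations stay exact.
* Each species' life-table truth is constructed so its analytic median
  matches the target (plateau survival solved by bisection; onset placed at
  ~60% of the target median) and its decline slope equals the target aging
  rate; tables are realised with cohort₀ = 200 000.

What the generator does **not** emulate: real compiled life tables mix count
and survival formats of very different precision, census intervals other
than one year, age-truncated published tables, digitisation error, and
measurement error in the trait covariates.  Passing the recovery and
end-to-end tests therefore demonstrates correctness of the estimators under
the stated statistical model, not robustness to the full heterogeneity of
literature-compiled data.

## Numerical choices and problem sizes

λ-profile tolerance 1e−6 with a 1e−5 tie window at the endpoints; smoothing
penalty solved on a log-λ grid/bisection over e^[−18, 18]; covariance
Cholesky with no jitter (a non-PSD V raises).  The parameter-recovery
experiment uses 200 replicates of 100-tip trees (λ_true = 0.7, slope 1,
σ² = 1) plus 200 matched null-slope replicates for CI coverage; the
demography recovery uses cohorts of 10⁶ with onset 5 yr and slope
−0.05 yr⁻¹; the end-to-end experiment uses 50 replicate 51-species studies.
These sizes give Monte-Carlo error comfortably below the recovery bands
they are checked against.

## Known limitations

* One correlation structure only (Pagel's λ); no Ornstein–Uhlenbeck, κ, δ
  or Grafen alternatives, no REML, no measurement-error models.
* The aging-rate regression is unweighted, so sparse terminal age classes
  of real tables add leverage-driven noise; the generator censors
  single-survivor classes but real data may not allow that.
* With ~6-model candidate sets and a 2-unit parsimony window, a spurious
  covariate is expected to enter the selected model in roughly 5% of
  null datasets per response (the χ² union of the k=6 and k=7 win events);
  the end-to-end reproduction figures should be read against that nominal
  floor, which also caps the joint two-response reproduction rate near 90%.
* Onset detection inherits the smoother's shoulder: on smoothly peaked
  (rather than kinked) trajectories the detected onset can lag the true
  peak by up to ~half the persistence window.
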