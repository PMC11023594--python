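# Methods

## The model

`madmix` clusters the rows of a table whose columns are declared either
categorical or numeric.  A clustering with K clusters is an assignment
vector A of length N with entries in 1..K.  Columns are modelled as
independent within a cluster, each with a conjugate prior, and the
distribution parameters are never estimated — they are integrated out in
closed form.  The objective for a fixed K is the collapsed likelihood of
the partition,

    P(D | A, K) = prod_j prod_l  m_l(d_j)

where `m_l(d_j)` is the marginal likelihood of column `l` restricted to the
rows `d_j` of cluster `j`:

* **Categorical column with k levels.**  Dirichlet prior with pseudo-counts
  c_1..c_k.  The posterior predictive for level i given counts N_1..N_k is
  `(N_i + c_i) / (N + C)` with `C = sum c_i`; the marginal is the
  Dirichlet-multinomial.  Levels come from the schema, not from the
  observed rows, so a cluster that happens to miss a level still assigns it
  positive predictive mass.
* **Numeric column.**  Normal-gamma prior
  `N(mu | mu0, (beta0 lam)^-1) Gamma(lam | a0, b0)` on mean and precision.
  The posterior hyperparameters are the standard conjugate updates
  (mu_n, beta_n = beta0 + n, a_n = a0 + n/2, b_n with the scatter and
  shrinkage terms); the posterior predictive is a Student-t with 2 a_n
  degrees of freedom and the marginal has the closed gamma-function form.
  Everything is computed in log space with log-gamma functions.

Sufficient statistics support incremental row addition and removal
(Welford updates for the numeric scatter), which gives the leave-one-out
scores the clustering loop needs, and makes the chain rule
`log m(d) = sum of sequential log predictives` hold to floating-point
accuracy — the master identity the test-suite leans on.

### Default hyperparameters

* pseudo-counts `c_i = 1` (uniform Dirichlet) for every categorical column;
* `beta0 = 1`, `a0 = 1`;
* `mu0` = the sample mean and `b0` = the sample variance of the whole
  column (empirical Bayes), so the prior sits on the scale of the data and
  no standardization of numeric columns is needed.  Both are overridable.

Because `mu0`/`b0` are resolved from the full column, leave-one-out scores
keep the prior fixed; only the cluster statistics change.

## The clustering loop

Hard-assignment EM: compute the score matrix `L[i, j]` — the log posterior
predictive of row i under cluster j, with i first removed from its own
cluster — then reassign every row to its argmax.  Two modes:

* **batch** (default): all rows move simultaneously.  This matches the
  classic description but is not provably monotone, so the loop keeps the
  best assignment seen and stops after `max_iters` (default 100) if it
  never converges (cycle protection).
* **sequential**: rows move one at a time with immediate state update.
  Each move can only increase the collapsed likelihood, so the objective
  trace is non-decreasing (property-tested).

Ties in the argmax keep the current cluster, otherwise take the lowest
index, making runs deterministic.  Empty clusters are dropped and the
surviving count reported.

The number of clusters is grown incrementally (`fit_incremental`): after
fitting K clusters, the floor(N/(K+1)) rows with the worst leave-one-out
score under their own cluster are split off as cluster K+1 to seed the
next fit.  This warm-start ladder is markedly more reliable than random
initialization at the same K (the package's recovery tests use it), since
random K-way initialization frequently lands in local optima that merge or
split planted clusters.

## Choosing K: the evidence over assignments

The evidence for K clusters marginalizes the assignment too:

    ML_K = sum_A P(D | A, K) P(A | K)

with `P(A | K)` uniform over assignments in which no cluster is empty
(a 20-row, K=2 table therefore has 2^20 - 2 = 1,048,574 terms, which
`exact_log_ml` sums directly — vectorized over subset masks for K=2, by
depth-first chain-rule enumeration for small general K, capped at 2e6
assignments).

Monte-Carlo estimators, all seeded and deterministic:

* **AM**: average likelihood over i.i.d. prior draws; biased low in
  practice because prior draws rarely hit the tiny high-likelihood region.
* **HM**: harmonic mean over posterior samples; biased high because the
  reciprocal average is dominated by rarely visited low-likelihood
  assignments.
* **HMβ** (tempered harmonic mean): sample a single Metropolis chain
  whose target is proportional to `P(D|A,K)^beta` and form

      log ML = log< P^(1-beta) > - log< P^(-beta) >

  over that one stream.  At beta=0 the chain is the prior and the
  expression is exactly the AM; at beta=1 it is the posterior and the
  expression is exactly the HM; beta=0.5 (default) splits the two biases
  and tracks the exact value closely on small tables where enumeration is
  possible.  A `two_chain` variant estimates the second factor from a
  separate posterior chain, `-log<P^-beta>_tempered -
  log<P^(beta-1)>_posterior`; it splits the prior-to-posterior bridge into
  two half-bridges at the cost of a second chain, but both of its endpoint
  reductions are the HM, so the single-chain ratio form — the member of
  the family that actually interpolates AM to HM — is the default.
* **TI** (thermodynamic integration): `log ML` is the integral over
  beta in [0,1] of the tempered expectation of `log P(D|A,K)`, estimated
  on a uniform grid of 11 inverse temperatures (odd, for Simpson's rule)
  with one chain per grid point.  The integrand is non-decreasing in beta
  (its derivative is a variance), which the tests check.  TI is the most
  accurate estimator here and the reference the others are judged against;
  HMβ(0.5) is about five times cheaper and comparable in practice.
* **BIC** on the -BIC/2 scale, as a baseline: plug-in maximum-likelihood
  fit of the hard partition minus `(p/2) log N`, counting `k_l - 1`
  parameters per categorical column, 2 per numeric column, per cluster,
  plus K-1 mixture weights.  On well-separated benchmark data BIC often
  finds the right K, but with many weakly separated clusters its penalty
  overwhelms the fit term and it underestimates K where the sampling
  estimators still track it (tested at K=6 and K=8).

### Sampler settings

Single-site Metropolis: propose relabelling a uniform row to a uniform
other cluster, reject proposals that would empty a cluster (the prior
gives them zero mass), accept with `min(1, exp(beta * delta))` where delta
is the collapsed log-likelihood change computed from two leave-one-out
predictive evaluations.  Defaults: burn-in 10N proposals, thinning N
proposals between retained samples, M = 200 samples per chain.  At beta=0
the target is the uniform prior itself and is sampled i.i.d. exactly; this
is what makes the HMβ endpoint reductions bit-for-bit identities rather
than asymptotic statements.  On strongly peaked tiny-table posteriors
(the enumeration-oracle comparisons) the chains are run longer — M = 500,
thinning 5N, burn-in 50N — because batch-means standard errors are honest
only once the retained samples are close to independent.  The reported
`mc_error` is a 10-batch batch-means standard error of the full estimator
statistic (for TI, Simpson-weighted across temperatures).

## Synthetic benchmark data

The generators plant K clusters (default five, sizes in ratio 5:4:3:2:1 by
largest remainder, 5000 rows, 10 columns) and return the true labels:

* **Categorical**: cluster j draws level probabilities proportional to
  `v0 + Delta * v_j`, where v0 (uniform on [0.1, 0.3] per level) is shared
  and v_j is the indicator of one uniformly drawn preferred level.  Delta
  in 0.5..4.5 tunes how strongly each cluster concentrates on its own
  characteristic level.  This recipe was calibrated against the
  Bayes-optimal classifier built from the true generative parameters:
  continuous perturbation vectors of comparable scale leave even the
  oracle below ARI 0.85 at the nominally easy end, i.e. they fail to
  create a "well-separated" condition at all, whereas the preferred-level
  recipe gives oracle ARI ≈ 0.97 at Delta = 4.5 while collapsing to a
  shared distribution as Delta → 0.  Separation is monotone in Delta.
* **Numeric**: cluster j has mean `j * mean_gap` (default 1.0) and
  standard deviation `1.0 + (j-1) * dsigma`; a `same_mean` flag keeps all
  means equal so only the variances separate the clusters.
* **Mixed** (5 numeric + 5 four-valued categorical): one difficulty knob,
  `dsigma = 5.0 - Delta`, moves both halves together.
* **K-series**: equal-sized clusters for K = 2..10 at fixed Delta.
* **Supervised**: a mixed table plus a binary outcome column that is a
  cluster-specific noisy linear function of the (one-hot, standardized)
  inputs, thresholded at the within-cluster median so classes stay
  balanced.

What the generators deliberately do not emulate: correlated columns within
a cluster, non-Gaussian numeric distributions, ordinal structure, missing
data, label noise.  Passing the recovery tests therefore shows the
inference machinery works when the model family matches the data; it says
nothing about robustness to model misspecification on real tables.

## Synthetic data generation from real tables

The generator pre-clusters the input columns (never the declared output),
merges clusters of fewer than two rows into their best-scoring neighbour,
fits per cluster: observed category frequencies, Gaussian mean/sd per
numeric column (maximum likelihood), and an ordinary-least-squares model
of the output on the one-hot inputs (one reference level dropped per
categorical column) with its residual sd.  Sampling draws each cluster at
its original size, columns independently, and generates the output as the
linear prediction plus Gaussian noise — thresholded at 0.5 for a binary
output.  A logistic alternative for binary outputs (within-cluster
logistic fit, Bernoulli sampling) sits behind `binary_mode="logistic"`.
Numeric draws are unbounded Gaussians; nothing is clipped to the observed
range, so post-processing is the caller's responsibility if ranges matter.
Cluster-number selection inside the pipeline defaults to HMβ(0.5);
utility is measured by training a scikit-learn classifier (logistic
regression or random forest — instruments, not contributions) on the
synthetic table and scoring AUC on the real rows, against a real-trained
reference, averaged over fresh synthetic draws (default 20).  The
evaluation protocol defaults to resubstitution (train and test rows both
the full real table); a held-out split is the caller's choice by passing
different tables.

## Problem sizes in the checked examples

The test-suite and the acceptance script run everything at desk scale,
chosen so the whole battery completes in minutes on one core: enumeration
oracles at 12–20 rows; clustering recovery at 500 rows (five clusters,
ratio 5:4:3:2:1, Delta = 4.5); cluster-number recovery at 150 rows with
equal clusters, K in 2..5, sweeping K up to truth+1; utility at 1000 rows
with 10 seeds × 20 synthetic draws.  The generators default to the full
5000-row benchmark shape when used directly.

## Known limitations

* Columns are independent within a cluster; correlated numeric columns
  would need a multivariate model, which is out of scope here.
* Batch EM can cycle; the best-seen fallback bounds the damage but the
  sequential mode is the principled variant.
* The harmonic-mean family (including HMβ) has no finite-variance
  guarantee in general; the reported batch-means errors understate the
  uncertainty when chains mix poorly.
* BIC's parameter count treats the hard partition as a fitted mixture,
  which is a heuristic rather than a derivation.
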