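# Methods

This note documents the models implemented in `tadard`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## The inference problem

A rare variant observed in an affected individual is either *de novo*
(absent from both parental germlines) or inherited. De novo
protein-truncating variants are the strongest single source of gene-level
association signal in developmental disorders, but they can only be called
directly when both parents are sequenced. In case-only collections the
inheritance class `I` of each variant is hidden; `tadard` infers it
probabilistically and propagates the uncertainty into a gene-level Bayesian
association test.

## ClassDn: scoring inheritance class under extreme imbalance

Rare inherited variants outnumber de novo variants roughly 30:1, so the
classifier must be imbalance-aware. Two ensembles over
`sklearn.tree.DecisionTreeClassifier` base learners are implemented:

* **RUSBoost** — AdaBoost-type reweighting where each weak learner is
  trained on a 1:1 subsample (all minority-class variants plus an equal
  random undersample of the majority class) carrying the current boosting
  weights; a member with weighted error ≥ 0.5 on the full training set is
  discarded and a fresh subsample drawn. The de novo score is the
  alpha-weighted mean of member positive-class probabilities, which keeps
  it in [0, 1]. If no member ever beats chance (pure-noise labels), a
  single unweighted balanced tree is used so scores remain defined.
* **Underbagging** — bagging where each member sees a bootstrap of the
  minority class plus an equal-size majority undersample; the score is the
  unweighted mean of member probabilities.

Defaults (configurable): 100 estimators, tree depth 3, learning rate 0.5
for RUSBoost. These are conventional settings for boosted stumps-plus on
tabular data with six features; the package's checks are insensitive to
them within reasonable ranges. Every member's subsample class counts are
recorded (`subsample_class_counts_`) so the 1:1 balance is assertable.

Preprocessing: allele frequency is `log10(AF + 1e-9)`-transformed (AF spans
orders of magnitude and contains zeros); the other five covariates enter
untransformed. Rows with missing covariates are dropped at training time
with a logged count; scoring requires complete rows. Classification at
threshold `c` uses the strict rule `X = 1 iff score > c`, so a score
exactly at the threshold is "likely inherited". Sensitivity `w1` and
specificity `w2` are estimated on held-out labeled data; along any
threshold grid sensitivity is non-increasing and specificity
non-decreasing by construction.

## The Random Draw gene model

For a gene with `xd` likely-de-novo and `xh` likely-inherited case
variants, the model treats each variant as an independent Bernoulli draw
of true de novo status with probability `p1` if the gene is a risk gene
(`D = 1`) and `p0 < p1` otherwise. Marginalising the unobserved status
through the classifier gives the call rate
`q(p) = w1·p + (1 − w2)·(1 − p)`, hence binomial likelihoods
`Binom(xd; xd + xh, q(p))` under either scenario, and the Bayes factor

    BF_RD = ∫ Binom(xd; n, q(p1)) dP1(p1) / ∫ Binom(xd; n, q(p0)) dP0(p0).

Two structural properties follow and are enforced by tests: a degenerate
classifier (`w1 = 1 − w2`, calls independent of truth) gives `BF = 1` for
all counts, and with prior mean of `p1` above that of `p0` the BF is
non-decreasing in `xd` and non-increasing in `xh` — each additional
likely-inherited variant is evidence *against* risk, which is the model's
key difference from case-control contrasts.

**Priors.** `P1` and `P0` accept point masses or Beta distributions. The
default is Beta with means 0.603 (risk) and 0.026 (non-risk) and total
concentration 10, i.e. Beta(6.03, 3.97) and Beta(0.26, 9.74). The means
are the observed de novo fractions among case variants in risk vs
non-risk genes in large family-based autism cohorts; the concentration
encodes moderate uncertainty around them and is configurable, including
collapse to point masses. The de novo fractions are treated as
mutation-rate-independent by default; per-gene priors can be supplied by
calling the scalar API per gene.

**Quadrature.** Beta-prior marginals are computed by 128-node
Gauss–Jacobi quadrature whose weight function is the Beta kernel itself
(`scipy.special.roots_jacobi` with `alpha = b − 1`, `beta = a − 1`, mapped
to [0, 1]), self-normalised so the Beta constant cancels. Because the
binomial integrand is a polynomial of degree `n = xd + xh`, the rule is
*exact* for `n < 255`, and Beta shapes below 1 — the default `p0` prior is
endpoint-singular — cost no accuracy, unlike generic Gauss–Legendre
nodes. Agreement with a 10⁶-draw Monte-Carlo integral is within its
sampling error (≲ 0.5% relative). All likelihoods are evaluated in log
space; Bayes factors are clamped to [1e−12, 1e12] with a logged warning.

## Family-based de novo Bayes factor and integration

The trio evidence per gene follows the classical transmitted/de novo
association model: `x ~ Poisson(2·N·μ·γ)` over `N` trios with per-
chromosome mutation rate `μ`; under H1 the relative risk has a
`Gamma(γ̄·β, rate β)` prior, making the H1 marginal negative-binomial and
the BF closed-form (verified against direct quadrature over γ to < 0.1%).
Defaults `γ̄ = 20`, `β = 1` are conventional for haploinsufficient
developmental-disorder genes; real analyses should set them deliberately.

Evidence streams are combined as `BF_final = max(BF_family, 1) ×
max(BF_RD, 1)`: flooring prevents absence of signal in one stream from
down-weighting the other (uniformly applied in both simulations and data
analysis). With prior risk proportion `π` (default 0.06) the posterior is
`π·BF/(π·BF + 1 − π)`; genes are ranked by BF (ties broken
lexicographically by gene identifier for determinism) and the q-value of
rank `i` is the cumulative mean of `1 − posterior` over the top `i` genes,
forced monotone down the ranking. Selection uses `q < 0.05` and,
alternatively, a Bonferroni rule. A q-to-p inversion is not unique; the
package inverts the Benjamini–Hochberg relation, `p_i = q_i · rank_i / m`,
an order-preserving documented convention under which the Bonferroni set
is provably a subset of the FDR set at equal α. With `BF_RD ≡ 1` the
pipeline reduces exactly to the family-only ranking.

## Synthetic data: what it emulates and what it does not

The generator produces the three table kinds the pipeline consumes, with
one gene table (lognormal mutation rates, Bernoulli risk flags) underlying
all of them for a given configuration seed.

* Per-gene variant counts are negative-binomial with mean proportional to
  the gene's mutation rate and dispersion `count_dispersion` (default 4);
  the lognormal sd of mutation rates defaults to 1.2, reflecting the 2–3
  orders of magnitude spanned by real per-gene PTV mutation rates.
* Labels: labeled (family-style) tables draw each variant's class
  Bernoulli with the gene's de novo fraction — defaults 0.603 in risk
  genes, 0.026 elsewhere, 5% risk genes. Case tables instead fix the
  hidden de novo count at `round(fraction × n_variants)`
  (half-away-from-zero, floored at 0, capped at `n`) and attach Gaussian
  scores `N(0.6, 0.1)` / `N(0.2, 0.1)` (variances) to de novo / inherited
  variants; scores are not clipped to [0, 1] and thresholding acts on the
  real line. Null tables use the background fraction (0.026) everywhere
  with no risk genes.
* Covariates are drawn from label-conditional univariate distributions
  (lognormal AF clipped strictly below the 0.001 rarity bound, scaled-Beta
  LOEUF and FDR, truncated-normal CCR, Poisson obs_lof, Gamma exp_lof)
  whose class separations (~1 SD each, in the directions seen in real
  family data: de novo variants rarer, in more constrained genes/regions)
  are validated at construction.

Not emulated: joint covariate dependence (real covariates are strongly
correlated through gene identity), family structure, sequencing error, and
realistic classifier difficulty — the six independent covariates make the
synthetic classes nearly separable (held-out AUC ≳ 0.99), whereas real
classifiers of this kind are far weaker (sensitivities below 0.4 at high
thresholds). Consequently, passing tests demonstrate correctness of the
machinery and the model's qualitative behaviour, not field performance on
real cohorts.

## Simulations

`gaussian_threshold_performance` gives the analytic
`w1(c) = 1 − Φ((c − 0.6)/√0.1)`, `w2(c) = Φ((c − 0.2)/√0.1)`; the power
simulation treats these as known, as the score distributions are part of
the design. Both simulations analyse genes with the *default Beta priors*
(the same priors as the data pipeline), not the generating point
fractions; a `priors` argument accepts alternatives, including
`generation_matched_priors` point masses.

* **Power**: per replicate, scores are drawn once and swept over the
  threshold grid (paired comparisons); RD BFs are combined with one fixed
  family draw (relative risk γ̄ in risk genes) and discoveries are genes
  with `q < 0.05`. Reported against the family-only baseline
  (`BF_RD ≡ 1`). At the default desk scale (800 genes, 2400 case
  variants, 10,000 trios, 50 replicates) the RD step adds about 1–3
  discoveries at `c = 0.7`, which is also the best-performing threshold.
* **Null**: replicates with no case signal anywhere. Default design:
  family counts redrawn signal-free per replicate; alternatively a fixed
  (possibly signal-bearing) family BF vector with a designated true-gene
  set is supported, and a classifier-based variant scores fresh null
  covariate tables with a fitted ClassDn model. The per-family error rate
  (PFER) is the mean number of false selections per analysis.

**A calibration fact worth knowing:** under the Gaussian score model with
correctly specified priors the null analysis is (nearly) well calibrated,
so `P(BF > K | null) ≤ 1/K` at *every* threshold — the PFER is small
(~0.1 under the Bonferroni rule) and essentially flat in `c`. A markedly
decreasing PFER with threshold arises only when the false-call rate
collapses with `c` much faster than the per-call evidence grows, as it
does for weak, conservative real-data classifiers; the parametric null
here cannot and does not reproduce that trend, and one test documents
this expectation gap. The desk-scale problem sizes above were chosen so
the full suite runs in seconds while leaving clear margins on the
bounds-type checks.

## Known limitations

* The RD model assumes exchangeable variants within a gene and a single
  genome-wide `(w1, w2)`; covariate-dependent classifier accuracy would
  bias gene-level counts in ways the model does not capture.
* `(w1, w2)` are plugged in as known; their estimation error on finite
  test sets is not propagated into the Bayes factor.
* The q→p inversion for the Bonferroni rule is a convention, not a
  probability statement; treat the Bonferroni flags as a stricter ordinal
  cut of the same ranking.
* Model persistence uses Python pickle and is not portable across major
  library versions.
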