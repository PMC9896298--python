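# Methods

This note records the statistical model behind `popwise`, the package's
numerical choices, what the built-in simulator does and does not emulate,
and the design decisions taken where more than one reasonable option
existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and error criterion

An overall population is the union of $m$ possibly overlapping target
populations $P_1,\dots,P_m$; each carries a treatment policy and a
one-sided null $H_i: \theta_i \le 0$ tested by a statistic $Z_i$. The
populations induce disjoint strata $P_J$, $J \subseteq \{1,\dots,m\}$, with
relative prevalences $\pi_J \ge 0$, $\sum_J \pi_J = 1$. The population-wise
error rate at a common critical value $c$ under a truth configuration with
true-null index set $I(\theta^*)$ is

$$\mathrm{PWER}(c) = \sum_J \pi_J \,
P\Big(\bigcup_{i \in J \cap I(\theta^*)} \{Z_i \ge c_i\}\Big),
\qquad c_i = w_i c,$$

with equal weights $w_i = 1$ unless the user specifies otherwise. Strata
whose intersection with $I(\theta^*)$ is empty contribute zero — explicit
in the code so no empty maximum is ever formed. The criterion is an average
of strata-wise family-wise error rates and hence never exceeds the FWER;
the two coincide exactly when a single stratum carries the whole population.

**Least favourable configuration.** Calibration defaults to the global
null, which maximizes the PWER under subset pivotality (contrast z- or
t-statistics with variance homogeneous across arms and strata — the
settings this package targets). Other truth configurations are supported
but must be supplied explicitly.

**Joint null models.** The statistics are multivariate normal with unit
marginals, or multivariate $t$ when a pooled residual variance is
estimated, with a correlation matrix determined by the design:

* *two overlapping populations, shared control*: with equal complement
  prevalences, $\rho = \tfrac32 \pi_{\{1,2\}}/(1+2\pi_{\{1,2\}})$ for
  different treatments (1:1 complements, 1:1:1 intersection,
  prevalence-weighted mean estimators) and
  $\rho = 2\pi_{\{1,2\}}/(1+\pi_{\{1,2\}})$ for one treatment (1:1 per
  stratum, pooled means); the single-treatment correlation dominates for
  every overlap. Asymmetric counts go through
  `nulldist.corr_two_pop_from_counts`, which generalizes both formulas to
  realized stratum counts with fractional arm splits (the appropriate
  treatment when conditioning on the counts).
* *nested chain with one treatment and prevalence-proportional sample
  sizes*: $\operatorname{Corr}(Z_i, Z_j) = \sqrt{\pi_j/\pi_i}$ for
  $j > i$, the inner statistic being a sub-sample contrast of the outer.
* *umbrella*: all $2^\ell - 1$ subset statistics
  $T_S = \hat\theta_S / \widehat{\mathrm{SE}}(\hat\theta_S)$ with
  $\theta_S = \sum_{i \in S} (\pi_i/\pi_S)\,\theta_i$ from one
  least-squares fit of $Y_{ij} = \mu_i + \theta_i X_{ij} + \varepsilon_{ij}$,
  jointly $t$ with $N - 2\ell$ degrees of freedom and correlations from the
  contrast vectors and per-stratum arm sizes.

## Calibration

$\mathrm{PWER}(c)$ is continuous and strictly decreasing for continuous
joint nulls, so $c^\*$ is found by bracketed Brent root-finding. With equal
weights and identical marginals the root is guaranteed inside
$[z_\alpha,\, z_{\alpha/k} + 1]$: the threshold can neither fall short of
the marginal $(1-\alpha)$-quantile nor exceed the Bonferroni value. The
bracket expands geometrically as a fallback for weighted models. Absolute
tolerance on $c^\*$ is $10^{-10}$; after the root is located the value is
nudged upward (in steps of $4 \times 10^{-10}$) if the achieved rate still
exceeds $\alpha$ at the $10^{-10}$ level, so `achieved <= alpha` holds up
to quadrature error.

Adjusted p-values invert the same map: $p_j$ is the PWER evaluated at the
common value $c = z_j^{\mathrm{obs}}/w_j$, the smallest level at which
$H_j$'s own weighted threshold is crossed; $p_j \le \alpha \iff
z_j^{\mathrm{obs}} \ge w_j c^\*$ by monotonicity.

**Complementary PWER and strata-wise error.** For a stratum $P_J$,
$\mathrm{cPWER}_J(c) = \sum_{J' \ne J} \tilde\pi_{J'}
P(\max_{j \in J'} Z_j \ge c)$ with $\tilde\pi_{J'} = \pi_{J'}/(1-\pi_J)$ is
the PWER after removing $P_J$ and renormalizing. Its level-$\alpha$
threshold $d_J^\*$ approximates the stratum's realized FWER under full
PWER-control with an error vanishing linearly in $\pi_J$ (verified
numerically in the test suite on a nested family with the complement
proportions held fixed as the innermost prevalence shrinks through
$0.02,\dots,0.0025$). The per-stratum report carries the realized
$\mathrm{FWER}_J(c^\*)$ alongside all analytic bounds.

## Multivariate tail probabilities

* dimension 1: exact normal / $t$ survival functions;
* dimension 2, normal: Owen's-T closed form (`scipy.special.owens_t`),
  exact to machine precision and sub-millisecond — this is what makes the
  count-cached robustness study and the closed-form/root-finder agreement
  checks at $10^{-8}$ feasible;
* dimension ≥ 3 (normal) and ≥ 2 ($t$): scipy's randomized
  quasi-Monte-Carlo quadrature with a fixed internal seed, so every call is
  bit-reproducible. Defaults: absolute tolerance $10^{-8}$ with a
  $2\times10^7$ point budget for normal models; a $1.5\times10^6$ point
  budget (accuracy around $10^{-6}$) for $t$ models, where scipy exposes no
  tolerance control. Both are per-model overridable.

Subset statistics can be exact linear combinations of each other (an
umbrella union statistic is a weighted sum of its stratum statistics), so
correlation sub-matrices may be singular. scipy's integrators require
positive definite shape matrices; sub-matrices with smallest eigenvalue
below $10^{-8}$ receive a $10^{-6}$ diagonal ridge (renormalized), which
perturbs rectangle probabilities by roughly $10^{-7}$ — below quadrature
tolerance, and cross-checked against Monte-Carlo rejection counting in the
tests.

## The trial simulator

`trial_simulator` draws subject-level data: stratum membership either
deterministic (largest-remainder rounding of $N\pi_J$ — the design
assumption that samples mirror prevalences, used by the power studies) or
multinomial (used by the robustness study); arms allocated 1:1 per stratum
(1:1:1 with a shared control in the intersection under different
treatments), with largest-remainder splits that leave every arm within one
subject of its exact share, leftover units going to control first; outcomes
$Y = \mu_J + \theta_{\mathrm{arm}} + \varepsilon$,
$\varepsilon \sim N(0, \sigma^2)$ i.i.d. Same seed, same call: byte-identical
output.

It deliberately does **not** emulate: non-normal endpoints,
variance heterogeneity across strata or arms, dropout, interim analyses,
off-label treatment use, or covariate-dependent allocation. Tests passing
against this generator therefore certify the error-rate arithmetic and the
calibration under the stated normal homoscedastic model, not robustness to
those real-data features.

## Simulation studies and default parameters

| parameter | default | meaning |
| --- | --- | --- |
| $\alpha$ | 0.025 | one-sided PWER/FWER level |
| $\beta$ | 0.2 | type-II rate for inflation factors (80% marginal power) |
| $\sigma$ | 1 | residual standard deviation (outcome units) |
| $N$ | 1056 | umbrella total sample size |
| $\theta_{\mathrm{overall}}$ | 0.1 | weighted mean positive effect (outcome units) |
| replicates | 10,000 | umbrella performance and robustness studies |

The umbrella benchmark magnitudes (e.g. detection power in the mid-30s
percent at $N = 1056$, $\theta = 0.1$) correspond to $\sigma = 1$; the
value is configurable. Effect configurations are parameterized by the
fraction $q$ of true nulls, the relative half-range
$\tau = (\theta_{\max}-\theta_{\min})/(\theta_{\max}+\theta_{\min})$ of the
positive effects, and $\theta_{\mathrm{overall}}$; these pin down a unique
equidistant effect grid ($q\ell$ zeros, then $\ell - q\ell$ equidistant
values from $\theta_{\mathrm{overall}}(1-\tau)$ to
$\theta_{\mathrm{overall}}(1+\tau)$; $\tau = 0$ is forced with at most one
positive effect). Performance measures: power
$= P(\text{reject any } H_S \text{ with } \theta_S > 0)$; the mean
prevalence fractions of correctly ($\theta_i > 0$) and falsely
($\theta_i \le 0$) selected strata within the argmax selection (0 when
nothing is selected — this convention makes the falsely-selected fraction
equal the realized FWER under the global null); and the relative average
effect $\mathrm{RAE} = 100\,E(\sum_{i\in S^*}\pi_i\theta_i)/
\theta_{\mathrm{overall}}$, reported as 0 under the all-null configuration
where $\theta_{\mathrm{overall}}$ is undefined. Both calibrations are
evaluated on the same simulated trials (common random numbers), so the
dominance relations (the FWER procedure's non-empty selection is always the
PWER procedure's selection; RAE is never smaller under PWER-control) hold
replicate by replicate. Ties in the argmax go to the smaller cardinality,
then lexicographic order — immaterial for continuous statistics, fixed for
reproducibility.

**Estimated prevalences.** The robustness study draws stratum counts
$\sim \mathrm{Multinomial}(N, \pi)$, calibrates $c$ from the ML estimates
$\hat\pi_J = n_J/N$ together with the correlation implied by the *realized*
counts (conditioning on the counts is what makes the plug-in calibration
asymptotically valid), then records the true PWER of that threshold — true
prevalences, same conditional correlation. A stratum drawing zero count
simply drops out of the calibration; a population with no patients at all
has no statistic, its hypothesis is untestable in that replicate, and the
remaining hypothesis is tested at the marginal quantile. An optional
prevalence floor $\pi_{\min}$ (applied to the estimates and renormalized by
proportionally shrinking the unfloored strata — the redistribution rule is
a package choice, flagged here because other rules are defensible) restores
conservatism against empty intersections. Because the threshold depends on
the data only through the count vector, replicates with equal counts share
one calibration (cached), which keeps the full grid-by-replicate study in
the seconds-to-minutes range.

## Simultaneous confidence intervals

Only Wald-type pivots are shipped: $\tilde\theta_i = \hat\theta_i - c^\*
\mathrm{SE}_i$ (lower), mirrored upper bounds, and two-sided intervals from
intersecting the two one-sided constructions — the two-sided interval at
level $\alpha$ uses the $\alpha/2$ one-sided threshold, since its
non-coverage is twice the one-sided one. The general construction
$\tilde\theta_i = \min\{\delta : T_i^{\delta} \le c^\*\}$ is exposed for a
user-supplied monotone statistic family via bisection
(`sci.invert_statistic_family`); the search bracket must come from the
caller since nothing constrains it in general. Coverage is *average
simultaneous*: $\sum_J \pi_J P(\tilde\theta_j \le \theta_j \;\forall j
\text{ affecting } J) \ge 1-\alpha$ — a prevalence-weighted guarantee for a
randomly drawn patient, weaker than classical simultaneous coverage over
all $m$ parameters at once.

## Design decisions and conventions

* Index subsets are canonical sorted tuples of 1-based indices; files use
  the `"1+2"` string dialect.
* Zero-prevalence strata are dropped with a logged warning (they contribute
  nothing to any error rate); with a floor they are raised instead.
* Input prevalence sums are accepted within $10^{-6}$ (hand-entered tables)
  and renormalized exactly; internal invariants hold to $10^{-9}$.
* For two independent samples the FWER threshold is Šidák's
  $c_F^\* = \Phi^{-1}(\sqrt{1-\alpha})$ — the exact solution of
  $1 - \Phi(c)^2 = \alpha$ — giving the flat $\approx 21\%$ inflation
  benchmark; the PWER threshold has the closed form implemented in
  `two_pop_designs.critical_value_independent`, which the generic
  calibrator reproduces to $10^{-8}$.
* The closed-form two-population correlations assume equal complement
  prevalences; asymmetric cases must go through the counts-based helper.
* Umbrella stratum sample sizes use largest-remainder rounding of $N\pi_i$;
  subsets are enumerated by cardinality then lexicographically, fixing
  matrix and output layouts.

## Known limitations

* Single-stage, single-step procedures only: no step-down refinement (none
  uniformly improves the single-step PWER test) and no group-sequential or
  adaptive extensions.
* Homogeneous variance across strata and arms; no resampling-based null
  distributions.
* The umbrella module guards at $\ell \le 12$ (subset enumeration is
  $2^\ell$); quadrature cost grows steeply with the number of jointly
  evaluated statistics, and calibrations in 8–15 dimensions take tens of
  seconds at default budgets.
* The robustness study ships for the two-population scenarios; larger
  structures can be composed from the same primitives but have no packaged
  grid study.
* Prevalence estimates are treated as the trial's own multinomial counts;
  external prevalence sources are accepted as inputs but not fetched or
  meta-analysed.
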