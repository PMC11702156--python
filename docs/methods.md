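# Methods

## Model and selection problem

We consider a generalized linear model $h(E[Y\mid X]) = \beta_0 + X\beta$
with $n$ observations, $p$ candidate regressors and a sparse true active
set $A^*$; the family is Gaussian with identity link (unit noise variance
in simulations) or Bernoulli with logit link. Selection means choosing a
support $\hat A$; we measure it by the family-wise error rate
(probability that $\hat A$ contains any inactive variable), the false
discovery rate (expected proportion of inactive variables in $\hat A$,
zero when nothing is selected), and sensitivity
($|\hat A \cap A^*| / |A^*|$).

## The critical bound and the extended AIC

Adding one variable to a support changes the maximal log-likelihood by
$\Delta l$, asymptotically Gamma(1/2, 1) under the null (Wilks), with CDF
$F(x) = \operatorname{erf}(\sqrt x)$. Scanning $q$ independent candidates
and accepting any with $\Delta l > x$ has FWER $1 - F(x)^q$. The bound

$$x_{q,\alpha} = \log q - \tfrac12\log\log q - \log(-\log(1-\alpha)) - \tfrac12\log\pi$$

satisfies $F(x_{q',\alpha})^q \to 1-\alpha$ for any $q' \sim q$, which is
what licenses replacing the true (support-dependent) number of implicit
tests $q = p - |A|$ by the fixed proxy $q' = p$. The extended AIC is the
linear-penalty criterion with weight $2 x_{p,\alpha}$. Minimizing any
linear-penalty criterion over a nested pair is exactly a likelihood-ratio
test at threshold weight/2; this identity is asserted in the tests.

Closed-form consequences used throughout: the simplification level
$\alpha_0 = 1-e^{-1/\sqrt\pi}$; the RIC coincidence
$\alpha_{\mathrm{RIC}}(p) = 1-e^{-1/\sqrt{\pi\log p}}$; the mAIC
coincidence $\alpha_{\mathrm{mAIC}}(p,c) = 1-e^{-(c/e)/\sqrt{\pi\log p}}$
and its inverse $c(p,\alpha) = -e\sqrt{\pi\log p}\,\log(1-\alpha)$; and
the BIC equivalence level solving $2x_{p,\alpha} = \log n$. All are
implemented as closed forms, not iterative solvers, so the coincidence
identities hold to machine precision. Note the known large-$p$
approximation $\alpha_{\mathrm{RIC}}(p) \approx 1/\sqrt{\pi\log p}$
differs visibly from the exact form already at $p = 10^4$ (0.186 vs
0.170); this package always reports the exact solution.

The approximate BIC FWER under a sparse truth,
$1-\exp(-p/\sqrt{\pi n \log(n)/2})$, follows from the Gaussian tail of
$F$; it tends to 1 whenever $p$ grows faster than $\sqrt{n\log n}$ —
including $p \propto n$ — and to 0 below that rate.

## Numerical choices

- $F$ is evaluated as $\operatorname{erf}(\sqrt x)$ and its tail as
  $\operatorname{erfc}(\sqrt x)$; $F(x)^q$ as
  $\exp(q\,\mathrm{log1p}(-\mathrm{erfc}(\sqrt x)))$. Naive
  $1 - \mathrm{CDF}$ underflows at the $q = 10^6$ scales the limit checks
  require.
- The bound is defined for $q \ge 3$; $q = 2$ (where $\log\log q < 0$) is
  accepted with a warning rather than an error, $q < 2$ rejected.
- Model size counts candidate regressors only; the intercept (and the
  profiled Gaussian variance) is in every model. This keeps the
  nested-difference identities (e.g. AIC difference $= 2 - 2\Delta l$)
  exact and matches the null scan's one-degree-of-freedom tests.
- Linear log-likelihoods use the profiled variance MLE,
  $l = -\tfrac n2(\log(2\pi\,\mathrm{RSS}/n)+1)$, so $\Delta l$ equals
  the classical LR statistic $\tfrac n2\log(\mathrm{RSS}_0/\mathrm{RSS}_1)$.
  Whether one profiles or fixes $\sigma^2 = 1$ is immaterial to the
  asymptotics; profiling keeps the criteria defined for generic data.
- Logistic fits use scikit-learn's unpenalized LBFGS solver with a 1000
  iteration cap; under complete separation the fit is retained at the
  optimizer's stopping point and flagged `converged=False` — dropping such
  models would bias selection toward the null.
- EBIC penalty: $\log(n)|A| + 2\gamma\log\binom{p}{|A|}$ via log-gamma,
  $\gamma = 1$ default. The binomial term vanishes at $|A| \in \{0, p\}$.
- Ties in criterion minimization go to the smaller support, then the
  earlier path position (conservative and deterministic).

## LASSO pre-selection

The candidate family is the set of distinct supports along a coordinate
descent LASSO path: 100 regularization values, geometric from
$\lambda_{\max}$ (all-zero solution) down to $10^{-2}\lambda_{\max}$ when
$n < p$ and $10^{-4}\lambda_{\max}$ otherwise, columns standardized
internally, path truncated at the first support larger than
`dfmax` (default 100). These mirror the defaults of the standard
coordinate-descent implementations. Duplicate supports are scored once
(criteria depend only on the support); the empty support is always a
candidate. Each support is then refit by unpenalized maximum likelihood —
scoring the shrunken LASSO coefficients instead would deflate the
log-likelihood of the sparser, more-penalized models and distort every
criterion.

## Synthetic data generator

The generator emulates the simulation design the criteria are meant for:

- **Design**: rows i.i.d. $N(0, \Sigma)$ with Toeplitz
  $\Sigma_{ij} = \rho^{|i-j|}$, $\rho \in \{0, 0.5\}$, drawn by the AR(1)
  recursion in $O(np)$.
- **Coefficients** (full study): 10 active variables uniform among $p$;
  raw magnitudes $|\tilde\beta_j| \sim U(0.25, 1)$ with independent fair
  signs.
- **SNR calibration**: the empirical signal-to-noise ratio is the
  $(n-1)$-divisor variance of the conditional means over the mean
  conditional variance. Linear: intercept 0 and closed-form scale
  $k = \sqrt{\mathrm{target}/\mathrm{SNR}(\tilde\beta)}$ (exact). Logistic:
  $(k, \beta_0)$ solve $\{\mathrm{SNR} = \mathrm{target},\ \bar\mu = 1/2\}$
  by Powell-hybrid root-finding on $(\log k, \beta_0)$, accepted only if
  the residual is below $10^{-6}$. The $\bar\mu = 1/2$ constraint is our
  choice to close the otherwise under-determined two-unknown system; it
  matches the balanced Bernoulli(1/2) null design. Linear simulations use
  $\beta_0 = 0$ (the linear SNR is intercept-free).
- **Null study**: outcome drawn independently of the design; the selector
  scans $\{\emptyset\} \cup \{\{j\}\}$ with the EAIC. At $p \ge 10^4$ the
  scan keeps only columns whose $|\mathrm{cor}(Y, X_j)|$ is within 90% of
  the maximum — in the linear family the scan winner always survives this
  screen, so it changes nothing but cost.

What the generator does **not** emulate: binary/sparse exposure matrices
(real spontaneous-reporting data are 0/1 and heavily skewed), heavy-tailed
noise, model misspecification, and non-Toeplitz dependence. Passing tests
therefore show FWER control under the stated Gaussian designs, not on
arbitrary real data — on correlated designs the paper-scale grids already
show deviations at moderate $n$.

Determinism: replicate $r$ of a study seeded $s$ draws from
`SeedSequence(s, spawn_key=(r,))`, so aggregation is order-independent and
extending a study never perturbs existing replicates. Redrawn (failed)
replicates use spawn keys beyond the replicate range.

## Implementation notes on the scans

The null study at 1000 replicates uses vectorized single-column fits: the
linear $\Delta l_j$ in closed form from Pearson correlations
($-\tfrac n2\log(1-r_j^2)$), the logistic ones by a damped 2-parameter
Newton iteration run simultaneously across columns. Both are tested for
equivalence (at $10^{-8}$) against the generic per-support refit route.

## Problem sizes and defaults

Library defaults follow the study design: `dfmax=100`, EAIC level 0.05,
mAIC $c = 1/2$, mBIC $E = 4$, EBIC $\gamma = 1$, 10 active variables,
1000 replicates. The bundled acceptance script runs the four
$p = 100$ null-study cells at full 1000-replicate scale; the full-procedure
checks in the test suite use one setting (linear, $n = 10^3$, $p = 10^2$,
SNR 1) at 200 replicates — enough for the conservativeness ordering
AIC $\ge$ BIC $\ge$ EAIC(0.5) $\ge$ EAIC(0.05) and the AIC's FWER $\approx 1$
to resolve far beyond Monte-Carlo noise, while the complete
308-setting grid remains a cluster-scale exercise runnable through
`eaic full-study` configs.

## Known limitations

- FWER control is asymptotic in both $n$ and $p$ and assumes independent
  tests. At $n = 100$ with strong signals (models of size ~10) the
  chi-square approximation degrades and the EAIC's realized FWER can
  exceed $\alpha$; correlated designs push the same way. This is a
  property of the method, reproduced — not fixed — here.
- The logistic null scan at $n = 100$ runs slightly above the analytic
  asymptote for the same reason.
- Only linear and logistic families are implemented; the theory extends to
  other GLMs but none are simulated.
- The criteria quantify multiplicity through the raw count $p$; with
  correlated regressors an effective number of tests would be a natural
  refinement and is deliberately out of scope.
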