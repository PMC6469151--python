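# Methods

## Model and score tests

Outcomes are i.i.d. from an exponential-family density
f(y; θ, φ) = exp{(yθ − b(θ))/a(φ) + c(y, φ)} with mean μ = b′(θ) and
variance b″(θ)a(φ). The canonical parameter of the working model for
coding *k* is θᵢ = γ**Z**ᵢ + β_k **X**ᵢ(k), where **Z**ᵢ is the adjustment
design (intercept first) and **X**ᵢ(k) = g_k(Xᵢ) the coded block with
m_k − 1 columns for an m_k-class categorisation, one column for a
dichotomy or Box-Cox transform, and m columns for a degree-m fractional
polynomial. Four family/link pairs are supported: gaussian-identity,
binomial-logit, binomial-probit, poisson-log. Probit, the one
non-canonical link, is handled through the general (dμ/dη)-weighted score
rather than a canonical-link shortcut.

The null model (β_k = 0, all k) is fitted once by iteratively reweighted
least squares with step-halving, so the deviance is non-increasing across
iterates; convergence is declared when the relative coefficient change
drops below `tol` (default 1e-9). The gaussian dispersion is estimated by
maximum likelihood, φ̂ = RSS/n, for consistency with the parametric
bootstrap, which simulates from the ML null fit; an unbiased RSS/(n−q)
option exists.

Each coding is tested with the Rao efficient score using **expected**
information: U_k = X(k)′ D V⁻¹(y − μ̂)/a(φ̂) with D = diag(dμ/dη), and null
covariance V_k = X̃_k′ W X̃_k where W = diag((dμ/dη)²/(V(μ̂)a(φ̂))) and X̃_k
is X(k) with the adjustment directions projected out under the W inner
product. 1-df codings report the signed statistic T_k = U_k/√V_k with
two-sided normal p-value; multi-df blocks report the quadratic form
Q_k = U_k′V_k⁻¹U_k on m_k − 1 (or m) df. Expected information is what
makes the joint law of (T₁,…,T_K) asymptotically N(0, R) with R available
in closed form, which the exact correction integrates; observed-information
variants would not change the asymptotics but would lose that closed form.

## Corrections

* **Bonferroni**: min(1, K·p_min).
* **Exact (maxT)**: with R[k,l] = X̃_k′WX̃_l/√(X̃_k′WX̃_k · X̃_l′WX̃_l), the
  adjusted p-value is 1 − P(−t_max < Z_k < t_max ∀k), Z ~ N(0, R),
  t_max = maxₖ|t_k|. The rectangle is symmetric because the individual
  tests are two-sided. The probability is computed by the Genz–Bretz
  quasi-Monte-Carlo algorithm (scipy's multivariate normal CDF) with three
  fixed internal seeds: the mean of the three evaluations is reported, half
  their range plus the target tolerance (default 1e-5) is the quoted
  integration error, and fixed seeds make the result fully deterministic.
  The value is finally projected into its analytic envelope
  [p₁, min(1, K·p₁)] (single-test and Bonferroni bounds, both exact), so
  the ordering p_min ≤ p^exact ≤ p^Bonf holds without integration slack.
  The method requires every coding to contribute one df; menus containing
  multi-class categorisations or FP of degree ≥ 2 mark it not-applicable.
* **Permutation minP**: valid under exchangeability of X given (Y, Z); the
  X column alone is permuted. The null fit is reused because H₀ does not
  involve X. Every supported coding is a pointwise transform whose
  thresholds depend only on the marginal sample of X, which permutation
  leaves unchanged, so re-deriving codings on permuted X equals
  row-permuting the original design — the implementation exploits this and
  a degenerate-replicate counter (necessarily zero for quantile and raw-cut
  menus) is kept and asserted in tests.
* **Parametric bootstrap minP**: outcomes are simulated from the fitted
  null (Bernoulli(μ̂ᵢ), Poisson(μ̂ᵢ), Normal(μ̂ᵢ, φ̂)); X and Z stay fixed so
  codings are realised once; each replicate re-fits the null and recomputes
  all K tests. Replicates whose re-fit fails are redrawn and counted; more
  than 1% failures aborts with a data-quality error.

Both resampling estimators use the strict-inequality form
p̂ = (1/B)Σ 1{p*ᵇ_min < p_min}, reported with the Monte-Carlo standard
error √(p̂(1−p̂)/B). Because the plain estimator can return exactly 0, an
opt-in add-one variant (Σ+1)/(B+1) is provided (default off). Permutation
and bootstrap streams are derived from the one user seed through distinct
fixed spawn keys, so requesting both never couples their randomness; a
seed is mandatory whenever a resampling method is requested. The
resampling replicates are processed in vectorised chunks (batched IRLS
across simulated outcome columns; batched score algebra across permuted
designs), which is an implementation detail — a chunked run is bitwise
identical for a given seed regardless of chunk boundaries except through
the fixed chunk size constant, which is part of the algorithm's definition.

**Best coding**: the label with the smallest individual p-value
(equivalently the largest |T_k| on 1-df menus). Exact ties resolve to the
first coding in menu order and raise a tie flag in the report.

## Codings

* Quantiles are linear-interpolation ("type 7") sample quantiles — the
  convention is fixed and documented because different quantile types move
  realised cutoffs on small samples.
* A value exactly equal to a threshold always joins the upper class
  (indicator X ≥ c), for dichotomies and categorisations alike.
* Auto-menus: `nb_dicho = n` gives dichotomies at levels j/(n+1) (median;
  terciles; quartiles; …). `nb_categ = n` gives categorisations of
  increasing resolution, the j-th using the full interior quantile set of
  order j+2 (terciles → 3 classes, quartiles → 4, quintiles → 5, …).
* Box-Cox: (X^λ − 1)/λ for λ ≠ 0 and ln X at λ = 0, requiring X > 0 (a
  hard error otherwise — no silent shifting). The classical λ table's
  negative entries (−0.5, −1) are covered by the same power formula, which
  is monotone-equivalent to the reciprocal transforms.
* Fractional polynomials: powers from the Royston–Altman set
  {−max(3,m), …, −2, −1, −0.5, 0, 0.5, 1, 2, …, max(3,m)}, columns built by
  the recursion H_j = X^(a_j) if a_j ≠ a_{j−1} else H_{j−1}·ln X, with
  X^(0) = ln X and H₀ = 1. If min(X) ≤ 0 the sample is shifted by
  ζ = min(X) − δ, δ the smallest positive gap between distinct sorted
  values (an approximation to the lower limit of the sample's rounding
  interval); the user may override ζ and the realised value is recorded in
  the report.
* Degenerate codings — a constant indicator column, an empty class — are
  hard errors naming the coding, never silent drops: dropping one would
  change K and therefore every correction.
* `dicho`/`nb_dicho` and `categ`/`nb_categ` are mutually exclusive
  configuration keys; NA-padded rows are accepted in the `categ`,
  `cutpoint` and `fp` matrices.

## Synthetic scenarios

The generator draws independent standard-normal adjustment covariates and
a variable of interest that is lognormal(0, 0.5) by default — positive
support so Box-Cox and FP codings apply unshifted; normal and uniform
options exercise the shift path. Effects on the linear predictor are
`none` (Y ⊥ X | Z by construction), `threshold` (a shift δ above the
τ-quantile of X, the classic change-point alternative dichotomisation is
meant to catch), or `smooth` (δ times a named Box-Cox/FP transform).
`binomial_intercept` solves the intercept for a target marginal prevalence
by Gaussian quadrature over the adjustment combination, which is how the
case-control style scenario (n = 311 at ~10.6% prevalence, i.e. ~33 cases)
and the calibration scenarios (prevalence 0.3) are parameterised.

What the generator does **not** emulate: correlated or non-normal
adjustment covariates, measurement error in X, longitudinal or matched
structure, and informative missingness. Passing calibration tests on
these scenarios therefore demonstrates correctness of the procedures
under clean exchangeable sampling, not robustness to those features.

## Calibration study sizes

The test suite checks type-I error on the null binomial scenario (n = 300,
prevalence 0.3, one adjustment covariate, menu of four dichotomies at
levels 0.2/0.4/0.6/0.8) with 1000 Monte-Carlo replicates at B = 500,
asserting each resampling/exact rejection rate falls in the 95% binomial
band around 0.05, and power ordering under a 0.8 log-odds threshold
alternative with 500 replicates. The acceptance script uses 300 and 200
replicates at B = 300 for the same two studies — sizes chosen so a full
run stays in the minutes range on one CPU while keeping Monte-Carlo error
around one percentage point.

## Numerical choices and limitations

* IRLS: mean-based initialisation, step-halving, relative-change tolerance
  1e-9, cap 100 iterations (50 inside bootstrap replicates); rank
  deficiency of Z is detected by pivoted QR and reported with the
  offending columns.
* Score correlation matrices are symmetrised and, if rounding yields
  eigenvalues below −1e-10, clipped to PSD with the diagonal renormalised.
* A singular score variance (coded column constant or collinear with Z)
  raises an error naming the coding.
* The exact method inherits its accuracy from the asymptotic normal
  approximation; at small n or extreme prevalence the resampling methods
  are the safer reference. No step-down (Westfall–Young) procedure, FDR
  control, or post-selection inference for the chosen coding's effect size
  is provided, and proportional-hazards models are out of scope.
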