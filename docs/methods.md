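# Methods

## The question and the model

Average winter wheat yields have been roughly flat for two decades, which
raises a question central statistics cannot answer: is there a ceiling on
the yield a commercial farm can attain under current technology and
climate, and if so, where is it?  `yieldtail` answers it with extreme value
analysis of the *highest* yields only.

For a yield variable X and a high threshold t, the excess X − t given
X > t approximately follows a generalized Pareto distribution (GPD),

    P(X − t ≤ y | X > t) ≈ H(y) = 1 − (1 + γ y / σ(t))^(−1/γ),

(the exponential law 1 − exp(−y/σ) at γ = 0).  The shape γ classifies the
tail: γ > 0 heavy, γ = 0 exponential, and γ < 0 a short tail with finite
endpoint.  In the bounded case the maximum attainable yield is estimated
from the fit on the k highest observations (threshold t_k = the (k+1)-th
highest value) as

    x̂* = t_k − σ̂ / γ̂.

### Inference

The primary estimator is maximum likelihood.  For γ > −1/2 the ML
estimator (γ̂, σ̂/σ) is asymptotically normal with covariance (1/k) V,
V = [[(1+γ)², −(1+γ)], [−(1+γ), 1 + (1+γ)²]], giving the Wald interval
γ̂ ± 1.96 (1+γ̂)/√k.  The endpoint estimator's normal limit has variance
(1/k)(σ̂/γ̂²)² · (1 + 4γ + 5γ² + 2γ³ + 2γ⁴), evaluated by Horner's rule.
Because the 1/γ̂² factor explodes as the shape approaches 0, the raw lower
confidence bound can fall below yields already observed; since the true
endpoint cannot lie below the sample maximum t₀, the reported interval is

    [ max(t₀, x̂* − h), x̂* + h ],   h = 1.96/√k · σ̂/γ̂² · √(1+4γ̂+5γ̂²+2γ̂³+2γ̂⁴),

with a flag recording when the truncation binds.  Truncation can only add
coverage, never remove it.  z is fixed at 1.96 for the 95% level (the
conventional printed value); other levels use the exact normal quantile.

Once-in-m return levels are t_k + (σ̂/γ̂)((mζ)^γ̂ − 1) with ζ = k/n, and
their profile-likelihood intervals come from reparameterizing (γ, σ) into
(γ, return level) and collecting levels whose profile deviance stays under
the χ²₁ cutoff.  The upper search stops at ten times the point estimate's
elevation above the threshold; beyond that the interval is reported as
unbounded — which, for very large m, happens exactly when the shape
interval cannot exclude γ ≥ 0.  Stratified comparisons use a likelihood
ratio test: the null shares one (γ, σ) across the strata's excess sets
(each stratum keeps its own threshold, as the stratified fits use distinct
k and t), the alternative fits each stratum freely, so df = 2(G − 1).  The
pooled construction over per-stratum thresholds is this package's
documented choice; alternatives (a common absolute threshold) would change
the null hypothesis being tested.

### Estimation details

The likelihood is optimized in (γ, log σ) by Nelder–Mead from multiple
starting points — probability-weighted moments, the Dekkers–Einmahl–de Haan
moment estimator, and an exponential-like start (0.1, log ȳ) — because the
GPD likelihood can be multimodal and is unbounded in the non-regular
region.  The support constraint 1 + γ y_i/σ > 0 is enforced by a graded
penalty rather than a moving box, keeping the optimizer generic; γ is
boxed to (−5, 5).  Below |γ| = 10⁻⁶ the exponential branch of the
likelihood (and of the distribution functions) is used; scipy's
`genpareto` parameterization backs the cdf/pdf/quantile, switching to
`expon` below the branch point because the direct formula loses all
accuracy once |γ| approaches the float epsilon.  Values tied with the
threshold are rejected rather than silently dropped: the model is defined
on the k highest values strictly above t_k.  Fits with γ̂ ≤ −1/2 carry a
warning and no covariance (the asymptotic theory does not apply).  No bias
correction or penalization is applied to the ML estimates.

The moment estimator follows Dekkers–Einmahl–de Haan (log-spacings of the
top order statistics, hence it requires a positive threshold scale); the
PWM estimator follows Hosking–Wallis with b₀ the mean excess and b₁ the
unbiased estimate of E[Y(1 − F(Y))].  Both serve as robustness
cross-checks and ML starting values, never as the reported estimator.

### Choosing k

The effective sample size k trades variance (small k) against bias (large
k).  `shape_trajectory` refits the model at every k in [15, 400] (the
range outside which variance and bias respectively dominate), and
`stability_region` proposes the largest k whose trailing 50 shape
estimates span at most 0.05.  The choice is ultimately visual; the
heuristic is an aid that never overrides an explicit k, and the full
trajectory is always returned.  Note the heuristic's flatness guarantee is
in shape units: near γ̂ = −0.11 a shape band of 0.05 still permits endpoint
drift of order (σ̂/γ̂²) × 0.05 ≈ 2–3 t/ha across the window.

## The synthetic panel

Farm-level survey microdata are confidential, so the pipeline is developed
and validated against a generator whose ground truth is known exactly.
Its defaults emulate the panel the method is designed for: 1550 farms over
2006–2015 with 45% yearly participation (≈ 700 farms per year, ≈ 1540
unique farms after deduplication), a truncated-normal yield bulk with mean
8.0 and sd 1.6 t/ha on [0, u], and with probability 0.04 per farm-year an
exceedance u + GPD(γ = −0.11, σ = 0.76) above u = 10.69 t/ha — implying a
true ceiling of 17.60 t/ha plus the regional shift, and about 250 unique
farms above the threshold, matching the scale at which the analysis
operates.  Region shifts (east +0.2, north −0.35, west 0.0 t/ha; weights
0.50/0.215/0.285) move bulk and tail alike, so the ceiling is a regional
property.  Input spending is log-normal (median £318/ha, log-sd 0.35,
split ~63% fertilizer) with a farm-persistent component, so tertile cuts
comparable to £270/£370 arise from the distribution rather than being
hard-coded.

Two structural choices deserve emphasis.  First, the farm effect
(sd 0.6 t/ha) and the input-spending effect (+0.25 t/ha per sd of
log-spend) shift the **bulk** component only — they move the mean of the
truncated normal, never the tail draws.  This guarantees support
conservation (no draw can exceed the regional ceiling) and keeps the
excess distribution above the regional threshold exactly GPD; the cost is
that input use raises typical yields but not the ceiling, which is itself
a defensible reading of input–output relationships near the biological
maximum.  Second, within-farm dependence is a single additive Gaussian
farm effect — the simplest mechanism that makes per-farm-maximum
deduplication non-trivial — and is a stand-in, not a claim about any real
survey's dependence structure.

Reproducibility: farm i draws from the i-th child of
`SeedSequence(seed)`, so a single farm's records can be regenerated in
isolation and panels are byte-identical under a fixed seed.

What the generator does **not** emulate: weather and temporal trends in
mean yield, survey weighting, spatially correlated shocks, and any
dependence of tail membership on inputs.  Tests passing on this generator
therefore demonstrate the estimators' correctness and calibration under
the model's own assumptions, not the validity of those assumptions for
real farm data.

## Survey preparation conventions

Costs are deflated by index[base]/index[year] (generic against any
user-supplied index series); deflation is applied once to original
records.  Deduplication retains each farm's maximum yield with the
covariates of the year achieving it; ties on the maximum keep the earliest
year.  Spend stratification sorts stably by (deflated spend of the
retained year, farm id) and splits into groups differing in size by at
most one, larger groups at the low-spend end; whether a multi-year spend
average would be preferable is unknowable without the survey's own
conventions, and the retained-year definition is the package default.
NUTS1 regions map onto three macro-regions (east England; north England;
west England and Wales) case-insensitively.

## Numerical and testing choices

Simulation sizes in the test suite (replicate counts of 25–2000, panels of
300–2000 farms) were chosen to keep each statistical gate's Monte Carlo
error well inside its tolerance while the whole suite runs in minutes;
they are stated in each test.  Fixed seeds make every stochastic gate
reproducible.

Known limitations, measured on the generator at the study's own scale
(k = 250):

* The Wald interval for γ covers ≈ 88–90% rather than 95%: the
  finite-sample sd of γ̂ exceeds its asymptotic value by ~13% and the
  estimator carries a small negative bias.  The ML optimum itself is exact
  (it matches an independent optimizer to machine precision and the
  asymptotic variance by k = 5000).
* The truncated endpoint interval covers ≈ 83%: the endpoint estimator is
  strongly right-skewed through the 1/γ̂ nonlinearity (empirical sd ~1.4
  vs delta-method ~1.0 at γ = −0.2), so a symmetric interval is
  anti-conservative.  Truncation at t₀ is not the cause.
* Consequently, interval-calibration checks at k = 250 fail a 95% ± 2%
  gate; point-estimate recovery (mean γ̂ within 0.01, mean endpoint within
  0.2 t/ha at k = 5000) is clean.

These are properties of the plain-ML Wald methodology at moderate k, kept
as-is deliberately: the package reports the method as practiced, and the
profile-likelihood route is provided for users who want asymmetric
uncertainty at the cost of possibly unbounded intervals.
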