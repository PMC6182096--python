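# Methods

## Sampling model

Throughout, a well-mixed source at true concentration *c* (organisms/L)
analysed in volume *V* (L) with recovery fraction *R* yields a count

    X | c, V, R  ~  Poisson(c · V · R).

Recovery — the fraction of organisms present that the method actually
observes — takes one of three profiles: perfect (R ≡ 1), constant
(R ≡ p ∈ (0, 1], equivalent by Poisson thinning to analysing p·V
liters), or Beta(a, b)-distributed across samples.  The model assumes
spatial randomness (no clustering, so counts are Poisson rather than
over-dispersed within a sample) and independence across sampling events.

### Non-detect probability

P(X = 0) is exp(−cV), exp(−cVp), or, under beta recovery, the mixture

    E_R[exp(−cV R)] = ₁F₁(a; a + b; −cV),

the Kummer confluent hypergeometric function (the MGF of a beta variable
at −cV).  `scipy.special.hyp1f1` is used and was verified against
arbitrary-precision evaluation and adaptive quadrature to ~1e-15
relative over cV ∈ [0.01, 200]; a quadrature fallback guards any
argument regime where the special function returns a non-finite or
out-of-range value.

### Method sensitivity limit

The MSL is the concentration c\* at which P(ND) equals a chosen α.
Since P(ND) is strictly decreasing in c, c\* is unique; it is
ln(1/α)/V (perfect) or ln(1/α)/(pV) (constant) in closed form, and for
beta recovery is found by Brent root-finding on a bracket [0, c_hi] with
c_hi doubled from ln(1/α)/(V·E[R]) until P(ND) < α (the mean-recovery
guess always lies below the beta MSL by Jensen's inequality, so the
doubling loop is the safe direction).  Default α = 0.01 — "non-detects
become improbable" read as a 1-in-100 event — exposed as a parameter
because the choice is a convention, not a standard.

### MPN

A presence/absence series is a set of censored counts: a negative test
is an exact zero, a positive test is the event X ≥ 1 with probability
1 − exp(−cV_j).  The MLE maximises the corresponding Bernoulli product.
Rather than generic optimisation, the score equation

    Σ_pos V_j e^{−cV_j}/(1 − e^{−cV_j}) = Σ_neg V_j

is solved by bracketed root-finding; its left side decreases
monotonically from +∞ to 0, so the root is unique.  Conventions at the
boundaries: an all-negative series returns the boundary MLE 0; an
all-positive series has an unbounded likelihood and is returned as an
explicit non-identifiability flag (`MpnResult.identifiable = False`,
`mle = inf`) rather than a capped number, so no information is hidden.

## Posterior for one count

With a flat (improper, semi-infinite uniform) prior on c over [0, ∞) and
the Poisson likelihood, the posterior is conjugate and proper for every
count:

    c | x  ~  Gamma(shape = x + 1, rate = p·V),

with mean (x+1)/(pV) and mode x/(pV).  The prior is used directly — no
truncation at an arbitrary upper bound, which would introduce a tuning
constant without changing any reported quantity materially.  Variable
(beta) recovery breaks the conjugacy and is deliberately out of scope
here; the posterior module covers the constant-recovery demonstration
only.

## The five estimators

Approaches A–D consume legacy per-sample reports (concentration for
detects, "<1/V_i" for NDs, where 1/V_i is the per-sample purported MDL —
sample-specific, since volumes differ); approach E consumes raw counts.
All fit a lognormal concentration distribution LogNormal(μ_L, σ_L) and
report, besides the log-scale parameters, the arithmetic mean
exp(μ_L + σ_L²/2) and SD mean·√(exp(σ_L²) − 1) in organisms/L — the
scale on which monitoring statistics are conventionally quoted.

* **A (omit)** and **B/C (substitute limit / half limit)** reduce to the
  uncensored lognormal MLE: μ̂_L the mean of logs, σ̂_L the RMS deviation
  with divisor n.  The n-divisor (not n−1) is the MLE and is what makes
  the two-detect fit of the worked dataset exactly reproducible.
* **D (censored MLE)** maximises Σ_detects log f_LN(v_i) +
  Σ_NDs log F_LN(limit_i), the standard left-censored treatment.
  Concentrations enter at full precision (count/volume), never at the
  2-significant-figure display rounding.  Verified against an
  independent dense 2-D grid search and against R's `fitdistrplus`
  (`fitdistcens`), which agrees to six decimals on the worked dataset.
* **E (Poisson-lognormal)** maximises Σ_i log ∫₀^∞ Poisson(x_i; cV_i)
  f_LN(c; μ_L, σ_L) dc.  With c = exp(μ_L + √2 σ_L t) the integral
  becomes a Gauss–Hermite sum; 61 nodes are used by default and agree
  with adaptive quadrature to better than 1e-6 relative for the counts
  (≤ 10) and volumes (~50–65 L) this model is aimed at.  TNTC records
  replace the Poisson mass by the survival probability P(X ≥ T | cV_i)
  inside the integrand — genuinely censored counts handled as such.
  All-zero datasets raise an explicit non-identifiability error: the
  likelihood increases monotonically as the concentration shrinks, so no
  finite MLE exists without an informative prior.

D and E are optimised by Nelder–Mead on (μ_L, log σ_L) — the log
transform keeps σ_L positive without constraints — with three starts
(moment-based, substitution-based, perturbed) and tolerances 1e-10 on
parameters and objective; the best of the three is kept and checked for
local optimality in tests.  Standard errors come from a central-difference
observed-information Hessian (delta method back to σ_L), or closed forms
for the uncensored fit; they are NaN when the Hessian is singular.

`bias_ratio` reports μ̂_approach/μ̂_E for each legacy approach plus min
and max.  On the packaged dataset the ratios are A 3.9, B 3.0, C 1.9,
D 2.1; note the smallest ratio belongs to C (half-limit substitution),
slightly below the censored-data ratio D — the often-quoted "2.1–3.9"
overestimation range corresponds to the D and A endpoints.

`naive_pooled_mean` (total count over total volume) is a valid mean
estimate under the sampling model and lands within a percent of the
approach E mean on the packaged dataset, but provides no distribution
fit, spread or uncertainty.

## Synthetic data

`simulate_counts` draws exactly the structure the estimators assume:
c_i ~ LogNormal(μ_L, σ_L), R_i from the recovery profile,
x_i ~ Poisson(c_i V_i R_i).  One seeded `numpy` Generator is used per
run with a documented draw order — all concentrations, then all
recoveries, then all counts — so identical configurations reproduce bit
for bit.  True concentrations are returned separately from the
observable records so estimators can never see them.

Defaults (n = 8, μ_L = −5.3, σ_L = 0.83, V = 50 L, perfect recovery)
mirror the small protozoan monitoring campaign the package ships as its
example: they give an arithmetic-mean concentration near 0.007
organisms/L and typically 5–7 non-detects in 8 samples, matching the
real dataset's 6 of 8.

What the generator deliberately does **not** emulate: temporal
autocorrelation between sampling events, non-Poisson source clustering,
matrix-dependent recovery drift, or counting/identification error beyond
recovery loss.  Passing parameter-recovery tests therefore demonstrates
correctness of the likelihood machinery under the model's own
assumptions, not robustness of the model to real-world violations of
them.

`bias_experiment` runs approaches A–E over replicate synthetic datasets
per scenario and tabulates mean/SD of the estimated mean and the ND
fraction.  Its acceptance checks are directional only (substitution
exceeds E in high-ND regimes; all approaches coincide without NDs):
the magnitude of bias as a function of ND fraction is left as an open
simulation question, with no numeric targets asserted.

## Numerical and test-size choices

* Gauss–Hermite: 61 nodes; cross-checked against `scipy.integrate.quad`
  in tests at multiple parameter points.
* Root-finding: Brent with xtol/rtol 1e-12; the ND probability at the
  returned MSL matches α to 1e-6 absolute in tests.
* Parameter-recovery harness: 20 synthetic campaigns of n = 500 samples
  at the default conditions; median |μ̂_L − μ_L| below 0.1.  Bias
  shrinkage is additionally checked between n = 50 and n = 500.
* Monte-Carlo detection oracle: 1e5 draws per recovery profile,
  agreement within 4 binomial standard errors.
* Degenerate inputs: equal-valued samples give σ̂_L = 0 with infinite
  log-density (a point mass) — returned, not rejected; fewer than two
  detects for A, TNTC in conversion paths, and invalid recovery/alpha
  parameters raise typed validation errors.

## Known limitations

* Approach E assumes perfect (or externally corrected) recovery; the
  likelihood extends naturally to recovery mixtures but that extension
  is not implemented here.
* The Poisson-lognormal surface is flat for small n (the worked dataset
  has standard errors on μ̂_L of ~1.1 log units); point estimates from
  8 samples are illustrations of method behaviour, not precise source
  characterisations.
* The improper flat prior on concentration is a convenience for the
  single-count demonstration; it is not a recommendation for multi-
  sample Bayesian inference, which is out of scope.
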