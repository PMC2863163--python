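# Methods

## Model and notation

Each study supplies follow-up data (*X̃*ᵢ, δᵢ), *X̃*ᵢ = min(*T*ᵢ, *C*ᵢ), with
independent censoring, and a genes × samples expression matrix; every gene is
screened with a univariate Cox model h(t | z) = h₀(t)·e^{βz}. Ties among
failures are handled with the Peto–Breslow approximation everywhere: the
partial log-likelihood is

ℓ(β) = Σ_j [ β Σ_{i∈D_j} z_i − d_j log Σ_{i∈R_j} e^{βz_i} ],

summed over distinct observed times t₁ < … < t_N (terms with d_j = 0 vanish,
but censoring-only times are retained in the decomposition, and tied censored
subjects stay in the risk set at their time — censoring-after-failure
convention). The Efron tie correction is deliberately not offered, so that
every downstream quantity refers to one likelihood.

## The separability index

* Null score components: U_j = Σ_{D_j} z − d_j·mean_{R_j}(z). Their sum is
  the Cox score at β = 0.
* Robust components: each subject carries the Lin–Wei score residual at β = 0,
  L_i = δ_i(z_i − z̄(t_{(i)})) − Σ_{t_j ≤ X̃_i} (d_j/n_j)(z_i − z̄(t_j)), and
  W_j = Σ_{i∈E(t_j)} L_i aggregates the residuals of the subjects leaving
  (failing or censored) at t_j. Σ W_j = Σ U_j = Δ₀ holds exactly — this
  identity and a brute-force per-subject oracle are the primary correctness
  checks in the test suite.
* Normalization: Δ₀² ≤ N·ΣW_j² by Cauchy–Schwarz over the N distinct-time
  components, with equality approached as |β| → ∞ (all components pull in one
  direction with comparable weight). The index is I = Δ₀²/(N·ΣW_j²) = S₀/N
  with S₀ = (ΣW)²/ΣW² the robust score statistic. N — not the number of
  failure times k — is the constant that makes the [0, 1] range a theorem;
  with k a three-subject censored counterexample reaches 1.8. Without
  censoring N = k and the two conventions coincide.
* The effect direction (HR > 1 vs HR < 1) is reported from the sign of Δ₀;
  the index itself is orientation-free.
* p-values come from the χ²(1) upper tail of S₀; q-values from a Storey-type
  estimator (below).

Measured behavior under the proportional hazards generator (Bernoulli(½)
covariate, 500 replicates; computed by the test suite and
`scripts/acceptance.py`, not asserted here): the null mean at n = 1,000 is
below 0.002; the mean rises monotonically with the hazard ratio; for a
Bernoulli covariate the large-effect plateau is ≈ 0.84 rather than 1, because
perfect separation does not make all W_j exactly equal. Two finite-sample
caveats: the mean carries an upward bias of order 1/N (the χ²(1) unit mean
divided by N), noticeable as a ≈ 0.03 elevation at n = 50 for moderate
effects; and the χ²(1) calibration of S₀ is asymptotic — at n = 100 the test
rejects at ≈ 6.5% instead of 5%, at n = 500 at ≈ 5.4%.

## Comparison indices

Allison's index 1 − e^{−LR/n}; the O'Quigley modification 1 − e^{−LR/k} with
k the total number of failures (the count of events, not of distinct failure
times — the convention that makes the index censoring-robust); Nagelkerke's
index, Allison's divided by its maximum 1 − e^{2ℓ(0)/n}; and the
Xu–O'Quigley index 1 − e^{−2Γ}, where Γ weights, by the renormalized
Kaplan–Meier jumps of the distribution of T at failure times, the
Kullback–Leibler divergence on each risk set between the fitted selection
probabilities π_i(β̂, t_j) = e^{β̂z_i}/Σ_{R_j}e^{β̂z_l} and the null (uniform)
ones. With no censoring and no ties the score equation makes
Σ_j KL_j = ℓ(β̂) − ℓ(0) exactly, so the Xu–O'Quigley index then coincides
with the modified Allison index; under censoring they diverge but track each
other. Non-converged fits yield missing indices rather than values at a
capped β.

The one-covariate Newton–Raphson solver starts at β = 0, uses step-halving on
likelihood decrease, and stops at |score| < 1e−8 after internally
standardizing the covariate (β is reported on the original scale; the LR
statistic is invariant). Monotone likelihoods (complete separation) are
capped at |β| = 20 on the standardized scale and flagged non-converged.

## Simulation machinery

Survival times are drawn by inverse transform from S(t; z) = e^{−t·e^{βz}}
(proportional hazards) or S(t; z) = (1 + t·e^{βz})^{−1} (proportional odds,
where the covariate effect wanes with time). Covariates are Bernoulli(½) or
Uniform[0, √3] — the upper bound chosen so both laws have variance ¼ and
effect sizes are comparable. Effects e^β span 1–5, sample sizes 50–1,000,
replicates default to 1,000 (the studies run in the tests use 200–500).

Censoring is independent of T given Z, Uniform(0, r) or Exponential(γ). The
parameter is solved by Brent root-finding so that the covariate-marginal
expected censored fraction equals p_c, using closed forms for P(C < T | z)
(e.g. (1 − e^{−λr})/(λr) for uniform censoring under PH; the exponential/PO
case uses the exponential integral E₁) and Gauss–Legendre quadrature over
the uniform covariate law. At p_c = 0.25 under the null this gives r ≈ 3.92,
and simulated censored fractions match p_c to within 1% at n = 10⁵.

`run_index_study` computes all five indices on the *same* replicate datasets,
so the differences δ = index − competitor are paired, with 95% normal CIs on
the mean difference. One master seed derives per-cell streams.

## Synthetic two-study genomics example

The generator emulates a two-cohort expression screen: n = 150 and n = 50
subjects, half low-risk (ξ = 0) and half high-risk (e^ξ ∈ {3, 5}), survival
exponential (PH) or log-logistic (PO), uniform censoring calibrated to an
expected 30%. The 1,000-gene matrix: genes 1–50 LogNormal(4, 1.5) and genes
51–100 LogNormal(3, 1.5) in the low-risk group versus LogNormal(0, 1.5)
elsewhere (the truly prognostic set); genes 101–150 / 151–250 / 251–350
elevated (log-means 1 / 0.5 / 0.1) in a random 40% / 50% / 70% of subjects
drawn independently of risk status (structured but non-prognostic); genes
351–1,000 pure LogNormal(0, 1.5) noise. Clumpy dependence: per 10-gene
block, one shared LogNormal(0, 1) subject vector scaled by ρ ∈ {0.25, 0.5,
0.75} is *added* to the block's values (the additive form; an interpolating
form ρa + (1−ρ)z is the main alternative, and the within-block correlation
audit in the tests is insensitive to the choice). Each study is then
quantile-normalized (columns forced onto the mean-of-sorted-columns
reference; ties get the mean of their tied reference quantiles).

What this emulates — and what it does not: cross-study rank concordance,
block correlation, heavy-tailed intensities and realistic censoring; it does
not model probe-level artifacts, batch effects beyond sample size, or
missing values. Passing operating-characteristic tests on this generator
therefore says nothing about probe-level preprocessing choices on real
arrays.

Screening is performed on log intensities (`run_meta_study(log_expression=
True)`, `--log-expression` in the CLI): the generator emits intensity-scale
values, but a log-linear hazard in raw intensities is badly mis-specified
for log-normal data and degrades every criterion — most strongly the
score-based index, which is linear in the covariate. On the log scale the
index attains the best operating characteristics of the five criteria.

## Meta-selection

Per-study gene tables are thresholded on a common grid of top fractions
(default 0.5%–20%, 40 points; criterion quantiles rather than raw values, so
grids are comparable across studies — the loosest per-study quantile is
applied to all studies). For each threshold t: O(t) = genes passing in every
study; E(t) = G·Π_k(|S_k(t)|/G) under independence; the chosen threshold is
the loosest with O/E > 2 (all qualifying thresholds are reported — when
several regions qualify, external relevance judgments cannot be computed, so
the default is simply the loosest). Rankings break ties by gene id (stable
sort). TPF/TNF are means over iterations of the fractions of truly
prognostic genes selected and non-prognostic genes not selected.

Q-values: Storey's non-parametric FDR with π₀ estimated on the λ-grid
0.05–0.95 (step 0.05), cubic-spline smoothed and read off at λ = 0.95,
clamped to (0, 1]; with π₀ = 1 the q-values reduce exactly to
Benjamini–Hochberg adjusted p-values (cross-checked against statsmodels).
LR-statistic q-values use χ²(1) p-values of the likelihood-ratio statistic.

## Numerical choices and degenerate inputs

Log-sum-exp with suffix accumulation for all risk-set denominators; linear
predictors clipped at ±500 before exponentiation; a constant covariate (or
one constant on all risk sets, ΣW² = 0) is a "zero separability scale" error
for the index and a non-identifiable error for the Cox fit; datasets with no
events are rejected outright; per-gene vectorized paths are exact matches of
the scalar paths (asserted in tests).

## Known limitations

The index's small-sample upward bias (≈ 1/N) and the mild anti-conservatism
of the χ²(1) calibration below n ≈ 200 are inherent to the sandwich-type
construction; the large-effect plateau depends on the covariate law (≈ 0.84
for Bernoulli(½)); only univariate screening is supported — no multivariable
models, stratification, time-varying covariates or baseline hazard
estimation; and the meta layer intersects ranked lists rather than pooling
effect sizes (no random-effects meta-analysis).
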