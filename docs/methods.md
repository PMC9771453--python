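# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the limits of what the tests establish.

## 1. Task scoring

**CPT / signal detection.** With H the hit rate over targets and F the
false-alarm rate over lures, d′ = Φ⁻¹(H) − Φ⁻¹(F) and
ln β = ½[Φ⁻¹(F)² − Φ⁻¹(H)²]. Observed rates of 0 or 1 are replaced by
1/(2N) and 1 − 1/(2N), N the relevant trial count — the standard correction
that keeps the quantiles finite; its effect is visible as a small upward
bias of the mean scored d′ at high performance (≈ +0.07 at d′ = 2 with 27
lures). RT statistics use responded trials only. The false-alarm RT SD
deserves a caveat it rarely gets: with a false-alarm rate near 0.16 on 27
lures it rests on ~4 observations and is close to pure noise; it is kept
because it is part of the published indicator set, and sessions with fewer
than two responded lures yield a (structurally) missing value that FIML
absorbs.

**WOF.** Choice and RT metrics are computed over trials that are neither
timeouts nor anticipatory (< 200 ms); cumulative winnings are the final
balances of the three runs summed, equivalently the sum of the full payoff
ledger including timeout losses (a timeout forfeits the higher amount). The
wheels are built so the *winning-side* expected value is identical across
risk levels (0.30·$7 = 0.70·$3 = $2.10; 0.10·$9Y = 0.90·$Y). Because a
losing spin forfeits the selected amount, the *net* expected payoff of the
risky side is negative (e.g. $7·(0.3 − 0.7) = −$2.8 per trial) — this is
what couples cumulative winnings negatively to risk propensity.

**EFR.** The negative block pools disgust, anger, sadness and fear (40
trials); the positive block is happiness (10 trials). RT summaries use all
trials in a block, correct or not: the published description averages
"accuracy and reaction time" without conditioning on correctness, and
conditioning would make the RT SD of near-ceiling blocks undefined.

**TD.** The adjusting-amount series (6 choices per delay, $5 start, halving
steps, offers clipped to [$0.50, $10]) is summarized per delay by the
midpoint between the largest immediate amount at which the delayed reward
was chosen and the smallest at which the immediate was taken. A
non-monotone series (no separating threshold) falls back to the midpoint of
a two-parameter logistic choice fit and is flagged. AUC integrates the
indifference values (normalized by $10) over delays normalized to one year
with 1 mo = 30 d, 6 mo = 182.5 d, 1 yr = 365 d; a zero-delay anchor at
value 1 is prepended when the curve lacks one (the staircase's own 0-day
condition produces it naturally). The staircase and midpoint estimator are
this package's documented choices; the source description of the adjustment
procedure is not specific enough to reproduce exactly.

**SES.** Household income and mean parental education are z-scored over the
cohort and averaged; a missing component leaves the other alone, both
missing propagates. **Exclusion.** A DUSI-R Lie score > 6 (strict) removes
every wave of that participant. **Standardization.** Indicators are
z-scored pooling all waves — one measurement model over person-waves — not
per wave; per-wave standardization would absorb exactly the age trend the
age model needs.

## 2. Latent models

The measurement model is x = μ + Λη + ε, η ~ N(0, Ψ), ε ~ N(0, Θ), with
unit factor variances (all loadings free — the "standardized factors"
identification) and Θ diagonal plus explicitly freed residual covariances.
The default battery model has ICLF (d′, ln β, hit RT SD, FA RT SD, BIS),
RRLF (P(high risk), risk-conditional RTs, winnings, TD AUC), and ENLF/EPLF
(block accuracy, mean RT, RT SD), with free residual covariances for the
within-task method pairs (d′–ln β, d′–hit RT SD, P(high)–RT(high),
RT(low)–RT(high), neg–pos RT, neg–pos accuracy).

**FIML.** Rows are grouped by missingness pattern g; the log-likelihood is
Σ_g −½ n_g [k_g log 2π + log|Σ_g| + tr(Σ_g⁻¹ A_g)] over the observed
sub-blocks, maximized by L-BFGS-B with the analytic gradient (chain rule
through Σ = ΛΨΛ′ + Θ, and through Ψ = (I−B)⁻¹Φ(I−B)⁻ᵀ when structural paths
B are present). Residual variances are optimized on the log scale with a
floor at 1e−6 — a Heywood case parks there and raises a warning — and
factor correlations pass through tanh. Convergence: relative likelihood
change below machine-level ftol or gradient norm 1e−7, max 500 iterations.
A non-positive-definite proposal returns a large penalty and the line
search backtracks. Each factor's reflection is resolved by flipping it so
its first listed indicator loads positively; analyses that compare against
generating loadings must align reflections first (the tests align by the
loading-vector inner product).

**Identification.** Exogenous factor variances are fixed at 1. In the
structural model the endogenous *disturbance* variances are also fixed at
1: with free loadings, a free disturbance variance would leave the
endogenous factor's scale unidentified (the information matrix acquires a
zero eigenvalue — observed directly during development). Standardized
paths and loadings are reported by rescaling with the implied factor SDs.

**Fit.** χ² = 2(ℓ_sat − ℓ_model), with the saturated model fitted by EM
over missingness patterns (closed form when complete). The null model
(zero loadings, free means/variances) factorizes column-wise.
RMSEA = √(max(χ²−df,0)/(df(n−1))) with the close-fit p-value from the
noncentral χ² at ε₀ = 0.05; CFI = 1 − max(χ²−df,0)/max(χ²₀−df₀, χ²−df, 0);
TLI = ((χ²₀/df₀)−(χ²/df))/((χ²₀/df₀)−1), which legitimately exceeds 1 when
χ² < df. Standard errors come from the observed information (central finite
differences of the analytic gradient), with the delta method for
transformed parameters.

**Factor scores.** Regression (conditional-mean) scores
E[η|x_obs] = ΨΛ_o′Σ_o⁻¹(x_obs − μ_o) per missingness pattern, z-standardized
across person-waves; Bartlett scores are available behind a flag and the
method is recorded in the output. A person-wave with no observed indicator
for a factor gets a missing score. Factor–covariate associations are
reported as score-on-covariate simple regressions, tagged
`score_on_covariate`; regressing factors on covariates *inside* the model
is deliberately not conflated with this.

## 3. Age model and CMI

Elastic-net regression of age (years) on the four standardized scores:
(1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2 ‖β‖²), α ∈ {0, 0.5, 1}, λ on a
100-point log grid from λ_max (computed at α, with α = 0.001 as the ridge
surrogate) down to 10⁻⁴λ_max. The split is random at the *participant*
level (50%), and cross-validation inside the training split leaves out one
participant — all waves together — per fold, avoiding within-person
leakage; row-level folds are a flag. Selection: minimum λ at the highest
CV R², with CV R² = 1 − CV-MSE/Var(train age). Held-out performance is
R² = 1 − MSE/Var(test age) and MAE in months.

For ridge the fold errors use the exact block identity
e_g = (I − H_gg)⁻¹ r_g with the penalty matrix held fixed on the absolute
scale (n_train·λ) across folds — the convention under which the identity is
exact, verified against explicit refits to 1e−10. For α > 0 each fold is
refit explicitly along the path (coordinate descent, per-fold-normalized
objective — the standard glmnet convention).

CMI = predicted − observed age by default, so positive = advanced relative
to the sample growth curve; the reversed subtraction order is available via
a flag because published descriptions of the sign differ internally, and
the package does not pretend to resolve that. CMI is relative to the
sample the model was trained on: its mean over the training sample is ~0 by
construction, and it is not a population-calibrated quantity. Covariate
correlations are plain Pearson r over person-waves; the report carries an
explicit caveat that repeated measures per participant are not adjusted
for.

## 4. Synthetic cohort: what it emulates, and what it does not

Defaults emulate the target study design: 141 participants, 3 waves,
wave-one age ~ U(11.1, 14.0), gaps ~ N(1.6, 0.3²) years, monotone dropout
at 8%/wave (≈ 141 → 130 → 119 expected), ~5% missing task sessions, and
~16% of participants planted with Lie > 6 (exercising the downstream
exclusion; their task data are otherwise normal). Demographics (sex ratio,
BMI, PDS, IQ, BIS/BAS, DUSI scales, income/education) are drawn around the
study's reported wave-one moments.

Each factor follows f = intercept + slope·z(effective age) + b_person +
e_wave, with effective age = age + δ, δ ~ N(0, σ_δ²) the planted maturity
offset shared across a person's waves. Default slopes are the reported age
trends (ICLF +0.72, RRLF −0.22, ENLF +0.35, EPLF −0.16 per SD of pooled
age), with person-intercept SD 0.3, wave residual SD 0.5, σ_δ = 1 year.
Indicator targets are λ·f plus residual noise (SD √(1−λ²) by default),
mapped to task-native scales (e.g. d′ mean 2.2, SD 0.6) and fed to the
trial simulators; the CPT simulator analytically inverts the SDT equations,
the TD simulator solves for the hyperbolic rate k matching the target AUC.
Two indicators are *emergent* rather than calibrated: cumulative winnings
(driven by the payoff ledger) and, partially, anything truncated by its
native clipping bounds. Inter-wave correlation beyond the random intercept
is not modeled and is exposed as a parameter rather than fixed.

**The strong-signal validation preset** exists to answer one question: does
the pipeline recover planted maturity when the signal is there to recover?
Two structural facts shape it. First, regression-to-the-mean: writing the
ideal score signal as age + δ + e, the fitted prediction is
ŷ ≈ ȳ + c(age + δ + e) with c = Var(age)/(Var(age)+σ_δ²+σ_e²) < 1, so
CMI = (c−1)(age−ȳ) + c(δ+e) contains an age-correlated shrinkage term that
caps corr(δ, CMI) regardless of sample size; the cap is only near 1 when
σ_δ is modest relative to Var(age) *and* σ_e is small. Second, the task
designs impose hard sampling-noise floors (27 lures, 10 happiness trials,
~4 false-alarm RTs), so σ_e cannot be made arbitrarily small by turning
generator dials. The preset therefore sits at the reliability ceiling:
unit slopes with the reported signs, |loadings| = 0.95, indicator residual
SD 0.15, person/wave SDs 0.05/0.1, σ_δ = 0.7 years; offset recovery is
evaluated per participant (waves averaged), where it reaches r ≈ 0.93–0.96.
The coefficient-direction check uses the ridge model (α = 0): directions
are a ridge/OLS notion, and sparse penalties zero collinear predictors by
design, which says nothing about direction recovery. Passing these tests
shows the chain is implemented correctly; it does *not* show that real
cohort data carry this much signal — under the realistic default preset the
same correlation is ~0.4–0.5, which is a statement about the information in
the battery, not about the code.

Validation problem sizes are the package's choices: 200-session score
round trips, 1000-table oracle equivalences, 500-replicate Z-test
calibration at n = 300, 20-seed end-to-end recovery (bar ≥ 19/20 for the
95% criterion), 5000-row CFA recovery within ±0.05.

## 5. Pipeline and reproducibility

One master seed fans out to per-stage substreams keyed by a CRC of the
stage name, so adding a stage never changes earlier draws; identical
configurations give byte-identical outputs and matching SHA-256 manifest
checksums. All outputs are text (CSV/TSV/JSON/Markdown); trial tables are
written on demand. Exit codes: 0 ok, 2 config error, 3 stage failure, with
partial outputs persisted for inspection.

## 6. Known limitations

- The CFA assumes multivariate normality of indicators; bounded indicators
  (accuracies, AUC) violate this in the tails. No robust (Satorra-Bentler)
  corrections and no categorical estimators are provided.
- FIML is valid under missingness-at-random; the generator's missingness is
  MCAR, so the tests do not probe MNAR sensitivity.
- The free residual covariances within a factor can trade off against
  loadings at moderate n, occasionally producing boundary (Heywood)
  solutions — surfaced as warnings, handled at the 1e−6 floor.
- Learning/practice effects across waves, in-scanner vs out-of-scanner
  differences, and nonlinear growth are all out of scope; growth is linear
  by design.
- CMI covariate correlations ignore within-participant clustering, as in
  the source analysis; treat the p-values as descriptive.
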