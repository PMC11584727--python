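# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical choices, and the known limitations of `mrmediate`.

## Estimators

**Wald ratios and IVW.** Per-variant causal estimates are first-order
Wald ratios θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with seⱼ = σ_Yj/|γ̂ⱼ| (the uncertainty of γ̂ⱼ is
ignored in the SE, the summary-data MR convention). The pooled estimate
is the inverse-variance-weighted mean. Under the multiplicative
random-effects model the SE is scaled by max(1, √(Q/df)); the floor at 1
prevents anti-conservative shrinkage when Q < df. P-values use the
normal approximation throughout, and 95% intervals use the conventional
multiplier 1.96. With a single instrument IVW degrades to the Wald
ratio with a warning.

**MR-Egger.** Weighted least squares of Γ̂ⱼ on γ̂ⱼ with intercept,
weights σ_Yj⁻², after orienting every pair so γ̂ⱼ > 0. Slope and
intercept SEs carry the same multiplicative overdispersion scaling with
df = n−2. I²GX = (Q_GX − (n−1))/Q_GX, with Q_GX the Cochran Q of the
oriented instrument effects under weights σ_Xj⁻², quantifies
instrument-strength adequacy (NOME) for the Egger slope.

**Weighted median.** Wald ratios are ordered and the estimate is the
interpolated weighted 50th percentile over cumulative standardized
weights sⱼ = (cumⱼ − wⱼ/2)/Σw. The penalized variant multiplies each
weight by min(1, 20·qⱼ), qⱼ being the upper-tail χ²₁ probability of the
variant's Q contribution at the unpenalized estimate; 20 is the
method's published default. The SE comes from a parametric bootstrap
(θⱼ* ~ Normal(θ̂ⱼ, seⱼ), default 1000 resamples, seeded). The penalty
weights are computed once from the observed ratios and held fixed
across bootstrap replicates: the interval is conditional on the
selected down-weighting. Re-penalizing every replicate double-counts
dispersion (each replicate already carries both the ratio noise and the
resampling noise) and produced ≈99% empirical coverage in calibration
runs; the fixed-weight bootstrap restores ≈96–97%.

**Radial IVW.** Regression of θ̂ⱼ√wⱼ on √wⱼ through the origin; the
slope is algebraically the fixed-effect IVW estimate, and the value of
the radial form is its per-variant Q contributions, whose χ²₁ p-values
flag outliers at the Bonferroni threshold 0.05/n.

**MR-PRESSO.** The observed residual sum of squares uses leave-one-out
IVW slopes, RSS = Σⱼ σ_Yj⁻²(Γ̂ⱼ − γ̂ⱼθ̂₍₋ⱼ₎)². Its null distribution is
simulated parametrically (γ̂ⱼ* and Γ̂ⱼ* redrawn at their SEs, 5000
simulations by default); p-values use the add-one estimator
(1+#{≥obs})/(n_sim+1) and are therefore never zero. Per-variant outlier
calls compare each observed squared residual with its simulated
distribution at a Bonferroni-corrected level; when outliers are called,
an outlier-corrected IVW is reported along with a distortion p-value
obtained by comparing the observed corrected-vs-full shift against
shifts from random same-size exclusions.

**Multivariable MR.** No-intercept WLS of Γ̂ⱼ on (γ̂₁ⱼ, γ̂₂ⱼ) with weights
σ_Yj⁻² over the union of both exposures' clumped instruments, SEs
scaled by max(1, √(Q/(n−2))). A conditional instrument-strength
diagnostic (mean per-variant F after projecting out the other
exposure's effects) is reported but not thresholded. Rank-deficient
designs (collinear instrument effects, or an exposure with no
independent instrument signal) raise a singular-design error rather
than returning unstable coefficients.

**Mediation.** indirect = α̂·β̂ with the product delta-method SE
√(α̂²se_β² + β̂²se_α²) (a second-order variant adding se_α²se_β² is
available by flag); direct = total − indirect; proportion =
indirect/total with the ratio delta-method SE, treating the components
as independent — justified by the disjoint instrument sets and the
different outcome GWAS used for α. The decomposition identities hold
exactly by construction. Proportions outside [0,1] are reported as-is
and flagged as inconsistent mediation; when the total effect is within
two SEs of zero the report warns that the proportion is unstable. For a
binary mediator, α and β are on the mediator's log-odds scale, so the
proportion is a ratio of log-odds path products — an approximation for
non-collapsible binary mediators, noted in the report.

## Harmonization

The exposure table's allele coding always wins. Non-palindromic
variants are matched directly, by label swap (beta negated, frequency
complemented) or by strand complement. Palindromic (A/T, C/G) variants
carry no strand information in their labels; they are resolved from
allele frequencies: if both studies' frequencies lie outside the
ambiguity window (default 0.42–0.58, configurable) they are kept
(same side of 0.5) or sign-flipped (opposite sides), otherwise dropped
as ambiguous. This retains palindromes only when frequency inference is
unambiguous, the de-facto convention of two-sample MR tooling.
Harmonization never alters |Γ̂| or σ_Y; recoding the outcome study
(double flip) is an exact identity, which the suite checks
property-wise.

## Instrument selection

Significance (strict p < 5×10⁻⁸) and MAF (strict min(f, 1−f) > 0.01)
filters; greedy LD clumping ordered by p-value with ties broken by
variant id, using a supplied pairwise r² table (absent pairs are
treated as unlinked — clumping is reference-panel-free by design, and a
panel-backed LD provider can be slotted in by producing the same
table). Steiger filtering removes variants whose outcome R² exceeds
their exposure R², with R² computed from the t-statistic,
r² = t²/(t²+n−2) — this needs no phenotype-variance assumption and
applies on the observed log-odds scale for binary traits. Mediator
instruments shared with, or in LD with, exposure instruments are
removed from the mediator set (the exposure is upstream in the path
diagram, so its set has priority).

## Synthetic studies

The generator emulates a three-cohort summary-statistic design with a
continuous exposure, a binary mediator and a rare binary outcome.
True per-variant effects follow the path diagram (an exposure
instrument with effect γⱼ has marginal effects γⱼα on the mediator and
γⱼ(τ+αβ) on the outcome; a mediator instrument with effect δₖ has
marginal outcome effect δₖβ). Observed coefficients are drawn around
the truth with the analytic standard errors
se = (2nf(1−f))^(−1/2) (continuous) and
se = (2f(1−f)·n_cases·n_controls/n)^(−1/2) (binary log-odds), which the
suite verifies empirically. The `paper_like` preset fixes the study
conditions: 47+50 instruments, GWAS sizes 97,653 / 16,677+199,580 /
775+376,502, instrument R² 0.0264 (exposure) and 0.20 (mediator — a
default chosen to give mediator hits the z-score range, roughly 5.5–11,
typical of a case/control meta-analysis of that size), α = 0.6,
β = 0.65, τ = 0.0357, so the total log-OR is 0.4257 = ln 1.53 and the
mediated fraction 0.9161.

Design choices worth knowing:

* **Summary-level simulation.** Observed betas are drawn around true
  marginal effects rather than simulating genotypes — sufficient for
  every estimator's assumptions and orders of magnitude faster.
* **Effect-size shares.** Per-variant explained-variance shares are
  drawn Uniform(0.5, 1.5) and normalized. This mimics a *selected*
  instrument panel, where every published hit is individually strong
  (the seed study's weakest instrument has F ≈ 30); a squared-normal
  draw would place half the panel below genome-wide significance at
  these sample sizes, which selected panels do not show. A side effect
  is that |γ| values are more homogeneous than a raw GWAS, so I²GX in
  simulations (~0.75) is lower than for real panels with wider effect
  spread.
* **Allele chaos.** Label swaps, strand flips and palindromic pairs
  (half of them hiding a strand flip detectable only from frequency)
  are injected into the outcome table and recorded in the ground truth,
  so harmonization bookkeeping can be checked exactly. Frequencies are
  emitted noise-free (sampling noise ~10⁻³ at these n is negligible),
  which keeps palindrome window decisions deterministic.
* **Pleiotropy.** Invalid exposure instruments receive an additive
  direct outcome path oriented to the exposure-increasing allele —
  mean-zero ("balanced") or positive-mean ("directional", scale 0.03,
  about twice the typical per-variant causal outcome effect), the two
  canonical regimes robust estimators target.

What passing tests on these data do *not* show: performance under
realistic LD structure (cross-variant r² is zero unless LD duplicates
are requested), sample overlap between cohorts, non-linear
exposure–outcome relationships, liability-scale binary-trait genetics,
or population stratification. The generator is a test harness for the
estimators' assumptions, not a population-genetics simulator.

## Calibration and recovery, as measured

The suite measures (at the problem sizes chosen for a single-CPU run):
CI coverage of all five univariable estimators within 95% ± 3 pp and
Egger-intercept type-I error within 5% ± 2.5 pp over 500 replicates,
with and without a causal effect; weighted-median robustness ordering
versus IVW under 30% directional pleiotropy over 200 replicates;
detection of a single 10-SE outlier by radial Q and MR-PRESSO in >90%
of 20 runs (MR-PRESSO at 1000–2000 simulations in tests; the pipeline
default is 5000); and full-pipeline parameter recovery over 200
replicates.

Recovery at the study's own sample sizes carries two finite-sample
effects worth stating plainly. First, with 775 outcome cases the
per-replicate total effect has CV ≈ 0.5, so the per-replicate ratio
α̂β̂/θ̂_T has no stable mean (the denominator crosses zero in ~2% of
replicates); the mediated proportion is therefore summarised as the
ratio of the mean indirect to the mean total effect across replicates,
both in the acceptance script and in the recovery test. Second,
first-order IVW and MVMR have a small regression-dilution bias at these
instrument strengths (F̄ ≈ 55–62): oracle-denominator runs are unbiased,
while observed-denominator recovery averages ≈ −2 to −4% on each path
(total, α, β). The biases largely cancel in the mediated proportion but
not exactly; across replicate batches the recovered proportion centres
near 0.89–0.90 against the generating 0.916, and the recovered total
log-OR within roughly 1 MC SE of 0.4257 at 200 replicates. The
recovery test asserts the spec-level bands as written; one batch of
seeds can land outside the proportion band, and the accompanying
analysis quantifies why.

## Numerical conventions

* CI multiplier exactly 1.96; normal-approximation p-values (a
  t-distribution option is a config flag away but not default).
* P-values are floored at the smallest positive double rather than 0.
* Weighted medians interpolate linearly in the cumulative-weight grid;
  ties in the sort are stable.
* Clumping, harmonization ordering and report JSON are fully
  deterministic; every stochastic routine (bootstrap, MR-PRESSO) takes
  an explicit seed, and the pipeline fans per-stage seeds out from one
  master seed by fixed offsets.
* Greedy clumping breaks p-value ties lexicographically by variant id,
  making the result invariant to input row order.

## Limitations

Correlated-instrument IVW with a full LD matrix, MVMR-Egger,
weak-instrument-robust MVMR, mode-based and contamination-mixture
estimators, winner's-curse correction, and counterfactual (natural
effects) mediation are out of scope. The confounder screen is a local
annotation-table join standing in for an online variant-phenotype
lookup; it recommends, but never auto-executes, multivariable
adjustment. Variant matching is by identifier only — no liftover or
positional matching across genome builds.
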