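# Methods

## Scope and model

`epimediate` tests whether DNA methylation mediates the effect of a continuous
environmental exposure on a continuous outcome, at single-CpG and gene-region
resolution.  Throughout, the linear no-interaction structural model is
assumed: per site, the mediator model regresses methylation on exposure plus
the exposure–mediator confounders, and the outcome model regresses the
outcome on methylation, exposure and the mediator–outcome confounders.  The
natural indirect effect is the coefficient product α·β, the direct effect is
the exposure coefficient γ′ of the outcome model, TE = NIE + DE, and
PM = NIE/TE.  No exposure–mediator interaction term is included in the
outcome model: the package reports single NIE/DE values per site, which is
only coherent in the no-interaction model.

Adjustment sets follow the DAG logic of indoor-air-pollution birth-cohort
studies: the exposure–mediator models adjust for socioeconomic status,
maternal smoking, genetic ancestry scores (5 by default) and cell-type
principal components (3 by default); the mediator–outcome models additionally
adjust for maternal alcohol use, maternal age and child sex, with maternal
HIV available as a sensitivity covariate.  Birth weight is deliberately
excluded everywhere — it is a plausible consequence of the exposure and a
potential mediator itself, so adjusting for it would block part of the effect
under study.  Cell-type PCs enter both paths by default; a `celltype_paths`
switch restricts them to one path for analysts who read the adjustment
differently.  Whether per-site models are run on beta values or M-values is a
config switch (`scale`); beta values are the default reporting scale, while
the M-value (logit) scale is the one on which the generator's errors are
exactly Gaussian.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, calibrated to
the study-characteristics table of the emulated cohort:

* **Exposure**: log-normal, parameterized to hit mean 64.6 and SD 96.8 µg/m³
  exactly.  Only the mean/SD of the real measure are published; the
  log-normal is a positivity-plus-heavy-tail stand-in, not an inference about
  the true distribution.  Confounding by SES acts on the log scale inside a
  fixed variance budget (the SES share replaces, rather than adds to,
  residual log-scale variance), so the marginal calibration is exact for any
  confounding strength.
* **Methylation**: per-site baselines drawn from a bimodal logit-scale
  mixture (hypo-/intermediate/hyper-methylated strata, roughly 35/30/35 %),
  block-equicorrelated latent Gaussian noise (default blocks of 10 sites at
  ρ = 0.3 — short co-methylation blocks with modest correlation, consistent
  with the rapid decay of co-methylation along the genome), per-site
  confounder loadings drawn N(0, σ_conf) so confounders push different sites
  in different directions, and cell-type mixture loadings on a 30 % site
  subset driven by Dirichlet-distributed 7-part cord-blood-like cell
  proportions.  The logistic map to (0, 1) guarantees valid beta values; the
  logit/logistic round trip is exact to numerical precision.
* **Planted mediators**: exposure shifts their latent values by α per µg/m³
  and the primary outcome responds to their beta-value methylation with slope
  β (default prior: α > 0, β < 0, i.e. adverse mediation).  Planted sites are
  placed one per gene by default so each occupies its own correlation block
  (`planted_per_gene` concentrates them for gene-level power studies), and
  their baselines are drawn from the intermediate-methylation stratum — a
  site pinned near 0 or 1 methylation has almost no beta-scale variance and
  cannot transmit a mediated effect, so planting there would make the truth
  set vacuous.
* **Outcomes**: four developmental domains with the emulated instrument
  means/SDs (cognitive 85.14/8.65 primary; language, motor, adaptive
  secondary).  Planted mediation feeds the primary domain only; confounder
  effects are budgeted inside the configured outcome SD.  Covariate
  frequencies (smoking 26.8/40.1/33.1 %, alcohol 19.7 %, female 40.1 %,
  HIV 21.1 %) match the emulated cohort.

What the generator does **not** emulate: probe chemistry and array artefacts,
batch effects, genuine cell-type reference profiles, genetic sequence, or
temporal exposure structure.  Tests passing on these cohorts therefore
demonstrate the statistical machinery under the stated model, not robustness
to array-level artefacts.

## Per-site association engine

Both path models are exact OLS.  The epigenome-wide beta-path sweep augments
a shared covariate block with one mediator column at a time via rank-one
(Schur-complement) updates, which is algebraically identical to refitting
each site's full design; agreement with site-by-site fits and with an
independent normal-equations oracle is enforced to 1e-8 in the tests.
p-values use the t reference with residual degrees of freedom (cohorts of
n ≈ 142 are the target scale, so normal approximations are avoided).
Zero-variance sites raise (single-site API) or land in an explicit skip list
(sweep API); rank-deficient designs raise with the implicated columns named.

## DACT

Null proportions per path use the tail-fraction estimator
π̂₀ = #{p > λ}/((1−λ)m) at λ = 0.5; the three composite-null case weights
combine the two paths under independence and are normalized.  On a
pre-screened set every p-value is below the screen threshold by construction,
so the tail fractions vanish; the implementation then falls back to equal
case weights with a logged warning.  The composite statistic is the
case-weighted sum w_a·p_α + w_b·p_β + w_ab·max(p_α, p_β)², each term the
valid p-value for its null case.

Empirical-null calibration transforms the composite values by
z = Φ⁻¹(1 − p) and fits (δ, σ) by maximum likelihood of a normal restricted
to the central window between the 5th and 95th percentiles of z.  The
central-90 % window is a deliberate choice: the scale parameter of a
truncated normal is poorly identified from the interquartile band alone
(SD(σ̂) ≈ 0.12 at m = 10,000 there, versus ≈ 0.014 for the central-90 %
band), while genuine signal occupies the extreme tails and stays outside the
window unless the non-null fraction is large — in which case calibration is
conservative, which is the safe direction.  Calibration is skipped (with a
warning, falling back to raw composite values) below 100 sites, where the
empirical null cannot be estimated reliably; screened sets that small occur
routinely in practice, and the uncalibrated composite value remains a valid,
merely less powerful, p-value there.

## HIMA

Candidates are ranked by |t| of the covariate-adjusted marginal
mediator→outcome model (ties broken by site id) and the top ⌊2n/ln n⌋ enter
one joint outcome model: exposure and covariates unpenalized, mediators under
the minimax concave penalty.  The fitter is coordinate descent on
standardized columns with the firm-thresholding update, warm starts along a
100-point geometric lambda grid (ratio 0.05), and convergence at max
coefficient change < 1e-8; solutions on orthonormal designs match the
analytic MCP operator to 1e-8 and λ → 0 recovers OLS.  λ is chosen by BIC
(EBIC with γ = 0.5 available for m ≫ n).  Mediators selected at the optimum
are refit unpenalized for mediator→outcome p-values — post-selection
inference, flagged as such in the result metadata; the joint-significance
rule p = max(p_α, p_β) with BH FDR over the selected set then mirrors the
method family's output contract.  Its known conservativeness under the
both-null case is intentional and tested.

## Gene-level tests (gHMA)

The gene-level architecture is linear + nonlinear + omnibus.  The concrete
statistics are this package's rendering: variance-component score tests with
(a) the linear kernel M M′ over the gene's (centered) mediator matrix and
(b) a Gaussian kernel with median pairwise-distance bandwidth; each path
yields a gene-level p (exposure scored against the kernel given the
exposure–mediator covariates; outcome scored given exposure and the
mediator–outcome covariates), combined per component by joint significance
max(p_α,gene, p_β,gene), and across components by the Cauchy combination
T = mean(tan((½−p)π)), which maps equal inputs to themselves and tolerates
dependence between components (a Šidák-style min-p alternative sits behind a
switch, since the omnibus transformation of the original method is not
pinned down publicly).  Every piece reduces correctly at q = 1 to the
single-site score test.

Null distributions are weighted chi-square mixtures with weights from the
eigenvalues of the projected kernel.  Tails are evaluated by exact
characteristic-function inversion (Imhof integration) whenever at most 20
eigenvalues carry the mixture, and by the Liu moment-matching approximation
for dense spectra: the moment-matched form is accurate in the far tail but
its bulk error under correlated kernel features is large enough to fail
uniformity diagnostics, whereas the exact inversion is uniform to numerical
precision.  A single eigenvalue short-circuits to the scaled chi-square
closed form.

Under the fully null model the component p-values are uniform; the
joint-significance maxima and their Cauchy combination are *by construction*
conservative there (a max of two independent uniforms has CDF t²), which is
the price of composite-null protection — calibration claims are therefore
stated, and tested, on the component score tests.

## Causal mediation

Quasi-Bayesian: 1000 draws (default) from each fitted model's asymptotic
multivariate-normal sampling distribution; per draw NIE = αβ, DE = γ′,
TE = NIE + DE (exact identity), PM = NIE/TE.  Point estimates are draw means
for NIE/DE/TE and the draw median for PM (the ratio is heavy-tailed);
intervals are 2.5/97.5 percentiles; a two-sided interval excluding 0 marks
significance.  PM is never truncated to [0, 1] — with a noisy total effect
the interval legitimately exceeds 1.  When the TE draws concentrate at 0 the
PM estimate is flagged unstable rather than suppressed.  Effects can be
rescaled to a one-IQR exposure increment (linear-interpolation quantile
convention, configurable); PM is scale-invariant and unchanged.  Per-site
seeds are spawned deterministically from the run seed keyed to the sorted
candidate list, so results are independent of candidate order.

## Pipeline

`run_pipeline` wires the stages per outcome domain: association sweep →
pre-screen → DACT; SIS → HIMA; gene map → gene-level tests; then
quasi-Bayesian validation of the union of DACT-FDR and HIMA-FDR survivors
plus any explicitly listed sites (nominal-only HIMA hits can be included by
config).  A complete-case rule drops samples with missing covariates and
reports the count.  Every run writes a JSON manifest with per-stage record
counts, warnings (calibration skips, degenerate sites/genes) and the config
echo; repeated runs with the same seed are file-for-file hash-identical.
FDR is always computed within a testing context (per domain, per method, per
screened or gene set) and the context size is logged.

## Numerical and testing choices

Simulation scales in the test suite (e.g. 50-seed KS batteries at
n = 300 / m = 5000, 100-seed error-control and power batteries at
m = 1000–2000, a 15-seed end-to-end battery at n = 400 / m = 2000) were
chosen to keep the full suite to a few minutes of one-CPU time while leaving
the Monte-Carlo margins of the asserted thresholds comfortable.  Uniformity
checks that feed the one-sample KS test use generator configs with
independent sites (block ρ = 0): the KS reference distribution assumes
independent draws, and with correlated blocks its variance inflates and
produces spurious rejections even when every p-value is exactly uniform —
the claim under test is calibration of the per-site models, not the KS
test's robustness to dependence.  Those checks also run on the M-value
scale, where the generator's mediator errors are exactly Gaussian and exact
uniformity is the correct expectation; beta-scale defaults are exercised by
separate smoke checks.

## Known limitations

* All inference is conditional on the linear no-interaction structural
  model; exposure–mediator interactions, binary outcomes and survival
  outcomes are out of scope.
* No correction for correlation between mediators beyond reporting Pearson
  matrices of selected sites; DACT and HIMA treat sites marginally.
* Post-selection p-values in HIMA are anti-conservative by construction;
  the joint-significance + FDR combination, not the refit p-values alone,
  carries the error-control guarantee.
* No sensitivity analysis for unmeasured mediator–outcome confounding.
* The empirical-null calibration assumes the majority of screened sites are
  null; heavily signal-laden screened sets push it toward conservatism.
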