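# Methods

## Scope and model

`synthits` estimates the effect of a single population-level intervention
on monthly health-event rates using a comparative interrupted time series
(ITSA) whose comparison series is a synthetic control. The pipeline is:
registry events → monthly counts on a complete month × 5-year-age-group
grid → directly age-standardized rates per 100 000 → trailing annual
moving average → natural log → synthetic control from a donor pool →
stacked two-group segmented regression with HAC inference → effect
conversions and averted-event accounting.

The outcome model for the stacked treated (Z=1) and control (Z=0) series is

    Y_t = β0 + β1 T + β2 X + β3 X T′ + β4 Z + β5 Z T + β6 Z X + β7 Z X T′ + ε_t

where T is the within-series month index (1..n), X indicates post-onset
months, and T′ is months-since-onset. β4 (level) and β5 (trend) measure
pre-period balance between the series; β6 and β7 are the causal level and
trend effects. With the default re-centering (T′ = T − T_onset), β6 is the
jump at the onset month itself, matching the "immediate effect" reading;
`build_design(..., centering=False)` reproduces the literal uncentered
interaction for sensitivity analysis.

## Rates

- **Age grid.** 5-year groups from 20–24 to the open-ended 80+; events
  below age 20 are excluded (negligible incidence of the tobacco-related
  outcomes at younger ages). Analysis bands are 20–44, 45–64, 65+ and the
  entire population 20+ (lower bound inclusive).
- **Standardization.** rate(m) = Σ_a w̃_a (count_a / pop_a) · 100 000 with
  standard weights renormalized over the band's groups. The shipped
  default is the WHO world standard population (2000–2025 vintage), with
  its 80–84 and 85+ rows collapsed to 80+ to match the registry grid;
  because weights are renormalized per band, the collapse is exact. Any
  other weight table can be loaded from CSV. Annual populations are held
  constant within the calendar year (no monthly interpolation).
- **Sexes** are combined by summing counts before rates are formed, never
  by averaging rates (rates are nonlinear in counts).
- **Smoothing.** The smoothed value at month m is the mean of the raw
  standardized rate over [m−11, m]; the first 11 months are dropped and
  the log is taken afterwards. Averaging on the rate scale (default) keeps
  the rate interpretation of summary tables; `order="log"` averages log
  rates instead, and removes a pure 12-month-periodic seasonal component
  exactly (any period-12 signal has a constant 12-window mean). On the
  rate scale the residual seasonal amplitude after smoothing is below 1%
  of the original for realistic trend sizes, which the tests assert.
  Zero monthly counts are allowed pre-smoothing; only the smoothed rate
  must be positive, and a series with a full window of zeros is flagged
  ineligible for the donor pool rather than imputed.
- **Onset rule.** With trailing smoothing the first analysis month fully
  governed by the policy is policy_month + window − 1: a March-2013
  enactment with a 12-month window gives a February-2014 onset.

## Synthetic control

The control series is an L1-penalized regression of the treated series on
the donor pool over pre-onset months: unconstrained signs, an unpenalized
intercept, donors standardized to zero mean/unit variance on the
pre-period with those statistics frozen for post-period prediction (no
leakage). This is the lasso variant of the synthetic-control idea; the
classic convex-hull weight constraint is deliberately not imposed.

- **Donor pool.** Candidate series must share the treated month grid; the
  treated cause, composites containing it, configured exclusions
  (tobacco-related or policy-covered causes) and ineligible series are
  removed with named reasons, never silently.
- **Penalty choice.** λ is selected by rolling-origin cross-validation
  inside the pre-period: validation blocks of length ⌈25% of the
  pre-period⌉, the last block ending at the final pre-onset month, each
  fold training on everything earlier (minimum 12 training months; 3
  folds by default). The grid is 20 log-spaced values from λ_max down to
  λ_max/1000 plus the unpenalized limit λ=0; ties in mean validation MSE
  break toward the largest (sparsest) λ, and a one-standard-error rule is
  available behind a flag. The solver is an exact coordinate-descent
  lasso (Gram form, input-order sweeps, tolerance 1e-7, warm starts along
  the λ path); exact coordinate minimization makes the penalized
  objective non-increasing, which a test verifies, and λ=0 falls back to
  a direct least-squares solve.
- **Adequacy.** A fit is adequate when its pre-period RMSPE is at most
  0.25 treated pre-period standard deviations (configurable) and, when a
  balance report is supplied, β4/β5 are jointly nonsignificant.
  Inadequate fits are reported, not dropped — mirroring real analyses
  where some strata simply have no usable control.
- **Placebo inference.** Every donor is refit as pseudo-treated against
  the remaining donors; placebos failing the adequacy filter are excluded
  with a logged count, and rank_p = (1 + #{placebo ratio ≥ treated
  ratio}) / (1 + #placebos) on the post/pre RMSPE ratio.

## Inference

OLS point estimates carry a Bartlett-kernel HAC ("Newey–West") sandwich
covariance, with lag cross-products computed within each stacked series
block only — lags never span the treated/control boundary. The default
lag is 12 (one seasonal cycle of monthly data), configurable. t statistics
are referred to Student-t with n−9 degrees of freedom; one-tailed
p-values default to the "declined with the intervention" direction
(alternative "less") and two-tailed p-values are always reported
alongside. Balance uses the two-tailed p-values of β4 and β5.

**Known limitation — HAC calibration at these sample sizes.** With ~121
months per series and lag 12, the residual-based Bartlett HAC
underestimates the sampling variance of the level-change coefficient:
Monte Carlo under the generator's conditions (AR(1) φ=0.3, σ=0.05) gives
95% CI coverage of ~0.85 and a one-tailed null rejection rate of ~0.12 at
nominal 0.05, and an independent HAC implementation (statsmodels) shows
the same distortion on the same design. The distortion persists with iid
errors and disappears as the series lengthen, identifying it as the
well-documented downward bias of kernel HAC estimators at large
lag-to-sample ratios rather than a property of this implementation. Point
estimates are unbiased (mean bias of β6 ≈ 0.003, of β7 ≈ 1e-5 in the same
experiment). Users should read borderline significance accordingly;
shorter lags reduce but do not remove the distortion.

## Effects

- **Percent.** 100·β, matching the convention by which a −0.087 level
  coefficient is reported as an 8.7% drop; the exact transform
  100·(e^β − 1) is reported alongside (for |β| < 0.1 the two differ by
  less than 0.6 percentage points).
- **Absolute.** reference_rate · β events per 100 000, with the reference
  (post-intervention mean by default, pre-mean selectable) and its
  provenance recorded; reported tables round to 2 decimals.
- **Averted events.** Monthly counterfactual count = observed count ×
  exp(synthetic − treated log rate), summed over post-onset months.
  Rate-ratio scaling is used because standardized rates are not
  invertible to crude counts without age detail; the identity "synthetic
  = treated ⇒ zero averted" holds exactly regardless of count noise.
- **Reporting.** Tidy tables per cause × band × {level, trend} with HAC
  CIs and stars (one-tailed p < .01 "***", < .05 "**", < .1 "*").

## Synthetic-data generator

`SimulationSpec` defaults encode the study conditions: 132 months
(2007–2017), policy month March 2013 (index 74), 12-month window hence
onset February 2014 (index 85), 33 donor series. Donors are intercept
(U(0.5, 4), spanning log rates of ~1.6 to ~55 per 100 000) + linear trend
(U(−0.006, 0.006)/month, i.e. up to ±0.8 log points over the window,
consistent with the secular declines seen in cardiovascular registry
series) + a 12-month sinusoid (amplitude up to 0.05) + loadings on two
shared latent factors (standardized random walks scaled to 0.5) + AR(1)
noise on the log scale (φ=0.3, innovation σ=0.05). The treated series is a
sparse weighted combination of the observed donors (weights 0.5/0.3/0.2
by default) plus the injected level/trend effect and optional
idiosyncratic noise. AR(1) on the log scale is the simplest structure
that exercises the HAC correction; seasonality is a single sinusoid
because that suffices to test its removal by the trailing annual mean.
An event-level generator draws Poisson counts with mean target_rate ×
population / 100 000 per month × 5-year group × sex (overdispersion is
out of scope), so the expected standardized rate equals the weighted
target and the event→rate stages can be tested end to end.

What the generator does **not** emulate: the demographic composition and
disease mix of real registries, reporting artifacts (late registration,
coding changes), monthly population dynamics, and cross-sex heterogeneity
in trends. Passing tests therefore demonstrate the correctness and
calibration of the estimation machinery under the assumed structure, not
the validity of the substantive conclusions for any particular registry.

## Problem sizes and reproducibility

The calibration experiments run at 500 replicates (bias/coverage), 1000
(null size), 200 (synthetic-control recovery, with a 30-donor pool) and
200 (placebo null, with a 15-donor pool and one extra exchangeable series
designated pseudo-treated — exchangeability is what makes rank_p uniform
under the null; 15 donors keeps ~16 lasso fits per replicate tractable).
All randomness flows from a single integer seed through
`numpy.random.SeedSequence`, so every experiment is bit-reproducible.

## Degenerate inputs and tie-breaks

Zero-variance treated pre-periods, empty donor pools, misaligned month
grids, rank-deficient designs (collinear columns are named via pivoted
QR), onsets at the first month, negative populations/rates and malformed
ICD-10 codes all raise immediately with specific messages. Constant
donors are retained with zero weight. λ ties break toward sparsity;
coordinate descent sweeps donors in input order, making fits
deterministic and permutation-invariant up to the solver tolerance.
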