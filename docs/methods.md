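# Methods

## Estimand and data model

The quantity of interest is the cohort fertility rate (CFR) of a
(country, region, education) cell: the mean completed number of children
per woman, measured after the reproductive lifespan.  The sufficient
statistics of a cell are N (women with known parity) and B (their total
children); the raw rate is B/N.  Each woman's completed parity is modelled
as Poisson, so B ~ Poisson(N·θ) with θ the cell's true rate.  This is an
approximation — real parity distributions are mildly under-dispersed
relative to Poisson and have parity-progression structure — but it is the
standard working model for small-area rate smoothing and is exactly the
model the synthetic generator simulates from.

Women with unknown parity (a census/survey artefact) are redistributed
before any rate is computed: each such woman is assigned the mean parity of
a reference group, by default the same education pooled over all regions of
her country.  That choice is deliberately conservative: imputing within
country × education preserves the educational gradient rather than pulling
groups toward the national mean.  An empty reference group contributes
parity 0 with a logged warning.  Totals are conserved: N gains the unknown
count, B gains `round(n_unknown · mean_ref)`.

Country-level summary tables pool cells (ΣB/ΣN) — the CFR of the national
population, not the unweighted mean of regional rates.  Educational
gradients (Δ high–medium, Δ medium–low, Δ high–low) are differenced from
unrounded rates and rounded only for display; consequently a printed pair
of 2-decimal CFRs can differ from the printed Δ by a few hundredths, and
the packaged reference table keeps its printed gradients as authoritative
rather than re-differencing rounded rates.

## Empirical Bayes smoother

Prior: θ ~ Gamma(ν·m, ν), i.e. prior mean m and prior "pseudo-women" count
ν.  Posterior: θ | B, N ~ Gamma(B + ν·m, N + ν).  The posterior mean
(B + ν·m)/(N + ν) moves from m (empty cell) to B/N (register-scale cell);
the weight on the prior, ν/(N + ν), is decreasing in N, so small samples
are smoothed hard and full registers barely at all.  Central 95% credible
intervals are Gamma quantiles.

The reference rate m of a cell mixes two sources with weights
(λ_region, λ_education) = (0.7, 0.3) by default:

1. **cross-region, same education** — m_reg = Σ w(r,r′)·B_{r′e} /
   Σ w(r,r′)·N_{r′e} over the other regions r′ of the same country, where
   w(r,r′) = exp(−(log g_r − log g_{r′})² / 2h²) is a Gaussian kernel on
   log GDP per capita.  Donors therefore count in proportion to their size
   N and their economic similarity; the kernel bandwidth h defaults to the
   pooled within-country SD of log GDP (on the data analysed this is the
   natural scale of between-region GDP spread; it is config-exposed).
   A cell never donates to itself (zero kernel diagonal), and weights never
   cross a country border.
2. **cross-education, same region** — the pooled rate of the region's other
   education groups, multiplied by ρ_e, the country-level ratio of
   education-e fertility to other-education fertility.  This imports the
   country's education-specific rate regularity into regions where the
   group itself is thinly observed.

λ_region dominates because same-education cells elsewhere in the country
are the more direct analogue of the target cell.  When one source has no
data its weight moves entirely to the other; a cell whose country has no
data for either source cannot be smoothed and is skipped with a warning.
A cell unobserved in the input but whose education is observed elsewhere in
the country receives the prior directly (estimate = m).

Prior strength ν is estimated per country by method of moments: the
between-cell variance of raw rates in excess of the average Poisson
sampling variance (mean of rate/N) is attributed to the prior, whose
variance is m/ν, giving ν = mean(rate)/excess, capped to [1, 10⁶].  The
caps handle the homogeneous limit (no excess variance → maximal shrinkage)
and the heterogeneous limit (minimal shrinkage).  Countries with fewer
than two populated cells fall back to a global estimate.  Reference rates
are floored at 10⁻⁸ so posteriors stay proper when a borrowing source is
all-zero.

## Gradient regressions

Each region with both education groups estimated contributes one point
(Δ, log g): the CFR difference (same estimation method on both sides,
never raw mixed with smoothed) against natural-log GDP per capita.  The
pooled model is OLS with intercept across all regions of all countries;
the fixed-effects model is the within estimator — demean Δ and log g
inside each country, OLS through the origin — which is algebraically
identical to OLS with country dummies (asserted in tests to 1e-10) and
averages the within-country associations.  Regressions are unweighted:
one region, one observation.  Slope units are children per woman per unit
of natural-log GDP.  No causal interpretation is attached; standard errors
are conventional homoskedastic OLS errors.

The HGDP comparison selects each country's highest-GDP region (ties broken
lexicographically by region code and logged) and contrasts its Δ with the
pooled Δ of all other regions (cells summed before rates; implemented as
the women-weighted average of cell rates, which is the same identity and
extends naturally to posteriors).  Credible intervals are empirical
2.5/97.5 percentiles of n_draws = 2000 Monte-Carlo draws from each cell's
Gamma posterior, differenced; a difference of Gammas has no closed form.
Countries with a single region report missing "rest" fields.

## Synthetic generator

One woman = one row; no household, partner, cohort-year or
parity-progression structure (the estimand needs only region, education,
parity).  For a region with GDP g in country c, a woman of education e has
parity ~ Poisson(μ_e + β_e·(log g − log-GDP mean) + u_c), floored at 10⁻⁶
with a logged warning if the linear predictor goes non-positive.  Defaults:
μ = (2.03, 1.78, 1.62) children for low/medium/high — the cross-country
averages of the published 15-country table — and pair slopes
(high−medium, medium−low) = (0.3, 0.2) per log-GDP unit, with the low
slope anchored at zero (three pair slopes cannot be independent under a
linear model).  Education shares start from (0.16, 0.53, 0.31) (the
cross-country average composition) and the high share is logit-tilted
upward in log GDP (tilt 1.0), mimicking the concentration of the
high-educated in developed regions.  Country effects u_c ~ N(0, 0.1²) are
additive and common to all education groups, so they cancel in gradients
and are exactly what country fixed effects absorb.  Regional log GDP is
N(10, 0.35²) (arbitrary currency units; only log-differences matter).
Sampling fractions emulate 1%-survey to 100%-register sources via
independent Bernoulli thinning; an optional unknown-parity fraction
(default 0) exercises the redistribution rule.  All randomness flows from
a single integer seed through deterministic per-region sub-streams, so
identical configs give byte-identical output.

What the generator does **not** emulate: spatial autocorrelation beyond the
GDP covariate, migration histories, non-Poisson parity dispersion, and
education-dependent response rates.  Passing recovery tests therefore show
the estimators are correct under the stated model, not that real registers
satisfy that model.

## Validation design and problem sizes

- **Oracle equivalence**: the full smoother is checked against an
  independent loop-based reimplementation on a 3-country × 4-region ×
  3-education problem to 1e-10, and posterior interval endpoints against
  numerical inversion of the quadrature CDF to 1e-6.
- **Slope recovery**: 200 replications of the full pipeline (generate →
  aggregate → smooth → gradient → within fit) at 5 countries × 6 regions ×
  10,000 women, full sampling, at true slopes 0.3 and 0.  Observed absolute
  bias is below 0.01; nominal-95% interval coverage lands near 0.93.
- **HGDP calibration**: 500 replications at 4 countries × 5 regions × 3,000
  women; at this register-like scale the prior's influence is mild and the
  credible intervals are near-nominal (observed ≈ 0.95).
- **Shrinkage economics**: at 1% sampling the EB estimates' mean squared
  error against the generator's true rates is roughly a third of the raw
  estimates' (ratio ≈ 0.35 over 100 replications); at register scale
  (N ≥ 10⁵) the maximum |EB − raw| gap is below 0.01 children.

These sizes were fixed once as representative study conditions; all
simulation checks derive their seeds deterministically from one base seed.

## Known limitations

- The borrowing constants (λ mix, bandwidth rule, moment-based ν) are this
  package's own reconstruction of a standard Poisson–Gamma small-area
  scheme; other defensible choices exist, and numerical agreement with any
  specific published regional estimates is not claimed.
- Credible intervals ignore the estimation uncertainty in m, ν and h
  (classic empirical-Bayes understatement); the calibration simulations
  show this is negligible at the simulated sizes but it may not be for very
  sparse countries.
- The within estimator's standard errors are not clustered and assume
  homoskedastic region-level errors.
- Degenerate inputs: a single-region country cannot borrow cross-region
  and reports no "rest" comparison; an education absent from an entire
  country cannot be estimated at all.
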