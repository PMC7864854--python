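# fertgrad

Educational gradients in women's completed (cohort) fertility across
sub-national European regions: small-area estimation of education-by-region
cohort fertility rates and regression of the educational gradient on
regional economic development.

## The problem

The cohort fertility rate (CFR) of a group of women observed at the end of
the reproductive lifespan is the mean number of children ever born per
woman.  Comparing CFRs between educational attainment groups (low / medium /
high, ISCED-based) at the level of NUTS-style sub-national regions raises a
statistical problem: many data sources are 1–10% samples, so the raw cell
rate B/N (children over women) in a small region-by-education cell is
dominated by sampling noise.  This package provides:

- **a synthetic microdata generator** producing register-style records —
  one woman per row with country, region, education, completed parity —
  with Poisson parities whose means are linear in regional log GDP per
  capita, known education-specific gradients, GDP-tilted education
  composition, and country-level heterogeneity, so every downstream
  estimator can be validated against ground truth;
- **empirical Bayes (EB) smoothing** of cell rates under a Poisson
  likelihood with a conjugate Gamma(ν·m, ν) prior.  With cell totals
  B ~ Poisson(N·θ), the posterior is θ ~ Gamma(B + ν·m, N + ν), with mean
  (B + ν·m)/(N + ν): a convex combination of the raw rate and a reference
  rate m that borrows strength — always within the country — from the same
  education in other regions (weighted by donor size and by a Gaussian
  kernel on log-GDP similarity) and from the region's other education
  groups (rescaled by the country's education-specific rate regularities).
  Prior strength ν is estimated per country by method of moments; 95%
  credible intervals come from Gamma quantiles;
- **gradient regressions**: per region, the CFR difference Δ between two
  education groups is regressed on log GDP per capita, pooled across all
  countries (Δ = α + β·log g + ε) and with country fixed effects (the
  within estimator, equal to OLS with country dummies), plus a comparison
  of each country's highest-GDP (HGDP) region against its remaining regions
  pooled, with Monte-Carlo credible intervals from the Gamma posteriors;
- **a packaged reference table** of published country-level CFRs by
  education for 15 European countries, used for exact cross-checks of the
  summary-table machinery.

## Worked example

```python
import fertgrad as fg

cfg = fg.SyntheticConfig(
    n_countries=4, regions_per_country=6, women_per_region=5000,
    gradient_slope_by_pair={"high_medium": 0.3, "medium_low": 0.2}, seed=1,
)
regions, cells, est = fg.estimate_pipeline(cfg, outcome_method="eb")
points = fg.gradient_table(est, regions, "high_medium")
pooled = fg.fit_pooled(points)
fe = fg.fit_fixed_effects(points)
print(f"pooled slope: {pooled.slope:.3f} (SE {pooled.slope_se:.3f})")
print(f"fixed-effects slope: {fe.slope:.3f} (SE {fe.slope_se:.3f})")
comp = fg.hgdp_compare(est, regions, "high_medium", fg.EBParams(seed=1))
print(comp[["country_id", "hgdp_region", "delta_hgdp", "delta_rest"]]
      .round(3).to_string(index=False))
```

prints

```
pooled slope: 0.335 (SE 0.043)
fixed-effects slope: 0.346 (SE 0.042)
country_id hgdp_region  delta_hgdp  delta_rest
       C01      C01R05      -0.031      -0.174
       C02      C02R02      -0.057      -0.124
       C03      C03R04      -0.168      -0.181
       C04      C04R05      -0.002      -0.176
```

Both regression slopes are within sampling error of the generator's true
high-minus-medium gradient slope of 0.3 children per woman per log-GDP
unit: the high-vs-medium fertility deficit shrinks as regional development
rises.  The HGDP comparison shows the same pattern non-parametrically — in
every synthetic country the educational gap is smaller (closer to zero) in
the highest-GDP region than in the other regions pooled.

The same pipeline is available from the shell:

```
fertgrad --config config.yaml simulate
fertgrad --config config.yaml estimate
fertgrad --config config.yaml report
```

All commands run with zero arguments using built-in defaults; outputs are
plain CSV/JSON files, logs go to stderr.

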