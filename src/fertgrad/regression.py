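"""Regressions of educational CFR gradients on regional log GDP per capita.

Each region contributes one observation per education pair: the difference
in CFR between the two groups (e.g. high minus medium), paired with the
natural log of the region's GDP per capita.  Two linear models are fitted:

* pooled — a single OLS line across all regions of all countries, the
  cross-country association between development and the gradient;
* fixed effects — the within estimator: demean outcome and covariate inside
  each country and fit through the origin, equivalent to OLS with country
  dummy variables; its slope averages the within-country associations.

A separate comparison contrasts the highest-GDP (HGDP) region of each
country against all its other regions pooled, with credible intervals
propagated from the Gamma posteriors of the smoothed rates by Monte Carlo.

Slopes are in children per woman per unit of natural-log GDP; regressions
are unweighted (one region, one point) and carry no causal interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cfr import aggregate, redistribute_unknown, raw_cfr_table
from .smoothing import EBParams, PosteriorRate, smooth_table
from .synthetic import PAIRS, SyntheticConfig, generate_microdata, generate_regions

logger = logging.getLogger("fertgrad")


@dataclass(frozen=True)
class GradientFit:
    """Fitted association between an educational CFR gap and log GDP."""

    pair: str
    model: str  # "pooled" | "fixed_effects"
    slope: float
    slope_se: float
    intercept: Optional[float]  # pooled only
    n_regions: int
    country_intercepts: dict[str, float] = field(default_factory=dict)


def gradient_table(
    estimates: pd.DataFrame, regions: pd.DataFrame, pair: str
) -> pd.DataFrame:
    """One gradient point per region: delta = CFR_e1 - CFR_e2, with log GDP.

    Both CFRs must come from the same estimation method (never mix raw with
    smoothed); regions missing either education are skipped with a logged
    count.  Columns: country_id, region_id, pair, delta, log_gdp.
    """
    if pair not in PAIRS:
        raise ValueError(f"unknown pair {pair!r}")
    if estimates["method"].nunique() > 1:
        raise ValueError("estimates mix methods; smooth and raw deltas must not be combined")
    e1, e2 = PAIRS[pair]
    wide = estimates.pivot_table(
        index=["country_id", "region_id"], columns="education", values="cfr"
    )
    for e in (e1, e2):
        if e not in wide.columns:
            wide[e] = np.nan
    ok = wide[e1].notna() & wide[e2].notna()
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("gradient_table(%s): %d region(s) missing an education estimate", pair, n_skipped)
    pts = wide[ok].reset_index()
    pts["pair"] = pair
    pts["delta"] = pts[e1] - pts[e2]
    gdp = regions.set_index("region_id")["gdp_pc"]
    pts["log_gdp"] = np.log(pts["region_id"].map(gdp).to_numpy(dtype=float))
    return pts[["country_id", "region_id", "pair", "delta", "log_gdp"]]


def fit_pooled(points: pd.DataFrame) -> GradientFit:
    """OLS of delta on log GDP with intercept, pooled over all regions."""
    if len(points) < 3:
        raise ValueError("pooled fit needs at least 3 points")
    if points["log_gdp"].nunique() < 2:
        raise ValueError("design is rank deficient: log_gdp has no variation")
    x = sm.add_constant(points["log_gdp"].to_numpy(dtype=float))
    fit = sm.OLS(points["delta"].to_numpy(dtype=float), x).fit()
    return GradientFit(
        pair=str(points["pair"].iloc[0]),
        model="pooled",
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        n_regions=len(points),
    )


def fit_fixed_effects(points: pd.DataFrame) -> GradientFit:
    """Within (country fixed effects) estimator.

    Demeans delta and log GDP within each country and fits OLS through the
    origin on the demeaned values — algebraically identical to OLS with
    country dummy variables.  The residual degrees of freedom account for
    the absorbed country means (n - n_countries - 1), so the slope SE
    matches the dummy-variable regression.
    """
    counts = points.groupby("country_id").size()
    if not (counts >= 2).any():
        raise ValueError("fixed-effects fit needs a country with at least 2 regions")
    y = points["delta"].to_numpy(dtype=float)
    x = points["log_gdp"].to_numpy(dtype=float)
    grp = points.groupby("country_id")
    y_t = y - grp["delta"].transform("mean").to_numpy(dtype=float)
    x_t = x - grp["log_gdp"].transform("mean").to_numpy(dtype=float)
    sxx = float(x_t @ x_t)
    if sxx <= 0:
        raise ValueError("design is rank deficient: no within-country log_gdp variation")
    slope = float(x_t @ y_t) / sxx
    resid = y_t - slope * x_t
    dof = len(points) - points["country_id"].nunique() - 1
    if dof <= 0:
        raise ValueError("not enough observations for a fixed-effects standard error")
    sigma2 = float(resid @ resid) / dof
    intercepts = {
        c: float(g["delta"].mean() - slope * g["log_gdp"].mean())
        for c, g in grp
    }
    return GradientFit(
        pair=str(points["pair"].iloc[0]),
        model="fixed_effects",
        slope=slope,
        slope_se=float(np.sqrt(sigma2 / sxx)),
        intercept=None,
        n_regions=len(points),
        country_intercepts=intercepts,
    )


def per_country_fits(points: pd.DataFrame) -> dict[str, GradientFit]:
    """Separate pooled OLS line per country (the per-country trend lines)."""
    out = {}
    for c, g in points.groupby("country_id"):
        if len(g) >= 3 and g["log_gdp"].nunique() >= 2:
            out[str(c)] = fit_pooled(g)
    return out


def _weighted_delta_draws(
    sub: pd.DataFrame, pair: str, n_draws: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Point estimate and posterior draws of a (pooled) CFR difference.

    ``sub`` holds smoothed-estimate rows (with post_shape/post_rate and
    n_women) for one or more regions.  Per education, cell rates are
    combined as a women-weighted average — identical, for raw rates, to
    summing the cells before dividing.  Returns (point, draws).
    """
    e1, e2 = PAIRS[pair]
    vals = {}
    draw_vals = {}
    for e in (e1, e2):
        rows = sub[sub["education"] == e]
        wts = rows["n_women"].to_numpy(dtype=float)
        if len(rows) == 0 or wts.sum() <= 0:
            return np.nan, np.full(n_draws, np.nan)
        wts = wts / wts.sum()
        means = rows["cfr"].to_numpy(dtype=float)
        vals[e] = float(wts @ means)
        draws = np.stack(
            [
                PosteriorRate(r.post_shape, r.post_rate).draws(n_draws, rng)
                for r in rows.itertuples()
            ]
        )
        draw_vals[e] = wts @ draws
    return vals[e1] - vals[e2], draw_vals[e1] - draw_vals[e2]


def hgdp_compare(
    estimates: pd.DataFrame,
    regions: pd.DataFrame,
    pair: str,
    params: EBParams = EBParams(),
) -> pd.DataFrame:
    """Highest-GDP region versus all other regions, per country.

    The HGDP region is the argmax of GDP per capita within the country
    (ties broken by region code order and logged).  The "rest" delta pools
    the remaining regions' cells before computing rates.  Credible
    intervals come from ``params.n_draws`` Monte-Carlo draws of each cell's
    Gamma posterior, so ``estimates`` must be smoothed output carrying
    ``post_shape``/``post_rate``.  Countries with a single region get
    missing rest fields.
    """
    if "post_shape" not in estimates.columns:
        raise ValueError("hgdp_compare needs smoothed estimates with posterior parameters")
    rng = np.random.default_rng(params.seed)
    alpha = (1.0 - params.ci_level) / 2.0
    rows = []
    for country, regs in regions.groupby("country_id", sort=True):
        top = regs["gdp_pc"].max()
        winners = sorted(regs.loc[regs["gdp_pc"] == top, "region_id"])
        if len(winners) > 1:
            logger.warning(
                "country %s: HGDP tie among %s; keeping %s", country, winners, winners[0]
            )
        hgdp_region = winners[0]
        est_c = estimates[estimates["country_id"] == country]
        point_h, draws_h = _weighted_delta_draws(
            est_c[est_c["region_id"] == hgdp_region], pair, params.n_draws, rng
        )
        rec = {
            "country_id": country,
            "pair": pair,
            "hgdp_region": hgdp_region,
            "delta_hgdp": point_h,
            "ci_hgdp_low": float(np.nanquantile(draws_h, alpha)) if np.isfinite(point_h) else np.nan,
            "ci_hgdp_high": float(np.nanquantile(draws_h, 1 - alpha)) if np.isfinite(point_h) else np.nan,
        }
        rest = est_c[est_c["region_id"] != hgdp_region]
        if len(regs) < 2 or len(rest) == 0:
            rec.update(delta_rest=np.nan, ci_rest_low=np.nan, ci_rest_high=np.nan)
        else:
            point_r, draws_r = _weighted_delta_draws(rest, pair, params.n_draws, rng)
            rec.update(
                delta_rest=point_r,
                ci_rest_low=float(np.nanquantile(draws_r, alpha)) if np.isfinite(point_r) else np.nan,
                ci_rest_high=float(np.nanquantile(draws_r, 1 - alpha)) if np.isfinite(point_r) else np.nan,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def estimate_pipeline(
    config: SyntheticConfig,
    outcome_method: str = "eb",
    eb_params: EBParams = EBParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """generate -> aggregate -> redistribute -> estimate, returning
    (regions, cells, estimates)."""
    regions = generate_regions(config)
    micro = generate_microdata(regions, config)
    cells = redistribute_unknown(aggregate(micro))
    if outcome_method == "eb":
        est = smooth_table(cells, regions, eb_params)
    elif outcome_method == "raw":
        est = raw_cfr_table(cells)
    else:
        raise ValueError("outcome_method must be 'raw' or 'eb'")
    return regions, cells, est


def recover_slope(
    config: SyntheticConfig,
    n_replications: int,
    seed: int,
    pair: str = "high_medium",
    outcome_method: str = "eb",
    eb_params: EBParams = EBParams(),
) -> dict:
    """Simulation study of the fixed-effects slope estimator.

    Runs the full pipeline ``n_replications`` times with fresh seeds,
    fitting the within estimator each time, and reports the mean estimated
    slope, its bias against the generator's ground-truth pair slope, the
    empirical SD, and the coverage of nominal 95% intervals
    (slope +/- 1.96 SE).
    """
    beta = config.pair_slope(pair)
    slopes, ses = [], []
    for rep in range(n_replications):
        rep_seed = int(
            np.random.SeedSequence([int(seed), rep]).generate_state(1)[0] & 0x7FFFFFFF
        )
        cfg = config.with_seed(rep_seed)
        regions, _, est = estimate_pipeline(cfg, outcome_method, eb_params)
        points = gradient_table(est, regions, pair)
        fit = fit_fixed_effects(points)
        slopes.append(fit.slope)
        ses.append(fit.slope_se)
    slopes_arr = np.asarray(slopes)
    ses_arr = np.asarray(ses)
    covered = np.abs(slopes_arr - beta) <= 1.96 * ses_arr
    return {
        "pair": pair,
        "true_slope": beta,
        "n_replications": n_replications,
        "mean_slope": float(slopes_arr.mean()),
        "bias": float(slopes_arr.mean() - beta),
        "sd_slope": float(slopes_arr.std(ddof=1)) if n_replications > 1 else 0.0,
        "coverage_95": float(covered.mean()),
    }
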