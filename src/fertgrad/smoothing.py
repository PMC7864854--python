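"""Empirical Bayes Poisson-Gamma smoothing of cell-level fertility rates.

Small cells — a 1% survey can leave an education group in a region with a
handful of women — make raw CFRs noisy.  Treating each woman's completed
parity as Poisson, the total children of a cell satisfy B ~ Poisson(N * theta)
with theta the cell's true rate.  A conjugate Gamma(nu * m, nu) prior on theta
gives the posterior

    theta | B, N  ~  Gamma(B + nu * m, N + nu),

whose mean (B + nu*m) / (N + nu) is a convex combination of the raw rate B/N
and the reference rate m, with prior strength nu acting as a pseudo-count of
women.  Large cells are barely moved; empty cells fall back to m entirely.

The reference rate m borrows strength, always within the country, from two
sources mixed with weights (lambda_region, lambda_education):

* cross-region, same education — a weighted mean of donor-cell rates, with
  weights proportional to donor size N and to a Gaussian kernel on the log
  GDP per capita distance between regions, so economically similar regions
  inform each other more;
* cross-education, same region — the pooled rate of the region's other
  education groups, rescaled by the country-level ratio of the target
  education's rate to the other groups' rate (the country's education-
  specific fertility regularity).

nu is estimated per country by method of moments: the between-cell variance
of raw rates in excess of Poisson sampling variance is attributed to the
prior, whose variance is m/nu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import EDUCATIONS

logger = logging.getLogger("fertgrad")

NU_BOUNDS = (1.0, 1e6)
_EPS = 1e-12
#: floor for reference rates so Gamma posteriors stay proper
_M_FLOOR = 1e-8


@dataclass(frozen=True)
class EBParams:
    """Tuning constants of the smoother.

    bandwidth_h : kernel scale on log GDP; ``"auto"`` uses the pooled
        within-country SD of log GDP per capita.
    prior_strength_nu : prior pseudo-women count; ``"auto"`` estimates it
        per country by method of moments.
    mix_weights : (lambda_region, lambda_education), non-negative, sum 1.
    ci_level : credible-interval mass, default 0.95.
    n_draws : posterior Monte-Carlo draws for derived quantities.
    seed : seed for those draws.
    """

    bandwidth_h: Union[float, str] = "auto"
    prior_strength_nu: Union[float, str] = "auto"
    mix_weights: tuple[float, float] = (0.7, 0.3)
    ci_level: float = 0.95
    n_draws: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bandwidth_h != "auto" and not float(self.bandwidth_h) > 0:
            raise ValueError("bandwidth_h must be positive or 'auto'")
        if self.prior_strength_nu != "auto" and not float(self.prior_strength_nu) > 0:
            raise ValueError("prior_strength_nu must be positive or 'auto'")
        lr, le = self.mix_weights
        if lr < 0 or le < 0 or abs(lr + le - 1.0) > 1e-9:
            raise ValueError("mix_weights must be non-negative and sum to 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be positive")


@dataclass(frozen=True)
class PosteriorRate:
    """Gamma posterior of a cell rate: theta ~ Gamma(shape, rate)."""

    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        lo, hi = stats.gamma.ppf([alpha, 1.0 - alpha], self.shape, scale=1.0 / self.rate)
        return float(lo), float(hi)

    def draws(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.shape, 1.0 / self.rate, size=n)


def gdp_kernel_weights(
    regions: pd.DataFrame, h: float, normalize: bool = True
) -> pd.DataFrame:
    """Gaussian similarity weights on log GDP, within country only.

    w(r, r') = exp(-(log g_r - log g_r')^2 / (2 h^2)) for r' != r in the
    same country, zero otherwise (a cell never informs its own prior, and
    borrowing never crosses a country border).  Rows with any neighbour are
    renormalised to sum to 1 (``normalize=False`` returns the raw kernel,
    which is symmetric); a country with a single region yields a zero row,
    in which case borrowing falls back to the cross-education source.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    if (regions["gdp_pc"] <= 0).any():
        raise ValueError("gdp_pc must be positive")
    log_gdp = np.log(regions["gdp_pc"].to_numpy(dtype=float))
    country = regions["country_id"].to_numpy()
    same_country = country[:, None] == country[None, :]
    gap = log_gdp[:, None] - log_gdp[None, :]
    w = np.exp(-(gap**2) / (2.0 * h * h)) * same_country
    np.fill_diagonal(w, 0.0)
    row_sums = w.sum(axis=1)
    lonely = row_sums == 0
    if lonely.any():
        logger.info(
            "%d region(s) have no within-country neighbour; "
            "cross-education borrowing only", int(lonely.sum())
        )
    if normalize:
        w[~lonely] /= row_sums[~lonely, None]
    ids = regions["region_id"].to_numpy()
    return pd.DataFrame(w, index=ids, columns=ids)


def default_bandwidth(regions: pd.DataFrame) -> float:
    """Pooled within-country SD of log GDP per capita (fallback 1.0)."""
    log_gdp = np.log(regions["gdp_pc"].to_numpy(dtype=float))
    df = pd.DataFrame({"c": regions["country_id"].to_numpy(), "x": log_gdp})
    centred = df["x"] - df.groupby("c")["x"].transform("mean")
    n_countries = df["c"].nunique()
    dof = len(df) - n_countries
    if dof <= 0 or (centred == 0).all():
        logger.warning("degenerate within-country GDP spread; bandwidth falls back to 1.0")
        return 1.0
    return float(np.sqrt((centred**2).sum() / dof))


def _cell_matrices(
    cells: pd.DataFrame, region_ids: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(N, B) as region x education matrices, zero-filled for absent cells."""
    n = cells.pivot(index="region_id", columns="education", values="n_women")
    b = cells.pivot(index="region_id", columns="education", values="total_children")
    n = n.reindex(index=region_ids, columns=list(EDUCATIONS)).fillna(0.0)
    b = b.reindex(index=region_ids, columns=list(EDUCATIONS)).fillna(0.0)
    return n, b


def _country_reference_rates(
    n: pd.DataFrame, b: pd.DataFrame, weights: pd.DataFrame, params: EBParams
) -> pd.DataFrame:
    """Reference rates m for every (region, education) of one country.

    Matrix form of the borrowing scheme; NaN marks cells with no usable
    source anywhere in the country.
    """
    lam_region, lam_edu = params.mix_weights
    w = weights.to_numpy(dtype=float)
    n_mat = n.to_numpy(dtype=float)
    b_mat = b.to_numpy(dtype=float)

    # cross-region, same education: size- and GDP-similarity-weighted rate
    denom_reg = w @ n_mat
    numer_reg = w @ b_mat
    with np.errstate(invalid="ignore", divide="ignore"):
        m_reg = np.where(denom_reg > 0, numer_reg / np.maximum(denom_reg, _EPS), np.nan)

    # cross-education, same region, scaled by country-level regularity
    n_other = n_mat.sum(axis=1, keepdims=True) - n_mat
    b_other = b_mat.sum(axis=1, keepdims=True) - b_mat
    with np.errstate(invalid="ignore", divide="ignore"):
        cfr_other = np.where(n_other > 0, b_other / np.maximum(n_other, _EPS), np.nan)
    n_edu_country = n_mat.sum(axis=0)  # per education, pooled over regions
    b_edu_country = b_mat.sum(axis=0)
    n_other_country = n_edu_country.sum() - n_edu_country
    b_other_country = b_edu_country.sum() - b_edu_country
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_e = np.where(n_edu_country > 0, b_edu_country / np.maximum(n_edu_country, _EPS), np.nan)
        rate_other = np.where(
            n_other_country > 0, b_other_country / np.maximum(n_other_country, _EPS), np.nan
        )
        rho = np.where(rate_other > 0, rate_e / rate_other, np.nan)
    m_edu = cfr_other * rho[None, :]

    # mix, reassigning weight when a source is unavailable
    have_reg = np.isfinite(m_reg)
    have_edu = np.isfinite(m_edu)
    m = np.full_like(m_reg, np.nan)
    both = have_reg & have_edu
    m[both] = lam_region * m_reg[both] + lam_edu * m_edu[both]
    only_reg = have_reg & ~have_edu
    m[only_reg] = m_reg[only_reg]
    only_edu = have_edu & ~have_reg
    m[only_edu] = m_edu[only_edu]
    return pd.DataFrame(m, index=n.index, columns=n.columns)


def reference_rate(
    cell: pd.Series,
    cells: pd.DataFrame,
    weights: pd.DataFrame,
    params: EBParams,
) -> float:
    """Reference (prior mean) rate m for a single cell.

    ``cell`` needs ``country_id``, ``region_id`` and ``education``;
    ``cells`` is the full cell table and ``weights`` the kernel matrix over
    all regions.  Raises when no borrowing source in the country has data.
    """
    country = cell["country_id"]
    cc = cells[cells["country_id"] == country]
    in_country = set(cc["region_id"]).union({cell["region_id"]})
    # restrict to the country's regions, preserving kernel-matrix order
    country_regions = [r for r in weights.index if r in in_country]
    n, b = _cell_matrices(cc, np.array(country_regions))
    w = weights.loc[country_regions, country_regions]
    m = _country_reference_rates(n, b, w, params)
    value = m.loc[cell["region_id"], cell["education"]]
    if not np.isfinite(value):
        raise ValueError(
            f"cell ({country}, {cell['region_id']}, {cell['education']}) "
            "has no borrowing source with data in its country"
        )
    return float(max(value, _M_FLOOR))


def estimate_nu(cells: pd.DataFrame) -> Optional[float]:
    """Method-of-moments prior strength from a set of cells.

    Between-cell variance of raw CFRs in excess of the mean Poisson sampling
    variance (mean of CFR/N) is attributed to the Gamma prior, whose
    variance is m/nu; hence nu = mean(CFR) / excess, capped to [1, 1e6].
    Returns None when fewer than two cells have data.
    """
    obs = cells[cells["n_women"] > 0]
    if len(obs) < 2:
        return None
    raw = obs["total_children"].to_numpy(dtype=float) / obs["n_women"].to_numpy(dtype=float)
    m_bar = raw.mean()
    sampling_var = (raw / obs["n_women"].to_numpy(dtype=float)).mean()
    excess = raw.var(ddof=1) - sampling_var
    if excess <= _EPS:
        logger.info("no excess between-cell variance; prior strength at upper cap")
        return NU_BOUNDS[1]
    if m_bar <= 0:
        logger.warning("all-zero rates; prior strength at upper cap")
        return NU_BOUNDS[1]
    return float(np.clip(m_bar / excess, *NU_BOUNDS))


def eb_posterior(
    n_women: float, total_children: float, m: float, nu: float
) -> PosteriorRate:
    """Conjugate update: Gamma(B + nu*m, N + nu).

    Posterior mean (B + nu*m)/(N + nu) interpolates raw rate and reference
    rate; N = 0 is allowed and returns the prior (mean m).
    """
    if m <= 0 or nu <= 0:
        raise ValueError("reference rate m and prior strength nu must be positive")
    return PosteriorRate(shape=float(total_children + nu * m), rate=float(n_women + nu))


def _complete_cells(cells: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Add explicit zero cells for every (region, education) not observed."""
    grid = regions.loc[:, ["country_id", "region_id"]].merge(
        pd.DataFrame({"education": list(EDUCATIONS)}), how="cross"
    )
    full = grid.merge(
        cells, on=["country_id", "region_id", "education"], how="left"
    ).fillna({"n_women": 0, "total_children": 0, "n_unknown": 0})
    full[["n_women", "total_children", "n_unknown"]] = full[
        ["n_women", "total_children", "n_unknown"]
    ].astype(int)
    return full


def smooth_table(
    cells: pd.DataFrame, regions: pd.DataFrame, params: EBParams = EBParams()
) -> pd.DataFrame:
    """EB-smooth every cell of every region.

    Returns one row per (region, education) — including cells unobserved in
    the input, which receive the reference rate — with columns ``cfr``
    (posterior mean), ``ci_low``/``ci_high`` (central Gamma credible
    interval at ``params.ci_level``), the posterior ``post_shape`` and
    ``post_rate``, ``n_women``, and ``method='eb'``.  Cells whose country
    holds no data at all are skipped with a logged warning.
    """
    if (cells["n_unknown"] != 0).any():
        raise ValueError("redistribute unknown parity before smoothing")
    h = default_bandwidth(regions) if params.bandwidth_h == "auto" else float(params.bandwidth_h)
    weights = gdp_kernel_weights(regions, h)
    full = _complete_cells(cells, regions)

    global_nu = (
        None if params.prior_strength_nu != "auto" else estimate_nu(full)
    )
    out_frames = []
    n_skipped = 0
    for country, cc in full.groupby("country_id", sort=True, observed=True):
        region_ids = regions.loc[regions["country_id"] == country, "region_id"].to_numpy()
        n, b = _cell_matrices(cc, region_ids)
        w = weights.loc[region_ids, region_ids]
        m = _country_reference_rates(n, b, w, params)

        if params.prior_strength_nu != "auto":
            nu = float(params.prior_strength_nu)
        else:
            nu = estimate_nu(cc)
            if nu is None:
                nu = global_nu if global_nu is not None else NU_BOUNDS[1]

        rows = cc.set_index(["region_id", "education"])
        recs = []
        for (region_id, education), row in rows.iterrows():
            m_val = m.loc[region_id, education]
            if not np.isfinite(m_val):
                n_skipped += 1
                continue
            post = eb_posterior(
                row["n_women"], row["total_children"], max(m_val, _M_FLOOR), nu
            )
            lo, hi = post.interval(params.ci_level)
            recs.append(
                {
                    "country_id": country,
                    "region_id": region_id,
                    "education": education,
                    "cfr": post.mean,
                    "method": "eb",
                    "ci_low": lo,
                    "ci_high": hi,
                    "post_shape": post.shape,
                    "post_rate": post.rate,
                    "n_women": int(row["n_women"]),
                    "ref_rate": float(max(m_val, _M_FLOOR)),
                    "nu": nu,
                }
            )
        out_frames.append(pd.DataFrame(recs))
    if n_skipped:
        logger.warning("smooth_table: %d cell(s) had no borrowing source and were skipped", n_skipped)
    out = pd.concat([f for f in out_frames if len(f)], ignore_index=True)
    return out
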