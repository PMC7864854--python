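"""Poisson-Gamma smoother: kernel weights, reference rates, prior strength,
posterior updates and whole-table smoothing against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from fertgrad import (
    EBParams,
    SyntheticConfig,
    aggregate,
    eb_posterior,
    estimate_nu,
    gdp_kernel_weights,
    generate_microdata,
    generate_regions,
    raw_cfr_table,
    reference_rate,
    smooth_table,
)

from conftest import make_cells, make_regions

EDUS = ("low", "medium", "high")


class TestKernelWeights:
    def test_equal_gdp_full_weight(self):
        regions = make_regions({"C1R1": 1e4, "C1R2": 1e4})
        w = gdp_kernel_weights(regions, h=0.5, normalize=False)
        assert w.loc["C1R1", "C1R2"] == pytest.approx(1.0)
        assert w.loc["C1R1", "C1R1"] == 0.0

    def test_gap_of_one_bandwidth(self):
        # closed form: exp(-1/2) at a log-GDP gap of exactly h
        h = 0.3
        regions = make_regions({"C1R1": np.exp(10.0), "C1R2": np.exp(10.0 + h)})
        w = gdp_kernel_weights(regions, h=h, normalize=False)
        assert w.loc["C1R1", "C1R2"] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_flat_limit_large_bandwidth(self):
        regions = make_regions({"C1R1": 5e3, "C1R2": 2e4, "C1R3": 8e4})
        w = gdp_kernel_weights(regions, h=1e6)
        off_diag = w.loc["C1R1", ["C1R2", "C1R3"]]
        assert np.allclose(off_diag, 0.5, atol=1e-9)

    def test_symmetric_before_normalisation(self):
        rng = np.random.default_rng(0)
        regions = make_regions(
            {f"C1R{i}": float(np.exp(rng.normal(10, 0.4))) for i in range(6)}
        )
        w = gdp_kernel_weights(regions, h=0.3, normalize=False).to_numpy()
        assert np.allclose(w, w.T)

    def test_no_cross_country_weight_and_singleton_zero_row(self):
        regions = make_regions({"C1R1": 1e4, "C1R2": 1.1e4, "C2R1": 1e4})
        w = gdp_kernel_weights(regions, h=0.5)
        assert w.loc["C1R1", "C2R1"] == 0.0
        assert w.loc["C2R1"].sum() == 0.0  # single-region country
        assert w.loc["C1R1"].sum() == pytest.approx(1.0)


class TestReferenceRate:
    def test_homogeneous_fixed_point(self):
        # every cell observes the common rate exactly => m equals it
        mu = 1.8
        cells = make_cells(
            [(f"C1", f"C1R{r}", e, 1000, int(1000 * mu)) for r in range(3) for e in EDUS]
        )
        regions = make_regions({f"C1R{r}": 1e4 for r in range(3)})
        w = gdp_kernel_weights(regions, h=0.5)
        for _, cell in cells.iterrows():
            assert reference_rate(cell, cells, w, EBParams()) == pytest.approx(mu)

    def test_size_weighted_donor_mean(self):
        # lambda_region = 1, equal GDP: m = (100*1.5 + 300*2.5) / 400
        cells = make_cells(
            [("C1", "C1R1", "high", 50, 100),
             ("C1", "C1R2", "high", 100, 150),
             ("C1", "C1R3", "high", 300, 750)]
        )
        regions = make_regions({"C1R1": 1e4, "C1R2": 1e4, "C1R3": 1e4})
        w = gdp_kernel_weights(regions, h=0.5)
        params = EBParams(mix_weights=(1.0, 0.0))
        m = reference_rate(cells.iloc[0], cells, w, params)
        assert m == pytest.approx(2.25)

    def test_education_source_when_no_donor_regions(self):
        # single-region country: all weight moves to the cross-education source
        cells = make_cells(
            [("C1", "C1R1", "high", 100, 150),
             ("C1", "C1R1", "medium", 200, 400),
             ("C1", "C1R1", "low", 100, 220)]
        )
        regions = make_regions({"C1R1": 1e4})
        w = gdp_kernel_weights(regions, h=0.5)
        m = reference_rate(cells.iloc[0], cells, w, EBParams(mix_weights=(0.7, 0.3)))
        cfr_other = (400 + 220) / 300
        rho = (150 / 100) / cfr_other  # country pooled = region here
        assert m == pytest.approx(cfr_other * rho)

    def test_no_source_anywhere_raises(self):
        cells = make_cells([("C1", "C1R1", "high", 0, 0)])
        regions = make_regions({"C1R1": 1e4})
        w = gdp_kernel_weights(regions, h=0.5)
        with pytest.raises(ValueError, match="no borrowing source"):
            reference_rate(cells.iloc[0], cells, w, EBParams())

    def test_matches_naive_reimplementation(self):
        # independent brute-force recomputation of the stated formula
        rng = np.random.default_rng(8)
        regs, recs = {}, []
        for r in range(4):
            regs[f"C1R{r}"] = float(np.exp(rng.normal(10, 0.3)))
            for e in EDUS:
                n = int(rng.integers(0, 80))
                recs.append(("C1", f"C1R{r}", e, n, int(rng.poisson(1.8 * n)) if n else 0))
        regions = make_regions(regs)
        cells = make_cells(recs)
        h, (lam_r, lam_e) = 0.25, (0.6, 0.4)
        w = gdp_kernel_weights(regions, h)
        params = EBParams(bandwidth_h=h, mix_weights=(lam_r, lam_e))

        def naive_m(cell):
            log_g = {rid: np.log(g) for rid, g in regs.items()}
            r0, e0 = cell["region_id"], cell["education"]
            num = den = 0.0
            for _, d in cells.iterrows():
                if d["region_id"] == r0 or d["education"] != e0 or d["n_women"] == 0:
                    continue
                k = np.exp(-((log_g[r0] - log_g[d["region_id"]]) ** 2) / (2 * h * h))
                num += k * d["total_children"]
                den += k * d["n_women"]
            m_reg = num / den if den > 0 else None
            other = cells[(cells["region_id"] == r0) & (cells["education"] != e0)]
            n_o, b_o = other["n_women"].sum(), other["total_children"].sum()
            same_all = cells[cells["education"] == e0]
            other_all = cells[cells["education"] != e0]
            m_edu = None
            if n_o > 0 and same_all["n_women"].sum() > 0 and other_all["n_women"].sum() > 0:
                rho = (same_all["total_children"].sum() / same_all["n_women"].sum()) / (
                    other_all["total_children"].sum() / other_all["n_women"].sum()
                )
                m_edu = (b_o / n_o) * rho
            if m_reg is not None and m_edu is not None:
                return lam_r * m_reg + lam_e * m_edu
            return m_reg if m_reg is not None else m_edu

        for _, cell in cells.iterrows():
            expected = naive_m(cell)
            if expected is None:
                continue
            assert reference_rate(cell, cells, w, params) == pytest.approx(
                expected, rel=1e-12
            )


class TestEstimateNu:
    def test_homogeneous_rates_hit_upper_cap(self):
        cells = make_cells(
            [("C1", f"C1R{r}", "high", 10_000, 18_000) for r in range(6)]
        )
        assert estimate_nu(cells) == 1e6

    def test_heterogeneous_rates_near_lower_cap(self):
        rates = [0.2, 0.9, 1.8, 2.9, 4.1, 5.6]
        cells = make_cells(
            [("C1", f"C1R{r}", "high", 10_000, int(10_000 * m)) for r, m in enumerate(rates)]
        )
        assert estimate_nu(cells) < 2.0

    def test_too_few_cells_returns_none(self):
        assert estimate_nu(make_cells([("C1", "C1R1", "high", 10, 18)])) is None

    def test_moment_estimator_recovers_gamma_prior(self):
        # cell rates ~ Gamma(shape k, mean m_bar) => true nu = k / m_bar
        rng = np.random.default_rng(17)
        k, m_bar, n_cells, n_women = 40.0, 1.8, 60, 1000
        nu_true = k / m_bar
        estimates = []
        for _ in range(200):
            theta = rng.gamma(k, m_bar / k, size=n_cells)
            b = rng.poisson(n_women * theta)
            cells = make_cells(
                [("C1", f"C1R{i}", "high", n_women, int(b[i])) for i in range(n_cells)]
            )
            estimates.append(estimate_nu(cells))
        assert abs(np.mean(estimates) - nu_true) / nu_true < 0.25


class TestEbPosterior:
    def test_conjugate_update_arithmetic(self):
        post = eb_posterior(20, 30, m=1.8, nu=10)
        assert post.mean == pytest.approx((30 + 18) / 30)

    def test_no_prior_limit_recovers_raw_rate(self):
        post = eb_posterior(50, 90, m=3.0, nu=1e-9)
        assert post.mean == pytest.approx(90 / 50, rel=1e-9)

    def test_no_data_limit_returns_reference(self):
        assert eb_posterior(0, 0, m=1.7, nu=25).mean == pytest.approx(1.7)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            eb_posterior(10, 15, m=0.0, nu=5)

    @pytest.mark.parametrize("n,b,m,nu", [(20, 30, 1.8, 10), (0, 0, 1.5, 3), (500, 900, 2.0, 50)])
    def test_interval_matches_quadrature(self, n, b, m, nu):
        # oracle: invert the Gamma CDF by numerical integration of the density
        post = eb_posterior(n, b, m, nu)
        a, rate = post.shape, post.rate

        def pdf(x):
            from scipy.special import gammaln
            return np.exp(a * np.log(rate) + (a - 1) * np.log(x) - rate * x - gammaln(a))

        def cdf(x):
            val, _ = integrate.quad(pdf, 0, x, limit=200)
            return val

        lo, hi = post.interval(0.95)
        for q, x in ((0.025, lo), (0.975, hi)):
            x_oracle = optimize.brentq(lambda t: cdf(t) - q, 1e-12, a / rate * 10 + 10, xtol=1e-10)
            assert x == pytest.approx(x_oracle, abs=1e-6)


def _toy_problem(seed=13, n_scale=60):
    cfg = SyntheticConfig(
        n_countries=3, regions_per_country=4, women_per_region=n_scale, seed=seed
    )
    regions = generate_regions(cfg)
    cells = aggregate(generate_microdata(regions, cfg))
    return regions, cells


class TestSmoothTable:
    def test_fills_empty_cells_with_reference_rate(self):
        # low education unobserved in region 1 but observed in region 2:
        # the empty cell still gets an estimate, equal to its reference rate
        cells = make_cells(
            [("C1", "C1R1", "high", 100, 150), ("C1", "C1R1", "medium", 100, 190),
             ("C1", "C1R2", "high", 100, 160), ("C1", "C1R2", "medium", 100, 180),
             ("C1", "C1R2", "low", 80, 170)]
        )
        regions = make_regions({"C1R1": 1e4, "C1R2": 1.2e4})
        est = smooth_table(cells, regions, EBParams(prior_strength_nu=50))
        low = est[est["education"] == "low"].set_index("region_id")
        assert len(low) == 2
        assert low.loc["C1R1", "cfr"] == pytest.approx(low.loc["C1R1", "ref_rate"])

    def test_education_absent_countrywide_is_skipped(self, caplog):
        cells = make_cells(
            [("C1", "C1R1", "high", 100, 150), ("C1", "C1R1", "medium", 100, 190),
             ("C1", "C1R2", "high", 100, 160), ("C1", "C1R2", "medium", 100, 180)]
        )
        regions = make_regions({"C1R1": 1e4, "C1R2": 1.2e4})
        est = smooth_table(cells, regions, EBParams(prior_strength_nu=50))
        assert (est["education"] != "low").all()
        assert len(est) == 4

    def test_estimates_lie_between_raw_and_reference(self):
        regions, cells = _toy_problem()
        est = smooth_table(cells, regions)
        obs = est[est["n_women"] > 0].merge(
            cells, on=["country_id", "region_id", "education"], suffixes=("", "_cell")
        )
        raw = obs["total_children"] / obs["n_women_cell"]
        lo = np.minimum(raw, obs["ref_rate"]) - 1e-12
        hi = np.maximum(raw, obs["ref_rate"]) + 1e-12
        assert ((obs["cfr"] >= lo) & (obs["cfr"] <= hi)).all()

    def test_small_cells_shrink_more(self):
        cells = make_cells(
            [("C1", "C1R1", "high", 50, 60),
             ("C1", "C1R2", "high", 5000, 6000),
             ("C1", "C1R3", "high", 1000, 2100)]
        )
        regions = make_regions({"C1R1": 1e4, "C1R2": 1e4, "C1R3": 1e4})
        est = smooth_table(cells, regions, EBParams(prior_strength_nu=200, mix_weights=(1.0, 0.0)))
        est = est.set_index("region_id")
        gap_small = abs(est.loc["C1R1", "cfr"] - 60 / 50)
        gap_big = abs(est.loc["C1R2", "cfr"] - 6000 / 5000)
        assert gap_small > gap_big

    def test_shrinkage_vanishes_as_n_grows(self):
        # N = 10^6 per cell: |EB - raw| below 1e-3
        cells = make_cells(
            [("C1", f"C1R{r}", e, 1_000_000, int(1_000_000 * mu))
             for r, mu in enumerate([1.5, 1.8, 2.1])
             for e, mu in [("high", mu - 0.1), ("medium", mu), ("low", mu + 0.1)]]
        )
        regions = make_regions({f"C1R{r}": g for r, g in enumerate([1e4, 2e4, 4e4])})
        est = smooth_table(cells, regions).merge(
            raw_cfr_table(cells), on=["country_id", "region_id", "education"],
            suffixes=("_eb", "_raw"),
        )
        assert (est["cfr_eb"] - est["cfr_raw"]).abs().max() < 1e-3

    def test_matches_brute_force_oracle(self):
        # independent loop-based smoother on a 3-country x 4-region x 3-education toy
        regions, cells = _toy_problem(seed=29)
        params = EBParams(bandwidth_h=0.3, prior_strength_nu=80.0, mix_weights=(0.7, 0.3))
        est = smooth_table(cells, regions, params).set_index(
            ["region_id", "education"]
        )

        log_g = dict(zip(regions["region_id"], np.log(regions["gdp_pc"])))
        country_of = dict(zip(regions["region_id"], regions["country_id"]))
        full = []
        for rid in regions["region_id"]:
            for e in EDUS:
                match = cells[(cells["region_id"] == rid) & (cells["education"] == e)]
                n = int(match["n_women"].iloc[0]) if len(match) else 0
                b = int(match["total_children"].iloc[0]) if len(match) else 0
                full.append((country_of[rid], rid, e, n, b))
        for c, rid, e, n, b in full:
            num = den = 0.0
            for c2, rid2, e2, n2, b2 in full:
                if c2 == c and rid2 != rid and e2 == e and n2 > 0:
                    k = np.exp(-((log_g[rid] - log_g[rid2]) ** 2) / (2 * 0.3**2))
                    num += k * b2
                    den += k * n2
            m_reg = num / den if den > 0 else None
            n_o = sum(x[3] for x in full if x[1] == rid and x[2] != e)
            b_o = sum(x[4] for x in full if x[1] == rid and x[2] != e)
            n_e = sum(x[3] for x in full if x[0] == c and x[2] == e)
            b_e = sum(x[4] for x in full if x[0] == c and x[2] == e)
            n_oc = sum(x[3] for x in full if x[0] == c and x[2] != e)
            b_oc = sum(x[4] for x in full if x[0] == c and x[2] != e)
            m_edu = None
            if n_o > 0 and n_e > 0 and n_oc > 0:
                m_edu = (b_o / n_o) * ((b_e / n_e) / (b_oc / n_oc))
            if m_reg is not None and m_edu is not None:
                m = 0.7 * m_reg + 0.3 * m_edu
            else:
                m = m_reg if m_reg is not None else m_edu
            assert m is not None
            expected_mean = (b + 80.0 * m) / (n + 80.0)
            got = est.loc[(rid, e)]
            assert got["ref_rate"] == pytest.approx(m, abs=1e-10)
            assert got["cfr"] == pytest.approx(expected_mean, abs=1e-10)

    def test_mse_improvement_under_sparse_sampling(self):
        # 1% samples: EB beats raw in MSE against the generator's true rates
        from fertgrad.synthetic import mean_parity
        n_reps, mse_eb, mse_raw = 30, [], []
        for rep in range(n_reps):
            cfg = SyntheticConfig(
                n_countries=2, regions_per_country=5, women_per_region=10_000,
                sampling_fraction=0.01, country_effect_sd=0.0, seed=1000 + rep,
            )
            regions = generate_regions(cfg)
            cells = aggregate(generate_microdata(regions, cfg))
            eb = smooth_table(cells, regions)
            raw = raw_cfr_table(cells)
            gdp = dict(zip(regions["region_id"], regions["gdp_pc"]))
            both = eb.merge(raw, on=["country_id", "region_id", "education"],
                            suffixes=("_eb", "_raw"))
            truth = np.array(
                [mean_parity(r.education, gdp[r.region_id], cfg) for r in both.itertuples()]
            )
            mse_eb.append(((both["cfr_eb"] - truth) ** 2).mean())
            mse_raw.append(((both["cfr_raw"] - truth) ** 2).mean())
        assert np.mean(mse_eb) < np.mean(mse_raw)
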