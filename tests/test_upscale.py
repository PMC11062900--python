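"""Upscaling machinery: mineral layer, truncated sampling, mixture SD,
per-cell propagation, uncertainty decomposition, regional totals."""

import numpy as np
import pandas as pd
import pytest

from ermeta import RunConfig, meta, upscale
from ermeta.upscale import SoilCell


def printed_model(vcov=None):
    """The two-moderator lnROM model with the published coefficient values."""
    return meta.MetaModel(
        beta=np.array([0.05, -0.16, 0.01]),
        vcov_beta=np.zeros((3, 3)) if vcov is None else np.asarray(vcov),
        sigma2_exp=0, sigma2_dataset=0, tau2_car=0, rho_car=0,
        loglik_reml=0.0, k=39, p=3, converged=True,
        names=["intercept", "TN", "CN"])


IDENTITY_REG = np.array([[0.0, 1.0]])


class TestMineralLayer:
    def test_single_passing_interval(self):
        tn, soc, ok = upscale.extract_mineral_layer(
            [0], [60], [0.005], [0.05], [1.3])
        assert (tn, soc, ok) == (0.005, 0.05, True)

    def test_organic_interval_excluded(self):
        tn, soc, ok = upscale.extract_mineral_layer(
            [0, 30], [30, 60], [0.02, 0.005], [0.2, 0.05], [0.8, 1.2])
        assert ok and tn == 0.005 and soc == 0.05

    def test_depth_weighting(self):
        # 0-20 mineral (tn 0.004), 20-60 mineral (tn 0.008): weights 1/3, 2/3
        tn, _, ok = upscale.extract_mineral_layer(
            [0, 20], [20, 60], [0.004, 0.008], [0.05, 0.05], [1.2, 1.2])
        assert tn == pytest.approx((20 * 0.004 + 40 * 0.008) / 60)

    def test_all_organic_is_invalid(self):
        _, _, ok = upscale.extract_mineral_layer(
            [0, 30], [30, 60], [0.02, 0.02], [0.2, 0.2], [0.7, 0.8])
        assert not ok

    def test_gapped_intervals_fatal(self):
        with pytest.raises(ValueError, match="tile"):
            upscale.extract_mineral_layer([0, 40], [30, 60],
                                          [0.005, 0.005], [0.05, 0.05],
                                          [1.2, 1.2])


class TestSdFromPercentiles:
    @pytest.mark.parametrize("q05,q95,expected", [
        (3.0, 3.0, 0.0),
        (-1.6448536, 1.6448536, 1.0),
        (10.0, 20.0, 3.03978),
    ])
    def test_values(self, q05, q95, expected):
        assert upscale.sd_from_percentiles(q05, q95) == pytest.approx(
            expected, abs=1e-5)


class TestTruncatedSampling:
    def test_degenerate_zero_sd(self, rng):
        cell = SoilCell(0, 1.0, 0.3, 0.0, 5.0, 0.0)
        tn, soc, ok = upscale.sample_soil(cell, 10, 0.8, 0.05, rng)
        assert ok and np.all(tn == 0.3) and np.all(soc == 5.0)

    def test_negligible_truncation_limit(self, rng):
        """With the bound many sds below the mean the adjustment vanishes
        and the empirical mean and correlation match the parameters."""
        cell = SoilCell(0, 1.0, 100.0, 1.0, 100.0, 1.0)
        tn, soc, ok = upscale.sample_soil(cell, 60_000, 0.8273, 0.05, rng)
        assert ok
        assert tn.mean() == pytest.approx(100.0, rel=2e-4)
        assert np.corrcoef(tn, soc)[0, 1] == pytest.approx(0.8273, abs=0.02)

    def test_heavy_truncation_mean_adjustment(self, rng):
        cell = SoilCell(0, 1.0, 0.2, 0.15, 5.0, 1.5)
        tn, soc, ok = upscale.sample_soil(cell, 100_000, 0.8273, 0.05, rng)
        assert ok
        assert tn.min() >= 0.05 * 0.2
        assert tn.mean() == pytest.approx(0.2, rel=0.01)
        assert soc.mean() == pytest.approx(5.0, rel=0.01)

    def test_seed_reproducibility(self):
        cell = SoilCell(0, 1.0, 0.2, 0.1, 5.0, 1.0)
        a = upscale.sample_soil(cell, 50, 0.8, 0.05, np.random.default_rng(3))
        b = upscale.sample_soil(cell, 50, 0.8, 0.05, np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestCnBias:
    def test_identity_regression(self):
        cn = upscale.cn_bias_correct([0.25], [5.0], IDENTITY_REG)
        assert cn[0] == pytest.approx(20.0)

    def test_affine_correction(self):
        cn = upscale.cn_bias_correct([0.25], [5.0], np.array([[2.0, 0.9]]))
        assert cn[0] == pytest.approx(2 + 0.9 * 20)

    def test_regressions_cycle_over_draws(self):
        regs = np.array([[0.0, 1.0], [10.0, 1.0]])
        cn = upscale.cn_bias_correct([0.25] * 4, [5.0] * 4, regs)
        assert list(cn) == pytest.approx([20.0, 30.0, 20.0, 30.0])

    def test_monotone_for_positive_slope(self, rng):
        raw_tn = rng.uniform(0.1, 1.0, 50)
        cn = upscale.cn_bias_correct(raw_tn, np.full(50, 5.0),
                                     np.array([[1.0, 0.8]]))
        order = np.argsort(5.0 / raw_tn)
        assert (np.diff(cn[order]) >= 0).all()

    def test_bootstrap_regressions_recover_bias_line(self, rng):
        calc = rng.uniform(8, 35, 300)
        reported = 1.5 + 0.92 * calc + rng.normal(0, 1.0, 300)
        regs = upscale.bootstrap_cn_regressions(calc, reported, n=100, rng=rng)
        assert regs.shape == (100, 2)
        assert regs[:, 1].mean() == pytest.approx(0.92, abs=0.02)


class TestMixtureSd:
    def test_degenerate_cases(self):
        assert upscale.mixture_sd([3.0, 3.0, 3.0], [0, 0, 0]) == 0.0
        assert upscale.mixture_sd([0.0, 2.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_reduces_to_population_sd_of_means(self, rng):
        means = rng.normal(size=30)
        assert upscale.mixture_sd(means, np.zeros(30)) == pytest.approx(
            np.std(means), rel=1e-12)

    def test_matches_monte_carlo_mixture(self, rng):
        means = rng.normal(0, 1, 50)
        ses = rng.uniform(0.1, 0.5, 50)
        comp = rng.integers(0, 50, 400_000)
        draws = rng.normal(means[comp], ses[comp])
        assert upscale.mixture_sd(means, ses) == pytest.approx(
            draws.std(), rel=5e-3)


class TestUpscaleCell:
    def _cfg(self):
        return RunConfig(mc_draws=50)

    def test_plug_in_with_no_uncertainty(self, rng):
        """Zero soil sd + zero coefficient covariance collapses to the
        closed-form prediction 100(exp(0.05 - 0.16 TN + 0.01 C:N) - 1)."""
        cell = SoilCell(0, 1e6, 0.5, 0.0, 6.0, 0.0, baseline_er=200.0)
        res = upscale.upscale_cell(cell, printed_model(), IDENTITY_REG, 50,
                                   self._cfg(), rng)
        rom = 0.05 - 0.16 * 0.5 + 0.01 * 12.0
        assert res.pct_change_mean == pytest.approx(100 * (np.exp(rom) - 1),
                                                    abs=1e-9)
        assert res.pct_change_sd == pytest.approx(0.0, abs=1e-6)
        assert res.abs_change == pytest.approx(200.0 * (np.exp(rom) - 1),
                                               abs=1e-9)

    def test_zero_soil_sd_leaves_parameter_uncertainty(self, rng):
        cell = SoilCell(0, 1e6, 0.5, 0.0, 6.0, 0.0, baseline_er=200.0)
        vcov = np.diag([1e-4, 1e-4, 1e-6])
        res = upscale.upscale_cell(cell, printed_model(vcov), IDENTITY_REG,
                                   50, self._cfg(), rng)
        # all draws identical -> combined sd equals the per-draw SE
        x = np.array([1.0, 0.5, 12.0])
        se = float(np.sqrt(x @ vcov @ x))
        assert res.rom_sd == pytest.approx(se, rel=1e-9)
        assert res.uncertainty_ratio == pytest.approx(0.0, abs=1e-6)

    def test_zero_vcov_makes_input_only_uncertainty(self, rng):
        cell = SoilCell(0, 1e6, 0.5, 0.1, 6.0, 1.0, baseline_er=200.0)
        res = upscale.upscale_cell(cell, printed_model(), IDENTITY_REG, 200,
                                   self._cfg(), rng)
        assert res.uncertainty_ratio == pytest.approx(1.0, abs=1e-9)
        assert res.rom_sd > 0

    def test_monotone_in_drivers(self, rng):
        """With the printed signs, more TN lowers and more C:N raises the
        predicted change."""
        cfg = self._cfg()
        base = dict(tn_sd=0.0, soc_sd=0.0, baseline_er=100.0)
        lo = upscale.upscale_cell(SoilCell(0, 1.0, 0.3, soc_mean=6.0, **base),
                                  printed_model(), IDENTITY_REG, 10, cfg, rng)
        hi = upscale.upscale_cell(SoilCell(0, 1.0, 0.8, soc_mean=6.0, **base),
                                  printed_model(), IDENTITY_REG, 10, cfg, rng)
        assert hi.pct_change_mean < lo.pct_change_mean
        lo2 = upscale.upscale_cell(SoilCell(0, 1.0, 0.5, soc_mean=5.0, **base),
                                   printed_model(), IDENTITY_REG, 10, cfg, rng)
        hi2 = upscale.upscale_cell(SoilCell(0, 1.0, 0.5, soc_mean=9.0, **base),
                                   printed_model(), IDENTITY_REG, 10, cfg, rng)
        assert hi2.pct_change_mean > lo2.pct_change_mean

    def test_invalid_cell_gives_nodata(self, rng):
        cell = SoilCell(0, 1.0, np.nan, np.nan, np.nan, np.nan, valid=False)
        res = upscale.upscale_cell(cell, printed_model(), IDENTITY_REG, 10,
                                   self._cfg(), rng)
        assert np.isnan(res.pct_change_mean)

    def test_decompose_shares_substreams(self):
        cell = SoilCell(0, 1.0, 0.5, 0.1, 6.0, 1.0, baseline_er=100.0)
        vcov = np.diag([1e-4, 1e-4, 1e-6])
        ratio = upscale.decompose_uncertainty(cell, printed_model(vcov),
                                              IDENTITY_REG, 500, self._cfg(),
                                              seed=5)
        assert 0.0 < ratio <= 1.0


class TestRegionalTotals:
    def _tables(self, rom, rom_sd, baseline=100.0, area=1e8, n=10_000):
        cells = pd.DataFrame({
            "cell_id": np.arange(n), "area": area,
            "baseline_er": baseline, "valid": True,
        })
        results = pd.DataFrame({
            "cell_id": np.arange(n), "rom_mean": rom, "rom_sd": rom_sd,
        })
        return results, cells

    def test_uniform_grid_arithmetic(self):
        # baseline 100 gC/m2/yr over 1e12 m2, +25% everywhere
        results, cells = self._tables(np.log(1.25), 0.0)
        tot = upscale.regional_totals(results, cells)
        assert tot["baseline_pg"] == pytest.approx(0.1)
        assert tot["delta_pg"] == pytest.approx(0.025)
        assert tot["delta_pct"] == pytest.approx(25.0)

    def test_zero_change(self):
        results, cells = self._tables(0.0, 0.0)
        assert upscale.regional_totals(results, cells)["delta_pg"] == 0.0

    def test_area_linearity(self):
        r1, c1 = self._tables(np.log(1.25), 0.01)
        r2, c2 = self._tables(np.log(1.25), 0.01, area=2e8)
        t1 = upscale.regional_totals(r1, c1)
        t2 = upscale.regional_totals(r2, c2)
        assert t2["delta_pg"] == pytest.approx(2 * t1["delta_pg"])
        assert t2["delta_sd_pg"] == pytest.approx(2 * t1["delta_sd_pg"])
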