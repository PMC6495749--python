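"""Generator determinism, zero-noise estimator identities, noise behaviour."""

import numpy as np
import pytest
from scipy import stats

from methanofrac.isotopes import rayleigh_closed_form, rayleigh_invert
from methanofrac.kinetics import (
    batch_yield,
    chemostat_production_rate,
    chemostat_yield,
    fit_growth_rate,
    metabolite_cell_specific_rate,
)
from methanofrac.synthetic import (
    SimConfig,
    gen_batch_growth,
    gen_chemostat_run,
    gen_coculture,
    gen_isotope_drawdown,
)


def quiet(seed=0, **kw):
    return SimConfig(seed=seed, noise_cv_counts=0.0, sigma_delta_permil=0.0, **kw)


class TestDeterminismAndValidation:
    def test_identical_config_identical_output(self):
        a = gen_batch_growth(1.0, 1e6, SimConfig(seed=42))
        b = gen_batch_growth(1.0, 1e6, SimConfig(seed=42))
        assert np.array_equal(a.count_per_ml, b.count_per_ml)
        c = gen_coculture(0.16, 9e-14, 9.1e12, SimConfig(seed=42))
        d = gen_coculture(0.16, 9e-14, 9.1e12, SimConfig(seed=42))
        assert np.array_equal(c.methanogen_cells_total, d.methanogen_cells_total)

    def test_seed_recorded_in_metadata(self):
        series = gen_batch_growth(1.0, 1e6, SimConfig(seed=42))
        assert series.meta["seed"] == 42

    def test_different_seed_different_noise(self):
        a = gen_batch_growth(1.0, 1e6, SimConfig(seed=1))
        b = gen_batch_growth(1.0, 1e6, SimConfig(seed=2))
        assert not np.array_equal(a.count_per_ml, b.count_per_ml)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, noise_cv_counts=-0.1)
        with pytest.raises(ValueError):
            SimConfig(seed=0, time_grid_h=np.array([0.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            gen_batch_growth(1.0, -1e6, quiet())
        with pytest.raises(ValueError):
            gen_chemostat_run(-0.5, 1e7, 1e-13, 9.0, 1.5, quiet())
        with pytest.raises(ValueError):
            gen_isotope_drawdown(-26.1, 22.1, 1.5, 5, quiet())


class TestZeroNoiseIdentities:
    def test_batch_growth_doubling(self):
        series = gen_batch_growth(
            0.693, 1e6, quiet(time_grid_h=np.array([0.0, 1.0, 2.0]))
        )
        expected = 1e6 * np.exp(0.693 * np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(series.count_per_ml, expected, rtol=1e-12)

    def test_zero_rate_constant_series(self):
        series = gen_batch_growth(0.0, 5e5, quiet())
        assert np.all(series.count_per_ml == 5e5)

    def test_growth_rate_round_trip(self):
        series = gen_batch_growth(1.04, 1e6, quiet())
        assert fit_growth_rate(series).k_per_h == pytest.approx(1.04, rel=1e-9)

    def test_chemostat_q_round_trip(self):
        state = gen_chemostat_run(0.21, 1e7, 139e-15, 9.18, 1.5, quiet())
        rate = chemostat_production_rate(state)
        assert rate.q_fmol_per_cell_h == pytest.approx(139.0, rel=1e-9)
        # high-H2 magnitude too
        state = gen_chemostat_run(0.6, 1e7, 496e-15, 9.15, 1.5, quiet())
        assert chemostat_production_rate(state).q_fmol_per_cell_h == pytest.approx(
            496.0, rel=1e-9
        )

    def test_chemostat_yield_round_trip(self):
        d, q_true = 0.6, 496e-15
        state = gen_chemostat_run(d, 1e7, q_true, 9.15, 1.5, quiet())
        y = chemostat_yield(state)
        assert y.yield_cells_per_mol == pytest.approx(d / q_true, rel=1e-9)

    def test_coculture_yield_and_growth_round_trip(self):
        series = gen_coculture(0.16, 9e-14, 9.1e12, quiet(time_grid_h=np.linspace(0, 12, 9)))
        fit = batch_yield(series, product="CH4")
        assert fit.yield_cells_per_mol == pytest.approx(9.1e12, rel=1e-9)
        from methanofrac.kinetics import CellCountSeries

        het = CellCountSeries(series.time_h, series.heterotroph_cells_total)
        assert fit_growth_rate(het).k_per_h == pytest.approx(0.16, rel=1e-9)

    def test_coculture_acetate_rate_round_trip(self):
        series = gen_coculture(
            0.16, 9e-14, 9.1e12, quiet(time_grid_h=np.linspace(0, 12, 9)),
            acetate_per_cell_mol_h=1.05e-12,
        )
        y_ac = batch_yield(series, product="acetate")
        q = metabolite_cell_specific_rate(0.16, y_ac)
        assert q.q_mol_per_cell_h == pytest.approx(1.05e-12, rel=1e-9)

    def test_coculture_no_h2_no_methane(self):
        series = gen_coculture(0.16, 0.0, 9.1e12, quiet())
        assert np.all(series.ch4_mol_total == 0.0)
        assert np.all(series.methanogen_cells_total == series.methanogen_cells_total[0])

    def test_isotope_drawdown_round_trip(self):
        df = gen_isotope_drawdown(-26.1, 22.1, 0.12, 6, quiet())
        last = df.iloc[-1]
        eps, f = rayleigh_invert(
            -26.1, last["delta_residual_permil"], last["delta_product_cum_permil"]
        )
        assert eps == pytest.approx(22.1, abs=0.05)
        assert f == pytest.approx(0.12, abs=1e-6)

    def test_isotope_drawdown_zero_epsilon(self):
        df = gen_isotope_drawdown(-26.1, 0.0, 0.3, 5, quiet())
        np.testing.assert_allclose(df["delta_residual_permil"], -26.1, atol=1e-9)
        np.testing.assert_allclose(df["delta_product_cum_permil"][1:], -26.1, atol=1e-9)

    def test_isotope_drawdown_f_one_product_absent(self):
        df = gen_isotope_drawdown(-26.1, 22.1, 1.0, 3, quiet())
        np.testing.assert_allclose(df["delta_residual_permil"], -26.1, atol=1e-12)
        assert df["delta_product_cum_permil"].isna().all()


class TestCarbonConservation:
    def test_ch4_is_quarter_of_transferred_h2(self):
        series = gen_coculture(0.2, 1.2e-13, 1e13, quiet(time_grid_h=np.linspace(0, 10, 8)))
        np.testing.assert_allclose(
            series.ch4_mol_total, series.h2_transferred_mol / 4.0, rtol=1e-12
        )

    def test_free_h2_pool_stays_empty(self):
        series = gen_coculture(0.2, 1.2e-13, 1e13, SimConfig(seed=3))
        assert np.all(series.h2_mol_total == 0.0)


class TestNoiseBehaviour:
    def test_noisy_growth_rate_within_ci(self):
        """5% count noise: the fitted k covers the true 1.04/h at 95%."""
        config = SimConfig(seed=1, noise_cv_counts=0.05, time_grid_h=np.linspace(0, 4, 8))
        fit = fit_growth_rate(gen_batch_growth(1.04, 1e6, config))
        t_crit = stats.t.ppf(0.975, df=8 - 2)
        assert abs(fit.k_per_h - 1.04) <= t_crit * fit.stderr_k_per_h

    def test_chemostat_replicates_recover_q(self):
        """Mean q over 3 noisy replicates lands within 10% of truth."""
        qs = [
            chemostat_production_rate(
                gen_chemostat_run(0.6, 1e7, 496e-15, 9.15, 1.5,
                                  SimConfig(seed=seed, noise_cv_counts=0.05))
            ).q_fmol_per_cell_h
            for seed in (11, 12, 13)
        ]
        assert np.mean(qs) == pytest.approx(496.0, rel=0.10)

    def test_estimator_sd_shrinks_like_root_n(self):
        """Growth-rate SD across seeds scales with the OLS leverage factor
        1/sqrt(sum (t - tbar)^2), i.e. ~1/sqrt(n) for a fixed time span."""
        n_seeds = 200
        sds, predicted = [], []
        for n_obs in (5, 20, 80):
            grid = np.linspace(0.0, 4.0, n_obs)
            ks = [
                fit_growth_rate(
                    gen_batch_growth(1.0, 1e6, SimConfig(seed=s, noise_cv_counts=0.05,
                                                         time_grid_h=grid))
                ).k_per_h
                for s in range(n_seeds)
            ]
            sds.append(np.std(ks, ddof=1))
            predicted.append(1.0 / np.sqrt(np.sum((grid - grid.mean()) ** 2)))
        assert sds[0] > sds[1] > sds[2]
        for (sd_a, pr_a), (sd_b, pr_b) in [(
            (sds[0], predicted[0]), (sds[2], predicted[2])
        ), ((sds[0], predicted[0]), (sds[1], predicted[1]))]:
            assert sd_a / sd_b == pytest.approx(pr_a / pr_b, rel=0.25)

    def test_isotope_noise_sd(self):
        """Additive noise on the drawdown deltas has the configured SD."""
        residuals = []
        for seed in range(300):
            df = gen_isotope_drawdown(
                -26.1, 22.1, 0.5, 3, SimConfig(seed=seed, sigma_delta_permil=0.3)
            )
            residuals.append(df["delta_residual_permil"].iloc[0] - (-26.1))
        assert np.std(residuals) == pytest.approx(0.3, rel=0.2)
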