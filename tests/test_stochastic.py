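"""Stochastic lineages: noise statistics, homeostasis regimes, exit lag."""

import numpy as np
import pytest

import sectorsize as ss
from sectorsize.errors import ParameterError

from conftest import steady_initial


@pytest.fixture(scope="module")
def rich_env(upshift_setup):
    return ss.Environment.constant(upshift_setup[2])


class TestNoiseDraws:
    def test_zero_parameters_give_zero_offset(self):
        noise = ss.NoiseModel(gr_slope_a=0.0, gr_intercept_b=0.0)
        rng = np.random.default_rng(0)
        assert ss.sample_growth_offset(1.0, noise, rng) == 0.0

    def test_offset_moments(self):
        """Mean 0 within 4 s.e.; sd = a<kappa> + b within 2% at <kappa>=1."""
        noise = ss.NoiseModel(gr_slope_a=0.15, gr_intercept_b=0.02)
        rng = np.random.default_rng(1)
        draws = np.array([ss.sample_growth_offset(1.0, noise, rng)
                          for _ in range(100_000)])
        target_sd = 0.17
        assert abs(draws.mean()) < 4 * target_sd / np.sqrt(draws.size)
        assert draws.std() == pytest.approx(target_sd, rel=0.02)

    def test_negative_sigma_rejected(self):
        noise = ss.NoiseModel(gr_slope_a=-0.5, gr_intercept_b=0.1)
        with pytest.raises(ParameterError):
            ss.sample_growth_offset(1.0, noise, np.random.default_rng(0))

    def test_division_ratio_moments_and_truncation(self):
        noise = ss.NoiseModel()
        rng = np.random.default_rng(2)
        draws = np.array([ss.sample_division_ratio(noise, rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(
            0.5, abs=3 * 0.04 / np.sqrt(draws.size))
        assert draws.std() == pytest.approx(0.04, rel=0.03)
        assert draws.min() > 0.05 and draws.max() < 0.95

    def test_zero_sd_ratio_is_exact_half(self):
        noise = ss.NoiseModel(division_ratio_sd=0.0)
        assert ss.sample_division_ratio(
            noise, np.random.default_rng(0)) == 0.5


class TestLineage:
    def test_zero_noise_reproduces_steady_cycle(self, upshift_setup,
                                                rich_env, rich_steady,
                                                rich_initial):
        params = upshift_setup[0]
        _, recs = ss.simulate_lineage(rich_env, params, ss.NoiseModel.quiet(),
                                      4.0, rich_initial)
        deltas = np.array([r.Delta for r in recs])
        np.testing.assert_allclose(deltas, rich_steady.Delta_star, rtol=1e-3)
        taus = np.array([r.tau for r in recs])
        np.testing.assert_allclose(taus, rich_steady.tau_star, rtol=1e-3)

    def test_fixed_seed_reproducibility(self, upshift_setup, rich_env,
                                        rich_initial):
        params = upshift_setup[0]
        noise = ss.NoiseModel(seed=11)
        df = [ss.records_to_dataframe(
            ss.simulate_lineage(rich_env, params, noise, 5.0,
                                rich_initial)[1]) for _ in range(2)]
        assert df[0].equals(df[1])

    def test_mother_daughter_growth_offsets_uncorrelated(self, upshift_setup,
                                                         rich_env,
                                                         rich_initial):
        params = upshift_setup[0]
        noise = ss.NoiseModel(seed=4, division_ratio_sd=0.0)
        _, recs = ss.simulate_lineage(rich_env, params, noise, 60.0,
                                      rich_initial)
        dk = np.array([r.delta_kappa for r in recs])
        assert dk.size > 60
        r = np.corrcoef(dk[:-1], dk[1:])[0, 1]
        assert abs(r) < 4.0 / np.sqrt(dk.size)

    def test_adder_slope_near_zero_at_fast_growth(self, upshift_setup,
                                                  rich_env, rich_initial):
        """mu_X << kappa: added volume independent of birth size."""
        params = upshift_setup[0].evolve(mu_X=0.05)
        st = ss.solve(160.0, params)
        initial = steady_initial(st, params)
        noise = ss.NoiseModel(seed=5)
        intensive = ss.integrate_intensive(initial, rich_env, params, 8.0)
        recs = []
        rng = noise.rng()
        for i in range(60):
            recs += ss.simulate_lineage(rich_env, params, noise, 8.0,
                                        initial, rng=rng, lineage_id=i,
                                        intensive=intensive)[1]
        df = ss.records_to_dataframe(recs)
        slope = np.polyfit(df.V0, df.Delta, 1)[0]
        assert abs(slope) < 0.15

    def test_sizer_slope_near_minus_one_at_strong_degradation(
            self, upshift_setup):
        """mu_X >> kappa: division at a set size, slope(Delta|V0) = -1."""
        params = upshift_setup[0].evolve(mu_X=60.0)
        env = ss.Environment.constant(4.8)
        st = ss.solve(4.8, params)
        initial = steady_initial(st, params)
        noise = ss.NoiseModel(seed=6)
        intensive = ss.integrate_intensive(initial, env, params, 10.0)
        recs = []
        rng = noise.rng()
        for i in range(40):
            recs += ss.simulate_lineage(env, params, noise, 10.0, initial,
                                        rng=rng, lineage_id=i,
                                        intensive=intensive)[1]
        df = ss.records_to_dataframe(recs)
        slope = np.polyfit(df.V0, df.Delta, 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)
        kP = ss.kP_at_growth_rate(st.kappa_star, params)
        assert df.Vd.mean() == pytest.approx(params.mu_X / kP, rel=0.05)


class TestEnsemble:
    def test_single_quiet_lineage_matches_deterministic(self, upshift_setup,
                                                        rich_env,
                                                        rich_initial):
        params = upshift_setup[0]
        series, recs = ss.ensemble(1, rich_env, params,
                                   ss.NoiseModel.quiet(), 4.0, rich_initial)
        _, solo = ss.simulate_lineage(rich_env, params,
                                      ss.NoiseModel.quiet(), 4.0,
                                      rich_initial)
        assert len(recs) == len(solo)
        np.testing.assert_allclose(recs.Delta.to_numpy(),
                                   [r.Delta for r in solo])

    def test_steady_state_series_is_flat(self, upshift_setup, rich_env,
                                         rich_initial):
        params = upshift_setup[0]
        noise = ss.NoiseModel(seed=8)
        series, _ = ss.ensemble(60, rich_env, params, noise, 5.0,
                                rich_initial)
        valid = series.dropna()
        mid = valid[valid.t > 1.0]
        assert mid.Delta.std() / mid.Delta.mean() < 0.1

    def test_standard_error_shrinks_with_ensemble_size(self, upshift_setup,
                                                       rich_env,
                                                       rich_initial):
        """Bin-average scatter decreases roughly as 1/sqrt(n)."""
        params = upshift_setup[0]
        scatter = {}
        for n in (16, 144):
            noise = ss.NoiseModel(seed=9)
            series, _ = ss.ensemble(n, rich_env, params, noise, 4.0,
                                    rich_initial)
            mid = series.dropna()
            scatter[n] = mid[mid.t > 1.0].Delta.std()
        ratio = scatter[16] / scatter[144]
        assert ratio == pytest.approx(3.0, rel=0.6)


class TestStationaryExit:
    def test_requires_protein_turnover(self, upshift_setup):
        params = upshift_setup[0]  # mu_ns = 0
        env = ss.Environment.constant(160.0)
        with pytest.raises(ParameterError):
            ss.simulate_stationary_exit(params, ss.NoiseModel(), env, 0.5)

    def test_initial_division_protein_density_is_constant(self,
                                                          stationary_setup):
        """Stationary cells hold constant c_X: X_tilde scales with volume."""
        params = stationary_setup[0]
        s1 = ss.stochastic.stationary_initial_state(params, 0.4)
        s2 = ss.stochastic.stationary_initial_state(params, 0.8)
        assert s2.X_tilde == pytest.approx(2 * s1.X_tilde, rel=1e-10)

    def test_larger_cells_divide_sooner(self, stationary_setup):
        params = stationary_setup[0]
        env = ss.Environment.constant(160.0)
        noise = ss.NoiseModel(threshold_sd=0.0)
        lags = []
        for V in (0.3, 0.6, 0.9):
            T, _ = ss.simulate_stationary_exit(params, noise, env, V,
                                               t_end=24.0)
            lags.append(T)
        assert lags[0] > lags[1] > lags[2]

    def test_degradation_delays_and_production_hastens_division(
            self, stationary_setup):
        params = stationary_setup[0]
        env = ss.Environment.constant(160.0)
        noise = ss.NoiseModel(threshold_sd=0.0)
        T_base, _ = ss.simulate_stationary_exit(params, noise, env, 0.5,
                                                t_end=24.0)
        T_slow, _ = ss.simulate_stationary_exit(
            params.evolve(mu_X=3.0), noise, env, 0.5, t_end=24.0)
        # division-protein production boosted by ~15%
        T_fast, _ = ss.simulate_stationary_exit(
            params.evolve(gamma_alpha=5.175, gamma_beta=1.265), noise, env,
            0.5, t_end=24.0)
        assert T_slow > T_base > T_fast

    def test_ensemble_reproducible_and_complete(self, stationary_setup):
        params = stationary_setup[0]
        env = ss.Environment.constant(160.0)
        dfs = [ss.stationary_exit_ensemble(
            30, params, ss.NoiseModel(seed=12), env, t_end=24.0)
            for _ in range(2)]
        assert dfs[0].equals(dfs[1])
        assert dfs[0].Delta.notna().all()
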