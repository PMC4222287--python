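"""Spiked-FDR screen, grid search, and sample-size interpolation."""

import itertools
import json

import numpy as np
import pytest

from metsizer import (
    ConfigError,
    DomainError,
    FDRCurve,
    ModelSpec,
    SizerConfig,
    SpectralMatrix,
    fdr_curve,
    fdr_one_permutation,
    fdr_one_simulation,
    interpolate_n_hat,
    run_metsizer,
    spike_statistics,
)
from metsizer.io import results_record
from metsizer.sizer import round_to_even


def oracle_fdr(abs_ts, spiked, p0):
    """Definition-level reimplementation: sort, cut at the p0-th largest."""
    order = sorted(abs_ts, reverse=True)
    crit = order[p0 - 1]
    declared = [j for j, v in enumerate(abs_ts) if v > crit]
    if not declared:
        return 0.0
    false = [j for j in declared if j not in spiked]
    return len(false) / len(declared)


def small_config(**kw):
    kw.setdefault("p", 20)
    kw.setdefault("model_spec", ModelSpec(p=kw["p"], q=2))
    return SizerConfig(**kw)


class TestConfig:
    def test_defaults(self):
        cfg = SizerConfig()
        assert (cfg.p, cfg.prop_significant, cfg.target_fdr) == (200, 0.2, 0.05)
        assert (cfg.min_n, cfg.delta, cfg.n_perms, cfg.n_sims) == (4, 2.3, 20, 20)
        assert cfg.p0 == 40
        assert cfg.model_spec.q == 2

    def test_p0_rounding_half_up(self):
        assert small_config(p=10, prop_significant=0.2).p0 == 2
        assert small_config(p=250, prop_significant=0.01).p0 == 3  # 2.5 -> 3

    def test_zero_spiked_bins_rejected(self):
        with pytest.raises(ConfigError):
            small_config(p=20, prop_significant=0.01)

    def test_odd_or_small_min_n_rejected(self):
        with pytest.raises(ConfigError):
            small_config(min_n=5)
        with pytest.raises(ConfigError):
            small_config(min_n=2)

    def test_bad_grid_rejected(self):
        with pytest.raises(ConfigError):
            small_config(grid=(4, 7))
        with pytest.raises(ConfigError):
            small_config(grid=(8, 6))

    def test_baseline_factor_tracks_min_n(self):
        cfg = small_config(min_n=10)
        assert cfg.baseline_factor == pytest.approx(np.sqrt(0.4))
        cfg2 = small_config(baseline_groups=(9, 9))
        assert cfg2.baseline_factor == pytest.approx(np.sqrt(2.0 / 9.0))


class TestSpike:
    def test_shift_is_delta_at_baseline_sizes(self):
        """With cf=0 and current sizes equal to the baseline, spiked bins
        gain exactly delta."""
        cfg = small_config(p=6, prop_significant=0.34, min_n=10, delta=2.3)
        TS = np.array([0.1, -0.4, 0.3, 0.0, 1.0, -1.2])
        S = np.array([0.5, 1.0, 0.2, 0.8, 0.3, 0.6])
        rng = np.random.default_rng(3)
        spiked, idx = spike_statistics(TS, S, 0.0, cfg, 5, 5, rng)
        assert len(idx) == 2  # p0 = round(0.34 * 6)
        np.testing.assert_allclose(spiked[idx], TS[idx] + 2.3, rtol=1e-12)
        mask = np.ones(6, bool)
        mask[idx] = False
        np.testing.assert_array_equal(spiked[mask], TS[mask])

    def test_shift_grows_with_current_sample_size(self):
        """The same calibrated effect is larger in statistic units at n
        beyond the baseline (the SE shrinks, the effect does not)."""
        cfg = small_config(p=6, prop_significant=0.34, min_n=10)
        TS = np.zeros(6)
        S_small = np.ones(6)
        rng = np.random.default_rng(3)
        spiked_small, idx = spike_statistics(TS, S_small, 0.0, cfg, 5, 5,
                                             np.random.default_rng(3))
        # at n=50 per group the same per-observation sd gives a smaller SE
        S_big = np.ones(6) * np.sqrt((1 / 50 + 1 / 50) / (1 / 5 + 1 / 5))
        spiked_big, idx2 = spike_statistics(TS, S_big, 0.0, cfg, 50, 50,
                                            np.random.default_rng(3))
        np.testing.assert_array_equal(idx, idx2)
        assert (spiked_big[idx2] > spiked_small[idx] * 2).all()

    def test_zero_delta_is_identity(self, rng):
        cfg = small_config(p=10, delta=0.0)
        TS = rng.standard_normal(10)
        S = rng.gamma(1.0, size=10)
        spiked, _ = spike_statistics(TS, S, 0.3, cfg, 4, 4, rng)
        np.testing.assert_array_equal(spiked, TS)


class TestFDROnePermutation:
    def test_dominant_spikes_give_zero(self):
        spiked = np.array([10.0, 9.0, 0.1, 0.2, 0.3])
        assert fdr_one_permutation(spiked, np.array([0, 1]), p0=2) == 0.0

    def test_all_ties_guarded(self):
        spiked = np.full(6, 2.0)
        assert fdr_one_permutation(spiked, np.array([0, 1]), p0=2) == 0.0

    def test_matches_exhaustive_oracle(self, rng):
        """Agreement with a definition-level oracle over every spike subset
        of a p=8 vector."""
        abs_ts = rng.gamma(2.0, size=8)
        for p0 in (1, 2, 3):
            for spiked in itertools.combinations(range(8), p0):
                got = fdr_one_permutation(abs_ts.copy(), np.array(spiked), p0)
                want = oracle_fdr(list(np.abs(abs_ts)), set(spiked), p0)
                assert got == pytest.approx(want)

    def test_delta_zero_hypergeometric_mean(self, rng):
        """With no spiking signal the spiked set is independent of the
        ranking, so E[FDR] matches the exhaustive enumeration (= 1 - p0/p
        for distinct statistics)."""
        p, p0 = 10, 2
        abs_ts = rng.gamma(2.0, size=p)
        exhaustive = np.mean([
            oracle_fdr(list(abs_ts), set(c), p0)
            for c in itertools.combinations(range(p), p0)
        ])
        assert exhaustive == pytest.approx(1 - p0 / p)
        draws = [
            fdr_one_permutation(abs_ts, rng.choice(p, p0, replace=False), p0)
            for _ in range(1000)
        ]
        assert np.mean(draws) == pytest.approx(exhaustive, abs=0.05)

    def test_invalid_p0_rejected(self):
        with pytest.raises(DomainError):
            fdr_one_permutation(np.ones(4), np.array([0]), p0=4)


class TestFDROneSimulation:
    def test_identical_rows_give_zero(self, rng):
        X = np.tile(np.arange(6.0), (6, 1))
        data = SpectralMatrix(X=X, groups=np.repeat([1, 2], 3))
        cfg = small_config(p=6, prop_significant=0.34, delta=1e6)
        assert fdr_one_simulation(data, cfg, rng) == 0.0

    def test_huge_delta_gives_zero(self, rng):
        X = rng.standard_normal((8, 20))
        data = SpectralMatrix(X=X, groups=np.repeat([1, 2], 4))
        cfg = small_config(p=20, delta=1e6)
        assert fdr_one_simulation(data, cfg, rng) == 0.0

    def test_single_permutation_median(self, rng):
        X = rng.standard_normal((8, 20))
        data = SpectralMatrix(X=X, groups=np.repeat([1, 2], 4))
        cfg = small_config(p=20, n_perms=1)
        v1 = fdr_one_simulation(data, cfg, np.random.default_rng(5))
        v2 = fdr_one_simulation(data, cfg, np.random.default_rng(5))
        assert v1 == v2
        assert 0.0 <= v1 <= 1.0


class TestFDRCurve:
    def test_percentile_ordering(self):
        cfg = small_config(p=20, n_sims=8, n_perms=5, grid=(4, 6, 8),
                           seed=11)
        curve = fdr_curve(cfg)
        assert (curve.fdr_p10 <= curve.fdr_p50).all()
        assert (curve.fdr_p50 <= curve.fdr_p90).all()
        assert (curve.sim_fdrs >= 0).all() and (curve.sim_fdrs <= 1).all()

    def test_huge_delta_flattens_curve_to_zero(self):
        cfg = small_config(p=20, delta=1e6, n_sims=5, n_perms=5,
                           grid=(4, 6), seed=2)
        curve = fdr_curve(cfg)
        assert np.all(curve.fdr_p50 == 0.0)

    def test_median_fdr_declines_with_sample_size(self):
        """Median FDR at n=50 is below its value at n=10 in >= 18/20 runs
        (default PPCA settings)."""
        wins = 0
        for seed in range(20):
            cfg = SizerConfig(n_sims=10, n_perms=10, grid=(10, 50), seed=seed)
            curve = fdr_curve(cfg)
            wins += curve.fdr_p50[1] <= curve.fdr_p50[0]
        assert wins >= 18


class TestInterpolation:
    def make_curve(self, ns, med):
        ns = np.asarray(ns)
        med = np.asarray(med, dtype=float)
        return FDRCurve(n_grid=ns, fdr_p10=med * 0.5, fdr_p50=med,
                        fdr_p90=med * 1.5,
                        sim_fdrs=np.tile(med[:, None], (1, 3)))

    def test_exact_hit_short_circuits(self):
        curve = self.make_curve([10, 12, 14], [0.08, 0.05, 0.01])
        assert interpolate_n_hat(curve, 0.05) == (12, True)

    def test_two_point_line_with_even_rounding(self):
        # line through (0.07, 20) and (0.03, 22) predicts 21 at 0.05;
        # nearest-even ties round upward -> 22
        curve = self.make_curve([20, 22], [0.07, 0.03])
        assert interpolate_n_hat(curve, 0.05) == (22, True)

    def test_never_crossing_returns_max_without_achieved(self):
        curve = self.make_curve([10, 12, 14], [0.5, 0.4, 0.3])
        with pytest.warns(UserWarning):
            n_hat, achieved = interpolate_n_hat(curve, 0.05)
        assert (n_hat, achieved) == (14, False)

    def test_starting_below_target_returns_min(self):
        curve = self.make_curve([10, 12], [0.01, 0.0])
        with pytest.warns(UserWarning):
            n_hat, achieved = interpolate_n_hat(curve, 0.05)
        assert (n_hat, achieved) == (10, False)

    def test_short_curve_rejected(self):
        curve = self.make_curve([10], [0.5])
        with pytest.raises(DomainError):
            interpolate_n_hat(curve, 0.05)

    @pytest.mark.parametrize("x,want", [(21.0, 22), (20.9, 20), (23.0, 24),
                                        (22.99, 22), (20.0, 20)])
    def test_round_to_even_tie_up(self, x, want):
        assert round_to_even(x) == want


class TestRunMetsizer:
    def test_same_seed_is_bit_identical(self):
        cfg = small_config(p=50, min_n=6, n_sims=5, n_perms=5,
                           grid=(6, 10, 14), seed=42,
                           model_spec=ModelSpec(p=50, q=2))
        a = run_metsizer(cfg)
        b = run_metsizer(cfg)
        assert a.n_hat == b.n_hat
        np.testing.assert_array_equal(a.curve.sim_fdrs, b.curve.sim_fdrs)
        ja = json.dumps(results_record(a), sort_keys=True)
        jb = json.dumps(results_record(b), sort_keys=True)
        assert ja == jb

    def test_pilot_path_uses_fitted_parameters(self, rng):
        X = rng.standard_normal((12, 40)) * 2.0
        pilot = SpectralMatrix(X=X, groups=np.repeat([1, 2], 6))
        cfg = small_config(p=20, n_sims=4, n_perms=5, grid=(6, 10),
                           seed=1, min_n=6, model_spec=ModelSpec(p=20, q=2))
        est = run_metsizer(cfg, pilot=pilot)
        # config adapts to the pilot's width and group sizes
        assert est.config.p == 40
        assert est.config.baseline_groups == (6, 6)
        assert est.n_hat >= 6

    def test_dppca_pilot_fitting_unsupported(self, rng):
        X = rng.standard_normal((10, 20))
        pilot = SpectralMatrix(X=X, groups=np.repeat([1, 2], 5))
        cfg = small_config(p=20, model_spec=ModelSpec(model="dppca", p=20))
        with pytest.raises(ConfigError):
            run_metsizer(cfg, pilot=pilot)

    def test_prior_band_wider_than_pilot_band(self, rng):
        """Fixed fitted parameters remove prior uncertainty, so the
        p90 - p10 FDR band shrinks relative to the prior-draw route
        (resolved with many simulations at one transition-region n)."""
        from metsizer.models import ModelParams

        p = 189
        W = rng.standard_normal((p, 2))
        params = ModelParams(W=W, mu=np.zeros(p), sigma2=1.5,
                             source="mle_fit")
        cfg = SizerConfig(p=p, min_n=10, n_sims=200, n_perms=20,
                          grid=(18,), seed=5,
                          model_spec=ModelSpec(p=p, q=2))
        prior_curve = fdr_curve(cfg)
        pilot_curve = fdr_curve(cfg, params=params)
        wp = float(prior_curve.fdr_p90[0] - prior_curve.fdr_p10[0])
        wf = float(pilot_curve.fdr_p90[0] - pilot_curve.fdr_p10[0])
        assert wf < wp
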