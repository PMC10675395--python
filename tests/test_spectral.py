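"""Burg AR estimation, spectra and band powers against independent oracles."""

import numpy as np
import pytest
from scipy.signal import periodogram

import eegfatigue as ef
from eegfatigue.errors import DegenerateInputError, InputError
from eegfatigue.spectral import DEFAULT_BANDS, TOTAL_BAND, default_grid


def simulate_ar(coeffs, n, seed, burn=500):
    """x(n) = sum coeffs[k] x(n-k-1) + u(n), unit-variance innovations."""
    rng = np.random.default_rng(seed)
    p = len(coeffs)
    x = np.zeros(n + burn)
    u = rng.standard_normal(n + burn)
    for i in range(p, n + burn):
        x[i] = np.dot(coeffs, x[i - p:i][::-1]) + u[i]
    return x[burn:]


def band_ratios_periodogram(x, fs, bands=DEFAULT_BANDS, total=TOTAL_BAND):
    """Independent FFT-based relative band powers."""
    f, p = periodogram(x, fs=fs)
    tot = p[(f >= total[1]) & (f < total[2])].sum()
    return {name: p[(f >= max(lo, total[1])) & (f < min(hi, total[2]))].sum()
            / tot for name, lo, hi in bands}


class TestFitBurg:
    def test_ar1_coefficient_recovery_vs_yule_walker(self):
        x = simulate_ar([0.9], 10_000, seed=1)
        model = ef.fit_burg(x, p=1)
        assert model.order == 1
        assert abs(model.coefficients[0] + 0.9) < 0.05
        from statsmodels.regression.linear_model import yule_walker
        rho, _ = yule_walker(x, order=1, method="mle")
        assert abs(model.coefficients[0] + rho[0]) < 0.02

    def test_white_noise_coefficients_near_zero(self):
        x = np.random.default_rng(2).standard_normal(10_000)
        model = ef.fit_burg(x, p=4)
        assert np.all(np.abs(model.coefficients) < 0.1)
        assert model.noise_variance == pytest.approx(x.var(), rel=0.1)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateInputError):
            ef.fit_burg(np.ones(100), p=2)
        with pytest.raises(InputError):
            ef.fit_burg(np.arange(5.0), p=5)
        with pytest.raises(InputError):
            ef.fit_burg(np.arange(100.0), p=0)


class TestOrderSelection:
    def test_ar2_order_recovery_monte_carlo(self):
        # AIC overselects each candidate higher order with probability
        # ~P(chi2_1 > 2) = 0.157, so exact recovery sits near 75%; require
        # a clear majority and never an underfit.
        hits = 0
        for seed in range(50):
            x = simulate_ar([0.75, -0.5], 10_000, seed=100 + seed)
            p = ef.select_order_aic(x, p_max=10)
            assert p >= 2, "AIC must never underfit a strong AR(2)"
            if p == 2:
                hits += 1
        assert hits >= 35  # >= 70% of 50 replicates

    def test_white_noise_prefers_small_orders(self):
        small = sum(
            ef.select_order_aic(
                np.random.default_rng(200 + s).standard_normal(5000),
                p_max=10) <= 3
            for s in range(20)
        )
        assert small >= 14

    def test_single_candidate(self):
        x = simulate_ar([0.5], 500, seed=3)
        assert ef.select_order_aic(x, p_max=1) == 1


class TestBurgPsd:
    def test_white_model_is_exactly_flat(self):
        model = ef.ARModel(coefficients=[0.0, 0.0], order=2,
                           noise_variance=2.0, final_error=2.0)
        psd = ef.burg_psd(model, np.linspace(0, 100, 201), fs=200)
        assert psd.max() / psd.min() == 1.0
        assert np.all(psd > 0)

    def test_ar1_lowpass_shape(self):
        model = ef.ARModel(coefficients=[-0.9], order=1,
                           noise_variance=1.0, final_error=1.0)
        psd = ef.burg_psd(model, np.array([0.0, 100.0]), fs=200)
        assert psd[0] > psd[1]

    def test_parseval_on_white_noise(self):
        x = np.random.default_rng(4).standard_normal(8000)
        model = ef.fit_burg(x, p=6)
        grid = default_grid(200.0)
        psd = ef.burg_psd(model, grid, fs=200)
        integral = psd.sum() * (grid[1] - grid[0])
        assert integral == pytest.approx(x.var(), rel=0.10)

    def test_frequency_above_nyquist_rejected(self):
        model = ef.ARModel(coefficients=[-0.5], order=1,
                           noise_variance=1.0, final_error=1.0)
        with pytest.raises(InputError):
            ef.burg_psd(model, np.array([150.0]), fs=200)


class TestBandPower:
    def test_flat_psd_rectangle_rule(self):
        grid = np.arange(0, 100.25, 0.25)
        psd = np.full(grid.size, 2.0)
        power = ef.band_power(psd, grid, ("theta", 4.0, 7.0))
        assert power == pytest.approx(3 * 2.0, rel=0.01)

    def test_partition_additivity_is_exact(self, rng):
        grid = np.arange(0, 100.25, 0.25)
        psd = rng.random(grid.size)
        edges = [1, 5, 11.5, 19, 30]
        parts = [ef.band_power(psd, grid, (f"b{i}", lo, hi))
                 for i, (lo, hi) in enumerate(zip(edges, edges[1:]))]
        total = ef.band_power(psd, grid, ("total", 1, 30))
        assert np.isclose(sum(parts), total, rtol=0, atol=1e-12)

    def test_pure_alpha_tone_dominates_theta(self, rng):
        x = np.sin(2 * np.pi * 10.0 * np.arange(12000) / 200.0) \
            + 0.01 * rng.standard_normal(12000)
        model = ef.fit_burg(x, p=10)
        grid = default_grid(200.0)
        psd = ef.burg_psd(model, grid, fs=200)
        alpha = ef.band_power(psd, grid, ("alpha", 8, 13))
        theta = ef.band_power(psd, grid, ("theta", 4, 7))
        assert alpha / theta > 10
        oracle = band_ratios_periodogram(x, 200.0)
        assert oracle["alpha"] / max(oracle["theta"], 1e-12) > 10


class TestRpsd:
    def test_band_equal_total_gives_one(self, rng):
        grid = np.arange(0, 100.25, 0.25)
        psd = rng.random(grid.size) + 0.1
        assert ef.rpsd(psd, grid, ("total", 1, 30), ("total", 1, 30)) == 1.0

    def test_scale_invariance(self, rng):
        x = simulate_ar([0.6, -0.2], 4000, seed=7)
        grid = default_grid(200.0)
        base = ef.burg_psd(ef.fit_burg(x, 10), grid, 200)
        scaled = ef.burg_psd(ef.fit_burg(123.4 * x, 10), grid, 200)
        for band in [("alpha", 8, 13), ("theta", 4, 7)]:
            r0 = ef.rpsd(base, grid, band)
            r1 = ef.rpsd(scaled, grid, band)
            assert abs(r0 - r1) < 1e-6

    def test_zero_total_power_is_degenerate(self):
        grid = np.arange(0, 100.25, 0.25)
        with pytest.raises(DegenerateInputError):
            ef.rpsd(np.zeros(grid.size), grid, ("alpha", 8, 13))


class TestExtractFeatures:
    def test_feature_table_shapes(self, small_epoch):
        f = ef.extract_features(small_epoch)
        assert f.psd.shape == (32, 4)
        assert f.rpsd.shape == (32, 4)
        assert list(f.psd.index) == list(small_epoch.channel_labels)
        assert np.all((f.rpsd.values >= 0) & (f.rpsd.values <= 1))
        assert np.all(f.rpsd.values.sum(axis=1) <= 1 + 1e-9)

    def test_duplicated_channel_gives_identical_rows(self, small_epoch):
        import copy
        ep = copy.deepcopy(small_epoch)
        ep.samples[1] = ep.samples[0]
        f = ef.extract_features(ep)
        row0 = f.rpsd.iloc[0].to_numpy()
        row1 = f.rpsd.iloc[1].to_numpy()
        assert np.array_equal(row0, row1)

    def test_fatigue_theta_exceeds_normal(self, profiles):
        recs = {s: ef.generate_recording(profiles[s], 120, 500, seed=5)
                for s in ("normal", "fatigue")}
        theta = {}
        for s, rec in recs.items():
            eps = ef.preprocess_recording(rec)
            f = ef.extract_features(eps[0])
            theta[s] = f.rpsd["theta"].mean()
        assert theta["fatigue"] > theta["normal"]


def test_burg_matches_periodogram_band_ratios_ar2():
    """Burg and FFT-periodogram relative band powers agree within 15%."""
    worst = 0.0
    for seed in range(10):
        x = simulate_ar([0.6, -0.3], 12_000, seed=300 + seed)
        grid = default_grid(200.0)
        psd = ef.burg_psd(ef.fit_burg(x, 10), grid, 200)
        oracle = band_ratios_periodogram(x, 200.0)
        for name, lo, hi in DEFAULT_BANDS:
            clipped = (name, max(lo, TOTAL_BAND[1]), min(hi, TOTAL_BAND[2]))
            mine = ef.rpsd(psd, grid, clipped)
            rel = abs(mine - oracle[name]) / oracle[name]
            worst = max(worst, rel)
    assert worst < 0.15
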