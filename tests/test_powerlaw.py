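import numpy as np
import pytest

from chromocorr.powerlaw import (fit_powerlaw, goodness_of_fit,
                                 mc_confidence_band, select_fit_bins)
from chromocorr.tpcf import BinScheme, CorrelationEstimate, PairCounts, make_log_bins


def make_estimate(one_plus_xi, sigma_boot, sigma_poisson=None, raw_rr=None,
                  bins=None):
    one_plus_xi = np.asarray(one_plus_xi, dtype=float)
    k = one_plus_xi.size
    if bins is None:
        bins = make_log_bins(1e3, 1e7, k)
    sigma_boot = np.asarray(sigma_boot, dtype=float)
    if sigma_poisson is None:
        sigma_poisson = sigma_boot
    if raw_rr is None:
        raw_rr = np.full(k, 1000)
    counts = PairCounts(bins, np.full(k, 500), np.full(k, 500), raw_rr, 100, 1000)
    return CorrelationEstimate(bins, one_plus_xi, sigma_boot,
                               np.asarray(sigma_poisson, dtype=float), counts)


def powerlaw_estimate(A, beta, k=10, noise=0.0, sigma=0.05, rng=None):
    bins = make_log_bins(1e3, 1e7, k)
    model = A * bins.centers**beta
    vals = model.copy()
    sig = np.full(k, sigma) * model
    if noise:
        vals = vals + rng.normal(0.0, noise * model, size=k)
    return make_estimate(vals, sig, bins=bins)


class TestSelectFitBins:
    def test_constructed_cut_point(self):
        vals = [5, 4, 3, 2.5, 2, 1.7, 1.4, 1.2, 1.05, 1.01]
        sig = [0.1] * 8 + [0.1, 0.1]   # bins 8,9 within 1 sigma of 1
        est = make_estimate(vals, sig)
        assert select_fit_bins(est).tolist() == list(range(8))

    def test_all_bins_above_random(self):
        est = powerlaw_estimate(100.0, -0.3, k=8)
        assert select_fit_bins(est).tolist() == list(range(8))

    def test_invalid_bins_excluded(self):
        vals = [5, 4, 3, 2.5, 2, 1.7, 1.4, 1.2]
        rr = np.array([1000] * 8)
        rr[3] = 0
        est = make_estimate(vals, [0.05] * 8, raw_rr=rr)
        sel = select_fit_bins(est)
        assert 3 not in sel.tolist()

    def test_no_signal_raises(self):
        est = make_estimate([1.01, 1.0, 0.99, 1.02], [0.1] * 4)
        with pytest.raises(ValueError, match="no clustering"):
            select_fit_bins(est)

    def test_too_few_bins_raises(self):
        est = make_estimate([5, 4, 1.0, 1.0, 1.0], [0.05] * 5)
        with pytest.raises(ValueError):
            select_fit_bins(est)


class TestFitPowerlaw:
    def test_exact_model_recovered_to_machine_precision(self):
        est = powerlaw_estimate(10.0, -0.5, k=8)
        fit = fit_powerlaw(est, np.arange(8))
        assert fit.amplitude == pytest.approx(10.0, rel=1e-12)
        assert fit.index == pytest.approx(-0.5, abs=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        est = powerlaw_estimate(50.0, -0.4, k=9, noise=0.05, rng=rng)
        fb = np.arange(9)
        fit = fit_powerlaw(est, fb)
        # dense grid search over (log10 A, beta) minimizing the same chi2
        x = np.log10(est.bins.centers)
        y = np.log10(est.one_plus_xi)
        sl = est.sigma_boot / (est.one_plus_xi * np.log(10))
        a_grid = np.linspace(np.log10(fit.amplitude) - 0.05,
                             np.log10(fit.amplitude) + 0.05, 401)
        b_grid = np.linspace(fit.index - 0.05, fit.index + 0.05, 401)
        A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
        chi2 = ((y - A[..., None] - B[..., None] * x) ** 2 / sl**2).sum(axis=-1)
        i, j = np.unravel_index(chi2.argmin(), chi2.shape)
        assert np.log10(fit.amplitude) == pytest.approx(a_grid[i], abs=4e-4)
        assert fit.index == pytest.approx(b_grid[j], abs=4e-4)
        assert fit.chi2 == pytest.approx(chi2[i, j], rel=1e-3)

    def test_two_bins_rejected(self):
        est = powerlaw_estimate(10.0, -0.5, k=8)
        with pytest.raises(ValueError):
            fit_powerlaw(est, np.array([0, 1]))

    def test_singular_design_rejected(self):
        bins = BinScheme([1e3, 2e3, 4e3])
        est = make_estimate([2.0, 2.0], [0.1, 0.1], bins=bins)
        # collapse separations via identical centers is impossible with a
        # valid BinScheme; instead check repeated single bin index
        with pytest.raises(ValueError):
            fit_powerlaw(est, np.array([0, 0, 0]))

    def test_covariance_positive(self):
        rng = np.random.default_rng(3)
        est = powerlaw_estimate(5.0, -0.6, k=10, noise=0.04, rng=rng)
        fit = fit_powerlaw(est, np.arange(10))
        assert fit.covariance[0, 0] > 0 and fit.covariance[1, 1] > 0
        assert fit.index_err > 0 and fit.amplitude_err > 0


class TestGoodnessOfFit:
    def test_perfect_model(self):
        est = powerlaw_estimate(10.0, -0.5, k=8)
        fit = fit_powerlaw(est, np.arange(8))
        chi2, p, chi2_nu = goodness_of_fit(est, fit)
        assert chi2 == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_reduced_chi2_calibrated(self):
        """Gaussian perturbations at the stated sigma give chi2_nu ~ 1 on
        average over many replicates."""
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(300):
            est = powerlaw_estimate(20.0, -0.5, k=10, noise=0.03, rng=rng)
            # stated sigma must equal the perturbation sigma for calibration
            est = make_estimate(est.one_plus_xi,
                                0.03 * 20.0 * est.bins.centers**-0.5,
                                bins=est.bins)
            fit = fit_powerlaw(est, np.arange(10))
            vals.append(fit.chi2_nu)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_gross_mismatch_detected(self):
        rng = np.random.default_rng(1)
        est = powerlaw_estimate(20.0, -0.5, k=10, noise=0.02, rng=rng)
        good = fit_powerlaw(est, np.arange(10))
        bad = type(good)(amplitude=good.amplitude, index=good.index - 1.0,
                         covariance=good.covariance, fit_bins=good.fit_bins,
                         chi2=good.chi2, chi2_nu=good.chi2_nu, p_value=good.p_value)
        chi2, p, _ = goodness_of_fit(est, bad)
        assert p < 0.01


class TestMcConfidenceBand:
    def test_zero_sigma_collapses_to_fit_line(self):
        est = powerlaw_estimate(10.0, -0.5, k=8, sigma=0.0)
        fb = np.arange(8)
        fit = fit_powerlaw(est, fb)
        band = mc_confidence_band(est, fb, n_real=200, rng=np.random.default_rng(0))
        line = fit.model(band.r)
        assert band.lower == pytest.approx(line, rel=1e-12)
        assert band.upper == pytest.approx(line, rel=1e-12)

    @pytest.mark.parametrize("n_real,lo,hi", [(10_000, 50, 9950), (1000, 5, 995),
                                              (200, 1, 199)])
    def test_rank_indices_scale(self, n_real, lo, hi):
        assert int(np.ceil(0.005 * n_real)) == lo
        assert int(np.floor(0.995 * n_real)) == hi

    def test_band_uses_prescribed_ranks(self):
        rng = np.random.default_rng(8)
        est = powerlaw_estimate(10.0, -0.5, k=8, sigma=0.05)
        fb = np.arange(8)
        band = mc_confidence_band(est, fb, n_real=1000, rng=rng)
        # re-derive the band from the recorded parameter draws
        curves = band.amp_draws[:, None] * band.r[None, :] ** band.beta_draws[:, None]
        srt = np.sort(curves, axis=0)
        assert band.lower == pytest.approx(srt[4])    # realization 5 of 1000
        assert band.upper == pytest.approx(srt[994])  # realization 995

    def test_too_few_realizations(self):
        est = powerlaw_estimate(10.0, -0.5, k=8)
        with pytest.raises(ValueError):
            mc_confidence_band(est, np.arange(8), n_real=50)

    def test_wider_errors_widen_band(self):
        est1 = powerlaw_estimate(10.0, -0.5, k=8, sigma=0.03)
        est2 = powerlaw_estimate(10.0, -0.5, k=8, sigma=0.09)
        fb = np.arange(8)
        b1 = mc_confidence_band(est1, fb, n_real=2000, rng=np.random.default_rng(4))
        b2 = mc_confidence_band(est2, fb, n_real=2000, rng=np.random.default_rng(4))
        assert np.all((b2.upper - b2.lower) > (b1.upper - b1.lower))

    def test_parameter_coverage(self):
        """True (A, beta) falls inside the 99% Monte-Carlo interval in at
        least 95% of replicates when the noise matches the stated sigma."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            est = powerlaw_estimate(20.0, -0.5, k=10, noise=0.05, rng=rng)
            band = mc_confidence_band(est, np.arange(10), n_real=1000, rng=rng)
            hits += band.contains_params(20.0, -0.5)
        assert hits / n_rep >= 0.95
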