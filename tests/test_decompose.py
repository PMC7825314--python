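import numpy as np
import pytest
from scipy.stats import norm

from fourcis import (
    DecayParams,
    Peak,
    Profile,
    SymmetrizedProfile,
    ValidationError,
    call_significant,
    detect_candidates,
    estimate_noise,
    evaluate_model,
    filter_fragments,
    fit_decay,
    fit_peaks,
    normalize,
    peak_pvalue,
)
from fourcis.model import FourCPeakCaller


DECAY = DecayParams(B=2.0, I=100.0, lam=50_000.0)
XV = 500_000.0


class TestEvaluateModel:
    def test_no_peaks_at_viewpoint_is_background_plus_intensity(self):
        assert evaluate_model(DECAY, [], 1.0, XV, XV) == pytest.approx(102.0)

    def test_decay_limit_is_background(self):
        far = evaluate_model(DECAY, [], 1.0, XV, XV + 1e9)
        assert far == pytest.approx(DECAY.B)

    def test_peak_value_at_its_own_center(self):
        center = XV + 30_000.0
        val = evaluate_model(DECAY, [(center, 50.0)], 3_000.0, XV, center)
        expected = 2.0 + 100.0 * np.exp(-30_000.0 / 50_000.0) + 50.0
        assert val == pytest.approx(expected)

    def test_never_below_background(self):
        x = np.linspace(XV - 2e6, XV + 2e6, 1_001)
        vals = evaluate_model(DECAY, [(XV + 1e5, 30.0)], 3_000.0, XV, x)
        assert np.all(vals >= DECAY.B)


def _noise_free_bins(decay, d=None, w=None):
    d = np.arange(2_000, 402_000, 2_000, dtype=float) if d is None else d
    m = decay.B + decay.I * np.exp(-d / decay.lam)
    w = np.ones_like(d) if w is None else w
    return SymmetrizedProfile(d, m, w)


class TestFitDecay:
    def test_noise_free_recovery_to_1e6(self):
        params, cov = fit_decay(_noise_free_bins(DECAY))
        assert params.B == pytest.approx(DECAY.B, rel=1e-6)
        assert params.I == pytest.approx(DECAY.I, rel=1e-6)
        assert params.lam == pytest.approx(DECAY.lam, rel=1e-6)
        assert cov.shape == (3, 3)

    def test_flat_profile_degenerates_to_constant(self):
        d = np.arange(2_000, 42_000, 2_000, dtype=float)
        sym = SymmetrizedProfile(d, np.full_like(d, 7.0), np.ones_like(d))
        with pytest.warns(UserWarning, match="flat"):
            params, _ = fit_decay(sym)
        assert params.B == pytest.approx(7.0, abs=1e-6)
        assert params.I == pytest.approx(0.0, abs=1e-6)

    def test_scaling_equivariance(self):
        sym = _noise_free_bins(DECAY)
        doubled = SymmetrizedProfile(sym.d, 2 * sym.m, sym.w)
        a, _ = fit_decay(sym)
        b, _ = fit_decay(doubled)
        assert b.B == pytest.approx(2 * a.B, rel=1e-6)
        assert b.I == pytest.approx(2 * a.I, rel=1e-6)
        assert b.lam == pytest.approx(a.lam, rel=1e-6)

    def test_weights_influence_fit(self):
        # corrupt far bins; heavy weight on near bins pulls the fit back
        sym = _noise_free_bins(DECAY)
        m = sym.m.copy()
        m[-20:] += 50.0
        heavy_near = np.where(sym.d < 100_000, 1e6, 1.0)
        corrupted, _ = fit_decay(SymmetrizedProfile(sym.d, m, np.ones_like(m)))
        reweighted, _ = fit_decay(SymmetrizedProfile(sym.d, m, heavy_near))
        true_err_c = abs(corrupted.lam - DECAY.lam)
        true_err_w = abs(reweighted.lam - DECAY.lam)
        assert true_err_w < true_err_c

    def test_too_few_bins_rejected(self):
        d = np.array([1_000.0, 2_000.0, 3_000.0, 4_000.0])
        sym = SymmetrizedProfile(d, d * 0 + 1, np.ones_like(d))
        with pytest.raises(ValidationError):
            fit_decay(sym)


def _synthetic_profile(counts, xv=XV, spacing=500.0, stage="normalized"):
    n = len(counts)
    starts = (xv - n * spacing / 2 + np.arange(n) * spacing).astype(np.int64)
    ends = (starts + spacing).astype(np.int64)
    return Profile("chrA", xv, starts, ends, np.maximum(counts, 0.0), stage=stage)


class TestEstimateNoise:
    def test_mad_recovers_gaussian_scale(self):
        tau = 10.0
        rng = np.random.default_rng(0)
        n = 2_000  # 4 bands x 500 fragments
        base = DecayParams(1_000.0, 0.0, 1.0)
        counts = base.B + rng.normal(0, tau, n)
        prof = _synthetic_profile(counts)
        bands = estimate_noise(prof, base, n_bands=4)
        assert np.all(np.abs(bands.scales - tau) / tau < 0.15)

    def test_zero_residuals_flagged_degenerate(self):
        base = DecayParams(5.0, 0.0, 1.0)
        prof = _synthetic_profile(np.full(100, 5.0))
        with pytest.warns(UserWarning, match="degenerate"):
            bands = estimate_noise(prof, base)
        assert bands.degenerate
        assert np.all(bands.scales == 0)

    def test_robust_to_one_outlier_per_band(self):
        tau = 10.0
        rng = np.random.default_rng(1)
        base = DecayParams(1_000.0, 0.0, 1.0)
        counts = base.B + rng.normal(0, tau, 2_000)
        clean = estimate_noise(_synthetic_profile(counts), base, n_bands=4)
        spiked = counts.copy()
        for lo, hi in zip(clean.edges[:-1], clean.edges[1:]):
            prof = _synthetic_profile(counts)
            idx = np.flatnonzero((prof.distances >= lo) & (prof.distances < hi))
            spiked[idx[0]] += 1_000 * tau
        dirty = estimate_noise(_synthetic_profile(spiked), base, n_bands=4)
        assert np.all(np.abs(dirty.scales - clean.scales) / clean.scales < 0.10)

    def test_small_bands_are_merged(self):
        rng = np.random.default_rng(2)
        base = DecayParams(100.0, 0.0, 1.0)
        counts = base.B + rng.normal(0, 1.0, 50)
        bands = estimate_noise(_synthetic_profile(counts), base, n_bands=8)
        assert np.all(bands.counts >= 20)

    def test_too_few_fragments_rejected(self):
        base = DecayParams(100.0, 0.0, 1.0)
        with pytest.raises(ValidationError):
            estimate_noise(_synthetic_profile(np.full(10, 100.0)), base)


class TestDetectCandidates:
    def test_injected_peak_is_top_candidate(self):
        tau, sigma = 5.0, 3_000.0
        rng = np.random.default_rng(3)
        base = DecayParams(500.0, 0.0, 1.0)
        prof0 = _synthetic_profile(np.full(4_000, base.B))
        x = prof0.midpoints
        center = XV + 250_000.0
        signal = 20 * tau * np.exp(-((x - center) ** 2) / (2 * sigma**2))
        counts = base.B + signal + rng.normal(0, tau, x.size)
        prof = _synthetic_profile(counts)
        bands = estimate_noise(prof, base)
        cands = detect_candidates(prof, base, bands, sigma_init=sigma)
        assert len(cands) >= 1
        assert abs(cands[0] - center) <= sigma

    def test_null_profile_rarely_yields_candidates(self):
        """Smoothed z >= 3 across ~2000 null fragments is a rare event."""
        base = DecayParams(500.0, 0.0, 1.0)
        n_cands = []
        for seed in range(100):
            rng = np.random.default_rng(1_000 + seed)
            prof = _synthetic_profile(base.B + rng.normal(0, 5.0, 2_000))
            bands = estimate_noise(prof, base)
            n_cands.append(len(detect_candidates(prof, base, bands)))
        assert np.median(n_cands) <= 10

    def test_all_quiet_returns_empty(self):
        base = DecayParams(500.0, 0.0, 1.0)
        rng = np.random.default_rng(4)
        prof = _synthetic_profile(base.B + rng.normal(0, 1.0, 500))
        bands = estimate_noise(prof, base)
        assert len(detect_candidates(prof, base, bands, z_min=10.0)) == 0

    def test_candidates_respect_minimum_separation(self):
        base = DecayParams(500.0, 0.0, 1.0)
        rng = np.random.default_rng(5)
        counts = base.B + rng.normal(0, 1.0, 3_000)
        prof = _synthetic_profile(counts)
        bands = estimate_noise(prof, base)
        cands = detect_candidates(prof, base, bands, z_min=0.0, sigma_init=3_000.0)
        cands = np.sort(cands)
        assert np.all(np.diff(cands) >= 2 * 3_000.0)


class TestPeakPvalue:
    def test_zero_amplitude_gives_half(self):
        assert peak_pvalue(0.0, 1.0) == pytest.approx(0.5)

    def test_z_329_is_near_threshold(self):
        assert peak_pvalue(3.29, 1.0) == pytest.approx(norm.sf(3.29))
        assert peak_pvalue(3.29, 1.0) == pytest.approx(5.01e-4, rel=1e-2)

    def test_monotone_decreasing_in_amplitude(self):
        ps = [peak_pvalue(a, 1.0) for a in np.linspace(0, 10, 25)]
        assert np.all(np.diff(ps) < 0)

    @pytest.mark.parametrize("se", [0.0, -1.0, np.nan])
    def test_invalid_se_rejected(self, se):
        with pytest.raises(ValidationError):
            peak_pvalue(1.0, se)


@pytest.fixture(scope="module")
def fitted_small(small_profile, small_map):
    return FourCPeakCaller().fit(small_profile, small_map)


class TestFitPeaks:
    def test_recovers_both_simulated_peaks(self, fitted_small, small_truth):
        fit = fitted_small.model_fit_
        centers = np.array([p.center for p in fit.significant_peaks])
        for tc, _ in small_truth.peaks:
            assert np.min(np.abs(centers - tc)) <= 2_000.0

    def test_no_candidates_returns_decay_only_fit(self, small_profile, small_map):
        from fourcis import symmetrize

        prof = normalize(filter_fragments(small_profile, small_map))
        sym_decay, _ = fit_decay(symmetrize(prof))
        fit = fit_peaks(prof, sym_decay, candidates=[])
        assert fit.n_peaks == 0
        assert fit.decay == sym_decay

    def test_rmse_non_increasing_along_selection(self, fitted_small):
        path = fitted_small.model_fit_.diagnostics["rmse_path"]
        assert all(b <= a + 1e-9 for a, b in zip(path, path[1:]))

    def test_peaks_sorted_by_center(self, fitted_small):
        centers = [p.center for p in fitted_small.model_fit_.peaks]
        assert centers == sorted(centers)


class TestCallSignificant:
    def _fit(self, ps):
        peaks = [Peak(float(i * 10_000 + 10_000), 1.0, z=1.0, p=p) for i, p in enumerate(ps)]
        from fourcis import ModelFit

        return ModelFit(decay=DECAY, peaks=peaks, sigma=3_000.0, xv=XV)

    def test_strictly_below_alpha_is_significant(self):
        fit = call_significant(self._fit([0.0004, 0.0005, 0.01]), alpha=0.0005)
        assert [p.significant for p in fit.peaks] == [True, False, False]

    def test_alpha_one_flags_everything(self):
        fit = call_significant(self._fit([0.5, 0.99]), alpha=1.0)
        assert all(p.significant for p in fit.peaks)

    def test_nonsignificant_peaks_are_retained(self):
        fit = call_significant(self._fit([0.9]), alpha=0.0005)
        assert fit.n_peaks == 1 and not fit.peaks[0].significant

    def test_bh_adjustment_is_more_conservative(self):
        ps = [0.0004, 0.00045, 0.9]
        raw = call_significant(self._fit(ps), alpha=0.0005)
        bh = call_significant(self._fit(ps), alpha=0.0005, fdr="bh")
        assert sum(p.significant for p in raw.peaks) == 2
        # BH adjusted p of both small peaks is 0.00045 * 3 / 2 = 0.000675
        assert sum(p.significant for p in bh.peaks) == 0

    def test_unknown_fdr_method_rejected(self):
        with pytest.raises(ValidationError):
            call_significant(self._fit([0.5]), fdr="bonferroni")
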