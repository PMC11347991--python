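"""Lifetime summaries, reconvolution fitting, model selection, lifetime maps."""

import numpy as np
import pytest

from flimplex import (
    DecayParams,
    FLIMImage,
    IRFModel,
    TimingConfig,
    expected_decay,
    simulate_pixel,
)
from flimplex.fitting import (
    FitResult,
    amplitude_weighted_lifetime,
    fit_decay,
    fit_image,
    intensity_weighted_lifetime,
    mean_arrival_time,
    reduced_chi2,
    select_model,
    wraparound_corrected_lifetime,
    _CurveFactory,
)
from flimplex.simulate import fast_species


class TestLifetimeSummaries:
    def test_worked_example(self):
        p = DecayParams((0.5, 0.5), (1.0, 3.0))
        assert intensity_weighted_lifetime(p) == pytest.approx(2.5)
        assert amplitude_weighted_lifetime(p) == pytest.approx(2.0)

    @pytest.mark.parametrize("amplitude", [0.1, 1.0, 42.0])
    def test_monoexponential_identity(self, amplitude):
        p = DecayParams.monoexp(1.7, amplitude)
        assert intensity_weighted_lifetime(p) == pytest.approx(1.7)
        assert amplitude_weighted_lifetime(p) == pytest.approx(1.7)

    def test_amplitude_scaling_invariance(self):
        p = DecayParams((0.6, 0.4), (0.8, 2.4))
        q = DecayParams((6.0, 4.0), (0.8, 2.4))
        assert intensity_weighted_lifetime(p) == pytest.approx(intensity_weighted_lifetime(q))


class TestMeanArrivalTime:
    def test_single_bin_delta(self, timing):
        h = np.zeros(timing.n_bins)
        k = 20
        h[k] = 50
        assert mean_arrival_time(h, timing) == pytest.approx(timing.bin_centers[k])

    def test_uniform_background_subtraction_invariance(self, timing, rng):
        h = rng.poisson(expected_decay(DecayParams.monoexp(2.0), IRFModel(kind="delta", center_t0=0), timing) * 1e5)
        m0 = mean_arrival_time(h, timing)
        m1 = mean_arrival_time(h + 7, timing, background_per_bin=7)
        assert m1 == pytest.approx(m0, abs=1e-12)

    def test_zero_photons_is_nan(self, timing):
        assert np.isnan(mean_arrival_time(np.zeros(timing.n_bins), timing))

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 4.0])
    def test_wraparound_correction_inverts_periodic_moment(self, timing, delta_irf, tau):
        curve = expected_decay(DecayParams.monoexp(tau), delta_irf, timing)
        m = float(np.sum(curve * timing.bin_centers))
        assert wraparound_corrected_lifetime(m, timing.period_ns) == pytest.approx(tau, abs=5e-3)


class TestReducedChi2:
    def test_exact_agreement_is_zero(self):
        e = np.full(100, 25.0)
        assert reduced_chi2(e, e, 3) == 0.0

    def test_residual_monotonicity(self):
        e = np.full(100, 25.0)
        o = e.copy()
        base = reduced_chi2(o, e, 3)
        o[10] *= 2
        assert reduced_chi2(o, e, 3) > base

    def test_low_count_bins_excluded_and_dof_guard(self):
        e = np.r_[np.full(5, 0.5), np.full(5, 10.0)]
        o = np.zeros(10)
        # only 5 bins pass the floor of 1 expected count
        assert reduced_chi2(o, e, 0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            reduced_chi2(o, e, 5)


class TestFitDecay:
    def test_noiseless_monoexp_self_consistency(self, timing, delta_irf):
        curve = np.round(expected_decay(DecayParams.monoexp(2.0), delta_irf, timing) * 1e6)
        fit = fit_decay(curve, delta_irf, timing, n_components=1)
        assert fit.params.lifetimes[0] == pytest.approx(2.0, rel=1e-3)
        assert fit.converged

    def test_biexp_ti_is_stable_compound(self, timing, gauss_irf, biexp_params, rng):
        """Even when individual components trade off, T_i is recovered."""
        true_ti = intensity_weighted_lifetime(biexp_params)
        curve = expected_decay(biexp_params, gauss_irf, timing)
        tis = [
            fit_decay(rng.poisson(curve * 1e5), gauss_irf, timing, 2).ti
            for _ in range(5)
        ]
        assert np.mean(tis) == pytest.approx(true_ti, rel=0.02)

    def test_lifetimes_sorted_and_ti_ge_ta(self, timing, gauss_irf, rng):
        h = rng.poisson(expected_decay(fast_species(1.89), gauss_irf, timing) * 2e4)
        fit = fit_decay(h, gauss_irf, timing, 2)
        assert fit.params.lifetimes[0] <= fit.params.lifetimes[1]
        assert fit.ti >= fit.ta

    def test_initial_component_order_irrelevant(self, timing, gauss_irf, rng):
        h = rng.poisson(expected_decay(fast_species(1.89), gauss_irf, timing) * 2e4)
        fit_a = fit_decay(h, gauss_irf, timing, 2,
                          init=DecayParams.from_intensity_fractions((0.5, 0.5), (1.0, 2.5)))
        fit_b = fit_decay(h, gauss_irf, timing, 2,
                          init=DecayParams.from_intensity_fractions((0.5, 0.5), (2.5, 1.0)))
        assert fit_a.ti == pytest.approx(fit_b.ti, abs=1e-4)

    def test_below_photon_threshold_refused(self, timing, gauss_irf):
        with pytest.raises(ValueError, match="below the minimum"):
            fit_decay(np.ones(timing.n_bins) * 0.1, gauss_irf, timing, 1)

    def test_background_recovered(self, timing, gauss_irf, rng):
        curve = 2e4 * expected_decay(DecayParams.monoexp(2.0), gauss_irf, timing) + 10.0
        fit = fit_decay(rng.poisson(curve), gauss_irf, timing, 1)
        assert fit.background == pytest.approx(10.0 * timing.n_bins, rel=0.3)


class TestSelectModel:
    def _fit(self, order, chi2, fracs=(0.5, 0.5), converged=True):
        taus = (1.0,) if order == 1 else (1.0, 2.5)
        p = DecayParams.from_intensity_fractions(fracs[: len(taus)], taus)
        return FitResult(p, 0.0, 0.0, chi2, 1e4, order,
                         intensity_weighted_lifetime(p), amplitude_weighted_lifetime(p),
                         converged)

    def test_tie_prefers_parsimony(self):
        assert select_model(self._fit(1, 1.0), self._fit(2, 1.0)).model_order == 1

    def test_clear_improvement_selects_biexponential(self):
        assert select_model(self._fit(1, 1.5), self._fit(2, 1.0)).model_order == 2

    def test_negligible_minor_component_vetoes_biexponential(self):
        bi = self._fit(2, 1.0, fracs=(0.995, 0.005))
        assert select_model(self._fit(1, 1.5), bi).model_order == 1

    def test_unconverged_fit_defers(self):
        assert select_model(self._fit(1, 0.9), self._fit(2, 2.0, converged=False)).model_order == 1
        assert select_model(self._fit(1, 2.0, converged=False), self._fit(2, 1.9)).model_order == 2

    def test_argument_order_enforced(self):
        with pytest.raises(ValueError):
            select_model(self._fit(2, 1.0), self._fit(1, 1.0))


class TestFitImage:
    def _two_region_image(self, timing, irf, photons=2000, n=12):
        curves = {
            1: expected_decay(fast_species(1.45), irf, timing),
            2: expected_decay(fast_species(2.10), irf, timing),
        }
        rng = np.random.default_rng(3)
        counts = np.zeros((n, n, timing.n_bins), dtype=np.uint32)
        labels = np.zeros((n, n), dtype=int)
        labels[:, : n // 2] = 1
        labels[:, n // 2 :] = 2
        labels[0, 0] = 0  # a masked pixel
        for lab, curve in curves.items():
            m = labels == lab
            counts[m] = rng.poisson(curve * photons, size=(m.sum(), timing.n_bins))
        return FLIMImage(counts, timing, irf=irf), labels

    def test_two_region_recovery_and_masked_nan(self, timing, gauss_irf):
        img, labels = self._two_region_image(timing, gauss_irf)
        lmap = fit_image(img, gauss_irf, timing)
        assert np.isnan(lmap.ti[0, 0])
        mean_a = np.nanmean(lmap.ti[labels == 1])
        mean_b = np.nanmean(lmap.ti[labels == 2])
        assert mean_a == pytest.approx(1.45, abs=0.05)
        assert mean_b == pytest.approx(2.10, abs=0.05)

    def test_uniform_image_precision(self, timing, gauss_irf):
        """Single-species pixels at 1e3 photons: T_i map SD below 5% of mean."""
        curve = expected_decay(fast_species(1.89), gauss_irf, timing)
        rng = np.random.default_rng(8)
        counts = rng.poisson(curve * 1000, size=(10, 10, timing.n_bins)).astype(np.uint32)
        lmap = fit_image(FLIMImage(counts, timing, irf=gauss_irf), gauss_irf, timing)
        assert np.nanstd(lmap.ti) < 0.05 * np.nanmean(lmap.ti)

    def test_binning_pools_blocks(self, timing, gauss_irf):
        img, labels = self._two_region_image(timing, gauss_irf, photons=300)
        lmap = fit_image(img, gauss_irf, timing, binning=3)
        # pixels in one 3x3 block share one fit
        block = lmap.ti[3:6, 3:6]
        assert np.unique(block[np.isfinite(block)]).size == 1

    def test_empty_image(self, timing):
        img = FLIMImage(np.zeros((0, 0, timing.n_bins), dtype=np.uint32), timing)
        lmap = fit_image(img, IRFModel(), timing)
        assert lmap.ti.shape == (0, 0)
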