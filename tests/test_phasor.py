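"""Phasor transform laws, calibration, clustering, and segmentation."""

import numpy as np
import pytest

from flimplex import DecayParams, FLIMImage, IRFModel, TimingConfig, expected_decay
from flimplex.fitting import intensity_weighted_lifetime
from flimplex.phasor import (
    ClusterSpec,
    angular_frequency,
    calibrate,
    find_clusters,
    ideal_phasor,
    phasor_image,
    phasor_transform,
    segment,
    tau_from_phasor,
)
from flimplex.simulate import fast_species


class TestPhasorTransform:
    def test_single_bin_histogram(self, timing):
        h = np.zeros(timing.n_bins)
        h[0] = 100
        pt = phasor_transform(h, timing)
        t0 = timing.bin_centers[0]
        assert pt.g == pytest.approx(np.cos(pt.omega * t0))
        assert pt.s == pytest.approx(np.sin(pt.omega * t0))

    def test_monoexp_closed_form(self, fine_timing, delta_irf):
        """Ideal monoexponential: g = 1/(1+(wt)^2), s = wt/(1+(wt)^2)."""
        tau = 2.0
        curve = expected_decay(DecayParams.monoexp(tau), delta_irf, fine_timing)
        pt = phasor_transform(curve * 1e6, fine_timing)
        g_th, s_th = ideal_phasor(tau, pt.omega)
        assert pt.g == pytest.approx(g_th, abs=1e-3)
        assert pt.s == pytest.approx(s_th, abs=1e-3)

    def test_uniform_histogram_at_origin(self, timing):
        pt = phasor_transform(np.ones(timing.n_bins), timing)
        assert pt.g == pytest.approx(0.0, abs=1e-12)
        assert pt.s == pytest.approx(0.0, abs=1e-12)

    def test_empty_histogram_rejected(self, timing):
        with pytest.raises(ValueError):
            phasor_transform(np.zeros(timing.n_bins), timing)


class TestTauFromPhasor:
    def test_worked_example(self):
        from flimplex.phasor import PhasorPoint

        omega = angular_frequency(TimingConfig(period_ns=12.5))
        pt = PhasorPoint(0.5, 0.5, omega=omega)
        assert tau_from_phasor(pt) == pytest.approx(1.989, abs=2e-3)

    def test_origin_of_semicircle_is_zero_lifetime(self):
        from flimplex.phasor import PhasorPoint

        assert tau_from_phasor(PhasorPoint(1.0, 0.0, omega=0.5)) == 0.0

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 4.0])
    def test_round_trip(self, tau):
        from flimplex.phasor import PhasorPoint

        omega = angular_frequency(TimingConfig())
        g, s = ideal_phasor(tau, omega)
        assert tau_from_phasor(PhasorPoint(g, s, omega=omega)) == pytest.approx(tau, rel=1e-9)


class TestCalibration:
    def _reference(self, irf, timing, tau=1.0):
        return phasor_transform(expected_decay(DecayParams.monoexp(tau), irf, timing) * 1e7, timing)

    def test_self_calibration_lands_on_ideal(self, timing, gauss_irf):
        ref = self._reference(gauss_irf, timing)
        cal = calibrate(ref, ref, 1.0)
        g_th, s_th = ideal_phasor(1.0, ref.omega)
        assert (cal.g, cal.s) == (pytest.approx(g_th), pytest.approx(s_th))

    def test_delta_irf_reference_is_near_identity(self, timing, delta_irf):
        ref = self._reference(delta_irf, timing)
        pt = phasor_transform(
            expected_decay(DecayParams.monoexp(2.0), delta_irf, timing) * 1e6, timing
        )
        cal = calibrate(pt, ref, 1.0)
        assert cal.g == pytest.approx(pt.g, abs=2e-3)
        assert cal.s == pytest.approx(pt.s, abs=2e-3)

    def test_calibrated_monoexp_lands_on_universal_circle(self, timing, gauss_irf, rng):
        ref = self._reference(gauss_irf, timing)
        curve = expected_decay(DecayParams.monoexp(2.0), gauss_irf, timing)
        pt = phasor_transform(rng.poisson(curve * 1e5).astype(float), timing)
        cal = calibrate(pt, ref, 1.0)
        assert abs(cal.g**2 + cal.s**2 - cal.g) < 0.01

    def test_degenerate_reference_rejected(self, timing, gauss_irf):
        from flimplex.phasor import PhasorPoint

        pt = self._reference(gauss_irf, timing)
        with pytest.raises(ValueError):
            calibrate(pt, PhasorPoint(0.0, 0.0, omega=pt.omega), 1.0)

    def test_biexp_phasor_differs_from_monoexp_of_same_ti(self, timing, delta_irf):
        """A biexponential with T_i = x lies inside the circle; it must not
        be conflated with a monoexponential of lifetime x."""
        p = DecayParams((0.6, 0.4), (0.8, 2.4))
        ti = intensity_weighted_lifetime(p)
        pt_bi = phasor_transform(expected_decay(p, delta_irf, timing) * 1e6, timing)
        g_th, s_th = ideal_phasor(ti, pt_bi.omega)
        assert np.hypot(pt_bi.g - g_th, pt_bi.s - s_th) > 0.01


class TestPhasorImage:
    def _uniform_image(self, timing, irf, params, photons, shape=(24, 24), seed=0):
        curve = expected_decay(params, irf, timing)
        rng = np.random.default_rng(seed)
        counts = rng.poisson(curve * photons, size=shape + (timing.n_bins,))
        return FLIMImage(counts.astype(np.uint32), timing, irf=irf)

    def test_single_species_centroid(self, timing, delta_irf):
        params = fast_species(1.89)
        img = self._uniform_image(timing, delta_irf, params, 1000)
        pmap = phasor_image(img, timing, median_filter_radius=1)
        pure = phasor_transform(expected_decay(params, delta_irf, timing) * 1e6, timing)
        g, s, _ = pmap.points()
        assert np.hypot(g.mean() - pure.g, s.mean() - pure.s) < 0.01

    def test_mixture_lies_on_chord_at_intensity_fraction(self, timing, delta_irf):
        """A pixel with a 50/50 intensity mix of two species sits at the
        midpoint of the segment joining the pure phasors."""
        a, b = DecayParams.monoexp(1.2), DecayParams.monoexp(2.6)
        mix = DecayParams.from_intensity_fractions((0.5, 0.5), (1.2, 2.6))
        pa = phasor_transform(expected_decay(a, delta_irf, timing) * 1e6, timing)
        pb = phasor_transform(expected_decay(b, delta_irf, timing) * 1e6, timing)
        rng = np.random.default_rng(4)
        pm = phasor_transform(
            rng.poisson(expected_decay(mix, delta_irf, timing) * 1e6).astype(float), timing
        )
        mid = ((pa.g + pb.g) / 2, (pa.s + pb.s) / 2)
        assert np.hypot(pm.g - mid[0], pm.s - mid[1]) < 5e-3

    def test_masked_and_dim_pixels_excluded(self, timing, delta_irf):
        img = self._uniform_image(timing, delta_irf, fast_species(1.5), 500, shape=(8, 8))
        mask = np.ones((8, 8), bool)
        mask[0] = False
        pmap = phasor_image(img, timing, mask=mask, median_filter_radius=0)
        assert np.all(np.isnan(pmap.g[0]))
        assert np.isfinite(pmap.g[1:]).all()


class TestClustersAndSegmentation:
    def _two_population_map(self, timing, delta_irf, seed=0, photons=1000):
        params = [fast_species(1.45), fast_species(2.05)]
        rng = np.random.default_rng(seed)
        counts = np.zeros((20, 40, timing.n_bins), dtype=np.uint32)
        for i, p in enumerate(params):
            curve = expected_decay(p, delta_irf, timing)
            counts[:, i * 20 : (i + 1) * 20] = rng.poisson(
                curve * photons, size=(20, 20, timing.n_bins)
            )
        img = FLIMImage(counts, timing, irf=delta_irf)
        return phasor_image(img, timing)

    def test_k1_centroid_recovery(self, timing, delta_irf):
        params = fast_species(1.89)
        curve = expected_decay(params, delta_irf, timing)
        rng = np.random.default_rng(1)
        counts = rng.poisson(curve * 1000, size=(24, 24, timing.n_bins)).astype(np.uint32)
        pmap = phasor_image(FLIMImage(counts, timing), timing)
        [spec] = find_clusters(pmap, k=1, seed=0)
        pure = phasor_transform(curve * 1e6, timing)
        assert np.hypot(spec.mean[0] - pure.g, spec.mean[1] - pure.s) < 0.01

    def test_two_population_segmentation_accuracy(self, timing, delta_irf):
        pmap = self._two_population_map(timing, delta_irf)
        clusters = find_clusters(pmap, k=2, seed=0, labels=["short", "long"])
        labels = segment(pmap, clusters)
        truth = np.ones((20, 40), int)
        truth[:, 20:] = 2
        acc = (labels.labels == truth).mean()
        assert acc >= 0.95

    def test_cluster_list_order_does_not_change_partition(self, timing, delta_irf):
        pmap = self._two_population_map(timing, delta_irf)
        clusters = find_clusters(pmap, k=2, seed=0, labels=["short", "long"])
        fwd = segment(pmap, clusters)
        rev = segment(pmap, clusters[::-1])
        # same pixels under each species name, regardless of list order
        name_fwd = np.vectorize({0: "0", **fwd.legend}.get)(fwd.labels)
        name_rev = np.vectorize({0: "0", **rev.legend}.get)(rev.labels)
        assert (name_fwd == name_rev).mean() > 0.999

    def test_too_few_points_rejected(self, timing, delta_irf):
        pmap = self._two_population_map(timing, delta_irf)
        with pytest.raises(ValueError, match="valid points"):
            find_clusters(pmap, k=100)

    def test_degenerate_cloud_rejected(self, timing):
        pmap_g = np.full((20, 20), 0.5)
        from flimplex.phasor import PhasorMap

        pmap = PhasorMap(pmap_g, pmap_g.copy(), np.full((20, 20), 100.0), 1, 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            find_clusters(pmap, k=2)

    def test_empty_cluster_list_leaves_unassigned(self, timing, delta_irf):
        pmap = self._two_population_map(timing, delta_irf)
        labels = segment(pmap, [])
        assert np.all(labels.labels == 0)

    def test_polygon_roi_and_list_order_precedence(self):
        from flimplex.phasor import PhasorMap

        g = np.array([[0.4, 0.6]])
        s = np.array([[0.3, 0.3]])
        pmap = PhasorMap(g, s, np.full((1, 2), 100.0), 1, 0.5)
        big = ClusterSpec("first", "polygon",
                          vertices=np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
        small = ClusterSpec("second", "polygon",
                            vertices=np.array([[0.3, 0.2], [0.5, 0.2], [0.5, 0.4], [0.3, 0.4]]))
        labels = segment(pmap, [small, big])
        assert labels.labels.tolist() == [[1, 2]]  # overlap goes to the first listed
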