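"""Phasor transform mathematics: closed forms, linearity, IRF deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aoflio import (AcquisitionMeta, DecayCube, RoiMask, aggregate_rois,
                    deconvolve_irf, irf_reference_phasor, phasor_of_biexp,
                    phasor_transform)
from aoflio.flim_io import Irf
from aoflio.phasor_core import (IllConditionedIrfError, UndefinedPhasorError,
                                discretize_biexp, phasor_of_biexp_binned,
                                phasor_of_monoexp)

OMEGA = 2 * np.pi * 8.0e7


class TestTransformClosedForms:
    def test_delta_at_time_origin_maps_to_one_zero(self, meta):
        d = np.zeros(256)
        d[0] = 1000
        p = phasor_transform(d, meta)
        # only a half-bin phase away from exactly (1, 0)
        assert abs(1 - p.g) <= 3e-4
        assert 0 < p.s < 0.013

    def test_uniform_decay_over_full_period_maps_to_origin(self, meta):
        p = phasor_transform(np.full(256, 7.0), meta)
        assert abs(p.g) <= 1e-12
        assert abs(p.s) <= 1e-12

    def test_monoexp_at_omega_tau_one_sits_mid_semicircle(self, meta):
        tau = 1.0 / OMEGA  # 1.98944 ns at 80 MHz
        decay = discretize_biexp(1.0, tau, 0.0, tau, meta)
        p = phasor_transform(decay, meta)
        assert p.g == pytest.approx(0.5, abs=3e-3)
        assert p.s == pytest.approx(0.5, abs=3e-3)

    def test_all_zero_decay_raises(self, meta):
        with pytest.raises(UndefinedPhasorError):
            phasor_transform(np.zeros(256), meta)

    @pytest.mark.parametrize("tau_ps", [100, 300, 800, 2000, 5000])
    def test_single_exponentials_lie_on_universal_semicircle(self, meta, tau_ps):
        decay = discretize_biexp(1.0, tau_ps * 1e-12, 0.0, tau_ps * 1e-12, meta)
        p = phasor_transform(decay, meta)
        radius2 = (p.g - 0.5) ** 2 + p.s**2
        assert abs(radius2 - 0.25) <= 1e-3
        assert p.s >= 0


class TestDeconvolution:
    def test_unit_irf_phasor_is_identity(self, meta):
        from aoflio.phasor_core import PhasorPoint
        p = PhasorPoint(g=0.3, s=0.4, frequency=8.0e7)
        out = deconvolve_irf(p, PhasorPoint(g=1.0, s=0.0, frequency=8.0e7))
        assert (out.g, out.s) == (0.3, 0.4)

    def test_self_division_gives_one_zero(self, meta):
        from aoflio.phasor_core import PhasorPoint
        p = PhasorPoint(g=0.3, s=0.4, frequency=8.0e7)
        out = deconvolve_irf(p, p)
        assert out.g == pytest.approx(1.0, abs=1e-12)
        assert out.s == pytest.approx(0.0, abs=1e-12)

    def test_tiny_irf_modulus_raises(self):
        from aoflio.phasor_core import PhasorPoint
        p = PhasorPoint(g=0.5, s=0.5, frequency=8.0e7)
        with pytest.raises(IllConditionedIrfError):
            deconvolve_irf(p, PhasorPoint(g=1e-12, s=0.0, frequency=8.0e7))

    @pytest.mark.parametrize("tau_ps", [200, 500, 1500])
    def test_deconvolution_inverts_periodic_convolution(self, meta, irf, tau_ps):
        """Convolving a decay with the IRF then dividing by the IRF reference
        phasor recovers the unconvolved decay's phasor to 1e-6."""
        tau = tau_ps * 1e-12
        pdf = discretize_biexp(1.0, tau, 0.0, tau, meta)
        direct = phasor_transform(pdf, meta)
        conv = np.fft.irfft(np.fft.rfft(pdf) * np.fft.rfft(irf.normalized()),
                            n=256)
        measured = phasor_transform(conv, meta)
        out = deconvolve_irf(measured, irf_reference_phasor(irf, meta))
        assert out.g == pytest.approx(direct.g, abs=1e-6)
        assert out.s == pytest.approx(direct.s, abs=1e-6)


class TestClosedFormOracles:
    def test_degenerate_biexp_reduces_to_monoexp(self):
        tau = 600e-12
        mono = phasor_of_monoexp(tau, OMEGA)
        for args in [(1.0, tau, 0.0, tau), (0.4, tau, 0.6, tau)]:
            p = phasor_of_biexp(*args, OMEGA)
            assert p.g == pytest.approx(mono.g, abs=1e-15)
            assert p.s == pytest.approx(mono.s, abs=1e-15)

    def test_zero_intensity_kinetics_raise(self):
        with pytest.raises(ValueError):
            phasor_of_biexp(0.0, 1e-10, 0.0, 1e-9, OMEGA)

    @given(a1=st.floats(0.05, 0.95), t1=st.floats(50e-12, 3e-9),
           t2=st.floats(50e-12, 3e-9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mixtures_lie_inside_semicircle(self, a1, t1, t2):
        p = phasor_of_biexp(a1, t1, 1 - a1, t2, OMEGA)
        assert (p.g - 0.5) ** 2 + p.s**2 <= 0.25 + 1e-12

    def test_binned_closed_form_matches_transform_of_discretized_decay(self, meta):
        a1, t1, t2 = 0.7, 150e-12, 1100e-12
        pdf = discretize_biexp(a1, t1, 1 - a1, t2, meta)
        p_num = phasor_transform(pdf, meta)
        p_cf = phasor_of_biexp_binned(a1, t1, 1 - a1, t2, meta)
        assert p_num.g == pytest.approx(p_cf.g, abs=1e-12)
        assert p_num.s == pytest.approx(p_cf.s, abs=1e-12)


class TestLinearity:
    def test_phasor_of_sum_is_photon_weighted_mean(self, meta, rng):
        d1 = rng.integers(0, 100, 256).astype(float)
        d2 = rng.integers(0, 100, 256).astype(float)
        p1, p2 = phasor_transform(d1, meta), phasor_transform(d2, meta)
        p = phasor_transform(d1 + d2, meta)
        w1 = d1.sum() / (d1.sum() + d2.sum())
        assert p.g == pytest.approx(w1 * p1.g + (1 - w1) * p2.g, abs=1e-12)
        assert p.s == pytest.approx(w1 * p1.s + (1 - w1) * p2.s, abs=1e-12)

    def test_roi_phasor_equals_weighted_mean_of_pixel_phasors(self, meta, rng):
        counts = rng.integers(1, 50, size=(3, 3, 256))
        cube = DecayCube(counts=counts, meta=AcquisitionMeta(pixel_dims=(3, 3)))
        labels = np.ones((3, 3), dtype=int)
        mask = RoiMask(labels=labels, kind_by_label={1: "cone"})
        roi = aggregate_rois(cube, mask)[0]
        p_roi = phasor_transform(roi.decay, meta)
        gs, ws = [], []
        for r in range(3):
            for c in range(3):
                p = phasor_transform(counts[r, c], meta)
                gs.append((p.g, p.s))
                ws.append(counts[r, c].sum())
        ws = np.array(ws, dtype=float)
        ws /= ws.sum()
        gmean = float(np.dot(ws, [g for g, _ in gs]))
        smean = float(np.dot(ws, [s for _, s in gs]))
        assert p_roi.g == pytest.approx(gmean, abs=1e-12)
        assert p_roi.s == pytest.approx(smean, abs=1e-12)


class TestAggregation:
    def test_single_pixel_roi_equals_pixel_histogram(self, rng):
        counts = rng.integers(0, 30, size=(5, 5, 16))
        counts[2, 2, 0] += 1  # ensure nonzero
        cube = DecayCube(counts=counts,
                         meta=AcquisitionMeta(n_bins=16, pixel_dims=(5, 5)))
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 2] = 1
        mask = RoiMask(labels=labels, kind_by_label={1: "cone"})
        roi = aggregate_rois(cube, mask)[0]
        np.testing.assert_array_equal(roi.decay, counts[2, 2])

    def test_photon_conservation_over_partition(self, rng):
        counts = rng.integers(1, 30, size=(6, 6, 16))
        cube = DecayCube(counts=counts,
                         meta=AcquisitionMeta(n_bins=16, pixel_dims=(6, 6)))
        labels = np.ones((6, 6), dtype=int)
        labels[:, 3:] = 2
        mask = RoiMask(labels=labels,
                       kind_by_label={1: "cone", 2: "rod_region"})
        rois = aggregate_rois(cube, mask)
        assert sum(r.total_photons for r in rois) == counts.sum()

    def test_matches_naive_per_pixel_accumulation(self, rng):
        counts = rng.integers(0, 30, size=(7, 7, 16))
        cube = DecayCube(counts=counts,
                         meta=AcquisitionMeta(n_bins=16, pixel_dims=(7, 7)))
        labels = np.zeros((7, 7), dtype=int)
        pixels = [(0, 0), (1, 3), (2, 2), (6, 6), (4, 1)]
        for r, c in pixels:
            labels[r, c] = 4
        mask = RoiMask(labels=labels, kind_by_label={4: "cone"})
        expected = np.zeros(16, dtype=int)
        for r, c in pixels:
            expected += counts[r, c]
        roi = aggregate_rois(cube, mask)[0]
        np.testing.assert_array_equal(roi.decay, expected)
        assert roi.roi_label == 4

    def test_zero_photon_roi_excluded_with_warning(self):
        counts = np.zeros((4, 4, 8), dtype=int)
        counts[0, 0, 0] = 5
        cube = DecayCube(counts=counts,
                         meta=AcquisitionMeta(n_bins=8, pixel_dims=(4, 4)))
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = 1
        labels[3, 3] = 2
        mask = RoiMask(labels=labels,
                       kind_by_label={1: "cone", 2: "cone"})
        with pytest.warns(UserWarning, match="zero photons"):
            rois = aggregate_rois(cube, mask)
        assert [r.roi_label for r in rois] == [1]
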