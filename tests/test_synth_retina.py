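"""Synthetic retina generator: mosaic geometry, rendering physics, damage."""

import numpy as np
import pytest

from aoflio import (AcquisitionMeta, apply_damage, build_mosaic, default_irf,
                    deconvolve_irf, irf_reference_phasor, phasor_transform,
                    render_cube)
from aoflio.phasor_core import phasor_of_biexp_binned
from aoflio.synth_retina import (DEFAULT_KINETICS, ML_CONE, S_CONE,
                                 expected_roi_decay)


class TestBuildMosaic:
    def test_s_cone_count_matches_requested_fraction(self):
        scene = build_mosaic(seed=3, s_fraction=0.12)
        n_s = int(scene.s_mask().sum())
        assert abs(n_s - 0.12 * scene.n_cones) <= 1

    def test_no_adjacent_s_cones_on_lattice(self):
        for seed in range(5):
            scene = build_mosaic(seed=seed, s_fraction=0.12)
            s = scene.s_mask()
            adjacent = sum(1 for i, j in scene.neighbor_pairs
                           if s[i] and s[j])
            assert adjacent == 0
            assert scene.s_labeling_warning is None

    def test_same_seed_reproduces_scene_exactly(self):
        a = build_mosaic(seed=42)
        b = build_mosaic(seed=42)
        np.testing.assert_array_equal(a.cell_centers, b.cell_centers)
        np.testing.assert_array_equal(a.cell_class, b.cell_class)
        np.testing.assert_array_equal(a.brightness_factor, b.brightness_factor)

    def test_cone_exclusion_distance(self):
        scene = build_mosaic(seed=7)
        from scipy.spatial.distance import pdist
        assert pdist(scene.cell_centers).min() > 0.5 * scene.cone_spacing_px

    def test_too_small_field_raises(self):
        with pytest.raises(ValueError, match="too small"):
            build_mosaic(field_dims=(20, 20), cone_spacing_px=16.0)

    def test_invalid_s_fraction_rejected(self):
        with pytest.raises(ValueError):
            build_mosaic(s_fraction=0.7)


class TestRenderCube:
    def test_mean_total_counts_per_cell_near_brightness(self, small_scene,
                                                        small_irf, small_meta):
        cube, mask = render_cube(small_scene, small_irf, small_meta, seed=2)
        totals = []
        for i in range(small_scene.n_cones):
            totals.append(cube.counts[mask.labels == i + 1].sum())
        b = DEFAULT_KINETICS[ML_CONE].brightness
        # cell-to-cell lognormal variability (sigma 0.12) averages out
        assert np.mean(totals) == pytest.approx(
            b, abs=3 * b * 0.12 / np.sqrt(len(totals)) + 3 * np.sqrt(b))

    def test_expectation_mode_matches_discretized_decay(self, small_meta):
        """With a delta IRF and noise off, a cone's aggregate decay is exactly
        the bin-integrated biexponential, scaled to its brightness."""
        from aoflio.flim_io import Irf
        from aoflio.phasor_core import discretize_biexp
        scene = build_mosaic(field_dims=(80, 100), cone_spacing_px=12.0,
                             seed=11)
        delta = Irf(curve=np.eye(256)[0], meta=small_meta)
        idx = 0
        dec = expected_roi_decay(scene, idx, delta, small_meta)
        kin = scene.kinetics_by_class[str(scene.cell_class[idx])]
        pdf = discretize_biexp(kin.a1, kin.tau1, kin.a2, kin.tau2, small_meta)
        expected = kin.brightness * scene.brightness_factor[idx] * pdf
        # delta-IRF convolution goes through an FFT; exact up to roundoff
        np.testing.assert_allclose(dec, expected, rtol=1e-9)

    def test_noise_free_phasor_hits_binned_closed_form(self, small_scene,
                                                       small_irf, small_meta):
        irf_ref = irf_reference_phasor(small_irf, small_meta)
        for cls in (S_CONE, ML_CONE):
            idx = int(np.where(small_scene.cell_class == cls)[0][0])
            dec = expected_roi_decay(small_scene, idx, small_irf, small_meta)
            p = deconvolve_irf(phasor_transform(dec, small_meta), irf_ref)
            kin = small_scene.kinetics_by_class[cls]
            cf = phasor_of_biexp_binned(kin.a1, kin.tau1, kin.a2, kin.tau2,
                                        small_meta)
            assert p.g == pytest.approx(cf.g, abs=1e-6)
            assert p.s == pytest.approx(cf.s, abs=1e-6)

    def test_poisson_statistics_variance_equals_mean(self):
        """Across repeated renders the per-bin count variance tracks the mean
        (index of dispersion within [0.9, 1.1] over 1000 seeds)."""
        meta = AcquisitionMeta(n_bins=32, pixel_dims=(60, 60))
        scene = build_mosaic(field_dims=(60, 60), cone_spacing_px=10.0,
                             seed=11)
        irf = default_irf(meta)
        rr, cc = int(scene.cell_centers[0, 0]), int(scene.cell_centers[0, 1])
        samples = []
        for seed in range(1000):
            cube, _ = render_cube(scene, irf, meta, seed=seed)
            samples.append(cube.counts[rr, cc])
        samples = np.array(samples, dtype=float)
        mean = samples.mean(axis=0)
        var = samples.var(axis=0, ddof=1)
        keep = mean > 1.0
        ratio = var[keep].sum() / mean[keep].sum()
        assert 0.9 <= ratio <= 1.1

    def test_render_is_deterministic_given_seed(self, small_scene, small_irf,
                                                small_meta):
        c1, _ = render_cube(small_scene, small_irf, small_meta, seed=9)
        c2, _ = render_cube(small_scene, small_irf, small_meta, seed=9)
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_mask_covers_field_with_cones_and_rods(self, small_render,
                                                   small_scene):
        _, mask = small_render
        assert (mask.labels > 0).all()
        assert len(mask.labels_of_kind("cone")) == small_scene.n_cones
        assert len(mask.labels_of_kind("rod_region")) > 0


class TestDamage:
    def test_damage_flags_exactly_the_s_cones(self, small_scene):
        damaged = apply_damage(small_scene)
        np.testing.assert_array_equal(damaged.damaged, small_scene.s_mask())

    def test_damaged_expected_counts_divided_by_intensity_factor(
            self, small_scene, small_irf, small_meta):
        damaged = apply_damage(small_scene, intensity_factor=2.6,
                               lifetime_scale=1.0)
        idx = int(np.where(small_scene.s_mask())[0][0])
        before = expected_roi_decay(small_scene, idx, small_irf, small_meta)
        after = expected_roi_decay(damaged, idx, small_irf, small_meta)
        assert after.sum() == pytest.approx(before.sum() / 2.6, rel=1e-12)

    def test_identity_damage_changes_only_flags(self, small_scene, small_irf,
                                                small_meta):
        damaged = apply_damage(small_scene, intensity_factor=1.0,
                               lifetime_scale=1.0)
        idx = int(np.where(small_scene.s_mask())[0][0])
        before = expected_roi_decay(small_scene, idx, small_irf, small_meta)
        after = expected_roi_decay(damaged, idx, small_irf, small_meta)
        np.testing.assert_allclose(after, before, rtol=1e-12)
        assert damaged.damaged.any()

    def test_shorter_lifetimes_move_phasor_toward_one_zero(self, small_scene,
                                                           small_meta):
        """Damaged-cone g must increase, following the closed-form phasor of
        the lifetime-scaled kinetics."""
        damaged = apply_damage(small_scene, intensity_factor=2.6,
                               lifetime_scale=0.6)
        kin = small_scene.kinetics_by_class[S_CONE]
        kin_d = damaged.damaged_kinetics(S_CONE)
        p0 = phasor_of_biexp_binned(kin.a1, kin.tau1, kin.a2, kin.tau2,
                                    small_meta)
        p1 = phasor_of_biexp_binned(kin_d.a1, kin_d.tau1, kin_d.a2, kin_d.tau2,
                                    small_meta)
        assert kin_d.tau1 == pytest.approx(kin.tau1 * 0.6)
        assert p1.g > p0.g

    def test_invalid_damage_parameters_rejected(self, small_scene):
        with pytest.raises(ValueError):
            apply_damage(small_scene, intensity_factor=0.5)
        with pytest.raises(ValueError):
            apply_damage(small_scene, lifetime_scale=0.0)


class TestKineticsDefaults:
    def test_cone_mean_lifetimes_similar_but_phasors_separate(self, meta):
        """The central qualitative finding: amplitude-weighted mean lifetime
        barely differs between cone classes (<5%) while their phasors separate
        by at least 5 shot-noise SDs at 1e4 photons/cell."""
        s, ml = DEFAULT_KINETICS[S_CONE], DEFAULT_KINETICS[ML_CONE]
        rel = abs(s.tau_mean - ml.tau_mean) / ml.tau_mean
        assert rel < 0.05
        ps = phasor_of_biexp_binned(s.a1, s.tau1, s.a2, s.tau2, meta)
        pml = phasor_of_biexp_binned(ml.a1, ml.tau1, ml.a2, ml.tau2, meta)
        gap = np.hypot(ps.g - pml.g, ps.s - pml.s)
        # shot-noise phasor SD at N photons is bounded by ~1/sqrt(2N)
        sd = 1.0 / np.sqrt(2 * 1e4)
        assert gap >= 5 * sd
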