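"""Generator determinism, noiseless intensity conservation, and schedules."""

import numpy as np
import pytest

import rimtrack as rt
from rimtrack.synthetic import GenerationError, default_params_at


def _noiseless_params(**kw):
    base = dict(
        image_size=(96, 96), seed=5, read_noise_sd=0.0,
        photon_noise=False, protein_scale_sd=0.0,
    )
    base.update(kw)
    return rt.SceneParams(**base)


class TestSchedules:
    GRID = np.linspace(0.0, 30.0, 301)

    def test_plin2_rim_starts_at_zero_and_peaks_between_onset_and_decline(self):
        s = rt.protein_schedule("plin2_like")
        assert s.rim_intensity(0.0) == 0.0
        values = np.array([s.rim_intensity(t) for t in self.GRID])
        t_peak = self.GRID[np.argmax(values)]
        assert s.onset_hr < t_peak <= s.decline_onset_hr
        # late decline
        assert s.rim_intensity(30.0) < s.rim_intensity(16.0)

    def test_plin3_contrast_declines_monotonically(self):
        s = rt.protein_schedule("plin3_like")
        assert s.cyto_intensity(0.0) > 0
        contrast = np.array(
            [s.rim_intensity(t) - s.cyto_intensity(t) for t in self.GRID]
        )
        assert np.all(np.diff(contrast) <= 0)

    def test_overexpressed_rises_from_first_sampled_time(self):
        s = rt.protein_schedule("overexpressed_like")
        early = [s.rim_intensity(t) for t in (0.75, 1.5, 3.0, 6.0)]
        assert all(b > a for a, b in zip(early, early[1:]))

    def test_all_schedules_finite_nonnegative(self):
        for kind in ("plin3_like", "plin2_like", "overexpressed_like"):
            s = rt.protein_schedule(kind)
            for t in self.GRID:
                for v in (s.rim_intensity(t), s.cyto_intensity(t)):
                    assert np.isfinite(v) and v >= 0


class TestApplyNoise:
    def _img(self, values):
        return rt.Micrograph(pixels=np.asarray(values, dtype=float))

    def test_zero_input_zero_noise_is_zero(self):
        out = rt.apply_noise(self._img(np.zeros((8, 8))), 0.0, 12, seed=1)
        assert np.all(out.pixels == 0)

    def test_poisson_moments_at_constant_100(self):
        clean = self._img(np.full((100, 100), 100.0))
        out = rt.apply_noise(clean, 0.0, 12, seed=2)
        # sample mean of 10^4 Poisson(100) draws: sd of the mean is 0.1
        assert abs(out.pixels.mean() - 100.0) < 3 * 0.1

    def test_clamped_to_bit_depth(self):
        clean = self._img(np.full((8, 8), 2 * 4096.0))
        out = rt.apply_noise(clean, 0.0, 12, seed=3)
        assert np.all(out.pixels == 4095)

    def test_deterministic_given_seed(self):
        clean = self._img(np.full((16, 16), 50.0))
        a = rt.apply_noise(clean, 3.0, 12, seed=9)
        b = rt.apply_noise(clean, 3.0, 12, seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            rt.apply_noise(self._img(np.ones((4, 4))), -1.0, 12, seed=0)


class TestDropletScene:
    def test_determinism_bit_identical(self):
        params = rt.SceneParams(seed=11)
        sched = rt.protein_schedule("plin2_like")
        a = rt.make_droplet_scene(params, sched, time_hr=6.0)
        b = rt.make_droplet_scene(params, sched, time_hr=6.0)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)
        assert np.array_equal(a[2].droplet_mask, b[2].droplet_mask)

    def test_noiseless_rendering_conserves_intensities(self, default_roi):
        params = _noiseless_params()
        sched = rt.protein_schedule("plin2_like")
        dye, protein, truth = rt.make_droplet_scene(
            params, sched, time_hr=12.0, roi=default_roi
        )
        bg = params.background_level
        core = truth.droplet_mask
        cyto_region = default_roi.mask & ~core
        lumen_region = ~default_roi.mask
        assert np.all(dye.pixels[core] == bg + params.droplet_core_dye_intensity)
        assert np.all(dye.pixels[cyto_region] == bg + params.cytoplasm_dye_intensity)
        assert np.all(dye.pixels[lumen_region] == bg + params.lumen_dye_intensity)
        rim_t = sched.rim_intensity(12.0)
        cyto_t = sched.cyto_intensity(12.0)
        assert np.allclose(protein.pixels[truth.rim_mask], bg + cyto_t + rim_t)
        assert np.allclose(protein.pixels[cyto_region], bg + cyto_t)
        # truth records the noiseless compartment means exactly
        assert truth.mean_rim_protein == pytest.approx(bg + cyto_t + rim_t)
        assert truth.mean_cyto_protein == pytest.approx(bg + cyto_t)

    def test_no_droplets_gives_uniform_protein_and_empty_rim(self, default_roi):
        params = _noiseless_params(n_droplets=0)
        sched = rt.protein_schedule("plin3_like")
        _, protein, truth = rt.make_droplet_scene(
            params, sched, time_hr=2.0, roi=default_roi
        )
        assert not truth.rim_mask.any()
        inside = protein.pixels[default_roi.mask]
        assert np.allclose(inside, inside.flat[0])

    def test_cytoplasm_sample_mean_near_schedule(self, default_roi):
        # law of large numbers: ROI cytoplasm has > 10^4 px at default noise
        params = rt.SceneParams(image_size=(128, 128), seed=1, protein_scale_sd=0.0)
        sched = rt.protein_schedule("plin3_like")
        roi = rt.RegionOfInterest(np.pad(np.ones((112, 112), bool), 8))
        _, protein, truth = rt.make_droplet_scene(params, sched, time_hr=3.0, roi=roi)
        cyto_region = roi.mask & ~truth.droplet_mask & ~truth.rim_mask
        expected = sched.cyto_intensity(3.0) + params.background_level
        assert cyto_region.sum() >= 10_000
        assert abs(protein.pixels[cyto_region].mean() - expected) / expected < 0.02

    def test_droplets_inside_roi_and_nonoverlapping(self):
        params = rt.SceneParams(seed=21)
        sched = rt.protein_schedule("plin2_like")
        _, _, truth = rt.make_droplet_scene(params, sched, time_hr=6.0)
        for (r1, c1), rad1 in zip(truth.centers, truth.radii):
            for (r2, c2), rad2 in zip(truth.centers, truth.radii):
                if (r1, c1) == (r2, c2):
                    continue
                assert np.hypot(r1 - r2, c1 - c2) > rad1 + rad2

    def test_infeasible_density_raises(self):
        params = rt.SceneParams(
            image_size=(48, 48), n_droplets=40, radius_range_px=(4, 6), seed=0
        )
        with pytest.raises(GenerationError):
            rt.make_droplet_scene(
                params, rt.protein_schedule("plin2_like"), time_hr=6.0
            )

    def test_late_time_defaults_have_fewer_droplets(self):
        early = default_params_at(4.0, seed=0)
        late = default_params_at(20.0, seed=0)
        assert late.n_droplets < early.n_droplets
        assert late.radius_range_px[1] > early.radius_range_px[1]


class TestWholemount:
    def test_zero_signal_groups_statistically_identical(self):
        images, truth = rt.make_wholemount_series(
            3, [0.0, 2.0], organ_signal=lambda t: 0.0, autofluor_level=10.0,
            seed=4, variation_sd=0.0,
        )
        raw = truth.groupby("genotype_label").expected_raw.mean()
        assert raw["reporter"] == raw["wild_type"]

    def test_zero_autofluor_wildtype_integrated_density_zero(self, default_roi):
        images, truth = rt.make_wholemount_series(
            2, [1.0], organ_signal=lambda t: 5.0, autofluor_level=0.0,
            seed=4, variation_sd=0.0,
        )
        full = rt.RegionOfInterest(np.ones(images[0].pixels.shape, bool))
        for img in images:
            if img.genotype_label == "wild_type":
                assert rt.raw_integrated_density(img, full) == 0.0

    def test_corrected_means_recover_linear_signal_exactly(self):
        images, truth = rt.make_wholemount_series(
            3, [0.0, 1.0, 2.0, 4.0], organ_signal=lambda t: 3.0 * t,
            autofluor_level=7.0, seed=4, variation_sd=0.0,
        )
        full = rt.RegionOfInterest(np.ones(images[0].pixels.shape, bool))
        points = [
            rt.TimecoursePoint(
                subject_id=i.subject_id, genotype_label=i.genotype_label,
                time_hr=i.time_hr,
                raw_integrated_density=rt.raw_integrated_density(i, full),
            )
            for i in images
        ]
        corrected = rt.autofluorescence_correct(points)
        area = truth.organ_area_px.iloc[0]
        for p in corrected:
            if p.genotype_label == "reporter":
                assert p.corrected_value == pytest.approx(3.0 * p.time_hr * area)

    def test_empty_time_points_rejected(self):
        with pytest.raises(ValueError):
            rt.make_wholemount_series(2, [], lambda t: 1.0, 1.0, seed=0)
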