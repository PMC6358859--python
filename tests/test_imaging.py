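"""Image pipeline tests: destriping, gradient removal, segmentation, metrics."""

import math
import warnings

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk

from poreloadkit import imaging as im, porosimetry as poro, synthetic as syn

warnings.filterwarnings("ignore")


def textured_image(seed=7, shape=(512, 512), sd=40.0):
    """Smooth random field standing in for structured, stripe-free content."""
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.normal(0, 1, shape), 6)
    return 120.0 + sd * base / base.std()


def stripe_pattern(seed=7, n=512, rms=20.0, band=(0.03, 0.2)):
    rng = np.random.default_rng(seed + 1)
    x = np.arange(n)
    f = rng.uniform(*band, 16)
    ph = rng.uniform(0, 2 * np.pi, 16)
    amp = rng.uniform(0.5, 1.0, 16)
    s = np.sum([a * np.sin(2 * np.pi * fi * x + p) for fi, a, p in zip(f, amp, ph)], axis=0)
    return s * rms / s.std()


class TestDestripe:
    def test_removes_most_stripe_energy(self):
        base = textured_image()
        striped = base + stripe_pattern()[None, :]
        out = im.destripe(im.CrossSectionImage(striped, 1.0))
        colvar = lambda a: np.var(a.mean(axis=0))
        assert 1 - colvar(out.pixels - base) / colvar(striped - base) >= 0.80

    def test_stripe_free_image_nearly_unchanged(self):
        base = textured_image()
        out = im.destripe(im.CrossSectionImage(base, 1.0))
        rms = np.sqrt(np.mean((out.pixels - base) ** 2))
        assert rms / (base.max() - base.min()) <= 0.02

    def test_mean_intensity_preserved(self):
        base = textured_image()
        striped = base + stripe_pattern()[None, :]
        out = im.destripe(im.CrossSectionImage(striped, 1.0))
        assert abs(out.pixels.mean() - striped.mean()) / striped.mean() < 0.01

    def test_weak_damping_stays_close_to_input(self):
        """Distortion of stripe-free content is bounded for any damping level."""
        base = textured_image()
        span = base.max() - base.min()
        for damp in (4.0, 1.0, 0.1, 0.01):
            out = im.destripe(im.CrossSectionImage(base, 1.0), damping_coefficient=damp)
            assert np.sqrt(np.mean((out.pixels - base) ** 2)) / span <= 0.02

    def test_rejects_bad_parameters(self):
        img = im.CrossSectionImage(textured_image(), 1.0)
        with pytest.raises(ValueError):
            im.destripe(img, damping_coefficient=0.0)
        with pytest.raises(ValueError):
            im.destripe(img, decomposition_levels=0)
        with pytest.raises(ValueError):
            im.destripe(im.CrossSectionImage(np.zeros((8, 8)), 1.0), "db15")


class TestBandpass:
    def test_constant_image_unchanged(self):
        img = im.CrossSectionImage(np.full((64, 64), 7.0), 1.0)
        out = im.bandpass(img, low_cut_px=16, high_cut_px=0.0)
        assert np.allclose(out.pixels, 7.0)

    def test_linear_gradient_suppressed(self):
        g = np.linspace(0.0, 100.0, 512)[None, :].repeat(512, axis=0)
        out = im.bandpass(im.CrossSectionImage(g, 1.0), low_cut_px=80, high_cut_px=0.0)
        assert out.pixels.max() - out.pixels.min() <= 10.0

    def test_disc_contrast_retained(self):
        """Two-disc image with a gradient: pore-scale contrast kept within 10%."""
        base = np.full((512, 512), 180.0)
        for c in ((160, 160), (350, 350)):
            base[disk(c, 12)] = 60.0
        grad = np.linspace(0.0, 60.0, 512)[None, :].repeat(512, axis=0)
        sel = np.zeros_like(base, dtype=bool)
        for c in ((160, 160), (350, 350)):
            sel[disk(c, 8)] = True  # inner part, away from edge blur

        def contrast(a):
            return a[~sel & (a > a.mean())].mean() - a[sel].mean()

        ref = im.bandpass(im.CrossSectionImage(base, 1.0), low_cut_px=100)
        out = im.bandpass(im.CrossSectionImage(base + grad, 1.0), low_cut_px=100)
        assert contrast(out.pixels) == pytest.approx(contrast(ref.pixels), rel=0.10)

    def test_rejects_bad_cutoffs(self):
        img = im.CrossSectionImage(np.zeros((32, 32)), 1.0)
        with pytest.raises(ValueError):
            im.bandpass(img, low_cut_px=0.0)
        with pytest.raises(ValueError):
            im.bandpass(img, low_cut_px=4.0, high_cut_px=8.0)


class TestSegment:
    def test_noiseless_render_segments_exactly(self, clean_render):
        img, truth = clean_render
        mask = im.segment(img, despeckle=False)
        assert np.array_equal(mask.data, truth.data)

    def test_iou_at_ten_percent_noise(self, dense_network, noisy_render):
        """Full cleanup + segmentation at noise = 10% of contrast: IoU >= 0.90."""
        img, truth = noisy_render
        mask = im.segment(im.bandpass(im.destripe(img)))
        iou = (mask.data & truth.data).sum() / (mask.data | truth.data).sum()
        assert iou >= 0.90

    def test_inverted_contrast_with_inverted_rule(self, clean_render):
        img, truth = clean_render
        flipped = im.CrossSectionImage(255.0 - img.pixels, img.pixel_size)
        mask = im.segment(flipped, threshold_rule="bright", despeckle=False)
        assert np.array_equal(mask.data, truth.data)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            im.segment(im.CrossSectionImage(np.full((64, 64), 3.0), 1.0))

    def test_invariant_to_constant_offset(self, noisy_render):
        img, _ = noisy_render
        a = im.segment(img)
        b = im.segment(im.CrossSectionImage(img.pixels + 37.0, img.pixel_size))
        assert np.array_equal(a.data, b.data)


class TestExcludeOutliers:
    def _mask(self, porosity, n=40):
        data = np.zeros((n, n), dtype=bool)
        data.flat[: int(porosity * n * n)] = True
        return im.PoreMask(data, 10.0)

    def test_identical_masks_all_kept(self):
        groups = [[self._mask(0.5)] * 3, [self._mask(0.5)] * 2]
        out = im.exclude_outliers(groups)
        assert [len(g) for g in out] == [3, 2]

    def test_single_strong_outlier_removed(self):
        groups = [
            [self._mask(0.1), self._mask(0.1)],
            [self._mask(0.1), self._mask(0.5)],
            [self._mask(0.1)],
        ]
        out = im.exclude_outliers(groups)
        assert [len(g) for g in out] == [2, 1, 1]
        assert all(abs(m.porosity_2d - 0.1) < 0.01 for g in out for m in g)

    def test_last_mask_of_section_never_removed(self):
        groups = [[self._mask(0.1)] * 4, [self._mask(0.9)]]
        out = im.exclude_outliers(groups)
        assert len(out[1]) == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            im.exclude_outliers([])


class TestPoreMetrics:
    def test_all_pore_mask(self):
        m = im.PoreMask(np.ones((32, 32), dtype=bool), 10.0)
        assert im.pore_metrics(m, 1.18).porosity_2d == 1.0

    def test_checkerboard_porosity_half(self):
        data = np.indices((64, 64)).sum(axis=0) % 2 == 0
        m = im.PoreMask(data, 10.0)
        assert im.pore_metrics(m, 1.18).porosity_2d == 0.5

    def test_centered_disc_analytic(self):
        data = np.zeros((201, 201), dtype=bool)
        data[disk((100, 100), 50)] = True
        pm = im.pore_metrics(im.PoreMask(data, 10.0), 1.18)
        assert pm.pore_areas[0] == pytest.approx(math.pi * 500**2, rel=0.02)
        v = (4 / 3) * math.pi * (pm.pore_diameters[0] / 2) ** 3
        assert v == pytest.approx((4 / 3) * math.pi * 500**3, rel=0.06)

    def test_empty_mask_signalled_not_nan(self):
        pm = im.pore_metrics(im.PoreMask(np.zeros((16, 16), dtype=bool), 10.0), 1.18)
        assert pm.porosity_2d == 0.0 and pm.D_AV is None and pm.V_SP == 0.0

    def test_vsp_inverse_in_tablet_density(self, clean_render):
        _, truth = clean_render
        a = im.pore_metrics(truth, 1.18)
        b = im.pore_metrics(truth, 2.36)
        assert a.V_SP == pytest.approx(2.0 * b.V_SP, rel=1e-12)

    def test_border_pores_counted_in_porosity_not_sizes(self):
        data = np.zeros((64, 64), dtype=bool)
        data[0:5, 0:5] = True           # touches border
        data[disk((32, 32), 6)] = True  # interior
        pm = im.pore_metrics(im.PoreMask(data, 10.0), 1.18)
        assert len(pm.pore_areas) == 1
        assert pm.porosity_2d == pytest.approx(data.mean())


class TestImagePsd:
    def test_single_population_single_bin(self):
        data = np.zeros((64, 64), dtype=bool)
        data[disk((32, 32), 6)] = True
        pm = im.pore_metrics(im.PoreMask(data, 10.0), 1.18)
        psd = im.image_psd(pm, np.array([5.0, 50.0, 500.0, 5000.0]))
        assert (psd.specific_volume > 0).sum() == 1

    def test_sum_equals_vsp(self, clean_render):
        _, truth = clean_render
        pm = im.pore_metrics(truth, 1.18)
        psd = im.image_psd(pm, poro.default_bin_edges(1.0, 10000.0, 20))
        assert psd.total_volume == pytest.approx(pm.V_SP, rel=1e-12)

    def test_bimodal_populations(self):
        data = np.zeros((256, 256), dtype=bool)
        for c in ((40, 40), (40, 120), (40, 200)):
            data[disk(c, 4)] = True
        for c in ((180, 60), (180, 180)):
            data[disk(c, 20)] = True
        pm = im.pore_metrics(im.PoreMask(data, 10.0), 1.18)
        psd = im.image_psd(pm, np.array([10.0, 200.0, 1000.0]))
        assert psd.specific_volume[0] > 0 and psd.specific_volume[1] > 0
        # large-population bin dominates volume
        assert psd.specific_volume[1] > 10 * psd.specific_volume[0]
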