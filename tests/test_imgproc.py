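"""Preprocessing, thresholding and particle measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanosyn import (
    BinaryMask,
    ChannelImage,
    DegenerateHistogramError,
    ParameterError,
    PipelineConfig,
    RenderSpec,
    SceneParams,
    binarize,
    detect_particles,
    gaussian_smooth,
    generate_scene,
    li_threshold_hist,
    measure_objects,
    moments_threshold_hist,
    render_channel,
    segment_channel,
    subtract_background,
    threshold_li,
)
from nanosyn.pipeline import match_detections

from oracles import li_oracle, moments_oracle, random_bimodal_histogram


class TestSubtractBackground:
    def test_flat_image_goes_to_zero(self, flat_image):
        out = subtract_background(flat_image(value=9.0), radius_px=10)
        assert np.allclose(out.pixels, 0.0)

    def test_single_pixel_spike_preserved(self):
        """The ball cannot enter a 1-px spike; it survives within 5%."""
        img = np.zeros((64, 64))
        img[30, 30] = 200.0
        out = subtract_background(ChannelImage(img, 100.0), radius_px=10)
        assert out.pixels[30, 30] == pytest.approx(200.0, rel=0.05)

    def test_shallow_ramp_removed(self):
        """A ramp with slope ≪ 1/radius is pure background."""
        ramp = np.tile(np.linspace(0, 5, 64), (64, 1))
        out = subtract_background(ChannelImage(ramp, 100.0), radius_px=10)
        assert out.pixels.max() < 0.05 * 5.0

    def test_output_never_exceeds_input(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (48, 48))
        out = subtract_background(ChannelImage(img, 100.0), radius_px=5)
        assert np.all(out.pixels <= img + 1e-9)
        assert np.all(out.pixels >= 0)

    def test_matches_explicit_ball_rolling_simulation(self):
        """The background equals the upper envelope traced by sliding a
        ball under the surface, computed here by brute-force loops."""
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 30, (24, 24))
        img[12, 12] += 100
        radius = 4.0
        n = int(radius)
        offs = [(dy, dx) for dy in range(-n, n + 1)
                for dx in range(-n, n + 1)
                if dy * dy + dx * dx <= radius * radius]
        h = {(dy, dx): np.sqrt(radius**2 - dy*dy - dx*dx) for dy, dx in offs}
        H, W = img.shape

        def pix(r, c):  # nearest-edge padding, as the implementation uses
            return img[min(max(r, 0), H - 1), min(max(c, 0), W - 1)]

        # ball centre height when the ball touches the surface from below
        centre_z = np.empty_like(img)
        for r in range(H):
            for c in range(W):
                centre_z[r, c] = min(
                    pix(r + dy, c + dx) - h[(dy, dx)] for dy, dx in offs)
        # envelope = highest ball surface passing over each pixel
        env = np.empty_like(img)
        for r in range(H):
            for c in range(W):
                env[r, c] = max(
                    (centre_z[min(max(r + dy, 0), H - 1),
                              min(max(c + dx, 0), W - 1)] + h[(dy, dx)])
                    for dy, dx in offs)
        out = subtract_background(ChannelImage(img, 100.0), radius_px=radius)
        expected = np.clip(img - env, 0, None)
        assert np.allclose(out.pixels[n:-n, n:-n], expected[n:-n, n:-n],
                           atol=1e-9)

    def test_invalid_radius(self, flat_image):
        with pytest.raises(ParameterError):
            subtract_background(flat_image(), radius_px=0)


class TestGaussianSmooth:
    def test_constant_image_unchanged(self, flat_image):
        out = gaussian_smooth(flat_image(value=4.2), sigma_px=1.5)
        assert np.allclose(out.pixels, 4.2)

    def test_impulse_response_peak(self):
        """Unit impulse → kernel; centre = 1/(2π·1.5²) ≈ 0.0707."""
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_smooth(ChannelImage(img, 100.0), sigma_px=1.5)
        assert out.pixels[16, 16] == pytest.approx(1 / (2 * np.pi * 1.5**2),
                                                   rel=1e-3)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 10, (50, 70))
        out = gaussian_smooth(ChannelImage(img, 100.0), sigma_px=1.5)
        assert out.pixels.sum() == pytest.approx(img.sum(), rel=1e-6)


class TestAutoThresholds:
    @pytest.mark.parametrize("rule,oracle", [
        (moments_threshold_hist, moments_oracle),
        (li_threshold_hist, li_oracle),
    ], ids=["moments", "li"])
    def test_matches_exhaustive_oracle(self, rule, oracle):
        """Both rules agree with brute-force scans within ±1 bin on
        random two-population histograms."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            h = random_bimodal_histogram(rng)
            assert abs(rule(h) - oracle(h)) <= 1

    @pytest.mark.parametrize("rule", [moments_threshold_hist,
                                      li_threshold_hist],
                             ids=["moments", "li"])
    def test_two_level_histogram_split(self, rule):
        h = np.zeros(256)
        h[10] = 500
        h[200] = 500
        assert 10 <= rule(h) < 200

    def test_li_fixed_point_property(self):
        """Re-applying the Li update at the converged cut moves < 0.5 bin."""
        rng = np.random.default_rng(3)
        h = random_bimodal_histogram(rng)
        t = li_threshold_hist(h)
        p = h / h.sum()
        u = np.arange(1, h.size + 1, dtype=float)
        below = u <= t + 1
        mb = (p[below] * u[below]).sum() / p[below].sum()
        mf = (p[~below] * u[~below]).sum() / p[~below].sum()
        t_next = (mb - mf) / (np.log(mb) - np.log(mf))
        assert abs(t_next - (t + 1)) < 1.0

    def test_li_consistent_with_skimage_on_image(self):
        """Independent cross-check against the library implementation."""
        from skimage.filters import threshold_li as sk_li

        rng = np.random.default_rng(4)
        img = np.concatenate([
            rng.normal(40, 6, 3000), rng.normal(180, 12, 1200)
        ]).clip(0, 255).reshape(60, 70)
        ours = threshold_li(ChannelImage(img, 100.0))
        theirs = sk_li(img)
        assert abs(ours - theirs) < 10  # same bin neighbourhood

    def test_rescaled_image_same_foreground(self):
        """Affine intensity rescale leaves the foreground set unchanged."""
        rng = np.random.default_rng(5)
        img = np.concatenate([
            rng.normal(30, 5, 3000), rng.normal(150, 15, 1000)
        ]).clip(0, None).reshape(40, 100)
        a = binarize(ChannelImage(img, 100.0), "moments")
        b = binarize(ChannelImage(img * 7.5 + 3.0, 100.0), "moments")
        assert np.array_equal(a.pixels, b.pixels)

    def test_binary_input_idempotent(self):
        """Thresholding a 0/255 image returns the same foreground."""
        rng = np.random.default_rng(6)
        img = (rng.uniform(size=(40, 40)) < 0.3).astype(float) * 255
        mask = binarize(ChannelImage(img, 100.0), "moments")
        assert np.array_equal(mask.pixels, img > 0)

    def test_constant_image_degenerate(self, flat_image):
        with pytest.raises(DegenerateHistogramError):
            binarize(flat_image(), "moments")


class TestDetectAndMeasure:
    def _mask(self, arr):
        return BinaryMask(arr.astype(bool), 102.4)

    def test_empty_mask(self):
        labels = detect_particles(self._mask(np.zeros((10, 10))), min_px=1)
        assert labels.max() == 0

    def test_two_squares_counted(self):
        m = np.zeros((12, 12))
        m[1:4, 1:4] = 1
        m[7:10, 7:10] = 1
        labels = detect_particles(self._mask(m), min_px=1)
        assert labels.max() == 2
        assert (labels == 1).sum() == 9 and (labels == 2).sum() == 9

    def test_min_size_filter_drops_seven_pixel_object(self):
        """The protocol's 8-Infinity size filter excludes a 7-px blob."""
        m = np.zeros((10, 10))
        m[2:3, 2:9] = 1  # 7 pixels in a row
        assert detect_particles(self._mask(m), min_px=8).max() == 0
        assert detect_particles(self._mask(m), min_px=7).max() == 1

    def test_min_px_monotonicity(self):
        rng = np.random.default_rng(7)
        m = self._mask(rng.uniform(size=(60, 60)) < 0.35)
        counts = [detect_particles(m, min_px=k).max() for k in range(1, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_diagonal_pixels_are_one_object(self):
        m = np.zeros((5, 5))
        m[1, 1] = m[2, 2] = 1  # touch only diagonally: 8-connectivity
        assert detect_particles(self._mask(m), min_px=1).max() == 1

    def test_measurements_on_raw_units(self):
        m = np.zeros((10, 10))
        m[2:5, 2:5] = 1
        raw = ChannelImage(np.full((10, 10), 100.0), 102.4)
        labels = detect_particles(self._mask(m), min_px=1)
        (rec,) = measure_objects(labels, raw)
        assert rec.mean_intensity == 100.0
        assert rec.integrated_intensity == 900.0
        assert rec.pixel_count == 9

    def test_area_from_pixel_size(self):
        m = np.zeros((10, 10))
        m[0, 0:10] = 1  # 10 px
        raw = ChannelImage(np.ones((10, 10)), 102.4)
        labels = detect_particles(self._mask(m), min_px=1)
        (rec,) = measure_objects(labels, raw)
        assert rec.area_um2 == pytest.approx(10 * 0.1024**2, rel=1e-9)
        assert rec.on_border

    def test_integrated_equals_mean_times_count(self):
        rng = np.random.default_rng(8)
        m = self._mask(rng.uniform(size=(40, 40)) < 0.3)
        raw = ChannelImage(rng.uniform(0, 500, (40, 40)), 102.4)
        labels = detect_particles(m, min_px=1)
        for rec in measure_objects(labels, raw):
            assert rec.integrated_intensity == pytest.approx(
                rec.mean_intensity * rec.pixel_count, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            measure_objects(np.zeros((5, 5), int),
                            ChannelImage(np.ones((6, 6)), 100.0))


class TestSegmentChannel:
    def test_recovers_well_separated_psds(self):
        """Noiseless high-res scene with ~50 PSDs: every punctum found."""
        params = SceneParams(field_size_um=(30.0, 30.0),
                             psd_density_per_um2=0.055,
                             min_psd_sep_um=2.0,
                             decoy_astro_density_per_um2=0.0,
                             nc_amplitude_sigma_log=0.0,  # ideal conditions
                             background_rate=5.0)
        scene = generate_scene(params, seed=11)
        spec = RenderSpec.highres(poisson=False, read_noise_sd=0.0)
        img = render_channel(scene, "psd95", spec, seed=0)
        res = segment_channel(img, PipelineConfig(), role="punctate")
        det = np.array([r.centroid_um for r in res.records])
        truth_xy = np.array([p.centre_um for p in scene.psds])
        _, precision, recall = match_detections(truth_xy, det, tol_um=0.5)
        assert len(scene.psds) >= 40
        assert precision == 1.0 and recall == 1.0

    def test_detection_recovery_with_noise(self):
        """Peak SNR ≥ 10, separations ≥ 3 PSF FWHM: P and R ≥ 0.95."""
        params = SceneParams(field_size_um=(30.0, 30.0),
                             psd_density_per_um2=0.055,
                             min_psd_sep_um=1.5,
                             decoy_astro_density_per_um2=0.0)
        scene = generate_scene(params, seed=12)
        img = render_channel(scene, "psd95", RenderSpec.highres(), seed=1)
        res = segment_channel(img, PipelineConfig(), role="punctate")
        det = np.array([r.centroid_um for r in res.records])
        truth_xy = np.array([p.centre_um for p in scene.psds])
        _, precision, recall = match_detections(truth_xy, det, tol_um=0.5)
        assert precision >= 0.95 and recall >= 0.95

    def test_role_constants(self):
        """punctate → 10 px + moments; gfap → 25 px + li."""
        cfg = PipelineConfig()
        rng = np.random.default_rng(13)
        img = ChannelImage(
            rng.uniform(0, 20, (64, 64)) + 5, 102.4)
        img.pixels[30:34, 30:34] += 200
        res_p = segment_channel(img, cfg, role="punctate")
        res_g = segment_channel(img, cfg, role="gfap")
        assert res_p.mask.provenance[1] == "moments"
        assert res_g.mask.provenance[1] == "li"

    def test_manual_threshold_definition(self):
        """Manual override: foreground = processed pixels > t."""
        rng = np.random.default_rng(14)
        img = ChannelImage(rng.uniform(0, 100, (48, 48)), 102.4)
        res = segment_channel(img, PipelineConfig(), role="vglut2_manual",
                              manual_threshold=40.0)
        assert np.array_equal(res.mask.pixels, res.processed.pixels > 40.0)

    def test_manual_role_requires_threshold(self, flat_image):
        with pytest.raises(ParameterError):
            segment_channel(flat_image(), PipelineConfig(),
                            role="vglut2_manual")

    def test_degenerate_histogram_warns_and_returns_empty(self, flat_image):
        with pytest.warns(UserWarning, match="degenerate"):
            res = segment_channel(flat_image(value=3.0), PipelineConfig(),
                                  role="punctate")
        assert res.records == [] and not res.mask.pixels.any()


@given(st.integers(min_value=0, max_value=400),
       st.integers(min_value=1, max_value=50))
@settings(max_examples=50, deadline=None)
def test_histogram_threshold_shift_invariance(shift, scale):
    """Shifting/stretching occupied bins cannot cross population order:
    the moments cut always separates the two spikes."""
    h = np.zeros(256)
    lo = shift % 100
    hi = min(lo + 50 + scale, 255)
    h[lo] = 300
    h[hi] = 200
    t = moments_threshold_hist(h)
    assert lo <= t < hi
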