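"""Phantom TAC shapes, rendering physics, noise model and frame rebinning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from nmfidif import (
    PhantomSpec,
    TacShapeParams,
    default_phantom_spec,
    fine_framing,
    make_region_tac,
    rebin_framing,
    render_dynamic_image,
)


class TestMakeRegionTac:
    def test_slow_uptake_starts_at_zero(self):
        p = TacShapeParams("slow_uptake", amplitude=1.0)
        assert make_region_tac(p, [0.0]) == pytest.approx([0.0])

    def test_gamma_variate_peaks_at_peak_time(self):
        p = TacShapeParams("gamma_variate_bolus", amplitude=5.0, peak_time_s=20.0)
        t = np.arange(0.0, 121.0)
        v = make_region_tac(p, t)
        assert abs(t[np.argmax(v)] - 20.0) <= 1.0
        assert v.max() == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize("model", ["gamma_variate_bolus", "delayed_bolus_plus_washout", "slow_uptake"])
    def test_zero_amplitude_gives_zero_curve(self, model):
        p = TacShapeParams(model, amplitude=0.0, peak_time_s=20.0)
        assert np.all(make_region_tac(p, np.arange(0.0, 100.0)) == 0)

    def test_unknown_model_error_names_valid_labels(self):
        with pytest.raises(ValueError, match="gamma_variate_bolus"):
            TacShapeParams("spline", amplitude=1.0)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        peak=st.floats(5.0, 120.0),
        sharp=st.floats(1.0, 8.0),
        frac=st.floats(0.0, 0.3),
    )
    def test_bolus_always_nonnegative(self, peak, sharp, frac):
        p = TacShapeParams(
            "gamma_variate_bolus", amplitude=10.0, peak_time_s=peak,
            sharpness=sharp, washout_frac=frac,
        )
        assert np.all(make_region_tac(p, np.arange(0.0, 3600.0, 7.0)) >= 0)


def _single_region_spec(tac_params, **kw):
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[2:5, 2:5, 2:5] = True
    return PhantomSpec(
        grid_shape=(8, 8, 8),
        voxel_size_mm=(1.0, 1.0, 1.0),
        framing=[[0, 10], [10, 10], [20, 10]],
        region_geometry={"LV": mask},
        region_tac_params={"LV": tac_params},
        **kw,
    )


class TestRenderDynamicImage:
    def test_constant_tac_renders_identically(self):
        # slow_uptake with huge tau ~ constant is awkward; use a bolus
        # evaluated at known mid-times and check exact painting instead
        p = TacShapeParams("gamma_variate_bolus", amplitude=4.0, peak_time_s=15.0)
        spec = _single_region_spec(p)
        image, truth = render_dynamic_image(spec)
        expected = truth.region_tacs["LV"].values
        mask = truth.region_masks["LV"]
        assert np.allclose(image.data[mask], expected[None, :])
        assert np.all(image.data[~mask] == 0)

    def test_region_means_match_truth_without_psf(self, clean_phantom):
        image, truth = clean_phantom
        for name, mask in truth.region_masks.items():
            mean_tac = image.data[mask].mean(axis=0)
            np.testing.assert_allclose(mean_tac, truth.region_tacs[name].values, rtol=1e-12)

    def test_total_activity_conserved_without_psf(self, clean_phantom):
        image, truth = clean_phantom
        expected = sum(
            truth.region_masks[name].sum() * truth.region_tacs[name].values
            for name in truth.region_masks
        )
        np.testing.assert_allclose(image.data.sum(axis=(0, 1, 2)), expected, rtol=1e-12)

    def test_psf_spill_in_raises_lv_late_phase(self):
        """Blur mixes late myocardial retention into the LV: verify the
        direction against brute-force Gaussian mixture weights."""
        spec = default_phantom_spec(regions=("LV", "MYO"), psf_fwhm_mm=2.0, noise_scale=0.0)
        image, truth = render_dynamic_image(spec)
        lv_mask = truth.region_masks["LV"]
        late = -1
        lv_true = truth.region_tacs["LV"].values
        myo_true = truth.region_tacs["MYO"].values
        assert myo_true[late] > lv_true[late]  # phantom premise
        observed = image.data[lv_mask, late].mean()
        assert observed > lv_true[late]
        # independent oracle: blur the indicator masks to get mixing weights
        sigma = [2.0 / (2 * np.sqrt(2 * np.log(2))) / s for s in spec.voxel_size_mm]
        w_lv = gaussian_filter(lv_mask.astype(float), sigma=sigma, mode="constant")
        w_myo = gaussian_filter(
            truth.region_masks["MYO"].astype(float), sigma=sigma, mode="constant"
        )
        predicted = (w_lv[lv_mask] * lv_true[late] + w_myo[lv_mask] * myo_true[late]).mean()
        assert observed == pytest.approx(predicted, rel=1e-10)

    def test_noise_variance_scales_inversely_with_duration(self):
        p = TacShapeParams("slow_uptake", amplitude=10.0, uptake_tau_s=1.0)  # ~flat 10
        mask = np.ones((12, 12, 12), dtype=bool)
        framing = [[0, 10], [10, 10], [20, 300], [320, 300]]
        spec = PhantomSpec(
            grid_shape=(12, 12, 12), voxel_size_mm=(1, 1, 1), framing=framing,
            region_geometry={"LIV": mask}, region_tac_params={"LIV": p},
            noise_scale=1.0, seed=3,
        )
        image, truth = render_dynamic_image(spec)
        resid = image.data - truth.pre_psf_image
        sd_short = resid[..., :2].std()
        sd_long = resid[..., 2:].std()
        assert sd_short / sd_long == pytest.approx(np.sqrt(300 / 10), rel=0.1)

    def test_same_seed_bit_identical(self):
        spec = default_phantom_spec(seed=11)
        a, _ = render_dynamic_image(spec)
        b, _ = render_dynamic_image(spec)
        assert np.array_equal(a.data, b.data)

    def test_empty_region_rejected(self):
        p = TacShapeParams("slow_uptake", amplitude=1.0)
        with pytest.raises(ValueError, match="empty"):
            PhantomSpec(
                grid_shape=(4, 4, 4), voxel_size_mm=(1, 1, 1),
                framing=[[0, 10]],
                region_geometry={"LIV": np.zeros((4, 4, 4), bool)},
                region_tac_params={"LIV": p},
            )

    def test_overlapping_regions_rejected(self):
        p = TacShapeParams("slow_uptake", amplitude=1.0)
        m = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="disjoint"):
            PhantomSpec(
                grid_shape=(4, 4, 4), voxel_size_mm=(1, 1, 1),
                framing=[[0, 10]],
                region_geometry={"A": m, "B": m},
                region_tac_params={"A": p, "B": p},
            )


class TestRebinFraming:
    def test_constant_tac_invariant(self):
        fine = fine_framing(60, 3.0)
        coarse = fine_framing(60, 15.0)
        out = rebin_framing(np.full(len(fine), 2.5), fine, coarse)
        assert np.allclose(out, 2.5)

    def test_equal_duration_mean(self):
        fine = np.array([[0, 10], [10, 10], [20, 10]], float)
        coarse = np.array([[0, 30]], float)
        assert rebin_framing([0.0, 3.0, 0.0], fine, coarse) == pytest.approx([1.0])

    def test_activity_time_conserved(self):
        rng = np.random.default_rng(5)
        fine = fine_framing(120, 2.0)
        coarse = fine_framing(120, 12.0)
        v = rng.uniform(0, 10, len(fine))
        out = rebin_framing(v, fine, coarse)
        assert np.sum(out * coarse[:, 1]) == pytest.approx(np.sum(v * fine[:, 1]))

    def test_coarse_peak_never_exceeds_fine_peak(self):
        fine = fine_framing(120, 1.0)
        t = fine[:, 0] + 0.5
        for peak in (8.0, 20.0, 45.0):
            p = TacShapeParams("gamma_variate_bolus", amplitude=20.0, peak_time_s=peak)
            v = make_region_tac(p, t)
            for width in (3.0, 10.0):
                out = rebin_framing(v, fine, fine_framing(120, width))
                assert out.max() <= v.max() + 1e-12

    def test_misaligned_boundaries_rejected(self):
        fine = fine_framing(60, 3.0)
        with pytest.raises(ValueError, match="align"):
            rebin_framing(np.zeros(len(fine)), fine, fine_framing(60, 10.0))
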