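import math

import numpy as np
import pytest

from helistripe import (
    NoStripesError,
    Profile,
    StripeImage,
    analyze_flat_profile,
    analyze_overbeaming,
    analyze_overranging,
    detect_stripes,
    extract_perpendicular_profile,
    overranging,
    pv_to_exposure,
    reduction_ratio,
    simulate_flat_profile,
    split_into_plates,
    stitch_plates,
    z_profile,
)
from helistripe.analysis import MeasurementReport, ProfileWindowError
from helistripe.profiles import measure_fwhm


class TestPvToExposure:
    @pytest.mark.parametrize("pv,expected", [(0.0, 1.0), (1024.0, 10.0), (512.0, 10.0**0.5)])
    def test_log_inverse(self, pv, expected):
        assert pv_to_exposure(np.array([pv]), 1024.0)[0] == pytest.approx(expected)

    def test_rejects_bad_gray_level(self):
        with pytest.raises(ValueError):
            pv_to_exposure(np.array([100.0]), 0.0)

    def test_profile_and_image_converted_in_place_types(self):
        prof = Profile(np.linspace(0, 1024, 16), spacing=1.0)
        out = pv_to_exposure(prof, 1024.0)
        assert isinstance(out, Profile) and out.units == "E"
        img = StripeImage(np.zeros((8, 8)), 0.5, units="PV")
        out = pv_to_exposure(img, 1024.0)
        assert out.units == "E" and out.values[0, 0] == pytest.approx(1.0)


class TestOverrangingArithmetic:
    @pytest.mark.parametrize(
        "fwtm,d,expected",
        [(276.6, 160.0, 58.3), (360.6, 160.0, 100.3), (160.0, 160.0, 0.0)],
    )
    def test_reported_values(self, fwtm, d, expected):
        assert overranging(fwtm, d) == pytest.approx(expected)

    def test_negative_overranging_warns(self):
        with pytest.warns(RuntimeWarning):
            assert overranging(150.0, 160.0) == pytest.approx(-5.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            overranging(float("nan"), 160.0)


class TestReductionRatio:
    @pytest.mark.parametrize(
        "wo,w,expected", [(58.3, 48.2, 17.3), (100.3, 83.1, 17.1), (42.0, 42.0, 0.0)]
    )
    def test_reported_values(self, wo, w, expected):
        assert round(reduction_ratio(wo, w), 1) == pytest.approx(expected)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            reduction_ratio(0.0, 1.0)


class TestZProfile:
    def test_constant_image(self):
        img = StripeImage(np.full((30, 12), 3.5), 0.5)
        prof = z_profile(img)
        assert np.allclose(prof.values, 3.5)
        assert prof.spacing == 0.5

    def test_single_column_roi_is_verbatim(self):
        rng = np.random.default_rng(3)
        img = StripeImage(rng.uniform(0, 1, (30, 12)), 0.5)
        prof = z_profile(img, roi=(2.0, img.z_origin, 2.5, img.z_origin + 15.0))
        assert np.array_equal(prof.values, img.values[:, 4])

    def test_empty_roi_rejected(self):
        img = StripeImage(np.zeros((10, 10)), 0.5)
        with pytest.raises(ValueError, match="ROI"):
            z_profile(img, roi=(100.0, 0.0, 120.0, 1.0))


def _band_image(width=8.0, spacing=0.25, value=100.0, n_u=160, n_z=240):
    """Horizontal (tilt 0) stripe band with linear 2-mm flanks."""
    z = (np.arange(n_z) + 0.5) * spacing
    center = n_z * spacing / 2
    prof = np.clip(((width + 4.0) / 2 - np.abs(z - center)) / 2.0, 0, 1) * value
    return StripeImage(np.tile(prof[:, None], (1, n_u)), spacing)


class TestPerpendicularProfile:
    def test_tilt_zero_profile_equals_column_cut(self):
        img = _band_image()
        reg = detect_stripes(img)[0]
        assert reg.tilt_deg == pytest.approx(0.0, abs=1e-6)
        prof = extract_perpendicular_profile(img, reg, length=30.0)
        # pure z cut through a u-invariant image: bilinear interpolation of
        # the band's pixel-center samples along z
        expected = np.interp(reg.centroid_z + prof.positions,
                             img.z_centers, img.values[:, 0])
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_too_short_window_rejected(self):
        img = _band_image()
        reg = detect_stripes(img)[0]
        with pytest.raises(ProfileWindowError):
            extract_perpendicular_profile(img, reg, length=6.0)

    def test_window_exiting_image_rejected(self):
        img = _band_image(n_z=80)
        reg = detect_stripes(img)[0]
        with pytest.raises(ProfileWindowError):
            extract_perpendicular_profile(img, reg, length=500.0)


class TestDetectStripes:
    def test_blank_image_raises(self):
        img = StripeImage(np.zeros((20, 20)), 0.5)
        with pytest.raises(NoStripesError):
            detect_stripes(img)

    def test_pv_units_rejected(self):
        img = StripeImage(np.zeros((20, 20), dtype=np.uint16), 0.5, units="PV")
        with pytest.raises(ValueError, match="exposure"):
            detect_stripes(img)

    def test_stripe_count_matches_rotations(self, small_sim):
        acq = small_sim["acquisition"]
        truth = small_sim["truth"]
        regions = detect_stripes(small_sim["image"])
        expected = truth.exposure_length / acq.feed
        assert abs(len(regions) - expected) <= 1.5

    def test_min_separation_keeps_strongest(self, small_sim):
        regions = detect_stripes(small_sim["image"])
        filtered = detect_stripes(small_sim["image"],
                                  min_separation=3.0 * small_sim["acquisition"].feed)
        assert len(filtered) < len(regions)


class TestPipelines:
    def test_overbeaming_round_trip(self, small_sim):
        res = analyze_overbeaming(small_sim["image"], small_sim["geometry"], 32.0)
        assert res.bw_mean == pytest.approx(39.0, rel=0.02)
        assert res.bw_sd < 0.5
        assert res.de_mean == pytest.approx(32.0 / 39.0, rel=0.02)

    def test_single_stripe_has_zero_sd(self, small_sim):
        res = analyze_overbeaming(small_sim["image"], small_sim["geometry"], 32.0,
                                  n_stripes=1)
        assert res.bw_sd == 0.0 and res.de_sd == 0.0

    def test_overranging_round_trip(self, small_sim):
        res = analyze_overranging(small_sim["image"], small_sim["acquisition"])
        tol = max(1.0, 2 * small_sim["image"].pixel_spacing)
        assert res.overranging == pytest.approx(
            small_sim["truth"].overranging_true, abs=tol)

    def test_flat_image_fails_cleanly(self, small_sim):
        img = StripeImage(np.full((40, 40), 5.0), 0.5)
        from helistripe.profiles import PeakNotResolvedError
        with pytest.raises(PeakNotResolvedError):
            analyze_overranging(img, small_sim["acquisition"])

    def test_results_invariant_to_stripe_phase(self, small_sim):
        """Circularly rotating the unwrapped image must not change results."""
        img = small_sim["image"]
        rolled = StripeImage(np.roll(img.values, img.n_u // 3, axis=1),
                             img.pixel_spacing, units="E", z_origin=img.z_origin,
                             meta=img.meta)
        a = analyze_overbeaming(img, small_sim["geometry"], 32.0)
        b = analyze_overbeaming(rolled, small_sim["geometry"], 32.0)
        assert b.bw_mean == pytest.approx(a.bw_mean, rel=0.005)
        oa = analyze_overranging(img, small_sim["acquisition"])
        ob = analyze_overranging(rolled, small_sim["acquisition"])
        assert ob.overranging == pytest.approx(oa.overranging, abs=1e-9)

    def test_results_invariant_to_plate_split(self, small_sim):
        img = small_sim["image"]
        restored = stitch_plates(split_into_plates(img, 5))
        a = analyze_overbeaming(img, small_sim["geometry"], 32.0)
        b = analyze_overbeaming(restored, small_sim["geometry"], 32.0)
        assert b.bw_mean == pytest.approx(a.bw_mean, rel=1e-6)

    def test_pv_encoding_does_not_bias_analysis(self, small_sim):
        from helistripe import encode_pv

        img = small_sim["image"]
        decoded = pv_to_exposure(encode_pv(img, 1024.0), 1024.0)
        a = analyze_overranging(img, small_sim["acquisition"])
        b = analyze_overranging(decoded, small_sim["acquisition"])
        assert b.overranging == pytest.approx(a.overranging, abs=0.5)


class TestFlatProfile:
    def test_trapezoid_beam_width(self):
        x = np.arange(-10, 10, 0.05)
        vals = np.clip((4.0 - np.abs(x)) / 2.0, 0, 1)
        prof = Profile(vals, spacing=0.05, start=float(x[0]))
        res = analyze_flat_profile(prof)
        assert res.actual_bw == pytest.approx(6.0, abs=0.05)
        assert res.exposure_length is None and res.overranging is None

    def test_isocenter_simulation_recovers_beam_width(self):
        from helistripe import BeamModel

        beam = BeamModel(88.0, 3.0)
        prof, truth = simulate_flat_profile(beam, helical=False, spacing=0.2)
        res = analyze_flat_profile(prof)
        assert res.actual_bw == pytest.approx(88.0, rel=0.02)

    def test_helical_flat_overranging(self):
        from helistripe import AcquisitionParams, BeamModel

        beam = BeamModel(39.0, 3.0)
        acq = AcquisitionParams(32.0, 1.48, scan_range_d=60.0)
        prof, truth = simulate_flat_profile(beam, acq, helical=True, spacing=0.2)
        res = analyze_flat_profile(prof, scan_range_d=60.0)
        assert res.overranging == pytest.approx(truth.overranging_true, abs=0.4)


class TestMeasurementReport:
    def test_rounding_rules(self):
        rep = MeasurementReport(
            collimation=32.0, pitch=1.48, active_collimator=False,
            bw_mean=39.0857, bw_sd=0.1234, de_mean=0.82051, de_sd=0.0049,
            exposure_length=276.64, overranging=58.32, reduction_ratio=17.32,
            dlp_console=247.3,
        )
        rounded = rep.rounded()
        assert rounded["bw_mean"] == 39.1
        assert rounded["de_mean"] == 0.82
        assert rounded["overranging"] == 58.3
        assert rounded["reduction_ratio"] == 17.3
        assert rep.raw()["bw_mean"] == 39.0857  # full precision retained
        assert rounded["dlp_console"] == 247.3  # pass-through, never computed
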