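import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssdekit import dosimetry
from ssdekit.dosimetry import (
    ConversionModel,
    center_slice_index,
    conversion_factor,
    ctdi_vol_z,
    dw_nslice,
    generate_sai,
    mean_ssde,
    normalized_ctdi,
    nslice_indices,
    per_slice_profiles,
    ssde_center,
    ssde_sai,
    ssde_sai_slicewise,
    summarize_scan,
    water_equivalent_diameter,
)
from ssdekit.segmentation import ROIStats, SegConfig
from ssdekit.volume_io import ScanDoseRecord

from conftest import make_disk_image, make_volume

A, B = 4.378094, 0.04331124  # published conversion-model constants


class TestWaterEquivalentDiameter:
    def test_water_disk_30cm(self):
        stats = ROIStats(area_cm2=math.pi * 15.0 ** 2, mean_hu=0.0,
                         pixel_count=1)
        assert water_equivalent_diameter(stats) == pytest.approx(30.0)

    def test_air_gives_zero(self):
        stats = ROIStats(area_cm2=500.0, mean_hu=-1000.0, pixel_count=1)
        assert water_equivalent_diameter(stats) == 0.0

    @given(area=st.floats(min_value=1.0, max_value=3000.0))
    def test_water_reduces_to_effective_diameter(self, area):
        stats = ROIStats(area_cm2=area, mean_hu=0.0, pixel_count=1)
        assert water_equivalent_diameter(stats) == pytest.approx(
            2.0 * math.sqrt(area / math.pi))

    def test_below_air_rejected(self):
        stats = ROIStats(area_cm2=100.0, mean_hu=-1100.0, pixel_count=1)
        with pytest.raises(ValueError, match="radicand"):
            water_equivalent_diameter(stats)


class TestConversionFactor:
    def test_anchor_at_zero(self):
        with pytest.warns(UserWarning, match="fit domain"):
            assert conversion_factor(0.0) == A

    def test_unity_crossing(self):
        dw = math.log(A) / B  # ~34.10 cm
        assert conversion_factor(dw) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing(self):
        assert conversion_factor(20.0) > conversion_factor(30.0) > 0

    @given(dw=st.floats(min_value=6.0, max_value=55.0))
    def test_matches_closed_form(self, dw):
        assert conversion_factor(dw) == pytest.approx(
            A * math.exp(-B * dw), rel=1e-15)

    def test_negative_dw_rejected(self):
        with pytest.raises(ValueError):
            conversion_factor(-1.0)

    def test_out_of_domain_warns(self):
        with pytest.warns(UserWarning, match="fit domain"):
            conversion_factor(60.0)

    def test_custom_model_validation(self):
        with pytest.raises(ValueError):
            ConversionModel(coefficient_a=-1.0)


class TestCtdiChain:
    def test_normalized_ctdi(self):
        rec = ScanDoseRecord(mean_ctdi_vol=12.0, mean_mas=120.0)
        assert normalized_ctdi(rec) == pytest.approx(0.1)

    def test_roundtrip_identity(self):
        rec = ScanDoseRecord(mean_ctdi_vol=10.0, mean_mas=100.0)
        assert normalized_ctdi(rec) * rec.mean_mas == rec.mean_ctdi_vol

    @pytest.mark.parametrize("norm,mas,expected", [
        (0.1, 150.0, 15.0), (0.1, 0.0, 0.0),
    ])
    def test_ctdi_vol_z(self, norm, mas, expected):
        assert ctdi_vol_z(norm, mas) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ctdi_vol_z(-0.1, 100.0)

    def test_mean_recovers_scan_ctdi(self):
        rec = ScanDoseRecord(mean_ctdi_vol=9.0, mean_mas=100.0)
        mas = np.full(7, rec.mean_mas)
        czs = [ctdi_vol_z(normalized_ctdi(rec), m) for m in mas]
        assert np.mean(czs) == pytest.approx(rec.mean_ctdi_vol)


class TestMeanSsde:
    def test_simple_average(self):
        profiles = [
            dosimetry.SliceDoseProfile(i + 1, 0.0, 30.0, 100.0, 1.0, 1.0, s)
            for i, s in enumerate([2.0, 4.0, 6.0])
        ]
        assert mean_ssde(profiles) == pytest.approx(4.0)

    def test_single_slice(self):
        p = dosimetry.SliceDoseProfile(1, 0.0, 30.0, 100.0, 1.0, 1.0, 5.5)
        assert mean_ssde([p]) == 5.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_ssde([])


class TestCenterIndex:
    @pytest.mark.parametrize("n,expected", [(5, 3), (4, 2), (1, 1), (2, 1),
                                            (100, 50), (101, 51)])
    def test_convention(self, n, expected):
        assert center_slice_index(n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            center_slice_index(0)


def two_diameter_volume(mas=None):
    """Six slices: three 20 cm water disks then three 30 cm ones, 2 mm px."""
    small, _ = make_disk_image(size=256, radius_px=50)   # 20 cm at 2 mm
    large, _ = make_disk_image(size=256, radius_px=75)   # 30 cm at 2 mm
    slices = [small] * 3 + [large] * 3
    return make_volume(slices, mas=mas, spacing=(2.0, 2.0))


class TestPerSliceProfiles:
    def test_two_diameter_phantom(self, dose_record):
        vol = two_diameter_volume(mas=[100.0] * 6)
        profiles = per_slice_profiles(vol, dose_record)
        dws = [p.dw_z for p in profiles]
        assert dws[0] == pytest.approx(20.0, rel=0.01)
        assert dws[5] == pytest.approx(30.0, rel=0.01)

    def test_eq3_identity_every_slice(self, dose_record):
        vol = two_diameter_volume(mas=[90.0, 95, 100, 105, 110, 100])
        for p in per_slice_profiles(vol, dose_record):
            assert p.ssde_z == p.ctdi_vol_z * p.f_z

    def test_constant_phantom_identical_profiles(self, dose_record):
        img, _ = make_disk_image(size=256, radius_px=60)
        vol = make_volume([img] * 4, mas=[100.0] * 4, spacing=(2.0, 2.0))
        profiles = per_slice_profiles(vol, dose_record)
        assert len({(p.dw_z, p.ssde_z) for p in profiles}) == 1

    def test_requires_exposures(self, dose_record):
        vol = two_diameter_volume(mas=None)
        with pytest.raises(ValueError, match="exposures"):
            per_slice_profiles(vol, dose_record)

    def test_bad_slice_fails_scan(self, dose_record):
        img, _ = make_disk_image(size=64, radius_px=20)
        air = np.full((64, 64), -1000.0)
        vol = make_volume([img, air, img], mas=[100.0] * 3)
        with pytest.raises(ValueError, match="slice 2"):
            per_slice_profiles(vol, dose_record)

    def test_skip_bad_slices(self, dose_record):
        img, _ = make_disk_image(size=64, radius_px=20)
        air = np.full((64, 64), -1000.0)
        vol = make_volume([img, air, img], mas=[100.0] * 3)
        config = SegConfig(skip_bad_slices=True)
        with pytest.warns(UserWarning, match="skipped"):
            profiles = per_slice_profiles(vol, dose_record, config)
        assert [p.slice_index for p in profiles] == [1, 3]


class TestSsdeCenterAndSai:
    def test_constant_phantom_degeneracy(self, dose_record):
        img, _ = make_disk_image(size=256, radius_px=75)
        vol = make_volume([img] * 5, mas=[100.0] * 5, spacing=(2.0, 2.0))
        summary, _ = summarize_scan(vol, dose_record)
        assert summary.ssde_center == pytest.approx(summary.mean_ssde,
                                                    rel=1e-9)
        assert summary.ssde_sai == pytest.approx(summary.mean_ssde, rel=1e-9)

    def test_center_selects_middle_slice(self, dose_record):
        vol = two_diameter_volume(mas=[100.0] * 6)
        # 6 slices -> center index 3 -> the 20 cm half
        dw, _ = ssde_center(vol, dose_record)
        assert dw == pytest.approx(20.0, rel=0.01)

    def test_center_uses_mean_ctdi(self, dose_record):
        # SSDE_center must use the scan-mean CTDI_vol, not CTDI_vol,z
        vol = two_diameter_volume(mas=[50.0, 50, 50, 150, 150, 150])
        dw, ssde = ssde_center(vol, dose_record)
        assert ssde == pytest.approx(
            dose_record.mean_ctdi_vol * conversion_factor(dw))

    def test_single_slice_sai_equals_center(self, dose_record):
        img, _ = make_disk_image(size=256, radius_px=60)
        vol = make_volume([img], mas=[100.0], spacing=(2.0, 2.0))
        assert ssde_sai(vol, dose_record) == ssde_center(vol, dose_record)


class TestGenerateSai:
    def test_identical_slices_identity(self):
        img, _ = make_disk_image(size=64, radius_px=20)
        vol = make_volume([img] * 3)
        np.testing.assert_array_equal(generate_sai(vol), img)

    def test_two_value_average(self):
        vol = make_volume([np.zeros((8, 8)), np.full((8, 8), -1000.0)])
        assert (generate_sai(vol) == -500.0).all()

    def test_masked_mean_linearity(self):
        # with a fixed contour, the SAI mean over the mask equals the mean
        # of per-slice masked means
        rng = np.random.default_rng(5)
        img, mask = make_disk_image(size=128, radius_px=40)
        slices = []
        for _ in range(6):
            s = img.copy()
            s[mask] += rng.normal(0, 30, mask.sum())
            slices.append(s)
        vol = make_volume(slices)
        sai = generate_sai(vol)
        per_slice = [s[mask].mean() for s in slices]
        assert sai[mask].mean() == pytest.approx(np.mean(per_slice),
                                                 rel=1e-12)


class TestConvexityProperties:
    def test_jensen_mean_ssde(self, dose_record):
        # constant mAs: mean SSDE >= mean_ctdi * f(mean D_w), strict when
        # diameters differ
        vol = two_diameter_volume(mas=[100.0] * 6)
        summary, profiles = summarize_scan(vol, dose_record)
        bound = dose_record.mean_ctdi_vol * conversion_factor(summary.mean_dw)
        assert summary.mean_ssde > bound

    def test_sai_concavity_fixed_contour(self, dose_record):
        # same mask every slice, z-varying interior HU:
        # D_w,SAI >= mean per-slice D_w (sqrt is concave in mean HU)
        img, mask = make_disk_image(size=128, radius_px=40)
        slices = []
        for hu in (-300.0, 0.0, 150.0):
            s = img.copy()
            s[mask] = hu
            slices.append(s)
        vol = make_volume(slices, mas=[100.0] * 3)
        summary, _ = summarize_scan(vol, dose_record)
        assert summary.dw_sai > summary.mean_dw

    def test_equality_in_constant_case(self, dose_record):
        img, _ = make_disk_image(size=128, radius_px=40)
        vol = make_volume([img] * 3, mas=[100.0] * 3)
        summary, _ = summarize_scan(vol, dose_record)
        assert summary.dw_sai == pytest.approx(summary.mean_dw, rel=1e-12)

    def test_scale_property(self, dose_record):
        # doubling mean CTDI, mean mAs and mAs(z) together leaves the
        # normalized CTDI and every D_w unchanged and doubles every SSDE
        mas = [90.0, 95, 100, 105, 110, 100]
        s1, _ = summarize_scan(two_diameter_volume(mas=mas), dose_record)
        doubled = ScanDoseRecord(
            mean_ctdi_vol=2 * dose_record.mean_ctdi_vol,
            mean_mas=2 * dose_record.mean_mas,
            reference_phantom_diameter=32)
        s2, _ = summarize_scan(
            two_diameter_volume(mas=[2 * m for m in mas]), doubled)
        assert s2.normalized_ctdi == pytest.approx(s1.normalized_ctdi,
                                                   rel=1e-12)
        assert s2.mean_dw == s1.mean_dw
        assert s2.dw_sai == s1.dw_sai
        assert s2.mean_ssde == pytest.approx(2 * s1.mean_ssde, rel=1e-12)
        assert s2.ssde_center == pytest.approx(2 * s1.ssde_center, rel=1e-12)
        assert s2.ssde_sai == pytest.approx(2 * s1.ssde_sai, rel=1e-12)


class TestNslice:
    def test_full_set_equals_mean_dw(self, dose_record):
        vol = two_diameter_volume(mas=[100.0] * 6)
        summary, _ = summarize_scan(vol, dose_record, nslice_n=6)
        assert summary.dw_nslice == pytest.approx(summary.mean_dw, rel=1e-12)

    def test_n1_equals_center(self, dose_record):
        vol = two_diameter_volume(mas=[100.0] * 6)
        dw_c, _ = ssde_center(vol, dose_record)
        assert dw_nslice(vol, 1) == pytest.approx(dw_c, rel=1e-12)

    def test_indices_evenly_spaced(self):
        assert nslice_indices(9, 9) == list(range(1, 10))
        assert nslice_indices(41, 5) == [1, 11, 21, 31, 41]
        assert nslice_indices(10, 2) == [1, 10]

    def test_indices_strictly_increasing(self):
        for n_slices in (5, 17, 40):
            for n in range(2, n_slices + 1):
                idx = nslice_indices(n_slices, n)
                assert idx[0] == 1 and idx[-1] == n_slices
                assert all(a < b for a, b in zip(idx, idx[1:]))

    def test_out_of_range(self, dose_record):
        vol = two_diameter_volume(mas=[100.0] * 6)
        with pytest.raises(ValueError):
            dw_nslice(vol, 7)
        with pytest.raises(ValueError):
            dw_nslice(vol, 0)


class TestSlicewiseDiagnostic:
    def test_matches_definition(self, dose_record):
        vol = two_diameter_volume(mas=[90.0, 95, 100, 105, 110, 100])
        profiles = per_slice_profiles(vol, dose_record)
        expected = conversion_factor(
            float(np.mean([p.dw_z for p in profiles]))
        ) * float(np.mean([p.ctdi_vol_z for p in profiles]))
        assert ssde_sai_slicewise(profiles) == pytest.approx(expected,
                                                             rel=1e-12)


class TestSummaryValidation:
    def test_rejects_absurd_diameter(self):
        with pytest.raises(ValueError, match="outside"):
            dosimetry.ScanDoseSummary(
                normalized_ctdi=0.1, mean_dw=150.0, dw_center=30.0,
                dw_sai=30.0, dw_nslice=30.0, nslice_n=9, mean_ssde=10.0,
                ssde_center=10.0, ssde_sai=10.0, n_slices=10)
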