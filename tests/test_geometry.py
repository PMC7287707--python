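"""Centerline, cross-sections, PMC localization and the composite measurement."""

import numpy as np
import pytest

from dissectra.geometry import (
    CrossSection,
    cross_sections,
    extract_centerline,
    find_pmc,
    fli,
    measure_case,
    voxel_volume,
)
from dissectra.imaging_io import LumenLabelMap
from dissectra.phantom import PhantomSpec, generate_phantom


def _labelmap(data, spacing=(1.0, 1.0, 1.0)):
    return LumenLabelMap(np.asarray(data, dtype=np.int16), spacing)


class TestVoxelVolume:
    def test_thousand_unit_voxels_is_one_cm3(self):
        data = np.zeros((10, 10, 10), np.int16)
        data[:] = LumenLabelMap.TL
        assert voxel_volume(_labelmap(data), LumenLabelMap.TL) == pytest.approx(1.0)

    def test_anisotropic_spacing_uses_product(self):
        data = np.full((10, 10, 10), LumenLabelMap.FL, np.int16)
        lm = _labelmap(data, (0.625, 0.625, 0.6))
        assert voxel_volume(lm, LumenLabelMap.FL) == pytest.approx(1000 * 0.234375 / 1000.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            voxel_volume(_labelmap(np.zeros((2, 2, 2), np.int16)), 7)

    def test_phantom_volumes_within_2pct_of_quadrature(self, noiseless_phantom):
        _, labels, gt = noiseless_phantom
        assert voxel_volume(labels, LumenLabelMap.TL) == pytest.approx(gt.tl_volume_cm3, rel=0.02)
        assert voxel_volume(labels, LumenLabelMap.FL) == pytest.approx(gt.fl_volume_cm3, rel=0.02)


class TestCenterline:
    def test_straight_tube_collinear_with_axis(self):
        # grid-aligned tube: flat end caps, so the whole path is on-axis
        spec = PhantomSpec(noise_sd_hu=0.0, axis_tilt_deg=0.0)
        _, labels, _ = generate_phantom(spec)
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        axis = np.array([0.0, 0.0, 1.0])
        perp = cl.points - np.outer(cl.points @ axis, axis)
        assert np.linalg.norm(perp, axis=1).max() < 1.0

    def test_tilted_tube_collinear_away_from_oblique_caps(self, noiseless_phantom):
        # the scan box cuts a tilted tube obliquely, so the traced path bends
        # toward the cap centroids near the ends; the interior stays on-axis
        _, labels, _ = noiseless_phantom
        tilt = np.deg2rad(PhantomSpec().axis_tilt_deg)
        axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        perp = cl.points - np.outer(cl.points @ axis, axis)
        interior = (cl.s_mm > 25) & (cl.s_mm < cl.s_mm[-1] - 25)
        assert np.linalg.norm(perp[interior], axis=1).max() < 1.0

    def test_endpoints_reach_extremal_slices(self, noiseless_phantom):
        _, labels, _ = noiseless_phantom
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        zs = np.nonzero((labels.data > 0).any(axis=(0, 1)))[0]
        z_lo = labels.origin_mm[2] + (zs.min() + 0.5) * labels.spacing_mm[2]
        z_hi = labels.origin_mm[2] + (zs.max() + 0.5) * labels.spacing_mm[2]
        assert abs(cl.points[0][2] - z_lo) < 2 * labels.spacing_mm[2]
        assert abs(cl.points[-1][2] - z_hi) < 2 * labels.spacing_mm[2]

    def test_arch_arc_length_matches_analytic(self):
        spec = PhantomSpec(
            centerline_shape="arch", length_mm=200.0, arch_radius_mm=40.0,
            compression_center_mm=100.0, dissection_start_mm=8.0,
            dissection_end_mm=192.0, tear_positions_mm=((30.0, 12.0), (170.0, 12.0)),
            noise_sd_hu=0.0,
        )
        _, labels, _ = generate_phantom(spec)
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        assert cl.length_mm == pytest.approx(200.0, rel=0.05)

    def test_output_is_simple_monotone_path(self, noiseless_phantom):
        _, labels, _ = noiseless_phantom
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        assert np.all(np.diff(cl.s_mm) > 0)
        np.testing.assert_allclose(np.linalg.norm(cl.tangents, axis=1), 1.0, atol=1e-6)

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((10, 10, 30), bool)
        mask[3:7, 3:7, 2:10] = True
        mask[3:7, 3:7, 20:28] = True
        with pytest.raises(ValueError, match="connected"):
            extract_centerline(mask)


class TestCrossSections:
    def test_half_split_tube_areas(self):
        spec = PhantomSpec(
            length_mm=80.0, tl_fraction_base=0.5, compression_depth=0.0,
            compression_center_mm=40.0, flap_thickness_mm=0.0, axis_tilt_deg=0.0,
            dissection_start_mm=0.0, dissection_end_mm=80.0,
            tear_positions_mm=(), noise_sd_hu=0.0,
        )
        _, labels, _ = generate_phantom(spec)
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        secs = cross_sections(labels, cl, step_mm=2.0)
        half_disk = 0.5 * np.pi * 15.0**2
        mid = [s for s in secs if 20 <= s.s_mm <= 60]
        for sec in mid:
            assert sec.tl_area_mm2 == pytest.approx(half_disk, rel=0.03)
            assert sec.fl_area_mm2 == pytest.approx(half_disk, rel=0.03)

    def test_background_section_has_zero_areas(self, noiseless_phantom):
        _, labels, _ = noiseless_phantom
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        # a synthetic section far outside the volume
        far = CrossSection(
            s_mm=0.0, origin_mm=np.array([500.0, 500.0, 500.0]),
            normal=np.array([0.0, 0.0, 1.0]), tl_area_mm2=0.0, fl_area_mm2=0.0,
        )
        assert far.tl_equiv_diameter_cm == 0.0
        secs = cross_sections(labels, cl, step_mm=50.0, extent_mm=5.0)
        assert all(s.tl_area_mm2 >= 0 and s.fl_area_mm2 >= 0 for s in secs)

    def test_invalid_step_rejected(self, noiseless_phantom):
        _, labels, _ = noiseless_phantom
        cl = extract_centerline(labels.data > 0, labels.spacing_mm, labels.origin_mm)
        with pytest.raises(ValueError, match="step"):
            cross_sections(labels, cl, step_mm=0.0)


def _sections_with_profile(diams, fl_present=None):
    out = []
    for i, d in enumerate(diams):
        area = np.pi * (10 * d / 2) ** 2
        fl = 100.0 if fl_present is None or fl_present[i] else 0.0
        out.append(
            CrossSection(
                s_mm=2.0 * i, origin_mm=np.zeros(3), normal=np.array([0, 0, 1.0]),
                tl_area_mm2=area, fl_area_mm2=fl,
            )
        )
    return out


class TestFindPmc:
    def test_minimum_located(self):
        diams = [2.0, 1.8, 1.2, 0.8, 1.2, 1.8, 2.0]
        s, d = find_pmc(_sections_with_profile(diams), smooth_window=1)
        assert s == 6.0 and d == pytest.approx(0.8)

    def test_constant_profile_returns_plateau_median(self):
        s, _ = find_pmc(_sections_with_profile([1.0] * 7), smooth_window=1)
        assert s == 6.0  # middle of seven tied sections

    def test_orientation_reversal_invariance(self):
        diams = [2.0, 1.5, 0.9, 0.9, 1.5, 2.0, 2.2]
        secs = _sections_with_profile(diams)
        s_fwd, d_fwd = find_pmc(secs, smooth_window=1)
        rev = [
            CrossSection(
                s_mm=secs[-1].s_mm - sec.s_mm, origin_mm=sec.origin_mm,
                normal=-sec.normal, tl_area_mm2=sec.tl_area_mm2,
                fl_area_mm2=sec.fl_area_mm2,
            )
            for sec in reversed(secs)
        ]
        s_rev, d_rev = find_pmc(rev, smooth_window=1)
        assert d_fwd == pytest.approx(d_rev)
        assert abs((secs[-1].s_mm - s_rev) - s_fwd) <= 2.0  # half-step of even plateau

    def test_restricted_to_dissected_extent(self):
        # the narrowest TL lies where no FL exists: must not win by default
        diams = [0.5, 0.6, 1.5, 1.2, 1.5]
        fl = [False, False, True, True, True]
        s, _ = find_pmc(_sections_with_profile(diams, fl), smooth_window=1)
        assert s == 6.0
        s_all, _ = find_pmc(
            _sections_with_profile(diams, fl), dissected_extent_only=False, smooth_window=1
        )
        assert s_all == 0.0

    def test_no_dissected_sections_is_an_error(self):
        secs = _sections_with_profile([1.0, 1.0], fl_present=[False, False])
        with pytest.raises(ValueError, match="no dissected sections"):
            find_pmc(secs)


class TestFli:
    def test_printed_table_values(self):
        assert round(fli(33.29, 77.05), 2) == 2.31
        assert round(fli(19.77, 218.37), 2) == 11.05

    def test_equal_lumens_give_unity(self):
        assert fli(50.0, 50.0) == 1.0

    def test_nonpositive_tl_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fli(0.0, 10.0)

    @pytest.mark.parametrize("tl_up,fl_down", [(1.1, 0.9), (1.5, 0.99), (1.01, 0.5)])
    def test_monotone_under_remodeling(self, tl_up, fl_down):
        # FLI strictly decreases whenever TL grows and FL shrinks
        base = fli(40.0, 120.0)
        assert fli(40.0 * tl_up, 120.0 * fl_down) < base


class TestMeasureCase:
    def test_phantom_recovery_within_5pct(self, segmented_phantom, noiseless_phantom):
        _, _, gt = noiseless_phantom
        m = measure_case(segmented_phantom)
        assert m.tl_vol_cm3 == pytest.approx(gt.tl_volume_cm3, rel=0.05)
        assert m.fl_vol_cm3 == pytest.approx(gt.fl_volume_cm3, rel=0.05)
        assert m.fli == pytest.approx(gt.fli, rel=0.05)
        assert m.tl_pmc_cm == pytest.approx(gt.tl_diameter_at_pmc_cm, rel=0.05)

    def test_default_phantom_fli_in_cohort_band(self, segmented_phantom):
        # defaults emulate a severely dissected case: FLI between 2 and 3
        m = measure_case(segmented_phantom)
        assert 2.0 < m.fli < 3.0

    def test_fl_free_case_gives_zero_fli_and_pmc_error(self, noiseless_phantom):
        _, labels, _ = noiseless_phantom
        data = labels.data.copy()
        data[data == LumenLabelMap.FL] = LumenLabelMap.TL
        solo = LumenLabelMap(data, labels.spacing_mm, labels.origin_mm)
        with pytest.raises(ValueError, match="no dissected sections"):
            measure_case(solo)

    def test_pmc_position_recovery_over_parameter_grid(self):
        # 3x3 grid of (depth, width): RMSE of the recovered compression
        # center below twice the section step
        spec0 = PhantomSpec(noise_sd_hu=0.0)
        tilt = np.deg2rad(spec0.axis_tilt_deg)
        axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        errors = []
        for depth in (0.06, 0.09, 0.12):
            for width in (8.0, 10.0, 12.0):
                spec = PhantomSpec(
                    noise_sd_hu=0.0, compression_depth=depth, compression_width_mm=width
                )
                _, labels, gt = generate_phantom(spec)
                m = measure_case(labels)
                recovered = float(m.pmc_point_mm @ axis)
                errors.append(recovered - gt.pmc_position_mm)
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        assert rmse < 2 * 2.0
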