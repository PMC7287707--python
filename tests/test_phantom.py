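"""Phantom generator: analytic ground truth, voxelization and invariants."""

import json

import numpy as np
import pytest
from scipy.optimize import brentq

from dissectra.imaging_io import LumenLabelMap
from dissectra.phantom import (
    PhantomSpec,
    chord_offset_for_fraction,
    generate_phantom,
    make_pre_post_pair,
    segment_area,
)


def quadrature_oracle_fli(r, length, alpha0, depth, center, width, flap_h, ds=0.05):
    """Independent FLI oracle: direct quadrature of circular-segment areas.

    Chord offsets are solved with Brent's method per step; written without
    touching the package's own area machinery.
    """
    disk = np.pi * r * r

    def seg(t):
        t = min(max(t, -r), r)
        return r * r * np.arccos(t / r) - t * np.sqrt(max(r * r - t * t, 0.0))

    tl = fl = 0.0
    for s in np.arange(ds / 2, length, ds):
        alpha = alpha0 - depth * np.exp(-((s - center) ** 2) / (2 * width**2))
        t = brentq(lambda x: seg(x) - alpha * disk, -r, r, xtol=1e-12)
        tl += seg(t + flap_h / 2) * ds
        fl += (disk - seg(t - flap_h / 2)) * ds
    return fl / tl, tl / 1000.0, fl / 1000.0


# spec of a plain full-length dissection tube (no tears, grid-aligned) whose
# analytic volumes the oracle above reproduces independently
_ORACLE_SPEC = dict(
    length_mm=100.0,
    lumen_radius_mm=15.0,
    tl_fraction_base=0.3,
    compression_depth=0.2,
    compression_center_mm=50.0,
    compression_width_mm=10.0,
    axis_tilt_deg=0.0,
    flap_angle_deg=0.0,
    dissection_start_mm=0.0,
    dissection_end_mm=100.0,
    tear_positions_mm=(),
    noise_sd_hu=0.0,
)


class TestAnalytics:
    def test_segment_area_inversion(self):
        r = 15.0
        alphas = np.linspace(0.02, 0.98, 25)
        t = chord_offset_for_fraction(alphas, r)
        np.testing.assert_allclose(segment_area(t, r) / (np.pi * r * r), alphas, atol=1e-9)

    def test_ground_truth_matches_independent_quadrature(self):
        spec = PhantomSpec(**_ORACLE_SPEC)
        _, _, gt = generate_phantom(spec)
        fli_oracle, tl_oracle, fl_oracle = quadrature_oracle_fli(
            15.0, 100.0, 0.3, 0.2, 50.0, 10.0, spec.flap_thickness_mm
        )
        assert gt.tl_volume_cm3 == pytest.approx(tl_oracle, rel=1e-3)
        assert gt.fl_volume_cm3 == pytest.approx(fl_oracle, rel=1e-3)
        assert gt.fli == pytest.approx(fli_oracle, rel=1e-3)

    def test_voxel_measurement_tracks_quadrature_within_5pct(self):
        spec = PhantomSpec(**_ORACLE_SPEC)
        _, labels, gt = generate_phantom(spec)
        vv = labels.voxel_volume_mm3 / 1000.0
        tl = np.count_nonzero(labels.data == LumenLabelMap.TL) * vv
        fl = np.count_nonzero(labels.data == LumenLabelMap.FL) * vv
        assert fl / tl == pytest.approx(gt.fli, rel=0.05)


class TestGeneration:
    def test_symmetric_split_gives_equal_lumens(self):
        spec = PhantomSpec(
            **{**_ORACLE_SPEC, "tl_fraction_base": 0.5, "compression_depth": 0.0,
               "flap_thickness_mm": 0.0}
        )
        _, labels, gt = generate_phantom(spec)
        assert gt.tl_volume_cm3 == pytest.approx(gt.fl_volume_cm3, rel=1e-6)
        n_tl = np.count_nonzero(labels.data == LumenLabelMap.TL)
        n_fl = np.count_nonzero(labels.data == LumenLabelMap.FL)
        assert n_tl == pytest.approx(n_fl, rel=0.02)

    def test_post_state_reduces_fli(self):
        spec = PhantomSpec(noise_sd_hu=0.0)
        (_, _, pre), (_, _, post) = make_pre_post_pair(spec)
        assert post.fli < pre.fli
        assert post.tl_volume_cm3 > pre.tl_volume_cm3
        assert post.fl_volume_cm3 < pre.fl_volume_cm3

    def test_pre_post_percent_change_matches_analytic(self):
        (_, pre_lab, pre_gt), (_, post_lab, post_gt) = make_pre_post_pair(
            PhantomSpec(noise_sd_hu=0.0)
        )
        vv = pre_lab.voxel_volume_mm3 / 1000.0
        meas = [
            np.count_nonzero(lab.data == LumenLabelMap.TL) * vv
            for lab in (pre_lab, post_lab)
        ]
        measured_pct = 100.0 * (meas[1] - meas[0]) / meas[0]
        analytic_pct = 100.0 * (post_gt.tl_volume_cm3 - pre_gt.tl_volume_cm3) / pre_gt.tl_volume_cm3
        assert measured_pct == pytest.approx(analytic_pct, rel=0.10)

    def test_partition_of_aorta(self, noiseless_phantom):
        _, labels, _ = noiseless_phantom
        aorta = labels.data > 0
        n_parts = sum(
            int(np.count_nonzero(labels.data == lab))
            for lab in (LumenLabelMap.TL, LumenLabelMap.FL, LumenLabelMap.FLAP)
        )
        assert n_parts == int(aorta.sum())

    def test_threshold_recovers_lumen_exactly_without_noise(self, noiseless_phantom):
        vol, labels, _ = noiseless_phantom
        lumen = labels.mask(LumenLabelMap.TL, LumenLabelMap.FL)
        np.testing.assert_array_equal(vol.data >= 175.0, lumen)

    def test_volume_error_shrinks_with_voxel_size(self):
        errors = {}
        for h in (2.0, 0.5):
            spec = PhantomSpec(noise_sd_hu=0.0, voxel_spacing_mm=(h, h, h))
            _, labels, gt = generate_phantom(spec)
            vv = labels.voxel_volume_mm3 / 1000.0
            tl = np.count_nonzero(labels.data == LumenLabelMap.TL) * vv
            fl = np.count_nonzero(labels.data == LumenLabelMap.FL) * vv
            errors[h] = abs(tl - gt.tl_volume_cm3) + abs(fl - gt.fl_volume_cm3)
        assert errors[0.5] < errors[2.0]

    def test_noise_is_seeded_and_reproducible(self):
        spec = PhantomSpec(rng_seed=11)
        v1, _, _ = generate_phantom(spec)
        v2, _, _ = generate_phantom(spec)
        np.testing.assert_array_equal(v1.data, v2.data)


class TestValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(compression_depth=0.25),               # alpha(s) reaches <= 0
            dict(voxel_spacing_mm=(20.0, 1.0, 1.0)),    # spacing >= lumen radius
            dict(tear_positions_mm=((5.0, 12.0),)),     # tear outside dissection interior
            dict(dissection_start_mm=100.0, dissection_end_mm=50.0),
            dict(tl_fraction_base=1.2),
            dict(state="during"),
        ],
    )
    def test_degenerate_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(**bad))

    def test_spec_serialization_round_trip(self, tmp_path):
        spec = PhantomSpec(flap_angle_deg=33.0, rng_seed=5)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        assert PhantomSpec.from_json(path) == spec
        assert PhantomSpec.from_json(spec.to_json()) == spec
        # flat key/value layout: every field is a top-level key
        keys = set(json.loads(spec.to_json()))
        assert "lumen_radius_mm" in keys and "tear_positions_mm" in keys
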