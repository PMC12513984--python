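"""Generator contracts: deficit fraction, ICD spectrum, rendering, volumes."""

import numpy as np
import pytest

from ccfd.devices import SD_V1, SD_V4, SS, DeviceProfile, get_device
from ccfd.synthetic import (
    GroundTruth,
    ShadowField,
    UnreachableFDFractionError,
    VesselNetworkParams,
    band_profile,
    generate_cc_pattern,
    generate_volume,
    radial_power_spectrum,
    render_device_image,
)


class TestPattern:
    def test_all_void_degenerate_target(self):
        gt = generate_cc_pattern(
            VesselNetworkParams(target_fd_fraction=1.0, seed=0)
        )
        assert not gt.flow_field.any()
        assert gt.fd_fraction_true == 1.0
        assert gt.fd_mask_true.all()

    def test_target_fraction_within_tolerance(self, default_truth):
        assert abs(default_truth.fd_fraction_true - 0.45) <= 0.01

    def test_mask_is_exactly_zero_flow_set(self, default_truth):
        np.testing.assert_array_equal(
            default_truth.fd_mask_true, default_truth.flow_field == 0
        )
        assert default_truth.fd_fraction_true == default_truth.fd_mask_true.mean()

    def test_mesh_spectral_peak_in_icd_band(self):
        # Minimal carving so the mesh itself dominates the spectrum.
        gt = generate_cc_pattern(
            VesselNetworkParams(target_fd_fraction=0.22, seed=3)
        )
        period, power = radial_power_spectrum(gt.flow_field, gt.pixel_size_um)
        assert 21.0 <= period[np.argmax(power)] <= 40.0

    def test_unreachable_target_reports_floor(self):
        with pytest.raises(UnreachableFDFractionError) as err:
            generate_cc_pattern(VesselNetworkParams(target_fd_fraction=0.05, seed=0))
        assert 0.05 < err.value.achievable_floor < 0.35

    def test_seed_determinism(self):
        kwargs = dict(fine_grid_px=512, extent_mm=1.5)
        p = VesselNetworkParams(target_fd_fraction=0.4, seed=42)
        a = generate_cc_pattern(p, **kwargs)
        b = generate_cc_pattern(p, **kwargs)
        np.testing.assert_array_equal(a.flow_field, b.flow_field)
        assert a.fd_fraction_true == b.fd_fraction_true

    def test_icd_range_derived_from_geometry(self):
        p = VesselNetworkParams()
        assert p.icd_um == (21.0, 40.0)

    def test_coarse_grid_refused(self):
        with pytest.raises(ValueError, match="resolve"):
            generate_cc_pattern(VesselNetworkParams(seed=0), fine_grid_px=128)


class TestRendering:
    def test_identity_rendering_zero_noise(self, default_truth):
        pair = render_device_image(
            default_truth, ShadowField.uniform(1024), SS.without_noise(), seed=0
        )
        np.testing.assert_array_equal(pair.flow, default_truth.flow_field)
        assert pair.pixel_size_um == pytest.approx(3000 / 1024)
        assert SD_V1.pixel_size_um == pytest.approx(7.5)

    def test_noise_sd_halved_by_four_volume_averaging(self, flat_field_truth):
        shadow = ShadowField.uniform(400)
        sds = {}
        for dev in (SD_V1, SD_V4):
            pair = render_device_image(flat_field_truth, shadow, dev, seed=9)
            sds[dev.name] = pair.flow.std()
        assert sds["SD_V4"] / sds["SD_V1"] == pytest.approx(0.5, rel=0.10)

    def test_upsampling_refused(self, flat_field_truth):
        with pytest.raises(ValueError, match="upsampling"):
            render_device_image(
                flat_field_truth, ShadowField.uniform(400), SS, seed=0
            )

    def test_channels_share_attenuation(self, flat_field_truth):
        shadow = ShadowField.generate(400, 3.0, n_drusen=3, seed=4)
        dev = SD_V1.without_noise()
        pair = render_device_image(flat_field_truth, shadow, dev, seed=0)
        # flow = 0.5*att, structural = 0.8*att -> exact proportionality
        np.testing.assert_allclose(pair.flow / 0.5, pair.structural / 0.8,
                                   atol=1e-12)

    def test_fd_fraction_survives_downsampling(self, default_truth):
        from skimage.transform import resize

        resampled = resize(
            default_truth.fd_mask_true.astype(float), (400, 400),
            order=1, anti_aliasing=True,
        ) > 0.5  # majority vote per device pixel
        assert abs(resampled.mean() - default_truth.fd_fraction_true) < 0.02


class TestShadowField:
    def test_factors_in_unit_interval_and_one_outside(self):
        shadow = ShadowField.generate(512, 3.0, n_drusen=2, seed=1)
        att = shadow.attenuation_map
        assert att.min() >= shadow.min_attenuation - 1e-12
        assert att.max() == 1.0
        assert (att == 1.0).mean() > 0.5  # footprints are localized

    def test_invalid_factors_refused(self):
        with pytest.raises(ValueError):
            ShadowField(np.zeros((8, 8)))


class TestVolume:
    def _truth(self, rng, n=32):
        field = np.where(rng.random((n, n)) > 0.4, rng.uniform(0.6, 1, (n, n)), 0.0)
        return GroundTruth(field, field == 0, float((field == 0).mean()), 3.0)

    def test_depth_uniform_volume_projects_to_truth(self):
        from ccfd.slabs import SlabSpec, extract_enface

        truth = self._truth(np.random.default_rng(0))
        bm = np.full((32, 32), 12.0)
        vol = generate_volume(truth, bm, 1.0, band_profile(0, 41))
        for zz in [(0, 41), (11, 21), (31, 41)]:
            enface = extract_enface(vol, bm, SlabSpec("s", *zz), 1.0)
            np.testing.assert_allclose(enface, truth.flow_field, atol=1e-12)

    def test_disjoint_support_projects_to_zero(self):
        from ccfd.slabs import SlabSpec, extract_enface

        truth = self._truth(np.random.default_rng(1))
        bm = np.full((32, 32), 10.0)
        vol = generate_volume(truth, bm, 1.0, band_profile(11, 21))
        deep = extract_enface(vol, bm, SlabSpec("31-41", 31, 41), 1.0)
        np.testing.assert_allclose(deep, 0.0, atol=1e-12)

    def test_tilted_bm_matches_flat_bm(self):
        from ccfd.slabs import SlabSpec, extract_enface

        truth = self._truth(np.random.default_rng(2))
        flat = np.full((32, 32), 20.0)
        ramp = 10.0 + np.linspace(0, 20, 32)[None, :] * np.ones((32, 1))
        profile = band_profile(0, 50)
        slab = SlabSpec("11-21", 11, 21)
        e_flat = extract_enface(generate_volume(truth, flat, 1.0, profile),
                                flat, slab, 1.0)
        e_ramp = extract_enface(generate_volume(truth, ramp, 1.0, profile),
                                ramp, slab, 1.0)
        np.testing.assert_allclose(e_ramp, e_flat, atol=1e-9)

    def test_shape_mismatch_refused(self):
        truth = self._truth(np.random.default_rng(3))
        with pytest.raises(ValueError, match="shape"):
            generate_volume(truth, np.zeros((8, 8)), 1.0, band_profile(0, 40))

    def test_coarse_axial_step_refused(self):
        truth = self._truth(np.random.default_rng(4))
        with pytest.raises(ValueError, match="axial_step"):
            generate_volume(truth, np.full((32, 32), 10.0), 3.0, band_profile(0, 40))


def test_device_profile_validation():
    with pytest.raises(ValueError):
        DeviceProfile("bad", 3.0, 0)
    with pytest.raises(KeyError):
        get_device("nope")
    assert get_device("sd_v4").n_averaged_volumes == 4
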