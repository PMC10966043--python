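"""Column-wise white-reference calibration: exactness, invariances, noise."""

import numpy as np
import pytest

from ginspect.calibration import ColumnReference, calibrate, column_reference
from ginspect.errors import CalibrationError
from ginspect.hsi_io import HyperCube, SampleRecord
from ginspect.segmentation import RoiMask, build_mask
from ginspect.spectra import extract_curve


def _dn_cube(data, wl=None):
    data = np.asarray(data, dtype=float)
    if wl is None:
        wl = 500.0 + 10.0 * np.arange(data.shape[2])
    return HyperCube(data=data, wavelengths=wl, range_tag="VNIR")


def _simple_scene():
    """4x4 single-band scene: rows 0-1 whiteboard, rows 2-3 sample."""
    data = np.zeros((4, 4, 1))
    data[0, :, 0] = [800, 820, 900, 1000]
    data[1, :, 0] = [820, 800, 900, 1000]
    data[2, :, 0] = [2, 4, 6, 8]
    data[3, :, 0] = [6, 8, 10, 12]
    cube = _dn_cube(data)
    wroi = np.zeros((4, 4), dtype=bool)
    wroi[:2] = True
    groi = np.zeros((4, 4), dtype=bool)
    groi[2:] = True
    return cube, RoiMask(groi=groi, wroi=wroi, reference_wavelength=500.0)


class TestColumnReference:
    def test_column_means(self):
        cube, mask = _simple_scene()
        ref = column_reference(cube, mask)
        np.testing.assert_allclose(ref.values[0], [810, 810, 900, 1000])
        assert ref.valid.all()

    def test_constant_whiteboard_gives_constant_reference(self):
        data = np.full((3, 5, 2), 7.0)
        cube = _dn_cube(data)
        wroi = np.zeros((3, 5), dtype=bool)
        wroi[0] = True
        groi = np.zeros((3, 5), dtype=bool)
        groi[2] = True
        ref = column_reference(cube, RoiMask(groi, wroi, 500.0))
        np.testing.assert_allclose(ref.values, 7.0)

    def test_empty_wroi_is_error(self):
        cube, mask = _simple_scene()
        empty = RoiMask(mask.groi, np.zeros_like(mask.wroi), 500.0)
        with pytest.raises(CalibrationError):
            column_reference(cube, empty)

    def test_columns_without_whiteboard_flagged_invalid(self):
        cube, mask = _simple_scene()
        wroi = mask.wroi.copy()
        wroi[:, 3] = False
        ref = column_reference(cube, RoiMask(mask.groi, wroi, 500.0))
        assert not ref.valid[3]
        assert np.isnan(ref.values[0, 3])


class TestCalibrate:
    def test_direct_ratio(self):
        # GROI DNs [[2,4],[6,8]] over column references [2,4] -> [[1,1],[3,2]]
        data = np.zeros((3, 2, 1))
        data[0, :, 0] = [2, 4]  # whiteboard row
        data[1, :, 0] = [2, 4]
        data[2, :, 0] = [6, 8]
        cube = _dn_cube(data)
        wroi = np.array([[1, 1], [0, 0], [0, 0]], dtype=bool)
        groi = np.array([[0, 0], [1, 1], [1, 1]], dtype=bool)
        refl = calibrate(cube, RoiMask(groi, wroi, 500.0))
        np.testing.assert_allclose(refl.data[1:, :, 0], [[1, 1], [3, 2]])
        assert refl.value_kind == "reflectance"
        assert np.isnan(refl.data[0, 0, 0])  # non-GROI pixels are sentinel

    def test_sample_equal_to_whiteboard_gives_unity(self):
        cube, mask = _simple_scene()
        cube.data[2:] = np.array([810, 810, 900, 1000.0])[None, :, None]  # column means
        refl = calibrate(cube, mask)
        np.testing.assert_allclose(refl.data[mask.groi], 1.0)

    def test_illumination_invariance_is_exact(self):
        cube, mask = _simple_scene()
        profile = np.array([0.5, 1.0, 1.5, 0.7])
        lit = _dn_cube(cube.data * profile[None, :, None])
        a = calibrate(cube, mask)
        b = calibrate(lit, mask)
        # the profile cancels in the ratio; agreement to float rounding
        np.testing.assert_allclose(a.data[mask.groi], b.data[mask.groi], rtol=1e-12)

    def test_global_gain_invariance(self):
        cube, mask = _simple_scene()
        a = calibrate(cube, mask)
        b = calibrate(_dn_cube(cube.data * 37.0), mask)
        np.testing.assert_allclose(a.data[mask.groi], b.data[mask.groi], rtol=1e-12)

    def test_reflectance_monotone_in_dn(self):
        cube, mask = _simple_scene()
        ref = column_reference(cube, mask)
        bumped = cube.data.copy()
        bumped[2, 1, 0] += 1.0
        refl_a = calibrate(cube, mask, ref)
        refl_b = calibrate(_dn_cube(bumped), mask, ref)
        assert refl_b.data[2, 1, 0] > refl_a.data[2, 1, 0]
        same = ~np.isnan(refl_a.data) & ~((np.arange(4) == 2)[:, None, None] & (np.arange(4) == 1)[None, :, None])
        np.testing.assert_array_equal(refl_a.data[same & ~np.isnan(refl_a.data)],
                                      refl_b.data[same & ~np.isnan(refl_b.data)])

    def test_missing_reference_policies(self):
        cube, mask = _simple_scene()
        wroi = mask.wroi.copy()
        wroi[:, 3] = False  # sample column 3 now has no reference
        holed = RoiMask(mask.groi, wroi, 500.0)
        with pytest.raises(CalibrationError, match="3"):
            calibrate(cube, holed, missing_ref="error")
        refl = calibrate(cube, holed, missing_ref="nearest")
        # column 3 filled from nearest valid column (2): DN 8 / 900, 12 / 900
        np.testing.assert_allclose(refl.data[2:, 3, 0], [8 / 900, 12 / 900])


class TestOnRenderedScenes:
    def test_noise_free_recovery_is_exact(self, calibrated_sample):
        cfg, calibrated, masks, truth = calibrated_sample
        curve = extract_curve(calibrated, masks)
        np.testing.assert_allclose(curve.values, truth.curve, rtol=1e-9)

    def test_column_illumination_removed(self):
        """Raw DN column means follow the quadratic illumination profile;
        calibrated column means are flat."""
        from ginspect.synthetic import base_curve, render_scene
        from conftest import small_config

        cfg = small_config(snr=None, sample_sigma=0.0, texture_sigma=0.0)
        rng = np.random.default_rng(3)
        record, truth = render_scene(base_curve(4, cfg), cfg, rng, "flat", 4)
        mask = build_mask(record.vnir, cfg.layout())
        band = record.vnir.data[:, :, 100]
        cols = np.flatnonzero(mask.groi.sum(axis=0) >= 5)
        raw_means = np.array([band[mask.groi[:, j], j].mean() for j in cols])
        # raw means are proportional to the illumination profile
        np.testing.assert_allclose(
            raw_means / raw_means.max(), truth.illum[cols] / truth.illum[cols].max(),
            rtol=1e-9,
        )
        assert raw_means.max() / raw_means.min() > 1.05
        # the whiteboard columns see the full width, hence the full gradient
        wb_dn = record.vnir.data[cfg.whiteboard_rows[0] + cfg.flare_width + 1, :, 100]
        assert wb_dn.max() / wb_dn.min() > 1.3
        refl = calibrate(record.vnir, mask)
        rband = refl.data[:, :, 100]
        cal_means = np.array([rband[mask.groi[:, j], j].mean() for j in cols])
        assert np.ptp(cal_means) / cal_means.mean() < 1e-9

    def test_snr100_recovery_below_one_percent(self, noisy_scene):
        cfg, record, truth = noisy_scene
        layout = cfg.layout()
        vmask = build_mask(record.vnir, layout)
        smask = build_mask(record.swir, layout)
        cal = SampleRecord(
            "s", calibrate(record.vnir, vmask), calibrate(record.swir, smask), 4
        )
        curve = extract_curve(cal, (vmask, smask))
        rel = np.abs(curve.values - truth.curve) / truth.curve
        assert rel.mean() < 0.01

    def test_whiteboard_ratio_is_unity(self, noise_free_scene):
        """Interior whiteboard pixels divided by the column reference sit at
        1 by construction (flare rows excluded by the eroded mask)."""
        cfg, record, truth = noise_free_scene
        mask = build_mask(record.vnir, cfg.layout())
        ref = column_reference(record.vnir, mask)
        wb = record.vnir.data[mask.wroi] / ref.values.T[np.nonzero(mask.wroi)[1]]
        np.testing.assert_allclose(wb, 1.0, rtol=1e-9)
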