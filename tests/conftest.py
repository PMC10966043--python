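"""Shared fixtures: small synthetic scenes sized for fast unit tests."""

import numpy as np
import pytest

from ginspect.calibration import calibrate
from ginspect.hsi_io import SampleRecord
from ginspect.segmentation import build_mask
from ginspect.synthetic import GeneratorConfig, make_reflectance_curve, render_scene


def small_config(**overrides) -> GeneratorConfig:
    """A desk-scale generator config whose geometry fits a 64x256 scene."""
    defaults = dict(
        rows=64,
        cols=256,
        whiteboard_rows=(4, 24),
        flare_margin=3,
        flare_width=2,
        ellipse_center=(0.7, 0.5),
        ellipse_radii=(0.2, 0.3),
        seed=0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def noise_free_scene():
    """One noise-free rendered sample with its ground truth."""
    cfg = small_config(snr=None, sample_sigma=0.0)
    rng = np.random.default_rng(7)
    curve = make_reflectance_curve(3, cfg, rng)
    record, truth = render_scene(curve, cfg, rng, sample_id="nf", label_year=3)
    return cfg, record, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """One rendered sample at SNR 100."""
    cfg = small_config(snr=100.0, sample_sigma=0.0, seed=5)
    rng = np.random.default_rng(5)
    curve = make_reflectance_curve(4, cfg, rng)
    record, truth = render_scene(curve, cfg, rng, sample_id="ny", label_year=4)
    return cfg, record, truth


@pytest.fixture(scope="session")
def calibrated_sample(noise_free_scene):
    """The noise-free sample segmented and calibrated, plus its masks."""
    cfg, record, truth = noise_free_scene
    layout = cfg.layout()
    vmask = build_mask(record.vnir, layout)
    smask = build_mask(record.swir, layout)
    calibrated = SampleRecord(
        sample_id=record.sample_id,
        vnir=calibrate(record.vnir, vmask),
        swir=calibrate(record.swir, smask),
        label_year=record.label_year,
    )
    return cfg, calibrated, (vmask, smask), truth
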