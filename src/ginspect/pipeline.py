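"""End-to-end convenience layer: raw scene -> calibrated sample -> features.

These helpers wire the stage modules together the way the command-line tool
and the experiments use them: segmentation, column-wise calibration, curve
extraction, and (optionally) the optimal-band image stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_selection import SelectedBands, stack_selected
from .calibration import calibrate
from .hsi_io import SampleRecord
from .segmentation import RoiMask, SceneLayout, build_mask
from .spectra import SpectralCurve, extract_curve
from .synthetic import GeneratorConfig, make_reflectance_curve, render_scene


@dataclass
class FeatureSet:
    """Model-ready features for a set of samples."""

    x_spec: np.ndarray                 # samples x bands mean-reflectance curves
    x_img: np.ndarray | None           # samples x H x W x C stacks (or None)
    y_year: np.ndarray
    sample_ids: list[str]


def calibrate_sample(
    sample: SampleRecord, layout: SceneLayout
) -> tuple[SampleRecord, tuple[RoiMask, RoiMask]]:
    """Segment and calibrate both cubes of a raw (DN) sample."""
    vnir_mask = build_mask(sample.vnir, layout)
    swir_mask = build_mask(sample.swir, layout)
    return (
        SampleRecord(
            sample_id=sample.sample_id,
            vnir=calibrate(sample.vnir, vnir_mask),
            swir=calibrate(sample.swir, swir_mask),
            label_year=sample.label_year,
        ),
        (vnir_mask, swir_mask),
    )


def process_sample(
    sample: SampleRecord,
    layout: SceneLayout,
    bands: SelectedBands | None = None,
    image_shape: tuple[int, int] = (256, 1024),
) -> tuple[SpectralCurve, np.ndarray | None, SampleRecord]:
    """Raw sample -> (spectral curve, optional image stack, calibrated record)."""
    calibrated, masks = calibrate_sample(sample, layout)
    curve = extract_curve(calibrated, masks)
    stack = stack_selected(calibrated, bands, image_shape) if bands is not None else None
    return curve, stack, calibrated


def simulate_features(
    cfg: GeneratorConfig,
    bands: SelectedBands | None = None,
    image_shape: tuple[int, int] = (64, 256),
    keep_calibrated: bool = False,
) -> FeatureSet | tuple[FeatureSet, list[SampleRecord]]:
    """Generate scenes from ``cfg`` and push each through the full pipeline
    (segmentation -> calibration -> curve -> stack), sample by sample so only
    one cube pair is in memory at a time."""
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    curves, stacks, years, ids, kept = [], [], [], [], []
    for year, count in enumerate(cfg.samples_per_year, start=1):
        for k in range(count):
            sid = f"y{year}_{k:02d}"
            true_curve = make_reflectance_curve(year, cfg, rng)
            record, _truth = render_scene(true_curve, cfg, rng, sample_id=sid, label_year=year)
            curve, stack, calibrated = process_sample(record, layout, bands, image_shape)
            curves.append(curve.values)
            if stack is not None:
                stacks.append(stack)
            years.append(year)
            ids.append(sid)
            if keep_calibrated:
                kept.append(calibrated)
    features = FeatureSet(
        x_spec=np.stack(curves),
        x_img=np.stack(stacks) if stacks else None,
        y_year=np.asarray(years),
        sample_ids=ids,
    )
    if keep_calibrated:
        return features, kept
    return features
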