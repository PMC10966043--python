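"""Synthetic hyperspectral scene generator.

Emulates the statistical structure of push-broom scans of plant roots next to
a Lambertian whiteboard strip, so every pipeline stage can be exercised
without instrument data:

* raw DN cubes with a multiplicative column illumination profile (bright
  center, dark edges) and multiplicative sensor noise of a chosen SNR;
* a whiteboard strip across the full sensor width whose edge rows are
  brightened by stray-light flare;
* per-year reflectance signatures: a reflectance peak near 800 nm, a
  VNIR-SWIR level gap at the 1000 nm range boundary that shrinks linearly
  with age, a small per-year level shift, and a set of planted discriminative
  bands with year-proportional contrasts;
* an elliptical sample region with smooth multiplicative spatial texture
  (normalized to mean 1 over the region, so per-band region means equal the
  true curve exactly in the noise-free case).

Default sample counts per year mirror a 84-specimen survey
(17/11/12/12/8/12/12 for years 1..7).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import hsi_io
from .errors import DomainError
from .hsi_io import HyperCube, SampleRecord
from .segmentation import SceneLayout


@dataclass
class GeneratorConfig:
    """All knobs of the scene generator (fully seeded)."""

    samples_per_year: tuple[int, ...] = (17, 11, 12, 12, 8, 12, 12)
    n_vnir: int = 288
    n_swir: int = 108
    rows: int = 128
    cols: int = 512
    whiteboard_rows: tuple[int, int] = (8, 40)
    flare_width: int = 3          # rows of flare at each strip edge
    flare_boost: float = 1.6      # brightness factor of flare rows
    flare_margin: int = 5         # erosion handed to segmentation layouts
    illum_a: float = 0.3          # quadratic column falloff (0 = flat)
    gain: float = 3000.0          # DN per unit reflectance at full light
    snr: float | None = 100.0     # multiplicative noise 1/SNR; None = noise-free
    vnir_level: float = 0.30
    level_step: float = 0.012     # per-year VNIR level increment
    peak_center: float = 800.0
    peak_height: float = 0.22
    peak_sigma: float = 110.0
    gap0: float = 0.12            # VNIR-SWIR gap for year 1; shrinks to 0 at year 7
    swir_end_factor: float = 0.85  # SWIR level at 2500 nm relative to its start
    planted_bands: tuple[int, ...] = (60, 140, 220, 308, 358)  # global indices
    planted_effect: float = 0.05
    sample_sigma: float = 0.05    # between-sample log-normal scatter
    curve_noise: float = 0.003    # per-band noise for curve-level datasets
    texture_sigma: float = 0.12
    texture_scale: float = 4.0
    ellipse_center: tuple[float, float] = (0.66, 0.5)   # fractions of rows/cols
    ellipse_radii: tuple[float, float] = (0.22, 0.30)
    background_rho: float = 0.02
    min_rho: float = 0.05
    seed: int = 0

    @property
    def n_bands(self) -> int:
        return self.n_vnir + self.n_swir

    def wavelengths(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            hsi_io.default_wavelengths("VNIR", self.n_vnir),
            hsi_io.default_wavelengths("SWIR", self.n_swir),
        )

    def gap(self, year: int) -> float:
        """Planted VNIR-SWIR boundary gap for a growth year."""
        return self.gap0 * (1.0 - (year - 1) / 6.0)

    def layout(self) -> SceneLayout:
        """Segmentation layout matching the generated geometry."""
        area = int(np.pi * self.ellipse_radii[0] * self.rows * self.ellipse_radii[1] * self.cols)
        return SceneLayout(
            whiteboard_rows=self.whiteboard_rows,
            flare_margin=self.flare_margin,
            min_component_px=min(50, max(1, area // 4)),
        )


@dataclass
class GroundTruth:
    """What the generator knows about one sample (the test oracle)."""

    sample_id: str
    label_year: int
    curve: np.ndarray           # true reflectance, VNIR then SWIR
    groi: np.ndarray            # true sample mask
    wroi: np.ndarray            # full whiteboard strip (including flare rows)
    illum: np.ndarray           # column illumination profile


def base_curve(year: int, cfg: GeneratorConfig) -> np.ndarray:
    """Analytic noise-free reflectance curve for a growth year."""
    if not 1 <= year <= 7:
        raise DomainError(f"year must be in 1..7, got {year}")
    wl_v, wl_s = cfg.wavelengths()
    level = cfg.vnir_level + cfg.level_step * (year - 1)
    peak = cfg.peak_height * np.exp(-((wl_v - cfg.peak_center) ** 2) / (2 * cfg.peak_sigma**2))
    vnir = level + peak
    v1000 = level + cfg.peak_height * np.exp(
        -((1000.0 - cfg.peak_center) ** 2) / (2 * cfg.peak_sigma**2)
    )
    s_start = v1000 - cfg.gap(year)
    frac = (wl_s - wl_s[0]) / (wl_s[-1] - wl_s[0])
    swir = s_start * (1.0 - (1.0 - cfg.swir_end_factor) * frac)
    curve = np.concatenate([vnir, swir])
    for b in cfg.planted_bands:
        if not 0 <= b < curve.size:
            raise DomainError(f"planted band index {b} outside 0..{curve.size - 1}")
        curve[b] += cfg.planted_effect * (year - 4) / 3.0
    return np.maximum(curve, cfg.min_rho)


def make_reflectance_curve(
    year: int, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """One sample's true curve: the analytic base times a log-normal
    between-sample factor."""
    curve = base_curve(year, cfg)
    if cfg.sample_sigma > 0:
        curve = curve * np.exp(rng.normal(0.0, cfg.sample_sigma))
    return curve


def make_curve_dataset(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Curve-level dataset (no scene rendering): returns
    ``(X, y_year, wavelengths, range_tags)``."""
    rng = rng or np.random.default_rng(cfg.seed)
    wl_v, wl_s = cfg.wavelengths()
    rows, years = [], []
    for year, count in enumerate(cfg.samples_per_year, start=1):
        for _ in range(count):
            curve = make_reflectance_curve(year, cfg, rng)
            if cfg.curve_noise > 0:
                curve = curve + rng.normal(0.0, cfg.curve_noise, curve.size)
            rows.append(np.maximum(curve, 0.0))
            years.append(year)
    wavelengths = np.concatenate([wl_v, wl_s])
    range_tags = np.array(["VNIR"] * cfg.n_vnir + ["SWIR"] * cfg.n_swir)
    return np.stack(rows), np.asarray(years), wavelengths, range_tags


def _scene_masks(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    r0, r1 = cfg.whiteboard_rows
    if not 0 <= r0 < r1 <= cfg.rows:
        raise DomainError(f"whiteboard_rows {cfg.whiteboard_rows} do not fit {cfg.rows} rows")
    cr = cfg.ellipse_center[0] * (cfg.rows - 1)
    cc = cfg.ellipse_center[1] * (cfg.cols - 1)
    ra = cfg.ellipse_radii[0] * cfg.rows
    rb = cfg.ellipse_radii[1] * cfg.cols
    rr, jj = np.ogrid[: cfg.rows, : cfg.cols]
    groi = ((rr - cr) / ra) ** 2 + ((jj - cc) / rb) ** 2 <= 1.0
    wroi = np.zeros((cfg.rows, cfg.cols), dtype=bool)
    wroi[r0:r1, :] = True
    if not groi.any():
        raise DomainError("sample ellipse is empty; scene too small")
    if (groi & wroi).any():
        raise DomainError("sample ellipse overlaps the whiteboard strip")
    return groi, wroi


def _texture(cfg: GeneratorConfig, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.texture_sigma <= 0:
        return np.ones((cfg.rows, cfg.cols))
    f = gaussian_filter(rng.standard_normal((cfg.rows, cfg.cols)), cfg.texture_scale)
    std = f.std()
    if std > 0:
        f = f / std
    tex = np.maximum(1.0 + cfg.texture_sigma * f, 0.1)
    return tex / tex[mask].mean()  # region mean exactly 1


def render_scene(
    curve: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    label_year: int = 1,
) -> tuple[SampleRecord, GroundTruth]:
    """Render one sample's (VNIR, SWIR) DN cubes from a true curve.

    ``DN(i, j, band) = gain * illum(j) * rho_scene(i, j, band) * (1 + noise)``
    where the scene reflectance is 1 on the whiteboard (boosted at its flare
    rows), the textured true curve on the sample ellipse, and a dark
    background elsewhere.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size != cfg.n_bands:
        raise DomainError(f"curve has {curve.size} bands, config implies {cfg.n_bands}")
    groi, wroi = _scene_masks(cfg)

    r0, r1 = cfg.whiteboard_rows
    flare = np.ones(cfg.rows)
    if cfg.flare_width > 0:
        flare[r0 : r0 + cfg.flare_width] = cfg.flare_boost
        flare[max(r0, r1 - cfg.flare_width) : r1] = cfg.flare_boost
    half = (cfg.cols - 1) / 2.0
    illum = 1.0 - cfg.illum_a * ((np.arange(cfg.cols) - half) / half) ** 2

    wl_v, _ = cfg.wavelengths()
    cubes = {}
    for tag, sl in (("VNIR", slice(0, cfg.n_vnir)), ("SWIR", slice(cfg.n_vnir, cfg.n_bands))):
        spectrum = curve[sl]
        tex = _texture(cfg, groi, rng)
        cube = np.full((cfg.rows, cfg.cols, spectrum.size), cfg.background_rho)
        cube[wroi] = flare[np.nonzero(wroi)[0]][:, None] * np.ones(spectrum.size)
        cube[groi] = tex[groi][:, None] * spectrum[None, :]
        cube *= cfg.gain * illum[None, :, None]
        if cfg.snr is not None and np.isfinite(cfg.snr):
            cube *= 1.0 + rng.normal(0.0, 1.0 / cfg.snr, cube.shape)
            np.maximum(cube, 0.0, out=cube)
        cubes[tag] = HyperCube(
            data=cube,
            wavelengths=hsi_io.default_wavelengths(tag, spectrum.size),
            range_tag=tag,
            value_kind="dn",
        )
    record = SampleRecord(
        sample_id=sample_id, vnir=cubes["VNIR"], swir=cubes["SWIR"], label_year=label_year
    )
    truth = GroundTruth(
        sample_id=sample_id,
        label_year=label_year,
        curve=curve,
        groi=groi,
        wroi=wroi,
        illum=illum,
    )
    return record, truth


def make_dataset(
    cfg: GeneratorConfig,
    out_dir: str | Path | None = None,
    keep_cubes: bool = True,
) -> tuple[list[SampleRecord], list[GroundTruth], dict]:
    """Generate the full labeled dataset; optionally persist it.

    With ``out_dir`` set, writes per-sample ENVI cube pairs, ``labels.csv``,
    a ``ground_truth.npz`` bundle and a ``manifest.json`` echoing the config.
    Everything is derived from ``cfg.seed``.  ``keep_cubes=False`` (only
    meaningful together with ``out_dir``) streams samples to disk without
    accumulating them in memory — full-size scenes are large.
    """
    if not keep_cubes and out_dir is None:
        raise DomainError("keep_cubes=False requires an out_dir to stream to")
    rng = np.random.default_rng(cfg.seed)
    samples: list[SampleRecord] = []
    truths: list[GroundTruth] = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for year, count in enumerate(cfg.samples_per_year, start=1):
        for k in range(count):
            sid = f"y{year}_{k:02d}"
            curve = make_reflectance_curve(year, cfg, rng)
            record, truth = render_scene(curve, cfg, rng, sample_id=sid, label_year=year)
            if out is not None:
                vp = hsi_io.write_cube(record.vnir, out / f"{sid}_vnir.img")
                sp = hsi_io.write_cube(record.swir, out / f"{sid}_swir.img")
                rows.append(
                    {"sample_id": sid, "label_year": year, "vnir": vp.name, "swir": sp.name}
                )
            if keep_cubes:
                samples.append(record)
            truths.append(truth)
    manifest = {
        "n_samples": len(truths),
        "config": dataclasses.asdict(cfg),
    }
    if out is not None:
        pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(
            out / "ground_truth.npz",
            curves=np.stack([t.curve for t in truths]),
            groi=np.stack([t.groi for t in truths]),
            wroi=np.stack([t.wroi for t in truths]),
            years=np.array([t.label_year for t in truths]),
        )
    return samples, truths, manifest
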