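"""Scene segmentation: split a raw cube into sample region (GROI),
white-reference region (WROI) and background, and trim noisy end bands.

The scanner images each specimen next to a Lambertian whiteboard strip that
runs across the full sensor width (so every image column contains reference
pixels — the column-wise calibration in :mod:`ginspect.calibration` needs
that).  The strip's row span is fixed by the acquisition geometry and is
therefore a layout input, not something detected per scene.  Segmentation
itself is a single Otsu binarization of the gray-scale image at a reference
wavelength (622 nm for VNIR, 1597 nm for SWIR): bright pixels inside the
whiteboard span become WROI (then eroded to drop flare-contaminated edge
pixels), bright pixels outside it become GROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from . import hsi_io
from .errors import DomainError, SegmentationError
from .hsi_io import HyperCube

DEFAULT_REF_WAVELENGTH = {"VNIR": 622.0, "SWIR": 1597.0}


@dataclass
class SceneLayout:
    """Fixed acquisition geometry and segmentation knobs.

    Parameters
    ----------
    whiteboard_rows
        Half-open ``(start, stop)`` row span of the whiteboard strip.
    flare_margin
        Pixels eroded off the whiteboard mask to exclude stray-light flare at
        the strip edges.
    ref_wavelength_vnir, ref_wavelength_swir
        Gray-scale binarization wavelengths (nm) per camera range.
    min_component_px
        Connected components of the sample mask smaller than this are
        discarded as speckle.
    """

    whiteboard_rows: tuple[int, int]
    flare_margin: int = 5
    ref_wavelength_vnir: float = DEFAULT_REF_WAVELENGTH["VNIR"]
    ref_wavelength_swir: float = DEFAULT_REF_WAVELENGTH["SWIR"]
    min_component_px: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneLayout":
        raw = yaml.safe_load(Path(path).read_text())
        raw["whiteboard_rows"] = tuple(raw["whiteboard_rows"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "whiteboard_rows": list(self.whiteboard_rows),
            "flare_margin": self.flare_margin,
            "ref_wavelength_vnir": self.ref_wavelength_vnir,
            "ref_wavelength_swir": self.ref_wavelength_swir,
            "min_component_px": self.min_component_px,
        }
        Path(path).write_text(yaml.safe_dump(d))

    def ref_wavelength(self, range_tag: str) -> float:
        return self.ref_wavelength_vnir if range_tag == "VNIR" else self.ref_wavelength_swir


@dataclass
class RoiMask:
    """Boolean rasters for the sample (groi) and white reference (wroi)."""

    groi: np.ndarray
    wroi: np.ndarray
    reference_wavelength: float

    def __post_init__(self) -> None:
        self.groi = np.asarray(self.groi, dtype=bool)
        self.wroi = np.asarray(self.wroi, dtype=bool)
        if self.groi.shape != self.wroi.shape:
            raise DomainError("groi and wroi must share a shape")
        if np.any(self.groi & self.wroi):
            raise DomainError("groi and wroi must be disjoint")


def _refined_threshold(values: np.ndarray, max_iter: int = 50) -> float:
    """Otsu's threshold refined to the inter-means fixed point
    (t = midpoint of the two class means), which is insensitive to the
    histogram binning Otsu relies on."""
    t = float(threshold_otsu(values))
    for _ in range(max_iter):
        lower = values[values <= t]
        upper = values[values > t]
        if lower.size == 0 or upper.size == 0:
            break
        t_new = 0.5 * (lower.mean() + upper.mean())
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return t


def build_mask(
    cube: HyperCube,
    layout: SceneLayout,
    reference_wavelength: float | None = None,
) -> RoiMask:
    """Segment a scene into GROI and WROI.

    Binarizes the band nearest ``reference_wavelength`` (default per range)
    with Otsu's threshold; bright pixels inside the whiteboard row span form
    the WROI (eroded by ``layout.flare_margin`` to reject flare), bright
    pixels elsewhere form the GROI (speckle below
    ``layout.min_component_px`` removed).
    """
    if reference_wavelength is None:
        reference_wavelength = layout.ref_wavelength(cube.range_tag)
    gray = cube.band_image(reference_wavelength)  # raises DomainError if out of range

    finite = np.isfinite(gray)
    vals = gray[finite]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise SegmentationError("reference band is constant; cannot binarize")

    r0, r1 = layout.whiteboard_rows
    if not (0 <= r0 < r1 <= gray.shape[0]):
        raise DomainError(f"whiteboard_rows {layout.whiteboard_rows} outside scene of {gray.shape[0]} rows")
    in_span = np.zeros_like(finite)
    in_span[r0:r1, :] = True

    # The scene is trimodal (background << sample << whiteboard), so a single
    # global threshold can land between sample and whiteboard.  The sample is
    # binarized against a threshold computed outside the whiteboard span,
    # where the histogram is bimodal (sample vs background); the whiteboard
    # sits far above that same threshold.  Thresholds are computed on log
    # intensities (the column illumination gradient is multiplicative and
    # would otherwise smear the class modes), seeded with Otsu's value and
    # refined by inter-means iteration so the cut lands in the gap between
    # the classes rather than at a histogram-bin edge inside one of them.
    log_gray = np.log1p(np.maximum(gray, 0.0))
    outside_mask = finite & ~in_span
    outside = log_gray[outside_mask] if in_span.any() else np.log1p(np.maximum(vals, 0.0))
    if outside.size == 0 or np.ptp(outside) == 0:
        raise SegmentationError("no usable pixels outside the whiteboard span")
    thr = _refined_threshold(outside)

    wroi = in_span & finite & (log_gray > thr)
    if layout.flare_margin > 0 and wroi.any():
        wroi = ndimage.binary_erosion(wroi, iterations=layout.flare_margin)

    groi = outside_mask & (log_gray > thr)
    if layout.min_component_px > 1:
        groi = remove_small_objects(groi, max_size=layout.min_component_px - 1)

    if not wroi.any():
        raise SegmentationError("whiteboard region empty after thresholding/erosion")
    if not groi.any():
        raise SegmentationError("sample region empty after thresholding")
    return RoiMask(groi=groi, wroi=wroi, reference_wavelength=reference_wavelength)


def trim_noisy_bands(cube: HyperCube, n_head: int = 0, n_tail: int = 0) -> HyperCube:
    """Drop the first ``n_head`` and last ``n_tail`` bands (high random noise
    at the spectrometer ends).  Defaults keep every band."""
    if n_head < 0 or n_tail < 0:
        raise DomainError("n_head and n_tail must be non-negative")
    if n_head + n_tail >= cube.n_bands:
        raise DomainError(
            f"trimming {n_head}+{n_tail} bands would leave nothing of {cube.n_bands}"
        )
    stop = cube.n_bands - n_tail
    return HyperCube(
        data=cube.data[:, :, n_head:stop],
        wavelengths=cube.wavelengths[n_head:stop],
        range_tag=cube.range_tag,
        value_kind=cube.value_kind,
        interleave=cube.interleave,
    )


def save_mask(mask: RoiMask, path: str | Path) -> Path:
    """Persist a mask as a single-band ENVI raster (0 bg, 1 groi, 2 wroi)."""
    coded = np.zeros(mask.groi.shape, dtype=np.uint8)
    coded[mask.groi] = 1
    coded[mask.wroi] = 2
    cube = HyperCube(
        data=coded[:, :, None],
        wavelengths=np.array([mask.reference_wavelength]),
        range_tag="VNIR" if mask.reference_wavelength <= 1100 else "SWIR",
        value_kind="dn",
    )
    return hsi_io.write_cube(cube, path)


def load_mask(path: str | Path) -> RoiMask:
    cube = hsi_io.read_cube(path)
    coded = cube.data[:, :, 0]
    return RoiMask(
        groi=coded == 1,
        wroi=coded == 2,
        reference_wavelength=float(cube.wavelengths[0]),
    )
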