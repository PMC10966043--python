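"""Mean-reflectance spectral curves.

Each calibrated sample is reduced to one curve of per-band GROI means:

    rho_lambda_I = sum(rho_lambda over GROI pixels) / N_GROI

concatenated VNIR-ascending then SWIR-ascending (288 + 108 = 396 points under
the default band counts).  The two camera ranges overlap near 1000 nm and the
overlap is kept in both segments, so the wavelength vector is increasing
within each segment but steps back at the VNIR/SWIR boundary — the familiar
discontinuity in the plotted curves.  No smoothing or scatter correction is
applied; the curve is the raw model input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DomainError
from .hsi_io import HyperCube, SampleRecord
from .segmentation import RoiMask


@dataclass
class SpectralCurve:
    """One sample's mean reflectance per band (VNIR block then SWIR block)."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_id: str
    n_groi: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ConsistencyError("curve values and wavelengths differ in length")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DomainError("curve values must be finite and non-negative")

    def __len__(self) -> int:
        return self.values.size


def band_mean(refl: HyperCube, mask: RoiMask, band_index: int) -> float:
    """Mean reflectance of the sample region in one band."""
    if refl.value_kind != "reflectance":
        raise DomainError("band_mean expects a calibrated (reflectance) cube")
    if not 0 <= band_index < refl.n_bands:
        raise DomainError(f"band index {band_index} out of range 0..{refl.n_bands - 1}")
    if not mask.groi.any():
        raise DomainError("sample region is empty")
    return float(refl.data[:, :, band_index][mask.groi].mean())


def extract_curve(
    sample: SampleRecord,
    masks: tuple[RoiMask, RoiMask],
) -> SpectralCurve:
    """Reduce a calibrated sample to its full spectral curve.

    ``masks`` is the (VNIR, SWIR) mask pair.  With default band counts the
    result has 396 points.
    """
    vnir_mask, swir_mask = masks
    parts = []
    wavelengths = []
    n_groi = {}
    for cube, mask in ((sample.vnir, vnir_mask), (sample.swir, swir_mask)):
        if cube.value_kind != "reflectance":
            raise DomainError(f"{cube.range_tag} cube is not calibrated")
        if not mask.groi.any():
            raise DomainError(f"{cube.range_tag} sample region is empty")
        # per-band mean over the GROI, vectorized (equals a band loop exactly)
        vals = cube.data[mask.groi].mean(axis=0)
        if not np.all(np.isfinite(vals)):
            raise DomainError(f"{cube.range_tag} curve contains non-finite values")
        parts.append(vals)
        wavelengths.append(cube.wavelengths)
        n_groi[cube.range_tag] = int(mask.groi.sum())
    return SpectralCurve(
        values=np.concatenate(parts),
        wavelengths=np.concatenate(wavelengths),
        sample_id=sample.sample_id,
        n_groi=n_groi,
    )


def curve_matrix(
    curves: list[SpectralCurve],
    label_years: list[int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack curves into a samples x bands feature matrix.

    Returns ``(X, y_year, y_use)`` where ``y_use`` is 0 for food (years 1-5)
    and 1 for medicinal (years 6-7).
    """
    if len(curves) < 1:
        raise DomainError("need at least one sample")
    if len(curves) != len(label_years):
        raise ConsistencyError("curves and labels differ in length")
    n = len(curves[0])
    for c in curves:
        if len(c) != n:
            raise ConsistencyError(
                f"sample {c.sample_id!r} has {len(c)} bands, expected {n}"
            )
    X = np.stack([c.values for c in curves])
    y_year = np.asarray(label_years, dtype=int)
    if np.any((y_year < 1) | (y_year > 7)):
        raise DomainError("label years must be in 1..7")
    y_use = (y_year >= 6).astype(int)
    return X, y_year, y_use


def curves_to_frame(curves: list[SpectralCurve], label_years: list[int]) -> pd.DataFrame:
    """Tabular export: sample_id, label_year, one wavelength-named column per band."""
    X, y_year, _ = curve_matrix(curves, label_years)
    wl = curves[0].wavelengths
    tags = ["VNIR"] * len(wl)
    # the wavelength vector steps back at the range boundary; everything after
    # the step belongs to SWIR
    steps = np.flatnonzero(np.diff(wl) < 0)
    if steps.size:
        for i in range(steps[0] + 1, len(wl)):
            tags[i] = "SWIR"
    cols = [f"{t}_{w:.1f}nm" for t, w in zip(tags, wl)]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "label_year", y_year)
    frame.insert(0, "sample_id", [c.sample_id for c in curves])
    return frame
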