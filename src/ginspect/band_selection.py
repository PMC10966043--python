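"""Random-forest band importance ranking and optimal-band image stacks.

A random forest is fit on the full 396-feature curve matrix over repeated
stratified random splits; the impurity-based feature importances of each fit
are recorded per split and averaged.  The top-k bands per spectral range
(default five VNIR and five SWIR) define the channels of the image stack fed
to the convolutional branch of the classifier.  The forest is fit jointly on
both ranges, which also yields the per-range share of total importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from .errors import ConsistencyError, DomainError
from .hsi_io import SampleRecord

__all__ = [
    "BandImportanceTable",
    "SelectedBands",
    "rank_bands",
    "select_top",
    "stack_selected",
]


@dataclass
class BandImportanceTable:
    """Per-band importances across splits, plus aggregate rank.

    ``frame`` columns: wavelength, range, imp_split_1..imp_split_k, imp_mean,
    rank (1 = most important; ties broken toward the lower wavelength).
    """

    frame: pd.DataFrame

    @property
    def n_splits(self) -> int:
        return sum(c.startswith("imp_split_") for c in self.frame.columns)

    def range_share(self, range_tag: str) -> float:
        """Fraction of total aggregate importance carried by one range."""
        total = self.frame["imp_mean"].sum()
        if total == 0:
            return 0.0
        return float(self.frame.loc[self.frame["range"] == range_tag, "imp_mean"].sum() / total)

    @property
    def vnir_share(self) -> float:
        return self.range_share("VNIR")

    @property
    def swir_share(self) -> float:
        return self.range_share("SWIR")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class SelectedBands:
    """Bands chosen for the image stack, in channel order (VNIR block
    wavelength-ascending, then SWIR block wavelength-ascending)."""

    entries: list[tuple[str, float]] = field(default_factory=list)  # (range_tag, wavelength)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def wavelengths(self) -> list[float]:
        return [w for _, w in self.entries]

    @property
    def range_tags(self) -> list[str]:
        return [t for t, _ in self.entries]


def rank_bands(
    features: np.ndarray,
    labels: np.ndarray,
    wavelengths: np.ndarray,
    range_tags: np.ndarray,
    n_splits: int = 10,
    seed: int = 0,
    test_size: int | float = 0.2,
    n_estimators: int = 500,
    max_features: str | float = "sqrt",
    aggregate: str = "mean",
) -> BandImportanceTable:
    """Rank band importance over ``n_splits`` repeated stratified splits.

    Each split fits a :class:`RandomForestClassifier` on the training portion
    only and records its normalized impurity importances (they sum to 1 over
    all bands).  Deterministic for a fixed ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    wavelengths = np.asarray(wavelengths, dtype=float)
    range_tags = np.asarray(range_tags)
    if X.ndim != 2:
        raise DomainError("features must be a 2-D samples x bands matrix")
    if X.shape[0] != y.size:
        raise ConsistencyError("features and labels differ in sample count")
    if X.shape[1] != wavelengths.size or X.shape[1] != range_tags.size:
        raise ConsistencyError("wavelengths/range_tags must match the band count")
    if np.unique(y).size < 2:
        raise DomainError("band ranking needs at least two classes")
    if n_splits < 1:
        raise DomainError("n_splits must be >= 1")
    if aggregate not in ("mean", "median"):
        raise DomainError("aggregate must be 'mean' or 'median'")

    splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
    imps = np.empty((n_splits, X.shape[1]))
    for k, (train_idx, _test_idx) in enumerate(splitter.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=seed + k,
            n_jobs=1,
        )
        rf.fit(X[train_idx], y[train_idx])
        imps[k] = rf.feature_importances_

    agg = imps.mean(axis=0) if aggregate == "mean" else np.median(imps, axis=0)
    # rank 1 = largest aggregate importance; ties go to the lower wavelength
    order = np.lexsort((wavelengths, -agg))
    rank = np.empty(X.shape[1], dtype=int)
    rank[order] = np.arange(1, X.shape[1] + 1)

    data = {"wavelength": wavelengths, "range": range_tags}
    for k in range(n_splits):
        data[f"imp_split_{k + 1}"] = imps[k]
    data["imp_mean"] = agg
    data["rank"] = rank
    return BandImportanceTable(frame=pd.DataFrame(data))


def select_top(table: BandImportanceTable, k_vnir: int = 5, k_swir: int = 5) -> SelectedBands:
    """Pick the ``k`` highest-aggregate-importance bands within each range,
    returned wavelength-sorted (VNIR block first)."""
    entries: list[tuple[str, float]] = []
    for tag, k in (("VNIR", k_vnir), ("SWIR", k_swir)):
        sub = table.frame[table.frame["range"] == tag]
        if k > len(sub):
            raise DomainError(f"k_{tag.lower()}={k} exceeds the {len(sub)} {tag} bands")
        if k == 0:
            continue
        top = sub.sort_values(["imp_mean", "wavelength"], ascending=[False, True]).head(k)
        for w in sorted(top["wavelength"]):
            entries.append((tag, float(w)))
    return SelectedBands(entries=entries)


def _fit_to_grid(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor rescale preserving aspect ratio, zero-padded and
    centered on the target grid (also co-registers SWIR onto the common
    grid; the two cameras have different native geometries)."""
    h, w = img.shape
    th, tw = shape
    scale = min(th / h, tw / w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    scaled = resize(img, (nh, nw), order=0, preserve_range=True, anti_aliasing=False)
    out = np.zeros(shape, dtype=float)
    r0 = (th - nh) // 2
    c0 = (tw - nw) // 2
    out[r0 : r0 + nh, c0 : c0 + nw] = scaled
    return out


def stack_selected(
    sample: SampleRecord,
    bands: SelectedBands,
    out_shape: tuple[int, int] = (256, 1024),
) -> np.ndarray:
    """Stack the selected band images of a calibrated sample into a
    ``rows x cols x channels`` array sized for the image branch.

    Off-sample sentinel pixels become 0; channels follow the selection order.
    """
    if len(bands) == 0:
        raise DomainError("cannot build a zero-channel image stack")
    channels = []
    for tag, wl in bands.entries:
        cube = sample.vnir if tag == "VNIR" else sample.swir
        if cube.value_kind != "reflectance":
            raise DomainError(f"{tag} cube is not calibrated")
        img = cube.band_image(wl)  # DomainError if wavelength outside range
        img = np.where(np.isfinite(img), img, 0.0)
        channels.append(_fit_to_grid(img, out_shape))
    return np.stack(channels, axis=-1)
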