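"""ENVI-style hyperspectral cube I/O and the in-memory cube data model.

A scene is stored as a header/binary file pair (``.hdr`` + ``.img``) in the
plain-text ENVI dialect that push-broom instruments in the HySpex class emit.
All three classic interleaves (BSQ, BIL, BIP) are accepted on read; in memory
a cube is always ``rows x cols x bands`` (band-last), with the row index
running along the scan direction and the column index across the sensor
width.  The band axis is wavelength-ascending after reading regardless of the
storage order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConsistencyError, DomainError, EnviFormatError

logger = logging.getLogger(__name__)

#: Default band counts / spectral ranges of the two camera heads (nm).
VNIR_BANDS = 288
VNIR_RANGE = (400.0, 1000.0)
SWIR_BANDS = 108
SWIR_RANGE = (930.0, 2500.0)

# ENVI "data type" codes <-> numpy dtypes.
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
    15: np.uint64,
}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")

_KNOWN_KEYS = {
    "description", "samples", "lines", "bands", "interleave", "data type",
    "byte order", "header offset", "wavelength", "wavelength units",
    "value_kind", "range_tag", "file type", "sensor type",
}


def default_wavelengths(range_tag: str, n_bands: int | None = None) -> np.ndarray:
    """Evenly spaced band-center wavelengths (nm) for a camera range."""
    tag = range_tag.upper()
    if tag == "VNIR":
        lo, hi = VNIR_RANGE
        n = VNIR_BANDS if n_bands is None else n_bands
    elif tag == "SWIR":
        lo, hi = SWIR_RANGE
        n = SWIR_BANDS if n_bands is None else n_bands
    else:
        raise DomainError(f"unknown range tag {range_tag!r} (expected VNIR or SWIR)")
    return np.linspace(lo, hi, n)


@dataclass(eq=False)
class HyperCube:
    """A 3-D raster of raw digital numbers (DN) or reflectance.

    Parameters
    ----------
    data
        ``rows x cols x bands`` array.  DN cubes must be non-negative.
    wavelengths
        Per-band center wavelengths in nm, strictly increasing.
    range_tag
        ``"VNIR"`` or ``"SWIR"``.
    value_kind
        ``"dn"`` for raw counts, ``"reflectance"`` after calibration.
    interleave
        Interleave the cube was stored with (bookkeeping only; in memory the
        layout is always band-last).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    range_tag: str
    value_kind: str = "dn"
    interleave: str = "bsq"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ConsistencyError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ConsistencyError(
                f"wavelength count {self.wavelengths.size} != band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConsistencyError("wavelengths must be strictly increasing")
        if self.range_tag not in ("VNIR", "SWIR"):
            raise DomainError(f"range_tag must be VNIR or SWIR, got {self.range_tag!r}")
        if self.value_kind not in ("dn", "reflectance"):
            raise DomainError(f"value_kind must be dn or reflectance, got {self.value_kind!r}")
        if self.interleave not in _INTERLEAVES:
            raise DomainError(f"interleave must be one of {_INTERLEAVES}, got {self.interleave!r}")
        if self.value_kind == "dn" and self.data.size and np.nanmin(self.data) < 0:
            raise DomainError("DN cubes must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength: float) -> int:
        """Index of the band whose center is nearest ``wavelength`` (nm).

        Raises :class:`DomainError` if the wavelength falls outside the
        cube's spectral range.
        """
        wl = self.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise DomainError(
                f"wavelength {wavelength} nm outside {self.range_tag} range "
                f"[{wl[0]:.0f}, {wl[-1]:.0f}] nm"
            )
        return int(np.argmin(np.abs(wl - wavelength)))

    def band_image(self, wavelength: float) -> np.ndarray:
        """2-D gray-scale image of the band nearest ``wavelength``."""
        return self.data[:, :, self.band_index(wavelength)]


@dataclass
class SampleRecord:
    """One physical specimen: its paired VNIR/SWIR cubes and labels."""

    sample_id: str
    vnir: HyperCube
    swir: HyperCube
    label_year: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.label_year) <= 7:
            raise DomainError(f"label_year must be in 1..7, got {self.label_year}")
        self.label_year = int(self.label_year)

    @property
    def label_use(self) -> str:
        """Usage class derived from age: years 1-5 are sold as food,
        years 6-7 as medicinal material."""
        return "food" if self.label_year <= 5 else "medicinal"


# -- ENVI header parsing -------------------------------------------------------


def _parse_header(text: str, path: Path) -> dict:
    body = text.strip()
    if body.upper().startswith("ENVI"):
        body = body[4:]
    fields: dict[str, str] = {}
    # key = value, where a value opening with "{" runs until the matching "}".
    pos = 0
    pattern = re.compile(r"^\s*([\w ][\w ]*?)\s*=\s*", re.M)
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        start = m.end()
        if start < len(body) and body[start] == "{":
            end = body.find("}", start)
            if end < 0:
                raise EnviFormatError(f"{path}: unterminated '{{' in field {key!r}")
            value = body[start + 1 : end]
            pos = end + 1
        else:
            nl = body.find("\n", start)
            nl = len(body) if nl < 0 else nl
            value = body[start:nl]
            pos = nl
        fields[key] = value.strip()
    for key in fields:
        if key not in _KNOWN_KEYS:
            logger.warning("%s: ignoring unknown header key %r", path, key)
    return fields


def _require_int(fields: dict, key: str, path: Path) -> int:
    if key not in fields:
        raise EnviFormatError(f"{path}: missing required header field {key!r}")
    try:
        return int(fields[key])
    except ValueError as exc:
        raise EnviFormatError(f"{path}: field {key!r} is not an integer: {fields[key]!r}") from exc


def _resolve_pair(path: str | Path) -> tuple[Path, Path]:
    """Return (header, binary) for a path naming either half of the pair."""
    p = Path(path)
    if p.suffix == ".hdr":
        hdr = p
        for ext in (".img", ".raw", ""):
            cand = p.with_suffix(ext)
            if cand.exists() and cand != hdr:
                return hdr, cand
        raise EnviFormatError(f"no binary file found next to header {hdr}")
    hdr = p.with_suffix(".hdr")
    if not hdr.exists():
        hdr = Path(str(p) + ".hdr")
    if not hdr.exists():
        raise EnviFormatError(f"no ENVI header found for {p}")
    return hdr, p


def read_cube(path: str | Path, range_tag: str | None = None) -> HyperCube:
    """Read an ENVI header + binary pair into a band-last :class:`HyperCube`.

    ``range_tag`` overrides the header's own tag (useful for files written by
    other software); cubes read from disk keep ``value_kind`` from the header
    and default to ``"dn"``.
    """
    hdr_path, bin_path = _resolve_pair(path)
    fields = _parse_header(hdr_path.read_text(), hdr_path)

    samples = _require_int(fields, "samples", hdr_path)
    lines = _require_int(fields, "lines", hdr_path)
    bands = _require_int(fields, "bands", hdr_path)
    dtype_code = _require_int(fields, "data type", hdr_path)
    if dtype_code not in _DTYPES:
        raise EnviFormatError(f"{hdr_path}: unsupported data type code {dtype_code}")
    interleave = fields.get("interleave", "bsq").strip().lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"{hdr_path}: unknown interleave {interleave!r}")
    byte_order = int(fields.get("byte order", "0"))
    offset = int(fields.get("header offset", "0"))

    if "wavelength" not in fields:
        raise EnviFormatError(f"{hdr_path}: missing required header field 'wavelength'")
    try:
        wavelengths = np.array(
            [float(tok) for tok in fields["wavelength"].replace("\n", ",").split(",") if tok.strip()]
        )
    except ValueError as exc:
        raise EnviFormatError(f"{hdr_path}: unparseable wavelength list") from exc
    if wavelengths.size != bands:
        raise ConsistencyError(
            f"{hdr_path}: header lists {wavelengths.size} wavelengths for {bands} bands"
        )

    dtype = np.dtype(_DTYPES[dtype_code])
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")
    raw = np.fromfile(bin_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ConsistencyError(
            f"{bin_path}: binary holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)
    data = np.ascontiguousarray(data)

    # Band axis is wavelength order in memory, whatever the file stored.
    if np.any(np.diff(wavelengths) < 0):
        order = np.argsort(wavelengths, kind="stable")
        wavelengths = wavelengths[order]
        data = data[:, :, order]

    tag = range_tag or fields.get("range_tag", "").strip().upper()
    if tag not in ("VNIR", "SWIR"):
        # fall back on the spectral range itself
        tag = "VNIR" if wavelengths[-1] <= 1100 else "SWIR"
    return HyperCube(
        data=data,
        wavelengths=wavelengths,
        range_tag=tag,
        value_kind=fields.get("value_kind", "dn").strip().lower(),
        interleave=interleave,
    )


def write_cube(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> Path:
    """Write ``cube`` as an ENVI header + binary pair; returns the binary path.

    The dtype on disk is the cube's own dtype.  ``read_cube(write_cube(c))``
    is the identity on data, wavelengths and metadata.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise DomainError(f"interleave must be one of {_INTERLEAVES}, got {interleave!r}")
    p = Path(path)
    if p.suffix == ".hdr":
        p = p.with_suffix(".img")
    elif p.suffix == "":
        p = p.with_suffix(".img")
    p.parent.mkdir(parents=True, exist_ok=True)

    dtype = np.dtype(cube.data.dtype)
    if dtype not in _CODES:
        dtype = np.dtype(np.float64)
    code = _CODES[dtype]
    data = np.ascontiguousarray(cube.data, dtype=dtype.newbyteorder("<"))

    rows, cols, bands = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    np.ascontiguousarray(out).tofile(p)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"range_tag = {cube.range_tag}\n"
        f"value_kind = {cube.value_kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    p.with_suffix(".hdr").write_text(hdr)
    return p
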