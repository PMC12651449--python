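"""Hyperspectral cube handling: data model, ENVI I/O, radiometric correction,
region-of-interest delineation and mean-spectrum extraction.

The instrument emulated throughout the package is a line-scan VNIR camera
producing cubes of 256 bands over 400-1000 nm.  Raw intensity cubes are
converted to relative reflectance with white/dark reference frames via

    R_c = (I_r - I_d) / (I_w - I_d)

after which a square region of interest centred on the fruit provides the
per-fruit mean spectrum used for model calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralAxis",
    "HyperCube",
    "ReferenceFrames",
    "ROI",
    "radiometric_correct",
    "fruit_mask",
    "auto_roi",
    "mean_spectrum",
    "read_envi",
    "write_envi",
    "EnviFormatError",
]

#: native detector geometry of the emulated instrument (lines x samples)
INSTRUMENT_LINES = 1040
INSTRUMENT_SAMPLES = 1392
#: ROI edge length, in pixels, at full instrument scale
FULL_SCALE_ROI = 110


@dataclass(frozen=True)
class SpectralAxis:
    """Band-index <-> wavelength mapping.

    Defaults to 256 evenly spaced bands spanning 400-1000 nm inclusive
    (sampling interval ~2.353 nm).
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(400.0, 1000.0, 256)
    )

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelengths must be a 1-D array of length >= 2")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_bands


@dataclass
class HyperCube:
    """A (height, width, bands) array plus its spectral axis.

    ``kind`` records whether values are raw intensities or corrected
    reflectance; corrected values normally lie in [0, ~1.5] (specular pixels
    may exceed 1 and are retained, not clipped).
    """

    data: np.ndarray
    axis: SpectralAxis
    kind: str = "raw"  # "raw" | "corrected"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (height, width, bands)")
        if self.data.shape[2] != self.axis.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but axis has "
                f"{self.axis.n_bands}"
            )
        if self.kind not in ("raw", "corrected"):
            raise ValueError("kind must be 'raw' or 'corrected'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceFrames:
    """White and dark reference frames (2-D per-pixel-per-band or 1-D per-band)."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must have identical shapes")


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular window, 0-based row/col coordinates."""

    row_offset: int
    col_offset: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI extents must be positive")
        if self.row_offset < 0 or self.col_offset < 0:
            raise ValueError("ROI offsets must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_offset, self.row_offset + self.height),
            slice(self.col_offset, self.col_offset + self.width),
        )


def scaled_roi_size(cube_height: int, cube_width: int) -> int:
    """Default ROI edge for a cube, scaling the full-instrument 110 px window
    proportionally to the cube's height relative to the 1040-line detector."""
    size = int(round(FULL_SCALE_ROI * cube_height / INSTRUMENT_LINES))
    return max(size, 3)


def radiometric_correct(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """White/dark radiometric correction: ``(I_r - I_d) / (I_w - I_d)``.

    References may be full frames (height, width, bands) or per-band vectors;
    they broadcast against the cube.  Bands where white <= dark anywhere are
    reported in the raised error.
    """
    ir = np.asarray(raw.data, dtype=float)
    iw, idk = refs.white, refs.dark
    denom = iw - idk
    if np.any(denom <= 0):
        if denom.ndim >= 1:
            bad = np.unique(np.nonzero(np.atleast_1d(denom) <= 0)[-1])
        else:  # pragma: no cover - scalar refs
            bad = np.array([0])
        raise ValueError(
            "white reference does not exceed dark reference at band indices "
            f"{bad.tolist()[:10]}{'...' if bad.size > 10 else ''}"
        )
    rc = (ir - idk) / denom
    return HyperCube(rc, raw.axis, kind="corrected", provenance=raw.provenance)


def fruit_mask(cube: HyperCube, nir_nm: float = 830.0) -> np.ndarray:
    """Boolean fruit/background mask from the band nearest ``nir_nm``.

    Threshold is Otsu's on the NIR band image — the fruit is strongly
    reflective in the NIR while the stage background is dark.
    """
    from skimage.filters import threshold_otsu

    band = np.asarray(cube.data[..., cube.axis.index_of(nir_nm)], dtype=float)
    if np.ptp(band) == 0:
        raise ValueError("NIR band is constant; cannot separate fruit from background")
    return band > threshold_otsu(band)


def auto_roi(cube: HyperCube, size: int | None = None) -> ROI:
    """Square ROI of edge ``size`` centred on the fruit-mask centroid.

    Deterministic automated stand-in for manual ROI delineation.  The default
    size scales the 110 px full-instrument window to the cube's height.
    """
    h, w, _ = cube.shape
    if size is None:
        size = scaled_roi_size(h, w)
    if size > h or size > w:
        raise ValueError(f"requested ROI size {size} exceeds cube extent {h}x{w}")
    mask = fruit_mask(cube)
    if mask.sum() < size * size:
        raise ValueError(
            f"fruit mask has {int(mask.sum())} pixels, fewer than the "
            f"{size * size} required for a {size}x{size} ROI"
        )
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    r0 = int(round(cr - size / 2))
    c0 = int(round(cc - size / 2))
    r0 = min(max(r0, 0), h - size)
    c0 = min(max(c0, 0), w - size)
    return ROI(r0, c0, size, size)


def mean_spectrum(cube: HyperCube, roi: ROI) -> np.ndarray:
    """Per-band arithmetic mean over the ROI pixels (length = n_bands)."""
    rs, cs = roi.slices()
    if roi.row_offset + roi.height > cube.shape[0] or (
        roi.col_offset + roi.width > cube.shape[1]
    ):
        raise ValueError("ROI extends beyond cube bounds")
    return np.asarray(cube.data[rs, cs, :], dtype=float).mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

class EnviFormatError(ValueError):
    """Raised for malformed ENVI headers or payloads."""


_DTYPE_TO_ENVI = {
    np.dtype("uint8"): 1, np.dtype("int16"): 2, np.dtype("int32"): 3,
    np.dtype("float32"): 4, np.dtype("float64"): 5,
    np.dtype("uint16"): 12, np.dtype("uint32"): 13,
}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write ``path`` (raw payload) + ``path + '.hdr'`` (ASCII header).

    Band-sequential (bsq) by default; bil/bip supported.  Wavelengths are
    recorded in nanometres.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data)
    if data.dtype not in _DTYPE_TO_ENVI:
        data = data.astype(np.float32)
    lines, samples, bands = data.shape
    if interleave == "bip":
        ordered = data  # (lines, samples, bands)
    elif interleave == "bil":
        ordered = np.transpose(data, (0, 2, 1))  # (lines, bands, samples)
    else:
        ordered = np.transpose(data, (2, 0, 1))  # (bands, lines, samples)
    ordered = np.ascontiguousarray(ordered)
    path.write_bytes(ordered.tobytes())
    wl = ", ".join(f"{w:.4f}" for w in cube.axis.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{{cube.kind} cube; {cube.provenance}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    Path(str(path) + ".hdr").write_text(hdr)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line in header")
    fields: dict[str, str] = {}
    # join continued '{...}' blocks
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq == -1:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1:]
        if rest.lstrip().startswith("{"):
            close = rest.find("}")
            if close == -1:
                raise EnviFormatError(f"unterminated '{{' block for key {key!r}")
            val = rest[rest.find("{") + 1: close]
            i = eq + 1 + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl == -1 else nl
            val = rest[:nl]
            i = eq + 1 + nl
        if key:
            fields[key] = val.strip()
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI cube written by :func:`write_envi` (or compatible).

    A header without a wavelength list yields an index-valued axis and a
    warning rather than an error.
    """
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        alt = path.with_suffix(".hdr")
        if alt.exists():
            hdr_path = alt
        else:
            raise EnviFormatError(f"no header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required key: {exc}") from exc
    if dtype_code not in _ENVI_TO_DTYPE:
        raise EnviFormatError(f"unsupported ENVI data type code {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    dtype = _ENVI_TO_DTYPE[dtype_code]
    raw = np.frombuffer(path.read_bytes(), dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"payload has {raw.size} values, expected {expected} "
            f"({lines}x{samples}x{bands})"
        )
    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    if "wavelength" in fields:
        wl = np.array([float(v) for v in fields["wavelength"].split(",")])
        axis = SpectralAxis(wl)
    else:
        warnings.warn(
            "ENVI header has no wavelength list; using band indices as axis",
            stacklevel=2,
        )
        axis = SpectralAxis(np.arange(bands, dtype=float))
    kind = "corrected" if "corrected" in fields.get("description", "") else "raw"
    return HyperCube(np.ascontiguousarray(data), axis, kind=kind,
                     provenance=str(path))
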