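"""Hyperspectral cube I/O, reflectance correction and ROI spectrum extraction.

Cubes are held as (row, col, band) arrays with a strictly increasing
wavelength vector in nm.  Raw sensor counts are converted to reflectance
against white (Teflon board) and dark (closed shutter) references:

    R = (I_raw - I_dark) / (I_white - I_dark)

Pixels where the white-dark gap is zero (saturated/dead) are flagged NaN
and excluded from every downstream region of interest.  ENVI-style
header + flat-binary files (BSQ/BIL/BIP) are read and written directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SpectralCube",
    "ROIMask",
    "SpectrumSet",
    "correct_reflectance",
    "segment_roi",
    "extract_mean_spectrum",
    "read_envi",
    "write_envi",
]

# ENVI data-type codes <-> numpy dtypes
_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8",
                12: "u2", 13: "u4", 14: "i8", 15: "u8"}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """Reflectance or raw-count cube: data (rows x cols x bands) + wavelengths."""

    data: np.ndarray
    wavelengths: np.ndarray
    role: str = "raw"  # raw | white | dark | corrected
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.wavelengths.size != self.data.shape[2]:
            raise ValueError("wavelength count must equal band count")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROIMask:
    """Boolean foreground mask over the cube's spatial grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SpectrumSet:
    """Samples x bands mean-reflectance matrix with wavelengths and IDs."""

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError("column count must equal wavelength count")
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of sample ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """First row: wavelengths; then one row per sample (id, values)."""
        import pandas as pd

        df = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumSet":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        ids = df["sample_id"].astype(str).tolist()
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(X=df.iloc[:, 1:].to_numpy(float), wavelengths=wl, sample_ids=ids)


def correct_reflectance(raw: SpectralCube, white: SpectralCube,
                        dark: SpectralCube) -> SpectralCube:
    """White/dark reflectance correction; undefined pixels become NaN.

    The correction is invariant to any common gain applied to all three
    cubes.  Elements with white == dark are flagged in
    ``metadata['invalid_mask']`` (2-D: any-band invalid).
    """
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise ValueError("raw, white and dark cubes must share one shape")
    for other in (white, dark):
        if not np.array_equal(raw.wavelengths, other.wavelengths):
            raise ValueError("wavelength grids must be identical")
    gap = white.data.astype(float) - dark.data.astype(float)
    bad = gap == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (raw.data.astype(float) - dark.data.astype(float)) / gap
    out[bad] = np.nan
    return SpectralCube(out, raw.wavelengths, role="corrected",
                        metadata={"invalid_mask": bad.any(axis=2)})


def segment_roi(cube: SpectralCube, band_index: int, method: str = "otsu",
                threshold: float | None = None) -> ROIMask:
    """Foreground mask from one band: threshold, then largest component.

    Pixels flagged invalid by the reflectance correction are excluded.
    ``method='fixed_threshold'`` requires ``threshold``; ``'otsu'``
    chooses it automatically.
    """
    if not 0 <= band_index < cube.shape[2]:
        raise ValueError(f"band_index {band_index} out of range")
    img = cube.data[:, :, band_index].astype(float)
    valid = np.isfinite(img)
    invalid_meta = cube.metadata.get("invalid_mask")
    if invalid_meta is not None:
        valid &= ~np.asarray(invalid_meta, dtype=bool)

    if method == "otsu":
        from skimage.filters import threshold_otsu

        vals = img[valid]
        if vals.size == 0 or np.ptp(vals) == 0:
            raise ValueError("cannot segment: band image is empty or constant")
        thr = float(threshold_otsu(vals))
    elif method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold method requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    fg = valid & (img > thr)
    if not fg.any():
        raise ValueError("empty foreground: threshold or band misconfigured")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return ROIMask(fg)


def extract_mean_spectrum(cube: SpectralCube, mask: ROIMask) -> np.ndarray:
    """Per-band arithmetic mean of reflectance over the masked pixels."""
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match cube spatial shape")
    m = mask.mask
    invalid_meta = cube.metadata.get("invalid_mask")
    if invalid_meta is not None:
        m = m & ~np.asarray(invalid_meta, dtype=bool)
    if not m.any():
        raise ValueError("empty ROI mask")
    spectrum = cube.data[m].mean(axis=0)
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("non-finite reflectance inside ROI")
    return spectrum


# --- ENVI header + flat binary ------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing magic line)")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    fields: dict[str, str] = {}
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, val = (s.strip() for s in line.split("=", 1))
        if val.startswith("{"):
            while "}" not in val and i < len(lines):
                val += " " + lines[i].strip()
                i += 1
            val = val.strip("{} ").strip()
        fields[key.lower()] = val
    return fields


def read_envi(header_path: str | Path) -> SpectralCube:
    """Read an ENVI header + binary cube; returns a (row, col, band) cube.

    BIL/BIP interleaves are converted to the canonical band-sequential
    axis order on read.  A missing ``wavelength`` field is an error.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    if "wavelength" not in fields:
        raise ValueError("ENVI header lacks required 'wavelength' field")
    samples = int(fields["samples"])  # columns
    lines_n = int(fields["lines"])   # rows
    bands = int(fields["bands"])
    dcode = int(fields["data type"])
    if dcode not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dcode}")
    interleave = fields.get("interleave", "bsq").lower()
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(("<" if byte_order == 0 else ">") + _ENVI_DTYPES[dcode])
    wavelengths = np.array([float(w) for w in fields["wavelength"].split(",")])

    data_path = None
    for cand in (header_path.with_suffix(""), header_path.with_suffix(".img"),
                 header_path.with_suffix(".dat"), header_path.with_suffix(".raw")):
        if cand.exists() and cand != header_path:
            data_path = cand
            break
    if data_path is None:
        raise FileNotFoundError(f"no data file found next to {header_path}")

    flat = np.fromfile(data_path, dtype=dtype)
    if flat.size != samples * lines_n * bands:
        raise ValueError("data file size does not match header dimensions")
    if interleave == "bsq":
        cube = flat.reshape(bands, lines_n, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(lines_n, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = flat.reshape(lines_n, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    role = fields.get("description", "raw").strip() or "raw"
    if role not in {"raw", "white", "dark", "corrected"}:
        role = "raw"
    return SpectralCube(np.ascontiguousarray(cube), wavelengths, role=role)


def write_envi(cube: SpectralCube, path_stem: str | Path,
               interleave: str = "bsq") -> tuple[Path, Path]:
    """Write ``<stem>.hdr`` + ``<stem>.img``; round-trips bit-exactly."""
    path_stem = Path(path_stem)
    dtype = np.dtype(cube.data.dtype)
    if dtype.newbyteorder("<") not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} has no ENVI type code")
    rows, cols, bands = cube.shape
    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = cube.data
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    hdr_path = path_stem.with_suffix(".hdr")
    img_path = path_stem.with_suffix(".img")
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        f"description = {cube.role}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype.newbyteorder('<')]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    np.ascontiguousarray(arr).astype(dtype.newbyteorder("<")).tofile(img_path)
    return hdr_path, img_path
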