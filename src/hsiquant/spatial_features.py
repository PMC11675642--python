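"""Spatial image features: GLCM texture statistics and color-space means.

Each sample contributes 14 features: the per-channel means of RGB,
CIE L*a*b* (sRGB companding, D65 white point) and HSV over the ROI
(9 values), plus five gray-level co-occurrence statistics - angular
second moment, contrast, dissimilarity, energy and homogeneity - each
averaged over the four offsets 0/45/90/135 degrees at step length 1 on
a 64-level quantized image.  Co-occurrence counting is mask-aware: a
pixel pair contributes only when both pixels lie inside the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsi_io import ROIMask, SpectralCube

__all__ = [
    "GlcmConfig",
    "ColorFeatures",
    "TextureFeatures",
    "quantize_gray",
    "glcm",
    "texture_features",
    "color_features",
    "rgb_from_bands",
    "spatial_feature_vector",
    "SPATIAL_FEATURE_NAMES",
]

SPATIAL_FEATURE_NAMES = ("R", "G", "B", "L", "a", "b", "H", "S", "V",
                         "ASM", "contrast", "dissimilarity", "energy",
                         "homogeneity")

# angle -> (row offset, col offset), matching the usual GLCM convention
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GlcmConfig:
    levels: int = 64
    distance: int = 1
    symmetric: bool = True
    normalization: bool = True
    angles: tuple[int, ...] = (0, 45, 90, 135)

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        for a in self.angles:
            if a not in _ANGLE_OFFSETS:
                raise ValueError(f"unsupported GLCM angle {a}")


@dataclass
class ColorFeatures:
    r: float; g: float; b: float
    l_star: float; a_star: float; b_star: float
    h: float; s: float; v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b, self.l_star, self.a_star,
                         self.b_star, self.h, self.s, self.v])


@dataclass
class TextureFeatures:
    asm: float
    contrast: float
    dissimilarity: float
    energy: float
    homogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.asm, self.contrast, self.dissimilarity,
                         self.energy, self.homogeneity])


def quantize_gray(image: np.ndarray, mask: np.ndarray | ROIMask,
                  levels: int = 64) -> np.ndarray:
    """Linear min-max binning of masked pixels to integers [0, levels-1].

    A constant image maps to level 0 everywhere.  Pixels outside the
    mask receive level 0 but are never used by the masked GLCM.
    """
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    img = np.asarray(image, dtype=float)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    vals = img[m]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(img.shape, dtype=np.int64)
    if hi > lo:
        scaled = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
        q = np.clip(scaled, 0, levels - 1)
    return q


def glcm(quantized: np.ndarray, mask: np.ndarray | ROIMask, angle: int,
         cfg: GlcmConfig | None = None) -> np.ndarray:
    """Masked gray-level co-occurrence matrix at one angle.

    Counts (i, j) pairs separated by the angle's offset times the step
    length, restricted to pairs with both pixels in the mask;
    symmetrized (both pixel orders) and normalized to sum 1 when
    configured.  Raises if no valid pair exists.
    """
    cfg = cfg or GlcmConfig()
    cfg.validate()
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"unsupported GLCM angle {angle}")
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    q = np.asarray(quantized)
    if q.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if q.min() < 0 or q.max() >= cfg.levels:
        raise ValueError("quantized image exceeds configured levels")

    dr, dc = (d * cfg.distance for d in _ANGLE_OFFSETS[angle])
    rows, cols = q.shape
    r0 = np.arange(max(0, -dr), min(rows, rows - dr))
    c0 = np.arange(max(0, -dc), min(cols, cols - dc))
    if r0.size == 0 or c0.size == 0:
        raise ValueError("no valid pixel pairs at this offset")
    src = np.ix_(r0, c0)
    dst = np.ix_(r0 + dr, c0 + dc)
    valid = m[src] & m[dst]
    if not valid.any():
        raise ValueError("no valid pixel pairs inside the mask")
    i = q[src][valid]
    j = q[dst][valid]
    P = np.zeros((cfg.levels, cfg.levels))
    np.add.at(P, (i, j), 1.0)
    if cfg.symmetric:
        P = P + P.T
    if cfg.normalization:
        P /= P.sum()
    return P


def _texture_from_glcm(P: np.ndarray) -> np.ndarray:
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    d = i - j
    asm = float((P**2).sum())
    return np.array([
        asm,
        float(((d**2) * P).sum()),
        float((np.abs(d) * P).sum()),
        float(np.sqrt(asm)),
        float((P / (1.0 + d**2)).sum()),
    ])


def texture_features(image: np.ndarray, mask: np.ndarray | ROIMask,
                     cfg: GlcmConfig | None = None) -> TextureFeatures:
    """Five GLCM statistics averaged over the configured angles."""
    cfg = cfg or GlcmConfig()
    cfg.validate()
    q = quantize_gray(image, mask, cfg.levels)
    feats = np.mean([_texture_from_glcm(glcm(q, mask, a, cfg))
                     for a in cfg.angles], axis=0)
    return TextureFeatures(*feats)


def color_features(rgb: np.ndarray, mask: np.ndarray | ROIMask) -> ColorFeatures:
    """Masked means of RGB, L*a*b* and HSV channels (per-pixel conversion).

    RGB must be float in [0, 1].  Conversions are applied per pixel and
    then averaged (the order matters for the nonlinear spaces).
    """
    from skimage.color import rgb2hsv, rgb2lab

    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an rows x cols x 3 RGB image")
    if rgb.shape[:2] != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    lab = rgb2lab(rgb)
    hsv = rgb2hsv(rgb)
    means = [rgb[..., k][m].mean() for k in range(3)]
    means += [lab[..., k][m].mean() for k in range(3)]
    means += [hsv[..., k][m].mean() for k in range(3)]
    return ColorFeatures(*means)


def rgb_from_bands(cube: SpectralCube, band_wavelengths: tuple[float, float, float]
                   ) -> np.ndarray:
    """False-color RGB composite from three cube wavelengths.

    Picks the nearest band to each requested wavelength, scales the
    three planes jointly (one min-max over all three) to [0, 1], and
    assigns the longest wavelength to R, middle to G, shortest to B.
    """
    wl = cube.wavelengths
    req = np.asarray(band_wavelengths, dtype=float)
    if req.size != 3:
        raise ValueError("exactly three wavelengths required")
    for w in req:
        if not (wl[0] <= w <= wl[-1]):
            raise ValueError(f"wavelength {w} nm outside cube range "
                             f"[{wl[0]}, {wl[-1]}]")
    idx = [int(np.argmin(np.abs(wl - w))) for w in req]
    order = np.argsort(req)[::-1]  # longest first -> R, G, B
    planes = np.stack([cube.data[:, :, idx[k]] for k in order], axis=-1).astype(float)
    lo, hi = planes.min(), planes.max()
    if hi > lo:
        planes = (planes - lo) / (hi - lo)
    else:
        planes = np.zeros_like(planes)
    return planes


def spatial_feature_vector(rgb: np.ndarray, mask: np.ndarray | ROIMask,
                           cfg: GlcmConfig | None = None) -> np.ndarray:
    """The 14-feature vector: 9 color means then 5 texture statistics.

    The GLCM gray image is the Rec.601 luminance of the RGB composite
    (0.299 R + 0.587 G + 0.114 B).
    """
    color = color_features(rgb, mask).as_array()
    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    tex = texture_features(gray, mask, cfg).as_array()
    return np.concatenate([color, tex])
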