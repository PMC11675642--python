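"""Synthetic hyperspectral chemometrics datasets with planted ground truth.

Emulates the statistical structure the pipeline assumes for dried-flower
(chrysanthemum) samples: SWIR mean-reflectance spectra on a 948-2513 nm
grid (288 bands) whose absorption-related features sit near 1200, 1460,
1730 and 1930 nm, per-sample multiplicative/additive scatter, white noise,
reference concentrations of total flavonoids (TF) and total chlorogenic
acids (TCA) in mg/g, and small RGB images whose mean hue and texture
contrast are coupled to the concentrations.

The generator plants which bands carry signal, so selector recall and
preprocessing fidelity can be measured exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hsi_io import SpectrumSet

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_pure_spectra",
    "generate_dataset",
    "baseline_spectrum",
    "mixture_spectra",
    "planted_regions",
    "planted_region_recall",
    "write_dataset",
]


def _default_wavelengths() -> np.ndarray:
    return np.linspace(948.0, 2513.0, 288)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the study conditions.

    Concentration statistics follow the reference-value summary of the
    real samples (TF mean 126.77, sd 9.97 mg/g; TCA mean 19.57, sd
    0.52 mg/g over 200 groups).  Component loadings are reflectance
    contribution per mg/g at each absorption peak, scaled so each
    component contributes O(0.1) reflectance at its mean content.
    """

    n_samples: int = 200
    wavelength_grid: np.ndarray = field(default_factory=_default_wavelengths)
    peak_centers: tuple[float, ...] = (1200.0, 1460.0, 1730.0, 1930.0)
    peak_widths: tuple[float, ...] = (25.0, 30.0, 25.0, 35.0)
    component_names: tuple[str, ...] = ("TF", "TCA")
    # rows: components, cols: peaks (reflectance per mg/g)
    component_loadings: tuple[tuple[float, ...], ...] = (
        (8.0e-4, 1.0e-3, 2.0e-4, 9.0e-4),
        (5.0e-3, 1.0e-3, 6.0e-3, 2.0e-3),
    )
    concentration_means: tuple[float, ...] = (126.77, 19.57)
    concentration_sds: tuple[float, ...] = (9.97, 0.52)
    scatter_slope_sd: float = 0.08
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.003
    image_size: int = 64
    texture_coupling: float = 1.0
    color_coupling: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        wl = np.asarray(self.wavelength_grid, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength_grid must be strictly increasing")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if len(self.peak_centers) == 0:
            raise ValueError("at least one peak center is required")
        for c in self.peak_centers:
            if not (wl[0] <= c <= wl[-1]):
                raise ValueError(f"peak center {c} nm outside wavelength grid")
        if len(self.peak_widths) != len(self.peak_centers):
            raise ValueError("peak_widths must match peak_centers")
        if len(self.component_names) == 0:
            raise ValueError("at least one component is required")
        if len(self.component_loadings) != len(self.component_names):
            raise ValueError("component_loadings must match component_names")
        for row in self.component_loadings:
            if len(row) != len(self.peak_centers):
                raise ValueError("each loading row must match peak_centers")
        if len(self.concentration_means) != len(self.component_names):
            raise ValueError("concentration_means must match component_names")
        if len(self.concentration_sds) != len(self.component_names):
            raise ValueError("concentration_sds must match component_names")
        for sd in (self.scatter_slope_sd, self.scatter_offset_sd, self.noise_sd,
                   *self.concentration_sds):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.image_size < 4:
            raise ValueError("image_size must be at least 4 pixels")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["wavelength_grid"] = np.asarray(self.wavelength_grid, float).tolist()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["wavelength_grid"] = np.asarray(d["wavelength_grid"], dtype=float)
        for key in ("peak_centers", "peak_widths", "component_names",
                    "concentration_means", "concentration_sds"):
            if key in d:
                d[key] = tuple(d[key])
        if "component_loadings" in d:
            d["component_loadings"] = tuple(tuple(r) for r in d["component_loadings"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    spectra: SpectrumSet
    references: "pd.DataFrame"  # noqa: F821 - imported lazily below
    images: np.ndarray  # (n, size, size, 3) float in [0, 1]
    planted_bands: np.ndarray
    true_scatter: np.ndarray  # (n, 2): slope, offset
    clean_spectra: np.ndarray  # scatter- and noise-free mixtures (n x bands)
    config: SyntheticConfig


def baseline_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth continuum reflectance: a low-order polynomial in wavelength.

    Carries no component information by construction.
    """
    wl = np.asarray(wavelengths, dtype=float)
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.45 + 0.10 * u - 0.08 * u**2


def generate_pure_spectra(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Component pure spectra (components x bands) and planted band indices.

    Each pure spectrum is a non-negative sum of Gaussian peaks on the
    wavelength grid; a band is planted when it lies within two peak
    widths of any peak center.
    """
    config.validate()
    wl = np.asarray(config.wavelength_grid, dtype=float)
    centers = np.asarray(config.peak_centers, dtype=float)
    widths = np.asarray(config.peak_widths, dtype=float)
    loadings = np.asarray(config.component_loadings, dtype=float)

    peaks = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    pure = loadings @ peaks  # (components, bands)

    planted = np.flatnonzero(
        (np.abs(wl[None, :] - centers[:, None]) <= 2.0 * widths[:, None]).any(axis=0)
    )
    return pure, planted


def planted_regions(config: SyntheticConfig) -> list[np.ndarray]:
    """Band indices of each planted peak window (center +/- 2 widths)."""
    wl = np.asarray(config.wavelength_grid, dtype=float)
    return [np.flatnonzero(np.abs(wl - c) <= 2.0 * w)
            for c, w in zip(config.peak_centers, config.peak_widths)]


def planted_region_recall(selected: np.ndarray, config: SyntheticConfig) -> float:
    """Fraction of planted peak regions containing at least one selected band.

    The region level is the meaningful recall for a redundancy-penalized
    selector: adjacent in-region bands are nearly collinear, so a good
    subset keeps a few bands per region rather than whole windows.
    """
    sel = set(np.asarray(selected, dtype=int).tolist())
    regions = planted_regions(config)
    return float(np.mean([bool(sel & set(r.tolist())) for r in regions]))


def mixture_spectra(config: SyntheticConfig, concentrations: np.ndarray) -> np.ndarray:
    """Noiseless, scatter-free forward model: baseline + conc @ pure."""
    pure, _ = generate_pure_spectra(config)
    conc = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if conc.shape[1] != pure.shape[0]:
        raise ValueError("concentration columns must match component count")
    return baseline_spectrum(config.wavelength_grid)[None, :] + conc @ pure


def _draw_concentrations(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Normal draws truncated at zero by resampling (contents are mg/g)."""
    means = np.asarray(config.concentration_means, float)
    sds = np.asarray(config.concentration_sds, float)
    conc = rng.normal(means, sds, size=(config.n_samples, means.size))
    for _ in range(100):
        bad = conc <= 0
        if not bad.any():
            break
        conc[bad] = rng.normal(np.broadcast_to(means, conc.shape)[bad],
                               np.broadcast_to(sds, conc.shape)[bad])
    else:
        raise RuntimeError("could not draw positive concentrations")
    return conc


def _render_images(config: SyntheticConfig, conc: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-sample RGB fields whose mean hue and texture contrast track content.

    The colour/texture driver is a weighted z-score of the component
    contents; hue shifts linearly with it (color_coupling) and the
    amplitude of per-pixel value noise grows with it (texture_coupling).
    """
    from skimage.color import hsv2rgb

    means = np.asarray(config.concentration_means, float)
    sds = np.asarray(config.concentration_sds, float)
    z = (conc - means) / np.where(sds > 0, sds, 1.0)
    weights = np.full(z.shape[1], 1.0 / z.shape[1])
    if z.shape[1] >= 2:
        weights = np.array([0.8, 0.2] + [0.0] * (z.shape[1] - 2))
    drive = z @ weights

    s = config.image_size
    images = np.empty((config.n_samples, s, s, 3))
    for i in range(config.n_samples):
        hue = 0.10 + 0.05 * config.color_coupling * drive[i] \
            + rng.normal(0.0, 0.01)
        hue = float(np.clip(hue, 0.0, 0.95))
        amp = 0.06 * (1.0 + 0.4 * config.texture_coupling * drive[i]) \
            + rng.normal(0.0, 0.01)
        amp = float(np.clip(amp, 0.005, 0.25))
        hsv = np.empty((s, s, 3))
        hsv[..., 0] = np.clip(hue + rng.normal(0.0, 0.01, (s, s)), 0.0, 0.9999)
        hsv[..., 1] = np.clip(0.65 + rng.normal(0.0, 0.02, (s, s)), 0.0, 1.0)
        hsv[..., 2] = np.clip(0.70 + amp * rng.uniform(-1.0, 1.0, (s, s)), 0.0, 1.0)
        images[i] = hsv2rgb(hsv)
    return images


def generate_dataset(config: SyntheticConfig,
                     concentrations: np.ndarray | None = None) -> SyntheticDataset:
    """Full synthetic dataset: spectra, references, images, ground truth.

    spectrum_i = (baseline + sum_c conc_ic * pure_c) * (1 + slope_i)
                 + offset_i + noise.  Identical seeds give bit-identical
    datasets.  ``concentrations`` overrides the random draw (shape
    n_samples x components), e.g. for noiseless forward-model tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pure, planted = generate_pure_spectra(config)

    if concentrations is None:
        conc = _draw_concentrations(config, rng)
    else:
        conc = np.atleast_2d(np.asarray(concentrations, dtype=float))
        if conc.shape != (config.n_samples, len(config.component_names)):
            raise ValueError("concentrations must be n_samples x components")
        if (conc <= 0).any():
            raise ValueError("concentrations must be positive")

    clean = baseline_spectrum(config.wavelength_grid)[None, :] + conc @ pure
    slopes = rng.normal(0.0, config.scatter_slope_sd, config.n_samples)
    slopes = np.clip(slopes, -0.9, None)  # keep the multiplicative gain positive
    offsets = rng.normal(0.0, config.scatter_offset_sd, config.n_samples)
    noise = rng.normal(0.0, config.noise_sd, clean.shape)
    X = clean * (1.0 + slopes)[:, None] + offsets[:, None] + noise

    images = _render_images(config, conc, rng)

    import pandas as pd

    ids = [f"S{i:04d}" for i in range(config.n_samples)]
    refs = pd.DataFrame({"sample_id": ids})
    for j, name in enumerate(config.component_names):
        refs[f"{name}_mg_g"] = conc[:, j]

    spectra = SpectrumSet(X=X, wavelengths=np.asarray(config.wavelength_grid, float),
                          sample_ids=ids)
    return SyntheticDataset(
        spectra=spectra,
        references=refs,
        images=images,
        planted_bands=planted,
        true_scatter=np.column_stack([slopes, offsets]),
        clean_spectra=clean,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path,
                  write_images: bool = True) -> dict[str, Path]:
    """Persist a dataset: spectra/references CSV, PNG images, config YAML."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": outdir / "spectra.csv",
        "references": outdir / "references.csv",
        "config": outdir / "config.yaml",
        "planted_bands": outdir / "planted_bands.csv",
    }
    dataset.spectra.to_csv(paths["spectra"])
    dataset.references.to_csv(paths["references"], index=False)
    dataset.config.to_yaml(paths["config"])
    np.savetxt(paths["planted_bands"], dataset.planted_bands[None, :],
               fmt="%d", delimiter=",")
    if write_images:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for i, sid in enumerate(dataset.spectra.sample_ids):
            arr = (np.clip(dataset.images[i], 0, 1) * 255).astype(np.uint8)
            iio.imwrite(img_dir / f"{sid}.png", arr)
        paths["images"] = img_dir
    return paths
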