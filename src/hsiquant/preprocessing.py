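"""Spectral preprocessing: Savitzky-Golay smoothing and scatter correction.

SGCS (Savitzky-Golay convolution smoothing) fits a local least-squares
polynomial per band window; MSC (multiplicative scatter correction)
regresses each spectrum on a reference spectrum, x = a*ref + b, and
returns (x - b)/a, removing per-sample multiplicative/additive scatter.
The joint MSC+SGCS pipeline is applied in a configurable order; the MSC
reference is fitted on calibration spectra only and reused when
transforming prediction spectra (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .hsi_io import SpectrumSet

__all__ = ["PreprocessConfig", "sg_smooth", "msc", "apply_pipeline",
           "save_fitted_state", "load_fitted_state"]


@dataclass
class PreprocessConfig:
    """Window/order of the smoother and the order of the joint pipeline.

    The smoothing window (11) and polynomial order (2) are common NIR
    practice; both are configurable.  ``order`` lists the steps to apply,
    default SGCS then MSC.
    """

    sg_window: int = 11
    sg_polyorder: int = 2
    order: tuple[str, ...] = ("sgcs", "msc")
    msc_reference: np.ndarray | None = None  # default: calibration column mean

    def validate(self, n_bands: int | None = None) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if n_bands is not None and self.sg_window > n_bands:
            raise ValueError("sg_window larger than band count")
        if len(self.order) == 0:
            raise ValueError("pipeline order must be nonempty")
        for step in self.order:
            if step not in {"sgcs", "msc"}:
                raise ValueError(f"unknown preprocessing step {step!r}")


def sg_smooth(spectra: SpectrumSet, window: int = 11,
              polyorder: int = 2) -> SpectrumSet:
    """Row-wise Savitzky-Golay smoothing; band count unchanged.

    Edges are handled by evaluating the edge-window polynomial fit
    (scipy's ``mode='interp'``), so rows that are global polynomials of
    degree <= polyorder pass through unchanged.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > spectra.n_bands:
        raise ValueError("window larger than band count")
    sm = savgol_filter(spectra.X, window, polyorder, axis=1, mode="interp")
    return SpectrumSet(sm, spectra.wavelengths, spectra.sample_ids)


def msc(spectra: SpectrumSet, reference: np.ndarray | None = None
        ) -> tuple[SpectrumSet, np.ndarray, np.ndarray]:
    """Multiplicative scatter correction; returns (corrected, slopes, offsets).

    Each row x is regressed on the reference by ordinary least squares,
    x ~ a*ref + b, and corrected to (x - b)/a.  The reference defaults
    to the column mean of the given set (use the calibration reference
    when transforming prediction spectra).
    """
    if spectra.n_bands < 2:
        raise ValueError("MSC requires at least 2 bands")
    ref = spectra.X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.size != spectra.n_bands:
        raise ValueError("reference length must equal band count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference is constant; slope undefined")
    Xc = spectra.X - spectra.X.mean(axis=1, keepdims=True)
    slopes = (Xc @ ref_c) / denom
    if np.any(np.abs(slopes) < 1e-12):
        bad = np.flatnonzero(np.abs(slopes) < 1e-12)
        raise ValueError(f"degenerate MSC fit (slope ~ 0) for rows {bad.tolist()}")
    offsets = spectra.X.mean(axis=1) - slopes * ref.mean()
    corrected = (spectra.X - offsets[:, None]) / slopes[:, None]
    return (SpectrumSet(corrected, spectra.wavelengths, spectra.sample_ids),
            slopes, offsets)


def apply_pipeline(spectra: SpectrumSet, config: PreprocessConfig,
                   fitted_state: dict | None = None, fit: bool = True
                   ) -> tuple[SpectrumSet, dict]:
    """Apply the configured steps in order; returns (result, fitted_state).

    When ``fit`` is True the MSC reference is taken from ``config`` or
    computed from these (calibration) spectra after any preceding steps.
    When ``fit`` is False, ``fitted_state`` from the calibration pass is
    required so prediction spectra are corrected against the calibration
    reference.
    """
    config.validate(spectra.n_bands)
    if not fit and "msc" in config.order and (
            fitted_state is None or "msc_reference" not in fitted_state):
        raise ValueError("fitted_state with 'msc_reference' is required when "
                         "transforming prediction spectra")
    state = dict(fitted_state) if fitted_state else {}
    out = spectra
    for step in config.order:
        if step == "sgcs":
            out = sg_smooth(out, config.sg_window, config.sg_polyorder)
        else:  # msc
            if fit:
                ref = (np.asarray(config.msc_reference, float)
                       if config.msc_reference is not None
                       else out.X.mean(axis=0))
                state["msc_reference"] = ref
            out, _, _ = msc(out, state["msc_reference"])
    return out, state


def save_fitted_state(state: dict, path: str | Path) -> None:
    """Persist the fitted MSC reference to a one-row CSV sidecar."""
    np.savetxt(path, np.asarray(state["msc_reference"], float)[None, :],
               delimiter=",")


def load_fitted_state(path: str | Path) -> dict:
    return {"msc_reference": np.loadtxt(path, delimiter=",").ravel()}
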