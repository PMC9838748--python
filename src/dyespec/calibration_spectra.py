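"""Stage 1: gray-panel reflectance calibration and per-dye peak extraction.

Raw sensor counts are converted to absolute reflectance against an in-scene
reference panel of known, spectrally flat reflectance (18%): for each band k,

    rho_hat(m, n, k) = panel_reflectance * DN(m, n, k) / mean_panel(DN(., ., k))

which cancels both the illumination spectrum and the sensor gain.  The dye's
spectrum is then the per-band arithmetic mean of the calibrated cube over the
dye region of interest, and its peak is localized to sub-band precision with
a three-point parabola through the argmax band and its neighbors.  A constant
offset added to the three samples leaves the parabola's vertex abscissa
unchanged, so a flat baseline does not bias the peak location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import PANEL_REFLECTANCE, RELATIVE_UNIT_SCALE
from .hypercube_io import SpectralCube

__all__ = [
    "CalibrationConfig",
    "CalibrationError",
    "Spectrum",
    "DyePeakSummary",
    "calibrate",
    "roi_mean_spectrum",
    "peak_summary",
    "analyze_dye",
]


class CalibrationError(ValueError):
    """Calibration precondition violated (kind, panel statistics, masks)."""


@dataclass(frozen=True)
class CalibrationConfig:
    """Reference-panel reflectance and the relative-unit reporting scale."""

    panel_reflectance: float = PANEL_REFLECTANCE
    relative_unit_scale: float = RELATIVE_UNIT_SCALE
    panel_statistic: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if not 0 < self.panel_reflectance < 1:
            raise ValueError("panel_reflectance must lie in (0, 1)")
        if self.relative_unit_scale <= 0:
            raise ValueError("relative_unit_scale must be positive")
        if self.panel_statistic not in ("mean", "median"):
            raise ValueError("panel_statistic must be 'mean' or 'median'")


@dataclass(frozen=True)
class Spectrum:
    """A per-band reflectance trace averaged over ``n_pixels`` pixels."""

    band_centers: np.ndarray  # nm
    values: np.ndarray  # reflectance fractions
    n_pixels: int

    def __post_init__(self) -> None:
        if self.band_centers.shape != self.values.shape:
            raise ValueError("band_centers and values must have equal length")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be at least 1")


@dataclass(frozen=True)
class DyePeakSummary:
    """Peak location and height of one dye's mean reflectance spectrum."""

    dye_name: str
    peak_wavelength_nm: float
    peak_wavelength_nm_rounded: int
    max_reflectance_ru: float
    max_band_index: int


def calibrate(
    raw: SpectralCube, panel_mask: np.ndarray, cfg: CalibrationConfig | None = None
) -> SpectralCube:
    """Flat-field a raw DN cube against its in-scene gray panel."""
    cfg = cfg or CalibrationConfig()
    if raw.kind != "dn":
        raise CalibrationError("cube is already reflectance-kind (double calibration)")
    panel_mask = np.asarray(panel_mask, dtype=bool)
    if panel_mask.shape != raw.shape[:2]:
        raise CalibrationError("panel mask shape does not match the cube")
    if not panel_mask.any():
        raise CalibrationError("panel mask selects no pixels")

    panel_px = raw.values[panel_mask]  # (n_panel, bands)
    stat = np.mean if cfg.panel_statistic == "mean" else np.median
    panel_level = stat(panel_px, axis=0)
    bad = np.flatnonzero(panel_level < 1e-9)
    if bad.size:
        raise CalibrationError(
            f"panel level is zero or near zero in band(s) {bad.tolist()[:8]}"
        )
    rho = cfg.panel_reflectance * raw.values / panel_level[None, None, :]
    return SpectralCube(rho, raw.grid, kind="reflectance")


def roi_mean_spectrum(cube: SpectralCube, mask: np.ndarray) -> Spectrum:
    """Per-band arithmetic mean of a reflectance cube over a pixel mask."""
    if cube.kind != "reflectance":
        raise CalibrationError("ROI spectra are extracted from calibrated cubes only")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise CalibrationError("ROI mask shape does not match the cube")
    n = int(mask.sum())
    if n == 0:
        raise CalibrationError("ROI mask selects no pixels")
    values = cube.values[mask].mean(axis=0)
    return Spectrum(cube.grid.band_centers, values, n_pixels=n)


def _parabolic_vertex(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Vertex of the parabola through three points (possibly unevenly spaced)."""
    # Lagrange second-divided-difference form; degenerate (collinear) triples
    # fall back to the central sample.
    (x0, x1, x2), (y0, y1, y2) = x, y
    d1 = (y1 - y0) / (x1 - x0)
    d2 = (y2 - y1) / (x2 - x1)
    a = (d2 - d1) / (x2 - x0)
    if a == 0.0:
        return float(x1), float(y1)
    b = d1 - a * (x0 + x1)
    xv = -b / (2.0 * a)
    c = y0 - (a * x0 + b) * x0
    return float(xv), float((a * xv + b) * xv + c)


def peak_summary(
    s: Spectrum, cfg: CalibrationConfig | None = None, dye_name: str = ""
) -> DyePeakSummary:
    """Locate the spectrum's maximum, refined to sub-band precision.

    The argmax band is found first (ties broken toward the lowest band, so
    results are deterministic); when it is interior, the peak wavelength and
    height are refined by the parabola through the three samples around it.
    At a grid edge no refinement is applied.  The height is reported in
    relative units (``cfg.relative_unit_scale`` per unit reflectance).
    """
    cfg = cfg or CalibrationConfig()
    if s.values.size < 3:
        raise ValueError("peak extraction needs at least 3 bands")
    if not np.all(np.isfinite(s.values)):
        raise ValueError("spectrum contains non-finite values")

    k = int(np.argmax(s.values))  # argmax returns the first (lowest) maximum
    if 0 < k < s.values.size - 1:
        lam, height = _parabolic_vertex(
            s.band_centers[k - 1 : k + 2].astype(float), s.values[k - 1 : k + 2]
        )
    else:
        lam, height = float(s.band_centers[k]), float(s.values[k])
    return DyePeakSummary(
        dye_name=dye_name,
        peak_wavelength_nm=lam,
        peak_wavelength_nm_rounded=int(round(lam)),
        max_reflectance_ru=cfg.relative_unit_scale * height,
        max_band_index=k,
    )


def analyze_dye(
    raw: SpectralCube,
    dye_mask: np.ndarray,
    panel_mask: np.ndarray,
    cfg: CalibrationConfig | None = None,
    dye_name: str = "",
) -> DyePeakSummary:
    """Full stage-1 chain: calibrate, ROI-mean spectrum, peak summary."""
    cfg = cfg or CalibrationConfig()
    reflectance = calibrate(raw, panel_mask, cfg)
    spectrum = roi_mean_spectrum(reflectance, dye_mask)
    return peak_summary(spectrum, cfg, dye_name=dye_name)
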