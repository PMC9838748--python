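"""Synthetic study data: hyperspectral dye scenes and exact-texture images.

The original imagery behind the dye study is not publicly deposited, so this
module generates stand-ins with *known* ground truth:

* hyperspectral scenes — a dye smear patch plus an 18% gray reference panel,
  imaged under spectrally flat incandescent illumination by an idealized
  12-bit line-scan camera.  Each dye's reflectance spectrum is modelled as a
  single broad Gaussian peak on a flat baseline,
  ``rho(lambda) = 1e-4 * (baseline + amplitude * exp(-(lambda - peak)^2 / (2 sigma^2)))``,
  with amplitudes expressed in "relative units" (1 r.u. = 1e-4 reflectance, so
  the 18% panel sits at 1800 r.u.);
* gray texture images whose horizontal right-neighbor absolute-difference
  histogram is reproduced *exactly*, so co-occurrence contrast and homogeneity
  have closed-form rational values.

Only a handful of the seven library dyes' parameters are published (red
634 nm / 751 r.u., brown 732 nm, black 85 r.u., dark pink 1304 r.u., white
3222 r.u.); the remaining entries are documented defaults chosen inside the
634–732 nm peak window and ordered by the published reflectance ranking.
They are configuration, not ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube_io import DN_MAX, SpectralCube, WavelengthGrid

__all__ = [
    "DyeSpecEntry",
    "SceneLayout",
    "IlluminationModel",
    "DiffHistogram",
    "SaturationError",
    "InfeasibleHistogramError",
    "RELATIVE_UNIT_SCALE",
    "PANEL_REFLECTANCE",
    "builtin_dye_library",
    "builtin_texture_suite",
    "default_layout",
    "default_illumination",
    "generate_dye_cube",
    "generate_texture_image",
]

#: 1 relative unit = 1e-4 absolute reflectance (so 18% panel = 1800 r.u.).
RELATIVE_UNIT_SCALE = 1.0e4
#: Nominal reflectance of the gray reference panel.
PANEL_REFLECTANCE = 0.18


class SaturationError(ValueError):
    """The noise-free forward model would exceed the sensor's DN ceiling."""


class InfeasibleHistogramError(ValueError):
    """A difference histogram cannot be realized on the requested image."""


@dataclass(frozen=True)
class DyeSpecEntry:
    """Generative spectral model of one dye."""

    name: str
    color_label: str
    peak_wavelength: float  # nm
    amplitude: float  # relative units above baseline at the peak
    width_sigma: float = 40.0  # nm
    baseline: float = 0.0  # relative units

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.baseline + self.amplitude > RELATIVE_UNIT_SCALE:
            raise ValueError("baseline + amplitude implies reflectance > 1")

    def reflectance(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Model reflectance (fraction, 0..1) at the given wavelengths."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        peak = np.exp(-((lam - self.peak_wavelength) ** 2) / (2.0 * self.width_sigma**2))
        return (self.baseline + self.amplitude * peak) / RELATIVE_UNIT_SCALE


@dataclass(frozen=True)
class Rect:
    """Half-open 0-based rectangle [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError("rectangle must be non-empty with non-negative bounds")

    def mask(self, rows: int, cols: int) -> np.ndarray:
        m = np.zeros((rows, cols), dtype=bool)
        m[self.row0 : self.row1, self.col0 : self.col1] = True
        return m

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )


@dataclass(frozen=True)
class SceneLayout:
    """Spatial arrangement of the dye smear and the gray panel in one scene."""

    rows: int
    cols: int
    dye_region: Rect
    panel_region: Rect

    def __post_init__(self) -> None:
        for name, r in (("dye", self.dye_region), ("panel", self.panel_region)):
            if r.row1 > self.rows or r.col1 > self.cols:
                raise ValueError(f"{name}_region exceeds scene bounds")
        if self.dye_region.overlaps(self.panel_region):
            raise ValueError("dye and panel regions must be disjoint")

    def dye_mask(self) -> np.ndarray:
        return self.dye_region.mask(self.rows, self.cols)

    def panel_mask(self) -> np.ndarray:
        return self.panel_region.mask(self.rows, self.cols)


@dataclass(frozen=True)
class IlluminationModel:
    """Per-band source power, sensor gain, and additive DN noise level."""

    spectrum: np.ndarray  # relative power per band, all > 0
    gain: float  # DN per unit (reflectance x power)
    noise_sd: float = 0.0  # DN

    def __post_init__(self) -> None:
        s = np.asarray(self.spectrum, dtype=float)
        if s.ndim != 1 or np.any(s <= 0):
            raise ValueError("illumination spectrum must be 1-D and strictly positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "spectrum", s)


@dataclass(frozen=True)
class DiffHistogram:
    """Counts of absolute gray-level differences between horizontal neighbors."""

    counts: dict[int, int]
    total_pairs: int

    def __post_init__(self) -> None:
        for d, c in self.counts.items():
            if not (0 <= int(d) <= 255):
                raise ValueError(f"difference {d} outside [0, 255]")
            if c < 0:
                raise ValueError(f"negative count for difference {d}")
        if sum(self.counts.values()) != self.total_pairs:
            raise ValueError("counts must sum to total_pairs")


def builtin_dye_library() -> list[DyeSpecEntry]:
    """The seven permanent-makeup / tattoo dyes of the study, in sample order.

    Peak wavelengths all lie in the published 634–732 nm window; amplitudes
    follow the published removal-difficulty ordering
    black < brown < red < dark pink < yellow < light pink < white.
    """
    return [
        DyeSpecEntry("red", "red", 634.0, 751.0),
        DyeSpecEntry("yellow", "yellow", 680.0, 2000.0),
        DyeSpecEntry("dark_pink", "dark pink", 655.0, 1304.0),
        DyeSpecEntry("black", "black", 700.0, 85.0),
        DyeSpecEntry("light_pink", "light pink", 660.0, 2600.0),
        DyeSpecEntry("brown", "brown", 732.0, 400.0),
        DyeSpecEntry("white", "white", 690.0, 3222.0),
    ]


def default_layout(rows: int = 48, cols: int = 64) -> SceneLayout:
    """Dye patch on the left, gray panel strip on the right."""
    split = (3 * cols) // 4
    return SceneLayout(
        rows=rows,
        cols=cols,
        dye_region=Rect(4, rows - 4, 4, split - 4),
        panel_region=Rect(4, rows - 4, split, cols - 4),
    )


def default_illumination(
    grid: WavelengthGrid, gain: float = 12000.0, noise_sd: float = 0.0
) -> IlluminationModel:
    """Spectrally flat incandescent source; gain keeps the library in range."""
    return IlluminationModel(np.ones(grid.count), gain=gain, noise_sd=noise_sd)


def generate_dye_cube(
    entry: DyeSpecEntry,
    layout: SceneLayout,
    grid: WavelengthGrid,
    illum: IlluminationModel,
    seed: int,
) -> tuple[SpectralCube, SpectralCube]:
    """Simulate one raw acquisition of a dye + panel scene.

    Forward model per pixel and band:
    ``DN(m, n, k) = gain * spectrum(k) * rho(m, n, k) + eps``, with
    ``rho`` the dye model inside the dye region, 0.18 inside the panel
    region and 0 elsewhere, and ``eps ~ N(0, noise_sd^2)`` i.i.d. DN noise
    drawn from a generator seeded with *seed*.  Noisy DN are clipped to the
    12-bit range; if the *noise-free* model itself would exceed the DN
    ceiling the scene is rejected with :class:`SaturationError` rather than
    silently truncated.

    Returns ``(raw_dn_cube, truth_reflectance_cube)``.
    """
    if grid.count < 3:
        raise ValueError("grid must have at least 3 bands")
    if illum.spectrum.size != grid.count:
        raise ValueError("illumination spectrum length must match the grid")

    rho = np.zeros((layout.rows, layout.cols, grid.count))
    rho[layout.dye_mask()] = entry.reflectance(grid.band_centers)
    rho[layout.panel_mask()] = PANEL_REFLECTANCE

    clean = illum.gain * illum.spectrum[None, None, :] * rho
    peak_dn = float(clean.max())
    if peak_dn > DN_MAX:
        raise SaturationError(
            f"noise-free model reaches {peak_dn:.1f} DN, above the "
            f"{DN_MAX} DN ceiling; reduce gain or illumination"
        )

    dn = clean
    if illum.noise_sd > 0:
        rng = np.random.default_rng(seed)
        dn = clean + rng.normal(0.0, illum.noise_sd, size=clean.shape)
        dn = np.clip(dn, 0.0, DN_MAX)

    raw = SpectralCube(dn, grid, kind="dn")
    truth = SpectralCube(rho, grid, kind="reflectance")
    return raw, truth


def _walk_row(diffs: np.ndarray, start: int) -> np.ndarray:
    """Realize a non-increasing difference sequence as an in-range gray walk.

    From value v, step d moves away from the nearer bound: down if v >= d,
    else up (mirrored when anchored at 255).  With diffs sorted in
    non-increasing order and start at 0 or 255 this never leaves [0, 255]:
    an up-move lands at v + d >= d >= d_next, forcing a down-move next, and a
    down-move leaves at most 255 - d_prev <= 255 - d_next of headroom used.
    """
    row = np.empty(diffs.size + 1, dtype=np.int16)
    row[0] = start
    v = start
    # Zeros form a suffix of the sorted chunk: walk only the nonzero prefix.
    nz = int(np.searchsorted(-diffs, 0))  # diffs[:nz] > 0, diffs[nz:] == 0
    if start <= 127:  # anchored low
        for i in range(nz):
            d = int(diffs[i])
            v = v - d if v >= d else v + d
            row[i + 1] = v
    else:  # anchored high (mirror)
        for i in range(nz):
            d = int(diffs[i])
            v = v + d if 255 - v >= d else v - d
            row[i + 1] = v
    row[nz + 1 :] = v
    return row


def generate_texture_image(hist: DiffHistogram, rows: int, cols: int) -> np.ndarray:
    """Build a gray image whose neighbor-difference multiset equals *hist*.

    The histogram's differences are sorted in descending order, chunked into
    ``rows`` runs of ``cols - 1`` steps, and each run is realized as an
    anchored greedy walk (:func:`_walk_row`).  The first row is anchored at
    gray level 255 and the rest at 0, so the image always attains both
    extremes and min–max normalization is the identity on it.

    Raises :class:`InfeasibleHistogramError` when the pair budget does not
    match ``rows * (cols - 1)`` or a single-row image cannot attain 255.
    """
    if rows < 1 or cols < 2:
        raise ValueError("image must have at least 1 row and 2 columns")
    budget = rows * (cols - 1)
    if hist.total_pairs != budget:
        raise InfeasibleHistogramError(
            f"histogram holds {hist.total_pairs} pairs but a {rows}x{cols} "
            f"image has {budget} horizontal neighbor pairs"
        )
    diffs = np.repeat(
        np.array(sorted(hist.counts, reverse=True), dtype=np.int16),
        [hist.counts[d] for d in sorted(hist.counts, reverse=True)],
    )
    per_row = cols - 1
    img = np.empty((rows, cols), dtype=np.uint8)
    for r in range(rows):
        chunk = diffs[r * per_row : (r + 1) * per_row]
        img[r] = _walk_row(chunk, 255 if r == 0 else 0)
    if rows == 1 and 0 not in img:
        # A single row is anchored at 255; it reaches gray 0 only when a
        # full-range difference is present, so both extremes cannot coexist.
        raise InfeasibleHistogramError(
            "single-row image cannot attain both gray 0 and 255"
        )
    return img


# ---------------------------------------------------------------------------
# Texture suite: per-dye difference histograms for the visible-light stage.
# ---------------------------------------------------------------------------

#: Default texture image geometry (rows, cols) -> 100,000 neighbor pairs.
_TEX_ROWS, _TEX_COLS = 100, 1001


def _hist(counts: dict[int, int], rows: int = _TEX_ROWS, cols: int = _TEX_COLS) -> DiffHistogram:
    return DiffHistogram(counts=counts, total_pairs=rows * (cols - 1))


def builtin_texture_suite() -> dict[str, tuple[DiffHistogram, int, int]]:
    """Per-dye difference histograms for the seven-dye texture fixtures.

    The dark-pink and white entries reproduce the study's printed contrast /
    homogeneity values exactly (3.019 / 0.6208 and 0.0057 / 0.9975); the
    other five are documented synthetic stand-ins that respect the study's
    qualitative findings (white most homogeneous with lowest contrast, dark
    pink highest contrast, yellow least homogeneous), since only those two
    dyes' metric values are published.
    """
    white_rows, white_cols = 2000, 1001  # 2,000,000 pairs
    return {
        "red": (_hist({0: 70000, 1: 20000, 2: 10000}), _TEX_ROWS, _TEX_COLS),
        "yellow": (_hist({0: 38000, 1: 24000, 2: 22000, 3: 16000}), _TEX_ROWS, _TEX_COLS),
        "dark_pink": (_hist({0: 45192, 2: 38275, 3: 16533}), _TEX_ROWS, _TEX_COLS),
        "black": (_hist({0: 80000, 1: 15000, 2: 5000}), _TEX_ROWS, _TEX_COLS),
        "light_pink": (_hist({0: 60000, 1: 25000, 2: 15000}), _TEX_ROWS, _TEX_COLS),
        "brown": (_hist({0: 75000, 1: 15000, 2: 10000}), _TEX_ROWS, _TEX_COLS),
        "white": (
            _hist({0: 1990175, 1: 9300, 2: 525}, white_rows, white_cols),
            white_rows,
            white_cols,
        ),
    }
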