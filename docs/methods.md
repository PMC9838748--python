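# Methods

## Measurement chain

The package implements a two-stage characterization of dried dye smears.

**Stage 1 — hyperspectral reflectance.** A line-scan hyperspectral camera
records a cube I(m, n, k) over 400–1000 nm in 128 channels at 12-bit depth.
The scene contains the dye smear and a spectrally flat reference panel of
known reflectance (18%). Per band, reflectance is estimated as
ρ̂ = 0.18 · DN / mean_panel(DN); because the panel sees the same source and
sensor as the dye, the illumination spectrum and gain cancel exactly (the
pipeline verifies this invariance to 1e-9 relative). The dye's spectrum is
the arithmetic mean of ρ̂ over the dye ROI — spatial aggregation happens
*before* peak extraction, i.e. we report the peak of the mean spectrum, not
a per-pixel extreme, reading "for the entire surface" as averaging. The
peak is the argmax band refined by the parabola through the three samples
around it; heights are reported in relative units (1 r.u. = 1e-4
reflectance).

**Stage 2 — visible-light texture.** The smear photo is reduced to gray by
integer channel averaging, floor((R+G+B)/3) — a deliberate reproduction of
the study's "divide by 3 discarding the remainder" rule rather than a
luminance-weighted conversion. The region is contrast-stretched so its
darkest pixel maps to 0 and brightest to 255 (round half away from zero),
then summarized by the ordered co-occurrence distribution of each pixel
with its right-hand neighbor at full 256-level depth:
contrast = Σ p·(i−j)², homogeneity = Σ p/(1+|i−j|).

## Assumptions

- The reference panel is spectrally flat and noise on it is zero-mean, so
  its per-band mean is an unbiased gain estimate (a median alternative is
  available via `CalibrationConfig(panel_statistic="median")` for panels
  with specular outliers).
- Dye spectra are smooth and single-peaked in 400–1000 nm, so a local
  quadratic is an adequate peak model.
- Illumination is spatially uniform across the scene (panel and dye see the
  same source power).

## Tunable parameters

| parameter | units | default | rationale |
|---|---|---|---|
| panel_reflectance | fraction | 0.18 | photographic 18% gray standard |
| relative_unit_scale | r.u. per unit reflectance | 1e4 | puts the panel at 1800 r.u. and the library at 85–3222 r.u. |
| grid | nm | 128 bands, 400 + k·600/128 | implies the camera's quoted 4.69 nm spacing; real band-center lists from ENVI headers override it |
| width_sigma | nm | 40 | broad single peak; with σ ≥ 30 nm on a ≈4.7 nm grid the parabolic-refinement bias is ≪ 0.5 nm / 0.5 r.u. |
| gain | DN per unit (reflectance × power) | 12000 | keeps the brightest library dye (0.3222 reflectance → ≈3866 DN) inside the 4095 DN ceiling |
| noise_sd | DN | 0 | noise-free acquisition is the reference condition; Gaussian DN noise is available for robustness studies |
| gray levels | — | 256 | full 8-bit co-occurrence depth; the common 8-level quantization is rejected because the stretch step makes all 256 levels meaningful, but the level count is configurable |

## The synthetic generator

The original study imagery is not publicly deposited, so the package ships
a generator whose defaults *are* the study conditions:

- **Scenes.** ρ(λ) = 1e-4·(b + A·exp(−(λ−λ₀)²/2σ²)) per dye;
  DN = gain·spectrum(k)·ρ + ε with ε ~ N(0, noise_sd²); panel pixels at
  ρ = 0.18; DN clipped to [0, 4095], but a *noise-free* model exceeding the
  ceiling is an error (`SaturationError`), never a silent clip. Scenes
  default to 48×64 pixels with a 40×44 px dye patch and a 40×12 px panel
  strip — far smaller than the camera's 696 px/line, which is metadata
  only; the statistics are means, so size affects runtime, not values.
- **Library.** Seven dyes in the study's sample order. Published values are
  encoded verbatim (red 634 nm / 751 r.u.; brown 732 nm; black 85 r.u.;
  dark pink 1304 r.u.; white 3222 r.u.). The unpublished peaks (yellow 680,
  dark pink 655, black 700, light pink 660, white 690 nm) are fixed
  documented constants strictly inside the 634–732 nm window, and the
  unpublished amplitudes (brown 400, yellow 2000, light pink 2600 r.u.)
  preserve the published removal-difficulty ordering
  black < brown < red < dark pink < yellow < light pink < white. They are
  configuration, not ground truth. Baselines are 0 so that a dye's maximum
  reflectance equals its amplitude.
- **Textures.** `generate_texture_image` realizes an arbitrary feasible
  absolute-difference histogram exactly: the differences are sorted
  descending, chunked row-wise, and each row is an anchored greedy walk —
  from value v, step d moves away from the nearer bound (down when v ≥ d,
  else up). With non-increasing steps this provably stays in [0, 255]: an
  up-move lands at v + d ≥ d ≥ d_next forcing a down-move, and a down-move
  leaves enough headroom for the next up. The first row is anchored at 255
  and the rest at 0, so both gray extremes are always attained and the
  min–max stretch is the identity on generated images. Single-row images
  cannot pin both extremes this way and are rejected when gray 0 is
  unreachable. The two reference fixtures — dark pink
  {d=2: 38275, d=3: 16533, d=0: 45192} on 100×1001 and white
  {d=1: 9300, d=2: 525, d=0: 1990175} on 2000×1001 — make the metrics
  closed-form rationals (301897/100000 and 0.6208358…; 0.0057 and 0.9975
  exactly). The other five dyes' histograms are synthetic stand-ins chosen
  to respect the study's qualitative findings (white smoothest, dark pink
  highest contrast, yellow least homogeneous); the cross-dye correlation of
  the real smears is therefore not recoverable, only its sign.

**What passing tests do and do not show.** The generator exercises the full
numeric chain (ENVI round trip, calibration ratio, averaging, refinement,
co-occurrence counting) against closed-form ground truth, and that is what
green tests certify. Real acquisitions additionally contain spatially
varying illumination, panel non-flatness, specularities, chromatic focus
shift and non-Gaussian sensor noise, none of which the generator emulates;
performance on real cubes is not certified by this suite.

## Numerical choices

- Peak ties break to the lowest band, so reports are deterministic.
- Parabolic refinement is applied only at interior argmax bands; at a grid
  edge the raw band value is reported (with a machine-readable warning in
  the pipeline log). A constant offset shifts all three samples equally and
  leaves the parabola's vertex abscissa unchanged, so a flat baseline does
  not bias the location; collinear triples fall back to the central sample.
- Cubes are stored as ENVI text header + band-sequential (BSQ)
  little-endian binary. The on-disk dtype follows the array dtype (uint8/16,
  int16, float32/64) so round trips are bit-exact; the simulator emits
  float64 DN because its contract is exact recovery of the model
  reflectance, which integer quantization would break. Cubes from real
  12-bit cameras are uint16 and round-trip as such.
- The co-occurrence matrix is left unsymmetrized. Both statistics depend
  only on |i − j|, so symmetrizing would not change them; the raw
  directional counts are preserved for fidelity to the right-neighbor
  definition.
- ROI texture analysis enumerates pairs within each region row run; pairs
  spanning a masked-out pixel are skipped, and the stretch extremes are
  taken over the region only.
- Reported precision follows the table conventions: contrast to 3 decimals,
  homogeneity to 4, wavelengths additionally as rounded integers.
- Reproduction sizes: the acceptance script uses the default 48×64 scene
  (1600-pixel dye ROI) per dye and the two reference texture fixtures
  (1e5 and 2e6 pairs); all quantities are deterministic at noise_sd = 0.

## Known limitations

- The true band centers of the reference camera are not published
  consistently; the default uniform grid matches the quoted 4.69 nm spacing
  but explicit center lists from headers should be preferred when
  available.
- The parabolic estimator assumes a locally quadratic peak; very narrow
  peaks (σ ≲ 2 band spacings) or multi-modal spectra would need a
  different localizer.
- Only the BSQ interleave and little-endian byte order are read; BIL/BIP
  cubes must be converted first.
- The texture generator controls the difference *histogram*, not
  higher-order spatial structure; it cannot emulate spatially correlated
  drying patterns.
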