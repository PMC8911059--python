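"""Spectral preprocessing chain.

Two fixed stage orders are provided, matching the two analysis branches:

* quantification: crop -> background removal -> rubber-band baseline ->
  per-sample averaging (integrated band areas need a corrected baseline);
* classification: crop -> background removal -> Savitzky-Golay second
  derivative -> SNV normalization -> per-sample averaging.

Numerical conventions: the Savitzky-Golay derivative is scaled by the signed
axis step to the power ``-deriv`` so the output is d^2 A / d nu^2 regardless
of point spacing or axis direction; vector length is preserved by fitting the
edge windows with their own least-squares polynomials, which keeps the filter
exact for polynomials up to the fit order at every point.  The rubber-band
baseline is the lower convex hull of the (wavenumber, absorbance) points,
linearly interpolated between hull vertices.  Classification mode reapplies
SNV to each averaged representative (bin means of unit-variance spectra are
not themselves unit variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    AxisError,
    ConfigError,
    DegenerateSpectrumError,
    EmptyTissueError,
    RangeError,
    ShapeError,
)
from .spectral_core import (
    BACKGROUND,
    HyperspectralImage,
    CohortSet,
    SampleRecord,
    Spectrum,
    TISSUE_UNASSIGNED,
    WavenumberAxis,
)


@dataclass(frozen=True)
class BandDefinition:
    """Named closed integration window, given as (high, low) cm^-1."""

    name: str
    high: float
    low: float

    def __post_init__(self):
        if self.high <= self.low:
            raise ConfigError(f"band {self.name}: high must exceed low")


#: amide I — the dominant tissue band, used for background thresholding
AMIDE_I = BandDefinition("amide_I", 1700.0, 1600.0)


@dataclass(frozen=True)
class PreprocessConfig:
    crop_high: float = 1801.0
    crop_low: float = 798.0
    sg_window: int = 9
    sg_polyorder: int = 3
    sg_deriv: int = 2
    background_band: BandDefinition = AMIDE_I
    background_fraction: float = 0.10
    n_avg: int = 25
    avg_seed: int = 0

    def __post_init__(self):
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError("sg_window must be odd and greater than sg_polyorder")
        if self.sg_polyorder < self.sg_deriv:
            raise ConfigError("sg_polyorder must be >= sg_deriv")
        if self.crop_high <= self.crop_low:
            raise ConfigError("crop_high must exceed crop_low")
        if not (0.0 < self.background_fraction < 1.0):
            raise ConfigError("background_fraction must be in (0, 1)")
        if self.n_avg < 1:
            raise ConfigError("n_avg must be >= 1")


# ---------------------------------------------------------------------------
# single-spectrum stages
# ---------------------------------------------------------------------------

def crop(spectrum: Spectrum, high: float, low: float) -> Spectrum:
    """Keep the axis points nu with low <= nu <= high (closed window)."""
    mask = (spectrum.axis.values >= low) & (spectrum.axis.values <= high)
    if not np.any(mask):
        raise RangeError(f"crop window ({high}, {low}) misses the axis entirely")
    return Spectrum(
        WavenumberAxis(spectrum.axis.values[mask]), spectrum.absorbance[mask], dict(spectrum.meta)
    )


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Andrew monotone chain, lower hull only; x must be strictly ascending."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            # keep a only if (o -> a -> i) turns counterclockwise (a below chord o-i)
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross > 0:
                break
            hull.pop()
        hull.append(i)
    return hull


def rubberband_baseline(spectrum: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Subtract the lower convex hull of the spectrum ("rubber band").

    Returns ``(corrected, baseline)``.  The corrected spectrum is >= 0
    everywhere (up to rounding) and exactly 0 at every hull vertex,
    including both endpoints.
    """
    y_desc = spectrum.absorbance
    if len(y_desc) < 3:
        raise ShapeError("rubber-band correction needs at least 3 points")
    # work on ascending wavenumbers so the hull runs left -> right
    x = spectrum.axis.values[::-1]
    y = y_desc[::-1]
    hull = _lower_hull_indices(x, y)
    baseline_asc = np.interp(x, x[hull], y[hull])
    baseline = baseline_asc[::-1]
    corrected = y_desc - baseline
    return (
        spectrum.with_values(corrected),
        spectrum.with_values(baseline),
    )


def savitzky_golay(spectrum: Spectrum, window: int, polyorder: int, deriv: int) -> Spectrum:
    """Savitzky-Golay smoothing / derivative on a uniform axis.

    The result is the derivative with respect to wavenumber (absorbance *
    cm^(2) for deriv=2), using the signed axis step so descending storage
    gives the same answer as ascending.
    """
    if window % 2 == 0:
        raise ConfigError("window must be odd")
    if polyorder >= window:
        raise ConfigError("window must exceed polyorder")
    if deriv > polyorder:
        raise ConfigError("deriv must be <= polyorder")
    if len(spectrum.axis) < window:
        raise ShapeError("spectrum shorter than the filter window")
    # WavenumberAxis construction already guarantees uniform descending spacing
    step = float(spectrum.axis.values[1] - spectrum.axis.values[0])  # signed (negative)
    # polynomial-interpolated edges keep the filter exact for polynomials
    # up to polyorder over the whole vector, not just the interior
    values = savgol_filter(
        spectrum.absorbance, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=1.0, mode="interp",
    )
    return spectrum.with_values(values * step**(-deriv) if deriv else values)


def snv(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate: center to mean 0 and scale to unit (n-1) sd."""
    x = spectrum.absorbance
    if len(x) < 2:
        raise ShapeError("SNV needs at least 2 points")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateSpectrumError("constant spectrum has no SNV transform")
    return spectrum.with_values((x - np.mean(x)) / sd)


# ---------------------------------------------------------------------------
# image-level stages
# ---------------------------------------------------------------------------

def _band_area_grid(image: HyperspectralImage, band: BandDefinition, corrected: bool) -> np.ndarray:
    """Per-pixel trapezoidal band area, optionally after rubber-band correction."""
    mask = image.axis.window_mask(band.high, band.low)
    if not np.any(mask):
        raise RangeError(f"band {band.name} misses the image axis")
    nu_asc = image.axis.values[mask][::-1]
    rows, cols, _ = image.cube.shape
    areas = np.empty((rows, cols))
    for i in range(rows):
        for j in range(cols):
            y = image.cube[i, j]
            if corrected:
                spec = Spectrum(image.axis, y)
                y = rubberband_baseline(spec)[0].absorbance
            areas[i, j] = np.trapezoid(y[mask][::-1], nu_asc)
    return areas


def remove_background(image: HyperspectralImage, cfg: PreprocessConfig) -> HyperspectralImage:
    """Flag low amide-I pixels as background.

    A pixel is background when its rubber-band-corrected amide-I integrated
    area falls below ``background_fraction`` of the image maximum.
    """
    areas = _band_area_grid(image, cfg.background_band, corrected=True)
    max_area = float(areas.max())
    if max_area <= 0.0:
        raise EmptyTissueError("no pixel carries amide-I signal")
    threshold = cfg.background_fraction * max_area
    is_bg = areas < threshold
    if np.all(is_bg):
        raise EmptyTissueError("background removal flagged every pixel")
    if image.labels is None:
        labels = np.full(image.shape, TISSUE_UNASSIGNED, dtype=np.int8)
    else:
        labels = image.labels.copy()
    labels[is_bg] = BACKGROUND
    return HyperspectralImage(image.axis, image.cube, image.pixel_size_um, labels)


def average_to_representatives(
    pixel_spectra: list[Spectrum], n_avg: int, seed: int
) -> list[Spectrum]:
    """Seeded random partition into ``n_avg`` near-equal bins, mean per bin.

    With fewer spectra than bins the input is returned one-per-pixel.
    """
    if not pixel_spectra:
        raise ShapeError("no spectra to average")
    if n_avg < 1:
        raise ConfigError("n_avg must be >= 1")
    if len(pixel_spectra) <= n_avg:
        return [Spectrum(s.axis, s.absorbance.copy(), dict(s.meta)) for s in pixel_spectra]
    axis = pixel_spectra[0].axis
    mat = np.stack([s.absorbance for s in pixel_spectra])
    order = np.random.default_rng(seed).permutation(len(pixel_spectra))
    return [
        Spectrum(axis, mat[chunk].mean(axis=0))
        for chunk in np.array_split(order, n_avg)
    ]


def _crop_image(image: HyperspectralImage, cfg: PreprocessConfig) -> HyperspectralImage:
    mask = (image.axis.values >= cfg.crop_low) & (image.axis.values <= cfg.crop_high)
    if not np.any(mask):
        raise RangeError("crop window misses the image axis")
    return HyperspectralImage(
        WavenumberAxis(image.axis.values[mask]),
        image.cube[:, :, mask],
        image.pixel_size_um,
        image.labels,
    )


def preprocess_image(
    image: HyperspectralImage, cfg: PreprocessConfig, mode: str
) -> HyperspectralImage:
    """Crop, remove background, and apply the per-pixel branch of ``mode``.

    Background pixels keep their raw (cropped) trace; tissue pixels carry the
    corrected / derivative spectra.
    """
    if mode not in ("quantification", "classification"):
        raise ConfigError(f"unknown mode {mode!r}")
    cropped = _crop_image(image, cfg)
    flagged = remove_background(cropped, cfg)
    cube = flagged.cube.copy()
    rows, cols = flagged.shape
    for i in range(rows):
        for j in range(cols):
            if flagged.labels is not None and flagged.labels[i, j] == BACKGROUND:
                continue
            spec = Spectrum(flagged.axis, cube[i, j])
            if mode == "quantification":
                cube[i, j] = rubberband_baseline(spec)[0].absorbance
            else:
                deriv = savitzky_golay(spec, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
                cube[i, j] = snv(deriv).absorbance
    return HyperspectralImage(flagged.axis, cube, flagged.pixel_size_um, flagged.labels)


def preprocess_pipeline(
    image: HyperspectralImage, cfg: PreprocessConfig, mode: str
) -> list[Spectrum]:
    """Full per-image chain ending in averaged representative spectra."""
    processed = preprocess_image(image, cfg, mode)
    assert processed.labels is not None
    tissue = [
        processed.pixel(i, j)
        for i in range(processed.shape[0])
        for j in range(processed.shape[1])
        if processed.labels[i, j] != BACKGROUND
    ]
    reps = average_to_representatives(tissue, cfg.n_avg, cfg.avg_seed)
    if mode == "classification":
        reps = [snv(r) for r in reps]
    return reps


# ---------------------------------------------------------------------------
# cohort-level preprocessing (records already hold representative spectra)
# ---------------------------------------------------------------------------

def preprocess_spectrum(spectrum: Spectrum, cfg: PreprocessConfig, mode: str) -> Spectrum:
    """Crop plus the per-spectrum branch of ``mode`` for one trace."""
    s = crop(spectrum, cfg.crop_high, cfg.crop_low)
    if mode == "quantification":
        return rubberband_baseline(s)[0]
    if mode == "classification":
        return snv(savitzky_golay(s, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv))
    raise ConfigError(f"unknown mode {mode!r}")


def preprocess_cohort(cohort: CohortSet, cfg: PreprocessConfig, mode: str) -> CohortSet:
    """Apply the per-spectrum chain of ``mode`` to every record spectrum."""
    records = [
        SampleRecord(
            r.animal_id,
            r.section_id,
            r.layer,
            r.severity,
            [preprocess_spectrum(s, cfg, mode) for s in r.spectra],
        )
        for r in cohort.records
    ]
    return CohortSet(records, records[0].axis)
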