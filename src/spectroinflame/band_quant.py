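"""Integrated-band biochemistry quantification and group comparisons.

Band areas are trapezoidal integrals over closed wavenumber windows of
rubber-band-corrected absorbance spectra.  Group comparisons aggregate to
one area per sample record (section) before testing — the section, not the
pixel, is the statistical unit — and use Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    ClassAbsentError,
    DegenerateError,
    RangeError,
    SampleSizeError,
)
from .preprocess import BandDefinition, _band_area_grid
from .spectral_core import BACKGROUND, CohortSet, HyperspectralImage, Spectrum

#: Built-in quantification windows (high, low) cm^-1: amide I/II protein,
#: the collagen triplet region, glycogen, RNA (around 1115) and DNA (around
#: 960).
DEFAULT_BAND_TABLE: dict[str, BandDefinition] = {
    "amide_I": BandDefinition("amide_I", 1700.0, 1600.0),
    "amide_II": BandDefinition("amide_II", 1580.0, 1510.0),
    "collagen": BandDefinition("collagen", 1300.0, 1200.0),
    "glycogen": BandDefinition("glycogen", 1250.0, 1000.0),
    "rna": BandDefinition("rna", 1120.0, 1080.0),
    "dna": BandDefinition("dna", 979.0, 948.0),
}


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    mean_diff: float  # mean(a) - mean(b)
    group_ns: tuple[int, int]


def integrate_band(spectrum: Spectrum, band: BandDefinition) -> float:
    """Trapezoidal area (absorbance * cm^-1) over the closed band window."""
    mask = spectrum.axis.window_mask(band.high, band.low)
    if not np.any(mask):
        raise RangeError(f"band {band.name} ({band.high}-{band.low}) misses the axis")
    nu = spectrum.axis.values[mask][::-1]  # ascending for a positive measure
    return float(np.trapezoid(spectrum.absorbance[mask][::-1], nu))


def chemical_map(image: HyperspectralImage, band: BandDefinition) -> np.ndarray:
    """Per-pixel band-area grid; background pixels are NaN.

    The image is expected to be preprocessed in quantification mode (pixels
    already baseline-corrected), so areas are plain integrals here.
    """
    areas = _band_area_grid(image, band, corrected=False)
    if image.labels is not None:
        areas = np.where(image.labels == BACKGROUND, np.nan, areas)
    return areas


def welch_test(group_a, group_b) -> WelchResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DegenerateError("non-finite values in a group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0 and np.mean(a) == np.mean(b):
        raise DegenerateError("both groups constant and equal: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_diff=float(np.mean(a) - np.mean(b)),
        group_ns=(len(a), len(b)),
    )


def record_band_areas(cohort: CohortSet, band: BandDefinition) -> list[float]:
    """One area per record: mean over its representative spectra."""
    return [
        float(np.mean([integrate_band(s, band) for s in rec.spectra]))
        for rec in cohort.records
    ]


def compare_groups(
    cohort: CohortSet, band: BandDefinition, class_a: str, class_b: str, layer: str
) -> WelchResult:
    """Welch test of per-record band areas, ``class_a`` minus ``class_b``.

    The cohort must already be preprocessed in quantification mode.
    """
    def _areas(severity: str) -> list[float]:
        try:
            sub = cohort.subset(layer=layer, severities=[severity])
        except Exception as exc:
            raise ClassAbsentError(f"class {severity!r} absent in layer {layer!r}") from exc
        return record_band_areas(sub, band)

    return welch_test(_areas(class_a), _areas(class_b))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; tests report raw p by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
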