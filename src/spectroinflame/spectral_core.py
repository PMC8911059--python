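"""Domain types and I/O for FTIR spectra, hyperspectral cubes and cohorts.

Conventions
-----------
* Wavenumber axes are stored **descending** (high -> low cm^-1), the usual
  FTIR plotting convention; every printed window in the package is given as
  ``(high, low)`` cm^-1.
* All window selections are closed on both ends: a point at exactly the
  window edge belongs to the window.
* Layer labels on image grids are ``int8``: -1 background, 0 MC (mucosa),
  1 SubMC (submucosa), 2 MP (muscularis propria), 3 tissue of unassigned
  layer (used when background removal runs on an unlabelled image).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import AxisError, FormatError, ShapeError

LAYERS = ("MC", "SubMC", "MP")
LAYER_ALL = "ALL"
SEVERITIES = ("control", "mild", "moderate", "severe")

BACKGROUND = -1
LAYER_CODES = {"MC": 0, "SubMC": 1, "MP": 2}
CODE_LAYERS = {v: k for k, v in LAYER_CODES.items()}
TISSUE_UNASSIGNED = 3

#: relative tolerance on axis-step uniformity (the derivative filter
#: assumes an equidistant grid)
AXIS_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class WavenumberAxis:
    """Descending, uniformly spaced wavenumber grid in cm^-1."""

    values: np.ndarray
    spacing: float = field(init=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise AxisError("axis needs at least two wavenumber points")
        steps = np.diff(values)
        if not np.all(steps < 0):
            raise AxisError("axis must be strictly descending after canonicalization")
        mean_step = float(np.mean(np.abs(steps)))
        if np.max(np.abs(np.abs(steps) - mean_step)) > AXIS_UNIFORM_RTOL * mean_step:
            raise AxisError("axis spacing is not uniform")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", mean_step)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def window_mask(self, high: float, low: float) -> np.ndarray:
        """Boolean mask of points inside the closed window [low, high]."""
        if high <= low:
            raise AxisError(f"window must be given as (high, low) cm^-1, got ({high}, {low})")
        return (self.values >= low) & (self.values <= high)


@dataclass
class Spectrum:
    """One absorbance trace on a wavenumber axis; the atomic data unit."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (len(self.axis),):
            raise ShapeError(
                f"absorbance length {self.absorbance.shape} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ShapeError("absorbance contains non-finite values")

    def with_values(self, values: np.ndarray, axis: WavenumberAxis | None = None) -> "Spectrum":
        return Spectrum(axis if axis is not None else self.axis, values, dict(self.meta))


@dataclass
class HyperspectralImage:
    """Pixel grid of spectra plus optional per-pixel layer labels."""

    axis: WavenumberAxis
    cube: np.ndarray  # rows x cols x n_wavenumbers
    pixel_size_um: float = 11.0
    labels: np.ndarray | None = None  # rows x cols int8, see module docstring

    def __post_init__(self):
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise ShapeError("cube must be rows x cols x wavenumbers")
        if self.cube.shape[2] != len(self.axis):
            raise ShapeError(
                f"cube wavenumber dimension {self.cube.shape[2]} != axis length {len(self.axis)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != self.cube.shape[:2]:
                raise ShapeError("labels grid does not match cube rows x cols")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.cube[row, col])


@dataclass
class SampleRecord:
    """Averaged representative spectra for one (animal, section, layer)."""

    animal_id: str
    section_id: str
    layer: str
    severity: str
    spectra: list[Spectrum]

    def __post_init__(self):
        if self.layer not in LAYERS + (LAYER_ALL,):
            raise ShapeError(f"unknown layer {self.layer!r}")
        if self.severity not in SEVERITIES:
            raise ShapeError(f"unknown severity {self.severity!r}")
        if not self.spectra:
            raise ShapeError("record holds no spectra")
        axis = self.spectra[0].axis
        if any(s.axis != axis for s in self.spectra[1:]):
            raise AxisError("all spectra of a record must share one axis")

    @property
    def axis(self) -> WavenumberAxis:
        return self.spectra[0].axis

    def values_matrix(self) -> np.ndarray:
        return np.stack([s.absorbance for s in self.spectra])


@dataclass
class CohortSet:
    """All sample records of a study arm, on one common axis."""

    records: list[SampleRecord]
    axis: WavenumberAxis

    def __post_init__(self):
        if not self.records:
            raise ShapeError("cohort holds no records")
        for rec in self.records:
            if rec.axis != self.axis:
                raise AxisError("record axis differs from cohort axis")

    def subset(self, layer: str | None = None, severities: Sequence[str] | None = None) -> "CohortSet":
        recs = [
            r
            for r in self.records
            if (layer is None or layer == LAYER_ALL or r.layer == layer)
            and (severities is None or r.severity in severities)
        ]
        if not recs:
            raise ShapeError("subset selected no records")
        return CohortSet(recs, self.axis)

    def severities_present(self) -> list[str]:
        return sorted({r.severity for r in self.records}, key=SEVERITIES.index)


# ---------------------------------------------------------------------------
# axis canonicalization
# ---------------------------------------------------------------------------

def canonicalize_axis(raw_axis: Sequence[float], raw_values: Sequence[float]) -> Spectrum:
    """Return a Spectrum on a descending axis, reordering values as needed.

    Accepts a strictly monotone axis in either direction; a non-monotone
    axis raises :class:`AxisError`, a length mismatch :class:`ShapeError`.
    """
    raw_axis = np.asarray(raw_axis, dtype=float)
    raw_values = np.asarray(raw_values, dtype=float)
    if raw_axis.shape != raw_values.shape:
        raise ShapeError("axis and values have different lengths")
    steps = np.diff(raw_axis)
    if np.all(steps < 0):
        axis_vals, vals = raw_axis, raw_values
    elif np.all(steps > 0):
        axis_vals, vals = raw_axis[::-1], raw_values[::-1]
    else:
        raise AxisError("axis is not strictly monotone")
    return Spectrum(WavenumberAxis(axis_vals), vals)


# ---------------------------------------------------------------------------
# hyperspectral cube I/O
# ---------------------------------------------------------------------------

def write_cube(image: HyperspectralImage, path: str | os.PathLike, format: str = "hdf5_grid") -> None:
    if format == "hdf5_grid":
        with h5py.File(path, "w") as f:
            f.create_dataset("axis", data=image.axis.values, dtype="float64", track_times=False)
            f.create_dataset("cube", data=image.cube, dtype="float64", track_times=False)
            if image.labels is not None:
                f.create_dataset("labels", data=image.labels, dtype="int8", track_times=False)
            f.attrs["pixel_size_um"] = image.pixel_size_um
    elif format == "csv_long":
        rows, cols, k = image.cube.shape
        r, c, w = np.meshgrid(np.arange(rows), np.arange(cols), np.arange(k), indexing="ij")
        pd.DataFrame(
            {
                "row": r.ravel(),
                "col": c.ravel(),
                "wavenumber": image.axis.values[w.ravel()],
                "absorbance": image.cube.ravel(),
            }
        ).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown cube format {format!r}")


def read_cube(path: str | os.PathLike, format: str = "hdf5_grid") -> HyperspectralImage:
    if format == "hdf5_grid":
        with h5py.File(path, "r") as f:
            if "axis" not in f:
                raise FormatError("missing /axis dataset")
            if "cube" not in f:
                raise FormatError("missing /cube dataset")
            axis = WavenumberAxis(f["axis"][()])
            cube = f["cube"][()]
            labels = f["labels"][()] if "labels" in f else None
            pixel = float(f.attrs.get("pixel_size_um", 11.0))
        return HyperspectralImage(axis, cube, pixel, labels)
    if format == "csv_long":
        df = pd.read_csv(path)
        required = {"row", "col", "wavenumber", "absorbance"}
        if not required.issubset(df.columns):
            raise FormatError(f"CSV must have columns {sorted(required)}")
        wavenumbers = np.sort(df["wavenumber"].unique())[::-1]
        rows = int(df["row"].max()) + 1
        cols = int(df["col"].max()) + 1
        counts = df.groupby(["row", "col"]).size()
        if counts.nunique() != 1 or len(counts) != rows * cols:
            raise ShapeError("ragged pixel rows in long CSV")
        order = {w: i for i, w in enumerate(wavenumbers)}
        cube = np.zeros((rows, cols, len(wavenumbers)))
        cube[
            df["row"].to_numpy(),
            df["col"].to_numpy(),
            df["wavenumber"].map(order).to_numpy(),
        ] = df["absorbance"].to_numpy()
        return HyperspectralImage(WavenumberAxis(wavenumbers), cube)
    raise FormatError(f"unknown cube format {format!r}")


# ---------------------------------------------------------------------------
# JCAMP-DX (XYDATA, (XY..XY) dialect) for single-spectrum fixtures
# ---------------------------------------------------------------------------

def write_jcamp(spectrum: Spectrum, path: str | os.PathLike, title: str = "spectrum") -> None:
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##NPOINTS={len(spectrum.axis)}",
        f"##FIRSTX={spectrum.axis.values[0]:.10g}",
        f"##LASTX={spectrum.axis.values[-1]:.10g}",
        "##XYDATA=(XY..XY)",
    ]
    lines += [
        f"{x:.10g}, {y:.12g}" for x, y in zip(spectrum.axis.values, spectrum.absorbance)
    ]
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_jcamp(path: str | os.PathLike) -> Spectrum:
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##XYDATA"):
                if "(XY..XY)" not in line:
                    raise FormatError("only the (XY..XY) XYDATA dialect is supported")
                in_data = True
                continue
            if line.startswith("##END"):
                in_data = False
                continue
            if in_data and line:
                try:
                    x, y = line.split(",")
                    xs.append(float(x))
                    ys.append(float(y))
                except ValueError as exc:
                    raise FormatError(f"bad XYDATA line {line!r}") from exc
    if not xs:
        raise FormatError("no XYDATA block found")
    return canonicalize_axis(xs, ys)


# ---------------------------------------------------------------------------
# cohort I/O: one HDF5 per record plus an index CSV
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortSet, directory: str | os.PathLike) -> str:
    """Write each record's spectra to HDF5 and an index CSV; returns CSV path."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, rec in enumerate(cohort.records):
        fname = f"record_{i:04d}.h5"
        with h5py.File(os.path.join(directory, fname), "w") as f:
            f.create_dataset("axis", data=rec.axis.values, dtype="float64", track_times=False)
            f.create_dataset("spectra", data=rec.values_matrix(), dtype="float64", track_times=False)
        rows.append(
            {
                "animal_id": rec.animal_id,
                "section_id": rec.section_id,
                "layer": rec.layer,
                "severity": rec.severity,
                "spectrum_file": fname,
            }
        )
    index_path = os.path.join(directory, "cohort.csv")
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return index_path


def read_cohort(directory: str | os.PathLike) -> CohortSet:
    directory = os.fspath(directory)
    index_path = os.path.join(directory, "cohort.csv")
    if not os.path.exists(index_path):
        raise FormatError(f"no cohort.csv in {directory}")
    df = pd.read_csv(index_path)
    required = {"animal_id", "section_id", "layer", "severity", "spectrum_file"}
    if not required.issubset(df.columns):
        raise FormatError(f"cohort.csv must have columns {sorted(required)}")
    records = []
    axis: WavenumberAxis | None = None
    for row in df.itertuples(index=False):
        with h5py.File(os.path.join(directory, row.spectrum_file), "r") as f:
            rec_axis = WavenumberAxis(f["axis"][()])
            mat = f["spectra"][()]
        if axis is None:
            axis = rec_axis
        records.append(
            SampleRecord(
                str(row.animal_id),
                str(row.section_id),
                row.layer,
                row.severity,
                [Spectrum(rec_axis, v) for v in mat],
            )
        )
    assert axis is not None
    return CohortSet(records, axis)
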