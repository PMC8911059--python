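"""Synthetic labelled FTIR cohorts of murine bowel tissue.

The generator emulates the qualitative biochemistry of DSS colitis in the
three bowel-wall layers so that every downstream stage (preprocessing, band
quantification, PLS-DA biomarkers, severity classification, layer
segmentation) can be exercised and validated against a known ground truth:

* layer signatures — amide I alpha-helix (~1650 cm^-1) dominates in mucosa
  (MC) and muscularis propria (MP) while the submucosa (SubMC) minimum is
  shifted to the beta-sheet band (~1635 cm^-1); the collagen triplet
  1280/1230/1200 cm^-1 is strongest in SubMC; glycogen bands 1151/1076/1028
  cm^-1 are highest in MC; the 960 cm^-1 DNA band is depleted in MP;
* severity effects — protein, collagen and nucleic-acid bands rise with
  colitis severity while glycogen falls.  Inflammation is modelled as a
  continuous process: each animal draws a latent intensity on the ordinal
  grade scale (control=0 ... severe=3) centered on its assigned grade, and
  band multipliers are interpolated along the severity curve at that
  intensity.  This emulates the noise of histological grading and makes
  adjacent grades overlap, so the interior grades (mild, moderate) are the
  hardest to separate;
* nuisance structure — a random per-pixel quadratic baseline, iid Gaussian
  pixel noise, per-band amplitude jitter per spectrum and a shared per-band
  per-animal effect that correlates spectra within an animal.

Each spectrum is a sum of Gaussian bands::

    A(nu) = sum_b  amp_b * m_layer(b) * m_sev(b) * (1 + jitter)
                 * exp(-(nu - c_b)^2 / (2 sigma_b^2))  + baseline(nu) + eps(nu)

with ``eps ~ N(0, noise_sd^2)`` iid per point.  Randomness is drawn from a
hierarchical seed tree (cohort -> animal -> section -> spectrum), so adding
spectra to one animal never perturbs another animal's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .spectral_core import (
    BACKGROUND,
    LAYER_CODES,
    LAYERS,
    SEVERITIES,
    CohortSet,
    HyperspectralImage,
    SampleRecord,
    Spectrum,
    WavenumberAxis,
)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorbance band."""

    name: str
    center: float  # cm^-1
    width_sigma: float  # cm^-1
    base_amplitude: float  # absorbance

    def __post_init__(self):
        if self.width_sigma <= 0:
            raise ConfigError(f"band {self.name}: width_sigma must be > 0")
        if self.base_amplitude < 0:
            raise ConfigError(f"band {self.name}: base_amplitude must be >= 0")


@dataclass(frozen=True)
class LayerChemistry:
    layer: str
    band_multipliers: Mapping[str, float]

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ConfigError(f"unknown layer {self.layer!r}")
        if any(v < 0 for v in self.band_multipliers.values()):
            raise ConfigError("layer band multipliers must be >= 0")


@dataclass(frozen=True)
class SeverityEffect:
    severity: str
    band_multipliers: Mapping[str, float]

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ConfigError(f"unknown severity {self.severity!r}")
        if any(v < 0 for v in self.band_multipliers.values()):
            raise ConfigError("severity band multipliers must be >= 0")


# band-name groups used for the monotone-direction validation
_INCREASING_GROUPS = ("amide", "protein", "collagen", "dna", "rna")
_DECREASING_GROUPS = ("glycogen",)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of the synthetic study conditions."""

    axis_high: float = 1900.0
    axis_low: float = 700.0
    axis_spacing: float = 4.0
    bands: tuple[BandSpec, ...] = ()
    layer_chem: Mapping[str, LayerChemistry] = field(default_factory=dict)
    severity_effects: Mapping[str, SeverityEffect] = field(default_factory=dict)
    baseline_offset_range: tuple[float, float] = (0.0, 0.05)
    baseline_tilt_range: tuple[float, float] = (-0.02, 0.02)
    baseline_curve_range: tuple[float, float] = (-0.02, 0.02)
    noise_sd: float = 0.005
    amplitude_jitter_cv: float = 0.05
    animal_effect_cv: float = 0.04
    severity_overlap_sd: float = 0.35  # animal-level grading-noise sd, in grade units
    #: per-grade scaling of the grading noise (control/mild/moderate/severe);
    #: inter-observer agreement of histological scoring is poorest for the
    #: intermediate grades, so the middle of the scale gets the widest spread
    overlap_grade_scale: tuple[float, float, float, float] = (0.4, 0.6, 1.8, 0.5)
    section_overlap_sd: float = 0.35  # per-section grading-noise sd, same grade scaling
    seed: int = 0

    def __post_init__(self):
        if self.axis_high <= self.axis_low:
            raise ConfigError("axis_high must exceed axis_low")
        if (
            self.noise_sd < 0
            or self.amplitude_jitter_cv < 0
            or self.animal_effect_cv < 0
            or self.severity_overlap_sd < 0
            or self.section_overlap_sd < 0
        ):
            raise ConfigError("noise/jitter parameters must be >= 0")
        band_names = {b.name for b in self.bands}
        for b in self.bands:
            if not (self.axis_low <= b.center <= self.axis_high):
                raise ConfigError(f"band {b.name} center outside the axis range")
        for chem in self.layer_chem.values():
            unknown = set(chem.band_multipliers) - band_names
            if unknown:
                raise ConfigError(f"layer {chem.layer}: unknown band names {sorted(unknown)}")
        for eff in self.severity_effects.values():
            unknown = set(eff.band_multipliers) - band_names
            if unknown:
                raise ConfigError(f"severity {eff.severity}: unknown band names {sorted(unknown)}")
        self._validate_layer_contrast()
        self._validate_severity_monotone()

    def _validate_layer_contrast(self):
        """Every layer pair must differ by >= 20% in at least one band."""
        layers = [self.layer_chem[l] for l in LAYERS if l in self.layer_chem]
        for i, a in enumerate(layers):
            for b in layers[i + 1 :]:
                names = set(a.band_multipliers) | set(b.band_multipliers)
                ok = any(
                    abs(a.band_multipliers.get(n, 1.0) - b.band_multipliers.get(n, 1.0))
                    >= 0.2 * max(a.band_multipliers.get(n, 1.0), b.band_multipliers.get(n, 1.0), 1e-12)
                    for n in names
                )
                if not ok:
                    raise ConfigError(
                        f"layers {a.layer} and {b.layer} are not distinguishable "
                        "(no band differs by >= 20%)"
                    )

    def _validate_severity_monotone(self):
        present = [s for s in SEVERITIES if s in self.severity_effects]
        for band in self.bands:
            name = band.name.lower()
            series = [
                self.severity_effects[s].band_multipliers.get(band.name, 1.0) for s in present
            ]
            diffs = np.diff(series)
            if any(name.startswith(g) for g in _INCREASING_GROUPS) and np.any(diffs < -1e-12):
                raise ConfigError(f"severity multipliers for {band.name} must be non-decreasing")
            if any(name.startswith(g) for g in _DECREASING_GROUPS) and np.any(diffs > 1e-12):
                raise ConfigError(f"severity multipliers for {band.name} must be non-increasing")

    # -- derived -----------------------------------------------------------
    def axis(self) -> WavenumberAxis:
        n = int(round((self.axis_high - self.axis_low) / self.axis_spacing)) + 1
        return WavenumberAxis(self.axis_high - self.axis_spacing * np.arange(n))

    def severity_multiplier(self, band: BandSpec, severity: str,
                            latent: float | None = None) -> float:
        """Severity multiplier for one band, optionally at a latent intensity.

        With ``latent`` given (continuous position on the grade scale) the
        multiplier is linearly interpolated between the grade multipliers;
        otherwise the assigned grade's multiplier is used directly.  The
        latent scale is floored at 0 (there is no "healthier than control")
        but extends past the top grade by linear extrapolation of the last
        segment, capped half a grade above it: inflammation intensity does
        not stop at the grading cutoff.
        """
        if latent is None or not all(s in self.severity_effects for s in SEVERITIES):
            return self.severity_effects[severity].band_multipliers.get(band.name, 1.0)
        curve = [self.severity_effects[s].band_multipliers.get(band.name, 1.0)
                 for s in SEVERITIES]
        top = len(curve) - 1
        z = float(np.clip(latent, 0.0, top + 0.5))
        lo = min(int(np.floor(z)), top - 1)
        frac = z - lo
        value = (1.0 - frac) * curve[lo] + frac * curve[lo + 1]
        return max(value, 0.0)

    def band_amplitude(self, band: BandSpec, layer: str | None, severity: str | None,
                       latent: float | None = None) -> float:
        amp = band.base_amplitude
        if layer is not None:
            amp *= self.layer_chem[layer].band_multipliers.get(band.name, 1.0)
        if severity is not None:
            amp *= self.severity_multiplier(band, severity, latent)
        return amp


def _group_multipliers(groups: Mapping[str, float]) -> dict[str, float]:
    """Expand {group prefix: multiplier} over the default band names."""
    out = {}
    for band in DEFAULT_BANDS:
        for prefix, mult in groups.items():
            if band.name.startswith(prefix):
                out[band.name] = mult
                break
    return out


#: Default band table: centers from the tissue band assignments
#: (amide I alpha/beta, amide II, 1481 protein, 1739 lipid ester, collagen
#: triplet, glycogen 1151/1076/1028, RNA 1115, DNA 960); widths and base
#: amplitudes are generator choices.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("amide_I_alpha", 1650.0, 16.0, 1.00),
    BandSpec("amide_I_beta", 1635.0, 14.0, 0.50),
    BandSpec("amide_II", 1545.0, 14.0, 0.60),
    BandSpec("protein_1481", 1481.0, 10.0, 0.10),
    BandSpec("lipid_ester_1739", 1739.0, 10.0, 0.08),
    BandSpec("collagen_1280", 1280.0, 10.0, 0.15),
    BandSpec("collagen_1230", 1230.0, 12.0, 0.20),
    BandSpec("collagen_1200", 1200.0, 9.0, 0.12),
    BandSpec("glycogen_1151", 1151.0, 10.0, 0.15),
    # the 1076 amplitude is kept below the 1028/1151 glycogen bands and the
    # 1115 RNA band slightly raised so the RNA window (1120-1080), which the
    # 1076 tail overlaps, still gains area with severity as tissue does
    BandSpec("glycogen_1076", 1076.0, 14.0, 0.12),
    BandSpec("glycogen_1028", 1028.0, 12.0, 0.20),
    BandSpec("rna_1115", 1115.0, 9.0, 0.12),
    BandSpec("dna_960", 960.0, 8.0, 0.07),
)

DEFAULT_LAYER_CHEM: dict[str, LayerChemistry] = {
    "MC": LayerChemistry(
        "MC",
        _group_multipliers(
            {"amide_I_alpha": 1.0, "amide_I_beta": 0.4, "amide_II": 0.9, "protein": 0.8,
             "lipid": 0.8, "collagen": 0.6, "glycogen": 1.4, "rna": 1.0, "dna": 1.0}
        ),
    ),
    "SubMC": LayerChemistry(
        "SubMC",
        _group_multipliers(
            {"amide_I_alpha": 0.6, "amide_I_beta": 1.3, "amide_II": 0.8, "protein": 0.9,
             "lipid": 0.7, "collagen": 1.8, "glycogen": 0.8, "rna": 0.9, "dna": 0.9}
        ),
    ),
    "MP": LayerChemistry(
        "MP",
        _group_multipliers(
            {"amide_I_alpha": 1.3, "amide_I_beta": 0.5, "amide_II": 1.2, "protein": 1.1,
             "lipid": 0.8, "collagen": 0.7, "glycogen": 0.6, "rna": 0.5, "dna": 0.3}
        ),
    ),
}

#: Severity multipliers (control/mild/moderate/severe): protein, collagen
#: and nucleic acids rise, glycogen falls; adjacent grades overlap.
_SEVERITY_TABLE = {
    "control": {"amide": 1.00, "protein": 1.00, "collagen": 1.00, "dna": 1.00, "rna": 1.00,
                "glycogen": 1.00, "lipid": 1.00},
    "mild": {"amide": 1.15, "protein": 1.15, "collagen": 1.10, "dna": 1.20, "rna": 1.20,
             "glycogen": 0.90, "lipid": 1.00},
    "moderate": {"amide": 1.30, "protein": 1.30, "collagen": 1.20, "dna": 1.45, "rna": 1.45,
                 "glycogen": 0.75, "lipid": 1.00},
    "severe": {"amide": 1.50, "protein": 1.50, "collagen": 1.35, "dna": 1.80, "rna": 1.80,
               "glycogen": 0.60, "lipid": 1.00},
}

DEFAULT_SEVERITY_EFFECTS: dict[str, SeverityEffect] = {
    sev: SeverityEffect(sev, _group_multipliers(groups))
    for sev, groups in _SEVERITY_TABLE.items()
}


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions; field overrides go through ``replace``."""
    cfg = GeneratorConfig(
        bands=DEFAULT_BANDS,
        layer_chem=DEFAULT_LAYER_CHEM,
        severity_effects=DEFAULT_SEVERITY_EFFECTS,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=tuple(key)))


def _band_profiles(config: GeneratorConfig, axis: WavenumberAxis) -> np.ndarray:
    """n_bands x n_points matrix of unit-amplitude Gaussian profiles."""
    nu = axis.values[None, :]
    centers = np.array([b.center for b in config.bands])[:, None]
    sigmas = np.array([b.width_sigma for b in config.bands])[:, None]
    return np.exp(-((nu - centers) ** 2) / (2.0 * sigmas**2))


def _baseline(config: GeneratorConfig, axis: WavenumberAxis, rng: np.random.Generator) -> np.ndarray:
    u = (axis.values - axis.values.min()) / (axis.values.max() - axis.values.min())
    c0 = rng.uniform(*config.baseline_offset_range)
    c1 = rng.uniform(*config.baseline_tilt_range)
    c2 = rng.uniform(*config.baseline_curve_range)
    return c0 + c1 * u + c2 * u**2


def expected_spectrum(config: GeneratorConfig, layer: str | None, severity: str | None) -> Spectrum:
    """Noiseless, baseline-free expectation of the band model."""
    axis = config.axis()
    profiles = _band_profiles(config, axis)
    amps = np.array([config.band_amplitude(b, layer, severity) for b in config.bands])
    return Spectrum(axis, amps @ profiles, {"layer": layer, "severity": severity})


#: nominal position of each grade on the latent inflammation scale
GRADE_POSITION = {s: float(i) for i, s in enumerate(SEVERITIES)}


def grade_overlap_sd(config: GeneratorConfig, severity: str) -> float:
    """Grading-noise sd for one grade (baseline sd times the grade scale)."""
    return config.severity_overlap_sd * config.overlap_grade_scale[
        int(GRADE_POSITION[severity])
    ]


def synth_spectrum(
    config: GeneratorConfig,
    layer: str,
    severity: str,
    rng: np.random.Generator,
    animal_effect: np.ndarray | None = None,
    latent_severity: float | None = None,
) -> Spectrum:
    """Draw one spectrum.

    ``animal_effect`` is a per-band relative amplitude offset shared by all
    spectra of one animal; ``latent_severity`` is the continuous inflammation
    intensity of the sample.  When ``latent_severity`` is omitted and
    ``severity_overlap_sd`` is positive, an intensity is drawn around the
    assigned grade.
    """
    if layer not in LAYERS:
        raise ConfigError(f"unknown layer {layer!r}")
    if severity not in SEVERITIES:
        raise ConfigError(f"unknown severity {severity!r}")
    axis = config.axis()
    profiles = _band_profiles(config, axis)
    if latent_severity is None and config.severity_overlap_sd > 0:
        latent_severity = GRADE_POSITION[severity] + rng.normal(
            0.0, grade_overlap_sd(config, severity)
        )
    amps = np.array(
        [config.band_amplitude(b, layer, severity, latent_severity) for b in config.bands]
    )
    if config.amplitude_jitter_cv:
        amps = amps * (1.0 + rng.normal(0.0, config.amplitude_jitter_cv, size=len(amps)))
    if animal_effect is not None:
        amps = amps * (1.0 + np.asarray(animal_effect))
    signal = amps @ profiles
    base = _baseline(config, axis, rng)
    noise = rng.normal(0.0, config.noise_sd, size=len(axis)) if config.noise_sd else 0.0
    return Spectrum(axis, signal + base + noise, {"layer": layer, "severity": severity})


def _background_spectrum(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    axis = config.axis()
    base = _baseline(config, axis, rng)
    noise = rng.normal(0.0, config.noise_sd, size=len(axis)) if config.noise_sd else 0.0
    return base + noise


@dataclass(frozen=True)
class StripeLayout:
    """Horizontal layer stripes (rows split MC / SubMC / MP) with a margin."""

    rows: int
    cols: int
    stripe_widths: tuple[int, int, int]
    margin: int = 0

    def __post_init__(self):
        if any(w < 1 for w in self.stripe_widths):
            raise ConfigError("stripe widths must be >= 1")
        if self.margin < 0:
            raise ConfigError("margin must be >= 0")
        if sum(self.stripe_widths) + 2 * self.margin != self.rows:
            raise ConfigError("stripe widths plus margins must sum to the row count")
        if self.cols < 1:
            raise ConfigError("cols must be >= 1")


def synth_image(
    config: GeneratorConfig, layout: StripeLayout, severity: str, seed: int
) -> HyperspectralImage:
    """Striped tissue phantom: MC/SubMC/MP bands plus background margins."""
    cfg = replace(config, seed=seed)
    axis = cfg.axis()
    labels = np.full((layout.rows, layout.cols), BACKGROUND, dtype=np.int8)
    r = layout.margin
    for layer, width in zip(LAYERS, layout.stripe_widths):
        labels[r : r + width, :] = LAYER_CODES[layer]
        r += width
    cube = np.empty((layout.rows, layout.cols, len(axis)))
    for i in range(layout.rows):
        for j in range(layout.cols):
            rng = _rng(cfg, i, j)
            code = labels[i, j]
            if code == BACKGROUND:
                cube[i, j] = _background_spectrum(cfg, rng)
            else:
                layer = LAYERS[code]
                # one image = one section: hold the inflammation intensity
                # at the grade's nominal level across pixels
                cube[i, j] = synth_spectrum(
                    cfg, layer, severity, rng,
                    latent_severity=GRADE_POSITION[severity],
                ).absorbance
    return HyperspectralImage(axis, cube, labels=labels)


def synth_cohort(
    config: GeneratorConfig,
    n_animals_per_class: Mapping[str, int],
    sections_per_animal: int,
    spectra_per_layer: int,
    seed: int,
    layers: tuple[str, ...] = LAYERS,
) -> CohortSet:
    """One SampleRecord per (animal, section, layer), correlated within animal."""
    if not n_animals_per_class:
        raise ConfigError("empty severity class map")
    unknown = set(n_animals_per_class) - set(SEVERITIES)
    if unknown:
        raise ConfigError(f"unknown severity classes {sorted(unknown)}")
    if sections_per_animal < 1 or spectra_per_layer < 1:
        raise ConfigError("counts must be >= 1")
    if any(n < 1 for n in n_animals_per_class.values()):
        raise ConfigError("counts must be >= 1")
    cfg = replace(config, seed=seed)
    axis = cfg.axis()
    records: list[SampleRecord] = []
    for si, severity in enumerate(s for s in SEVERITIES if s in n_animals_per_class):
        for a in range(n_animals_per_class[severity]):
            animal_rng = _rng(cfg, si, a)
            animal_effect = (
                animal_rng.normal(0.0, cfg.animal_effect_cv, size=len(cfg.bands))
                if cfg.animal_effect_cv
                else None
            )
            animal_latent = GRADE_POSITION[severity] + (
                animal_rng.normal(0.0, grade_overlap_sd(cfg, severity))
                if cfg.severity_overlap_sd
                else 0.0
            )
            animal_id = f"{severity}_{a:02d}"
            for s in range(sections_per_animal):
                section_latent = animal_latent + (
                    animal_rng.normal(
                        0.0,
                        cfg.section_overlap_sd
                        * cfg.overlap_grade_scale[int(GRADE_POSITION[severity])],
                    )
                    if cfg.section_overlap_sd
                    else 0.0
                )
                for li, layer in enumerate(layers):
                    spectra = [
                        synth_spectrum(cfg, layer, severity, _rng(cfg, si, a, s, li, k),
                                       animal_effect=animal_effect,
                                       latent_severity=section_latent)
                        for k in range(spectra_per_layer)
                    ]
                    records.append(
                        SampleRecord(animal_id, f"{animal_id}_sec{s}", layer, severity, spectra)
                    )
    return CohortSet(records, axis)
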