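import numpy as np
import pytest

import spectroinflame as si
from spectroinflame.synthetic_cohort import BandSpec, LayerChemistry, SeverityEffect


@pytest.fixture(scope="session")
def default_cfg():
    return si.default_config(seed=1)


@pytest.fixture(scope="session")
def quiet_cfg():
    """Default chemistry with every noise source switched off."""
    return si.default_config(
        seed=1,
        noise_sd=0.0,
        amplitude_jitter_cv=0.0,
        animal_effect_cv=0.0,
        severity_overlap_sd=0.0,
        section_overlap_sd=0.0,
        baseline_offset_range=(0.0, 0.0),
        baseline_tilt_range=(0.0, 0.0),
        baseline_curve_range=(0.0, 0.0),
    )


def single_band_config(center=1650.0, sigma=15.0, amp=1.0, **kwargs):
    """Minimal one-band generator with flat chemistry, for analytic checks."""
    band = BandSpec("amide_I_alpha", center, sigma, amp)
    layer_chem = {l: LayerChemistry(l, {"amide_I_alpha": m})
                  for l, m in (("MC", 1.0), ("SubMC", 1.3), ("MP", 0.7))}
    sev = {s: SeverityEffect(s, {"amide_I_alpha": m})
           for s, m in (("control", 1.0), ("mild", 1.1), ("moderate", 1.2), ("severe", 1.5))}
    defaults = dict(
        bands=(band,),
        layer_chem=layer_chem,
        severity_effects=sev,
        noise_sd=0.0,
        amplitude_jitter_cv=0.0,
        animal_effect_cv=0.0,
        severity_overlap_sd=0.0,
        section_overlap_sd=0.0,
        baseline_offset_range=(0.0, 0.0),
        baseline_tilt_range=(0.0, 0.0),
        baseline_curve_range=(0.0, 0.0),
        seed=0,
    )
    defaults.update(kwargs)
    return si.GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort(default_cfg):
    """Control vs severe, 3 animals x 2 sections x 3 layers x 10 spectra."""
    return si.synth_cohort(
        default_cfg, {"control": 3, "severe": 3}, 2, 10, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort_classif(small_cohort):
    return si.preprocess_cohort(small_cohort, si.PreprocessConfig(), "classification")


@pytest.fixture(scope="session")
def small_cohort_quant(small_cohort):
    return si.preprocess_cohort(small_cohort, si.PreprocessConfig(), "quantification")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
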