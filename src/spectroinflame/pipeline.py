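"""End-to-end workflow orchestration from one configuration.

``run_all`` executes synthesize -> preprocess -> quantify -> PLS-DA ->
severity -> segmentation, writing every intermediate artifact plus a
manifest of content hashes and stage seeds.  Stage seeds are derived from
the global seed by hashing the stage name, so each stage is independently
reproducible; an identical config + seed yields identical manifest hashes.

Artifact hashes are computed over the logical content (arrays and
metadata), not raw file bytes, so they are stable across HDF5 library
details; ``verify_manifest`` recomputes them from disk and raises
:class:`IntegrityError` on any mismatch, which is how resumption refuses
corrupt intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import band_quant, chemometrics, severity_models
from .errors import ConfigError, IntegrityError
from .preprocess import PreprocessConfig, preprocess_cohort
from .spectral_core import LAYERS, CohortSet, read_cohort, write_cohort, write_cube
from .synthetic_cohort import GeneratorConfig, StripeLayout, default_config, synth_cohort, synth_image

logger = logging.getLogger("spectroinflame")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(f"{stage}:{global_seed}".encode()) ^ global_seed) & 0x7FFFFFFF


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=default_config)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_animals_per_class: dict = field(
        default_factory=lambda: {"control": 3, "mild": 3, "moderate": 3, "severe": 3}
    )
    sections_per_animal: int = 2
    spectra_per_layer: int = 25
    plsda_classes: tuple[str, str] = ("control", "severe")
    plsda_layer: str = "ALL"
    plsda_max_lv: int = 8
    plsda_n_blinds: int = 10
    severity_layer: str = "SubMC"
    severity_repeats: int = 10
    severity_train_frac: float = 0.7
    severity_variance_target: float = 0.95
    segment_rows: int = 24
    segment_cols: int = 12
    output_dir: str = "run_output"
    global_seed: int = 0


def _hash_array(h: "hashlib._Hash", arr: np.ndarray) -> None:
    h.update(np.ascontiguousarray(arr).tobytes())


def _cohort_hash(cohort: CohortSet) -> str:
    h = hashlib.sha256()
    _hash_array(h, cohort.axis.values)
    for rec in cohort.records:
        h.update(f"{rec.animal_id}|{rec.section_id}|{rec.layer}|{rec.severity}".encode())
        _hash_array(h, rec.values_matrix())
    return h.hexdigest()


def _json_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, resume: bool = False) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest_path = os.path.join(out, "manifest.json")
    if resume and os.path.exists(manifest_path):
        verify_manifest(out)
    manifest: dict = {"global_seed": config.global_seed, "stages": {}}

    def record_stage(name: str, seed: int, artifacts: dict[str, str]) -> None:
        manifest["stages"][name] = {"seed": seed, "artifacts": artifacts}
        logger.info("stage %s done (%d artifacts)", name, len(artifacts))

    # --- synthesize -------------------------------------------------------
    seed = stage_seed(config.global_seed, "synth")
    cohort = synth_cohort(
        config.generator,
        config.n_animals_per_class,
        config.sections_per_animal,
        config.spectra_per_layer,
        seed=seed,
    )
    cohort_dir = os.path.join(out, "cohort")
    write_cohort(cohort, cohort_dir)
    record_stage("synth", seed, {"cohort": _cohort_hash(cohort)})

    # --- preprocess -------------------------------------------------------
    quant = preprocess_cohort(cohort, config.preprocess, "quantification")
    classif = preprocess_cohort(cohort, config.preprocess, "classification")
    write_cohort(quant, os.path.join(out, "cohort_quant"))
    write_cohort(classif, os.path.join(out, "cohort_classif"))
    record_stage(
        "preprocess",
        stage_seed(config.global_seed, "preprocess"),
        {"quantification": _cohort_hash(quant), "classification": _cohort_hash(classif)},
    )

    # --- quantify ---------------------------------------------------------
    rows = []
    for band in band_quant.DEFAULT_BAND_TABLE.values():
        for rec, area in zip(quant.records, band_quant.record_band_areas(quant, band)):
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "section_id": rec.section_id,
                    "layer": rec.layer,
                    "severity": rec.severity,
                    "band": band.name,
                    "area": area,
                }
            )
    areas = pd.DataFrame(rows)
    areas_path = os.path.join(out, "areas.csv")
    areas.to_csv(areas_path, index=False)
    welch = {}
    present = cohort.severities_present()
    if "control" in present and "severe" in present:
        for name, band in band_quant.DEFAULT_BAND_TABLE.items():
            res = band_quant.compare_groups(quant, band, "severe", "control", "ALL")
            welch[name] = {"t": res.t_stat, "df": res.df, "p": res.p_value,
                           "mean_diff": res.mean_diff}
    welch_path = os.path.join(out, "welch_severe_vs_control.json")
    with open(welch_path, "w") as fh:
        json.dump(welch, fh, indent=2, sort_keys=True)
    record_stage(
        "quantify",
        stage_seed(config.global_seed, "quantify"),
        {"areas": _file_hash(areas_path), "welch": _json_hash(welch)},
    )

    # --- PLS-DA -----------------------------------------------------------
    mat = chemometrics.cohort_to_matrix(
        classif, layer=config.plsda_layer, severities=list(config.plsda_classes)
    )
    curve = chemometrics.venetian_cv(
        mat.X, mat.y, max_lv=config.plsda_max_lv, n_blinds=config.plsda_n_blinds
    )
    n_lv = chemometrics.select_n_lv(curve)
    model = chemometrics.plsda_fit(mat.X, mat.y, n_lv)
    cv_eval = crossval_binary_eval(mat.X, mat.y, n_lv, config.plsda_n_blinds)
    vip_table = pd.DataFrame(
        {
            "wavenumber": mat.axis.values,
            "vip": model.vip,
            "significant": model.vip > 1.0,
        }
    )
    vip_path = os.path.join(out, "plsda_vip.csv")
    vip_table.to_csv(vip_path, index=False)
    plsda_report = {
        "classes": list(model.classes),
        "n_lv": n_lv,
        "cv_curve": curve,
        "cv_sensitivity": cv_eval.sensitivity,
        "cv_specificity": cv_eval.specificity,
    }
    plsda_path = os.path.join(out, "plsda_report.json")
    with open(plsda_path, "w") as fh:
        json.dump(plsda_report, fh, indent=2, sort_keys=True)
    record_stage(
        "plsda",
        stage_seed(config.global_seed, "plsda"),
        {"vip": _file_hash(vip_path), "report": _json_hash(plsda_report)},
    )

    # --- severity ensemble ------------------------------------------------
    sev_seed = stage_seed(config.global_seed, "severity")
    report = severity_models.repeated_holdout(
        classif,
        layer=config.severity_layer,
        n_repeats=config.severity_repeats,
        train_frac=config.severity_train_frac,
        variance_target=config.severity_variance_target,
        seeds=[(sev_seed + r) % (1 << 31) for r in range(config.severity_repeats)],
    )
    sev_report = {
        c: {
            "auroc": report.auroc[c],
            "ca": report.ca[c],
            "mean_auroc": report.mean_auroc[c],
            "mean_ca": report.mean_ca[c],
        }
        for c in report.classes
    }
    sev_path = os.path.join(out, "severity_report.json")
    with open(sev_path, "w") as fh:
        json.dump(sev_report, fh, indent=2, sort_keys=True)
    record_stage("severity", sev_seed, {"report": _json_hash(sev_report)})

    # --- layer segmentation ----------------------------------------------
    seg_seed = stage_seed(config.global_seed, "segment")
    margin = 1 if config.segment_rows >= 5 else 0
    interior = config.segment_rows - 2 * margin
    w1 = w2 = interior // 3
    layout = StripeLayout(
        rows=config.segment_rows,
        cols=config.segment_cols,
        stripe_widths=(w1, w2, interior - w1 - w2),
        margin=margin,
    )
    train_img = synth_image(config.generator, layout, "severe", seed=seg_seed)
    test_img = synth_image(config.generator, layout, "severe", seed=seg_seed + 1)
    segmenter = severity_models.layer_segmenter_train(
        train_img, config.preprocess, seed=seg_seed
    )
    pred = severity_models.segment_image(segmenter, test_img)
    truth = test_img.labels
    tissue = truth != -1
    accuracy = float(np.mean(pred[tissue] == truth[tissue]))
    seg_path = os.path.join(out, "segmentation_labels.h5")
    write_cube(
        type(test_img)(test_img.axis, test_img.cube, test_img.pixel_size_um, pred),
        seg_path,
    )
    seg_report = {"pixel_accuracy": accuracy}
    record_stage(
        "segment", seg_seed, {"labels": _json_hash(pred.tolist()), "report": _json_hash(seg_report)}
    )
    with open(os.path.join(out, "segmentation_report.json"), "w") as fh:
        json.dump(seg_report, fh, indent=2)

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def crossval_binary_eval(X, y, n_lv: int, n_blinds: int = 10) -> chemometrics.BinaryEval:
    """Pooled venetian-blind cross-validated confusion of the PLS-DA model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = chemometrics.venetian_blind_folds(y, n_blinds)
    preds = np.empty(len(y), dtype=object)
    for fold in folds:
        mask = np.zeros(len(y), dtype=bool)
        mask[fold] = True
        model = chemometrics.plsda_fit(X[~mask], y[~mask], n_lv)
        preds[mask] = model.predict(X[mask])
    classes = sorted(np.unique(y).tolist())
    positive = classes[1]
    pos = y == positive
    pred_pos = np.array([p == positive for p in preds])
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    return chemometrics.BinaryEval(
        tp, fn, tn, fp,
        tp / (tp + fn) if tp + fn else float("nan"),
        tn / (tn + fp) if tn + fp else float("nan"),
    )


def verify_manifest(output_dir: str) -> None:
    """Recompute artifact hashes from disk; raise IntegrityError on mismatch."""
    manifest_path = os.path.join(output_dir, "manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    recomputable = {
        ("synth", "cohort"): lambda: _cohort_hash(read_cohort(os.path.join(output_dir, "cohort"))),
        ("preprocess", "quantification"): lambda: _cohort_hash(
            read_cohort(os.path.join(output_dir, "cohort_quant"))
        ),
        ("preprocess", "classification"): lambda: _cohort_hash(
            read_cohort(os.path.join(output_dir, "cohort_classif"))
        ),
        ("quantify", "areas"): lambda: _file_hash(os.path.join(output_dir, "areas.csv")),
        ("plsda", "vip"): lambda: _file_hash(os.path.join(output_dir, "plsda_vip.csv")),
    }
    for (stage, name), recompute in recomputable.items():
        stored = manifest["stages"].get(stage, {}).get("artifacts", {}).get(name)
        if stored is None:
            continue
        if recompute() != stored:
            raise IntegrityError(f"artifact {stage}/{name} does not match its manifest hash")


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------

def load_run_config(path: str) -> RunConfig:
    """Build a RunConfig from a YAML file of (nested) field overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    gen_overrides = raw.pop("generator", {})
    pre_overrides = raw.pop("preprocess", {})
    if gen_overrides:
        cfg.generator = default_config(**gen_overrides)
    if pre_overrides:
        cfg.preprocess = dataclasses.replace(cfg.preprocess, **pre_overrides)
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown run-config field {key!r}")
        if key == "plsda_classes":
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg
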