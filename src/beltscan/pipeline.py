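"""One-command reproduction of the full synthetic study.

``run_all`` executes generate -> calibrate -> image -> features -> balance
-> train -> fine-tune -> evaluate and writes every artifact (manifest,
features, rendered images, four model bundles, fine-tuned bundles, report)
to a run directory stamped with the config hash and seed.

The default configuration is the *smoke profile*: the study's case counts
and frequency grid are kept in full, while the pixel grid, the CNN input
resolution and the CNN epoch budgets are reduced so a complete run fits in
minutes on one CPU. The full-scale settings (400x400 CNN input, 300/100
epochs, finer pixel grids) are plain config fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as M
from ._rng import subseed, substream
from .errors import ValidationError
from .evaluate import accuracy, evaluation_report, mean_squared_error
from .imaging import PixelGrid, normalize_to_reference, reconstruct_image, render_image, save_png
from .manifest import manifest_frame, write_manifest
from .phantom import DatasetDesign, GeneratedCase, generate_dataset, make_belt, simulate_sweep
from .preprocess import band_average_features, calibrate, preprocess_case
from .resampling import LabeledTable, augment_images, balance_dataset, leakage_safe_split
from .types import FrequencyGrid, TorsoScenario, assign_stage


logger = logging.getLogger("beltscan.pipeline")


@contextmanager
def _stage(name: str):
    """Log a pipeline stage with its wall-clock duration (stderr logger)."""
    t0 = time.time()
    logger.info("stage %s: start", name)
    yield
    logger.info("stage %s: done in %.2fs", name, time.time() - t0)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    design: DatasetDesign = field(default_factory=DatasetDesign)
    band: tuple[float, float] = (1.5e9, 3.0e9)
    pixel_grid: PixelGrid = field(default_factory=lambda: PixelGrid(48, 48))
    cnn_input: tuple[int, int] = (32, 32)
    detector_config: M.DetectorConfig = M.XGB_DETECTOR_CONFIG
    size_config: M.DetectorConfig = M.XGB_SIZE_CONFIG
    cnn_config: M.CnnConfig = field(
        default_factory=lambda: M.CnnConfig(input_size=(32, 32, 3), epochs=40,
                                            finetune_epochs=20)
    )
    adasyn_k: int = 5
    adasyn_beta: float = 1.0
    n_size_test: int = 10
    train_fraction: float = 0.8
    noise_levels: tuple[float, ...] = (0.01, 0.05, 0.10)
    finetune_fraction: float = 0.5
    n_noise_test: int = 20
    noise_test_level: float = 0.10
    finetune_cnn: bool = True
    clip_percentile: float = 99.5
    save_renders: int = 8  # how many PNG renders to keep on disk

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["grid"] = dataclasses.asdict(self.design.grid)
        d["pixel_grid"] = dataclasses.asdict(self.pixel_grid)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _healthy_reference(
    base: TorsoScenario, grid: FrequencyGrid, pixels: PixelGrid
) -> float:
    """Peak of the healthy case imaged after calibration.

    The skin-artifact step nulls a healthy synthetic case exactly, so the
    reference is taken one step earlier: the clutter-free image of the
    benign (skin) response. All case images are normalized to this level.
    """
    healthy = replace(base, tumor=None, belt_offset_mm=0.0)
    body, empty = simulate_sweep(healthy, grid=grid)
    img = reconstruct_image(calibrate(body, empty), make_belt(healthy), pixels,
                            healthy.background_tissue)
    peak = img.peak
    if peak <= 0:
        raise ValidationError("healthy reference image is identically zero")
    return peak


@dataclass
class ProcessedStudy:
    """All per-case intermediates of a run, kept in memory."""

    cases: list[GeneratedCase]
    manifest: pd.DataFrame
    features: LabeledTable  # 128-vector per case, y = label
    radii: np.ndarray  # ground-truth radius per case, mm
    images: LabeledTable  # rendered rasters per case, y = label
    normalized_peaks: np.ndarray
    processed: list[M.ProcessedCase]
    healthy_refs: dict[str, float]
    clip_max: float


def process_study(config: RunConfig, with_images: bool = True) -> ProcessedStudy:
    """Generate the dataset and compute features (and images) for every case.

    ``with_images=False`` skips reconstruction and rendering for
    feature-only experiments (the tabular route).
    """
    cases = generate_dataset(config.design, seed=config.seed)
    rows = [c.row for c in cases]
    mdf = manifest_frame(rows)

    refs: dict[str, float] = {}
    if with_images:
        for c in cases:
            if c.scenario.phantom_id not in refs:
                refs[c.scenario.phantom_id] = _healthy_reference(
                    c.scenario, config.design.grid, config.pixel_grid
                )

    feats, processed, recon = [], [], []
    for c in cases:
        sweep = preprocess_case(c.body, c.empty)
        feats.append(band_average_features(sweep, config.band).values)
        processed.append(
            M.ProcessedCase(c.row.case_id, sweep, c.row.tumor_diameter_mm, c.row.label)
        )
        if with_images:
            img = reconstruct_image(sweep, make_belt(c.scenario), config.pixel_grid,
                                    c.scenario.background_tissue)
            recon.append(normalize_to_reference(img, refs[c.scenario.phantom_id]))

    labels = mdf["label"].to_numpy()
    ids = mdf["case_id"].tolist()
    if with_images:
        # one fixed color scale across the study: a high percentile of the
        # normalized training (set A/B) pixel values
        ab = [im for im, c in zip(recon, cases)
              if c.row.simulation_set in ("A", "B")]
        clip_max = float(
            np.percentile(np.concatenate([im.normalized.ravel() for im in ab]),
                          config.clip_percentile)
        )
        rasters = np.stack(
            [render_image(im, size=config.cnn_input, clip_max=clip_max)
             for im in recon]
        )
        peaks = np.array([im.normalized.max() for im in recon])
    else:
        clip_max = 0.0
        rasters = np.zeros((len(cases), 1, 1, 3), dtype=np.uint8)
        peaks = np.zeros(len(cases))
    return ProcessedStudy(
        cases=cases,
        manifest=mdf,
        features=LabeledTable(np.asarray(feats), labels, ids),
        radii=mdf["radius_mm"].to_numpy(),
        images=LabeledTable(rasters, labels, ids),
        normalized_peaks=peaks,
        processed=processed,
        healthy_refs=refs,
        clip_max=clip_max,
    )


def _detector_split(study: ProcessedStudy, config: RunConfig):
    """A+B cases split by case into train/val/test for the detectors."""
    ab_idx = np.flatnonzero(study.manifest["simulation_set"].isin(["A", "B"]))
    rng = substream(config.seed, "detector-split")
    perm = rng.permutation(len(ab_idx))
    n_test = int(round((1 - config.train_fraction) * len(ab_idx)))
    test_idx = ab_idx[perm[:n_test]]
    train_idx = ab_idx[perm[n_test:]]
    return train_idx, test_idx


def _size_test_ids(study: ProcessedStudy, config: RunConfig) -> list[str]:
    a_ids = study.manifest.loc[study.manifest["simulation_set"] == "A", "case_id"]
    rng = substream(config.seed, "size-test")
    pick = rng.choice(len(a_ids), size=config.n_size_test, replace=False)
    return sorted(a_ids.iloc[sorted(pick)])


def run_all(config: RunConfig | None = None, out_dir: str | Path = "runs") -> dict:
    """Execute the full study; returns a results dict (also written as JSON)."""
    config = config or RunConfig()
    t0 = time.time()
    run_dir = Path(out_dir) / f"run-{config.config_hash()}-seed{config.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, default=str)
    )

    with _stage("simulate+preprocess+image"):
        study = process_study(config)
    write_manifest([c.row for c in study.cases], run_dir / "manifest.csv")
    from .preprocess import FEATURE_COLUMNS

    fdf = pd.DataFrame(study.features.X, columns=FEATURE_COLUMNS)
    fdf.insert(0, "case_id", study.features.case_ids)
    fdf.to_csv(run_dir / "features.csv", index=False)

    img_dir = run_dir / "images"
    img_dir.mkdir(exist_ok=True)
    for i in range(min(config.save_renders, len(study.images.X))):
        save_png(study.images.X[i], img_dir / f"{study.images.case_ids[i]}.png")

    results: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "n_cases": len(study.cases), "clip_max": study.clip_max}
    mdf = study.manifest

    # ---- tabular detector (A+B): split by case, balance the training set
    logger.info("stage train: xgb detector")
    train_idx, test_idx = _detector_split(study, config)
    det_train = balance_dataset(study.features.subset(train_idx),
                                k=config.adasyn_k, beta=config.adasyn_beta,
                                seed=subseed(config.seed, "adasyn-feat"))
    det_bundle = M.train_xgb_detector(det_train, config.detector_config,
                                      seed=subseed(config.seed, "xgbdet"))
    det_test = study.features.subset(test_idx)
    det_pred = M.predict(det_bundle, det_test)
    results["xgb_detector_accuracy"] = accuracy(det_test.y, det_pred.labels)
    results["n_detector_test"] = len(test_idx)

    # ---- tabular size regressor (A only, radius targets, 10 held-out cases)
    size_test_ids = _size_test_ids(study, config)
    a_mask = mdf["simulation_set"] == "A"
    a_idx = np.flatnonzero(a_mask)
    id_arr = mdf["case_id"].to_numpy()
    a_test = [i for i in a_idx if id_arr[i] in size_test_ids]
    a_train = [i for i in a_idx if id_arr[i] not in size_test_ids]
    size_train = study.features.subset(a_train)
    size_train = LabeledTable(size_train.X, study.radii[a_train],
                              size_train.case_ids)
    size_bundle = M.train_xgb_size(size_train, config.size_config,
                                   seed=subseed(config.seed, "xgbsize"))
    xgb_size_pred = M.predict(size_bundle, study.features.subset(a_test))
    results["xgb_size_mse_mm2"] = mean_squared_error(study.radii[a_test],
                                                     xgb_size_pred.sizes_mm)
    results["size_target_variance_mm2"] = float(np.var(study.radii[a_idx]))
    results["n_size_test"] = len(a_test)

    # ---- CNN detector (A+B images): balance training rasters with ADASYN
    cnn_det_train = balance_dataset(study.images.subset(train_idx),
                                    k=config.adasyn_k, beta=config.adasyn_beta,
                                    seed=subseed(config.seed, "adasyn-img"))
    logger.info("stage train: cnn detector")
    cnn_det = M.build_cnn("detector", config.cnn_config,
                          seed=subseed(config.seed, "cnndet-init"))
    M.train_cnn(cnn_det, cnn_det_train, config.cnn_config,
                seed=subseed(config.seed, "cnndet"))
    cnn_det_pred = M.predict(cnn_det, study.images.subset(test_idx))
    results["cnn_detector_accuracy"] = accuracy(study.images.subset(test_idx).y,
                                                cnn_det_pred.labels)

    # ---- CNN size regressor (A images, augmented x4, leakage-safe split)
    a_images = study.images.subset(a_idx)
    a_images = LabeledTable(a_images.X, study.radii[a_idx], a_images.case_ids)
    augmented = augment_images(a_images)
    cnn_train, cnn_val, cnn_test = leakage_safe_split(
        augmented, size_test_ids, config.train_fraction,
        seed=subseed(config.seed, "cnn-split"),
    )
    results["n_cnn_size_training_pool"] = len(cnn_train) + len(cnn_val)
    logger.info("stage train: cnn size")
    cnn_size = M.build_cnn("size", config.cnn_config,
                           seed=subseed(config.seed, "cnnsize-init"))
    M.train_cnn(cnn_size, cnn_train, config.cnn_config,
                seed=subseed(config.seed, "cnnsize"))
    cnn_size_pred = M.predict(cnn_size, cnn_test)
    results["cnn_size_mse_mm2"] = mean_squared_error(cnn_test.y,
                                                     cnn_size_pred.sizes_mm)

    # ---- noise fine-tuning (study protocol: XGB detector + CNN size)
    logger.info("stage finetune")
    a_processed = [study.processed[i] for i in a_idx]
    ft = noise_robustness_trial(
        det_bundle, size_bundle, a_processed, config, seed=config.seed
    )
    results.update({f"finetune_{k}": v for k, v in ft.items()})
    pick, hold = M.finetune_split(len(a_processed), config.finetune_fraction,
                                  subseed(config.seed, "ft"))
    det_ft = M.finetune_with_noise(det_bundle, a_processed, config.noise_levels,
                                   config.finetune_fraction,
                                   seed=subseed(config.seed, "ft"), indices=pick)
    cnn_size_ft = None
    if config.finetune_cnn:
        phantom_ref = study.healthy_refs["phantom-A"]

        def image_featurizer(sweep, _belt=make_belt(study.cases[0].scenario)):
            img = reconstruct_image(sweep, _belt, config.pixel_grid)
            img = normalize_to_reference(img, phantom_ref)
            return render_image(img, size=config.cnn_input, clip_max=study.clip_max)

        cnn_size_ft = M.finetune_with_noise(
            cnn_size, a_processed, config.noise_levels, config.finetune_fraction,
            seed=subseed(config.seed, "ft-cnn"), featurizer=image_featurizer,
            cnn_config=config.cnn_config, indices=pick,
        )

    # ---- evaluation report (held-out + cross-phantom)
    c_idx = np.flatnonzero(mdf["simulation_set"] == "C")
    preds = {}
    det_cases = np.concatenate([test_idx, c_idx]).astype(int)
    det_all = M.predict(det_bundle, study.features.subset(det_cases))
    preds["xgb_detector"] = pd.DataFrame(
        {"case_id": id_arr[det_cases], "label": det_all.labels}
    )
    cnn_det_all = M.predict(cnn_det, study.images.subset(det_cases))
    preds["cnn_detector"] = pd.DataFrame(
        {"case_id": id_arr[det_cases], "label": cnn_det_all.labels}
    )
    size_cases = np.asarray(list(a_test) + list(c_idx), dtype=int)
    preds["xgb_size"] = pd.DataFrame({
        "case_id": id_arr[size_cases],
        "size_mm": M.predict(size_bundle, study.features.subset(size_cases)).sizes_mm,
    })
    preds["cnn_size"] = pd.DataFrame({
        "case_id": id_arr[size_cases],
        "size_mm": M.predict(cnn_size, study.images.subset(size_cases)).sizes_mm,
    })
    held = mdf.iloc[np.unique(np.concatenate([det_cases, size_cases]))]
    report, summary = evaluation_report(held, preds)
    if len(c_idx):
        results["cross_phantom_xgb_detector_accuracy"] = float(
            report.query("model == 'xgb_detector' and domain == 'cross_phantom'")[
                "value"
            ].iloc[0]
        )
    report.to_csv(run_dir / "report.csv", index=False)

    # staging of the size-test cases from the CNN size predictions
    stage_rows = []
    for cid, pred_r in zip(preds["cnn_size"]["case_id"], preds["cnn_size"]["size_mm"]):
        true_d = float(mdf.loc[mdf["case_id"] == cid, "tumor_diameter_mm"].iloc[0])
        stage_rows.append({
            "case_id": cid,
            "true_stage": assign_stage(true_d).value,
            "predicted_stage": assign_stage(max(2 * pred_r, 0.0)).value,
        })
    pd.DataFrame(stage_rows).to_csv(run_dir / "stages.csv", index=False)

    bundles = {"xgb_detector": det_bundle, "xgb_size": size_bundle,
               "cnn_detector": cnn_det, "cnn_size": cnn_size,
               "xgb_detector_finetuned": det_ft}
    if cnn_size_ft is not None:
        bundles["cnn_size_finetuned"] = cnn_size_ft
    for name, b in bundles.items():
        M.save_bundle(b, run_dir / "bundles" / name)

    results["elapsed_s"] = round(time.time() - t0, 2)
    (run_dir / "report.md").write_text(summary + "\n")
    (run_dir / "results.json").write_text(json.dumps(results, indent=1))
    results["run_dir"] = str(run_dir)
    results["report"] = report
    return results


def noise_robustness_trial(
    det_bundle: M.ModelBundle,
    size_bundle: M.ModelBundle,
    a_processed: list[M.ProcessedCase],
    config: RunConfig | None = None,
    seed: int = 0,
) -> dict:
    """Fine-tuned vs naive on a noisy held-out test set (tabular route).

    Fine-tunes the detector and size regressor on a noise-infused half of
    the on-plane cases, then compares against the naive bundles on
    ``n_noise_test`` unseen cases perturbed at the 10% level. Returns the
    four metrics.
    """
    config = config or RunConfig()
    pick, hold = M.finetune_split(len(a_processed), config.finetune_fraction,
                                  subseed(seed, "ft"))
    det_ft = M.finetune_with_noise(det_bundle, a_processed, config.noise_levels,
                                   config.finetune_fraction,
                                   seed=subseed(seed, "ft"), indices=pick)
    size_ft = M.finetune_with_noise(size_bundle, a_processed, config.noise_levels,
                                    config.finetune_fraction,
                                    seed=subseed(seed, "ft"), indices=pick)
    rng = substream(seed, "noise-test")
    test_pick = rng.choice(len(hold), size=min(config.n_noise_test, len(hold)),
                           replace=False)
    rows, labels, radii = [], [], []
    for j in sorted(test_pick):
        case = a_processed[hold[j]]
        rng_c = substream(subseed(seed, "noisetest", case.case_id), "x")
        rows.append(M.perturb_values(M.default_featurizer(case.sweep),
                                     config.noise_test_level, rng_c))
        labels.append(case.label)
        radii.append(case.diameter_mm / 2.0)
    X = np.asarray(rows)
    labels, radii = np.asarray(labels), np.asarray(radii)
    out = {
        "naive_detector_accuracy": accuracy(labels, M.predict(det_bundle, X).labels),
        "finetuned_detector_accuracy": accuracy(labels, M.predict(det_ft, X).labels),
        "naive_size_mse_mm2": mean_squared_error(radii,
                                                 M.predict(size_bundle, X).sizes_mm),
        "finetuned_size_mse_mm2": mean_squared_error(radii,
                                                     M.predict(size_ft, X).sizes_mm),
    }
    return out


def xgb_noise_robustness(seed: int, config: RunConfig | None = None) -> dict:
    """Tabular-route fine-tuned vs naive comparison for one seed.

    Trains the detector (balanced A+B split) and the size regressor
    (set A minus the held-out test cases), then runs the noisy-test
    comparison; no imaging, so one seed takes seconds.
    """
    config = replace(config or RunConfig(), seed=seed)
    study = process_study(config, with_images=False)
    train_idx, _ = _detector_split(study, config)
    det_train = balance_dataset(study.features.subset(train_idx),
                                k=config.adasyn_k, beta=config.adasyn_beta,
                                seed=subseed(seed, "adasyn-feat"))
    det = M.train_xgb_detector(det_train, config.detector_config,
                               seed=subseed(seed, "xgbdet"))
    a_idx = np.flatnonzero(study.manifest["simulation_set"] == "A")
    test_ids = set(_size_test_ids(study, config))
    id_arr = study.manifest["case_id"].to_numpy()
    a_train = [i for i in a_idx if id_arr[i] not in test_ids]
    strain = study.features.subset(a_train)
    strain = LabeledTable(strain.X, study.radii[a_train], strain.case_ids)
    size = M.train_xgb_size(strain, config.size_config,
                            seed=subseed(seed, "xgbsize"))
    a_processed = [study.processed[i] for i in a_idx]
    return noise_robustness_trial(det, size, a_processed, config, seed=seed)


FIXTURE_DIAMETERS = (4.0, 8.0, 12.0, 20.0, 36.0, 48.0)


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> dict:
    """12-case miniature dataset (6 diameters per lung) with files on disk.

    Uses a 160-point frequency grid so the whole bundle (sweeps, features,
    images, manifest) stays well under 20 MB.
    """
    design = DatasetDesign(
        grid=FrequencyGrid(0.5e9, 3.5e9, 160),
        sizes_a_mm=FIXTURE_DIAMETERS,
        include_b=False,
        include_c=False,
    )
    out = Path(out_dir)
    cases = generate_dataset(design, seed=seed, out_dir=out)
    pixels = PixelGrid(48, 48)
    ref = _healthy_reference(cases[0].scenario, design.grid, pixels)
    feats, peaks = [], {}
    for c in cases:
        sweep = preprocess_case(c.body, c.empty)
        feats.append(band_average_features(sweep).values)
        img = normalize_to_reference(
            reconstruct_image(sweep, make_belt(c.scenario), pixels), ref
        )
        peaks[c.row.case_id] = float(img.normalized.max())
        save_png(render_image(img, size=(64, 64)), out / f"{c.row.case_id}.png")
    from .preprocess import FEATURE_COLUMNS

    fdf = pd.DataFrame(np.asarray(feats), columns=FEATURE_COLUMNS)
    fdf.insert(0, "case_id", [c.row.case_id for c in cases])
    fdf.to_csv(out / "features.csv", index=False)
    return {"manifest": out / "manifest.csv", "n_cases": len(cases),
            "normalized_peaks": peaks, "dir": out}
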