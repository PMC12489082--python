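"""The four learners and the noise fine-tuning protocol.

Tabular route: gradient-boosted trees (XGBoost) on the 128 band-averaged
S-parameter features — a detector with (n_estimators=10, max_depth=3,
eta=0.3, subsample=0.5) and a size regressor with (1000, 4, 0.3, 0.5).
Image route: a small CNN detector (binary cross-entropy head) and size
regressor (linear head) on rendered reconstruction rasters.

Fine-tuning for noise robustness: half of the on-plane cases are sampled,
perturbed at 1/5/10% relative noise (three noisy copies per sampled case),
and the trained model continues — additional boosting rounds for the tree
models (incremental learning), additional epochs for the CNNs.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import xgboost as xgb

from . import nn
from ._rng import subseed, substream
from .errors import DimensionError, ValidationError
from .preprocess import band_average_features
from .resampling import LabeledTable
from .types import SMatrixSweep

XGB_DETECTOR = "xgb_detector"
XGB_SIZE = "xgb_size"
CNN_DETECTOR = "cnn_detector"
CNN_SIZE = "cnn_size"
KINDS = (XGB_DETECTOR, XGB_SIZE, CNN_DETECTOR, CNN_SIZE)

DETECTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class DetectorConfig:
    """Gradient-boosted tree hyperparameters."""

    n_estimators: int = 10
    max_depth: int = 3
    eta: float = 0.3
    subsample: float = 0.5


XGB_DETECTOR_CONFIG = DetectorConfig(10, 3, 0.3, 0.5)
XGB_SIZE_CONFIG = DetectorConfig(1000, 4, 0.3, 0.5)

# Incremental-learning budgets: (extra trees, continuation learning rate).
# The fine-tuning set is small (a few hundred noisy rows), so the regressor
# continues with strong shrinkage; an aggressive continuation memorizes the
# individual noise draws and defeats the purpose of the protocol.
FINETUNE_XGB = {XGB_DETECTOR: (10, 0.3), XGB_SIZE: (100, 0.02)}


@dataclass(frozen=True)
class CnnConfig:
    """CNN topology and training budget.

    input_size is the raster fed to the network; global average pooling
    makes the weights valid at any resolution, so reduced-size profiles
    reuse the same topology.
    """

    input_size: tuple[int, int, int] = (400, 400, 3)
    channels: tuple[int, ...] = (8, 16, 32, 32)
    dense_units: int = 16
    epochs: int = 300
    finetune_epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 16


@dataclass
class ModelBundle:
    """A trained (or untrained) model plus its training manifest."""

    kind: str
    model: object
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown model kind {self.kind!r}")

    @property
    def is_cnn(self) -> bool:
        return self.kind in (CNN_DETECTOR, CNN_SIZE)

    @property
    def is_detector(self) -> bool:
        return self.kind in (XGB_DETECTOR, CNN_DETECTOR)


@dataclass
class Prediction:
    """Detector output (probability + thresholded label) or sizes in mm."""

    kind: str
    proba: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    sizes_mm: Optional[np.ndarray] = None


def _as_matrix(table: LabeledTable | np.ndarray) -> np.ndarray:
    X = table.X if isinstance(table, LabeledTable) else np.asarray(table)
    return X.reshape(X.shape[0], -1)


def _cnn_input(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.dtype == np.uint8:
        X = X.astype(np.float32) / 255.0
    return X.astype(np.float32)


def train_xgb_detector(
    features: LabeledTable,
    config: DetectorConfig = XGB_DETECTOR_CONFIG,
    seed: int = 0,
) -> ModelBundle:
    """Fit the gradient-boosted detector on a balanced 128-feature table."""
    X = _as_matrix(features)
    if X.shape[1] != 128:
        raise DimensionError(f"detector features must have length 128, got {X.shape[1]}")
    y = features.y.astype(int)
    model = xgb.XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.eta,
        subsample=config.subsample,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )
    model.fit(X, y)
    manifest = {"config": asdict(config), "seed": seed,
                "case_ids": list(features.case_ids)}
    return ModelBundle(XGB_DETECTOR, model, manifest)


def train_xgb_size(
    features: LabeledTable,
    config: DetectorConfig = XGB_SIZE_CONFIG,
    seed: int = 0,
) -> ModelBundle:
    """Fit the gradient-boosted size regressor (targets: tumor radius, mm)."""
    X = _as_matrix(features)
    y = features.y.astype(float)
    if np.any(y < 0):
        raise ValidationError("size targets must be non-negative (radius in mm)")
    model = xgb.XGBRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.eta,
        subsample=config.subsample,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    manifest = {"config": asdict(config), "seed": seed,
                "case_ids": list(features.case_ids)}
    return ModelBundle(XGB_SIZE, model, manifest)


def build_cnn(kind: str, config: CnnConfig = CnnConfig(), seed: int = 0) -> ModelBundle:
    """Untrained CNN bundle; 'detector' or 'size'."""
    kind_full = {"detector": CNN_DETECTOR, "size": CNN_SIZE}.get(kind, kind)
    if kind_full not in (CNN_DETECTOR, CNN_SIZE):
        raise ValidationError(f"unknown CNN kind {kind!r}")
    model = nn.SmallCNN(
        channels=config.channels,
        dense_units=config.dense_units,
        in_channels=config.input_size[2],
        seed=seed,
    )
    manifest = {"config": asdict(config), "seed": seed, "loss_history": []}
    return ModelBundle(kind_full, model, manifest)


def train_cnn(
    bundle: ModelBundle,
    rasters: LabeledTable,
    config: CnnConfig = CnnConfig(),
    seed: int = 0,
) -> ModelBundle:
    """Train a CNN bundle in place on labeled rasters; logs the loss curve."""
    if not bundle.is_cnn:
        raise ValidationError("train_cnn requires a CNN bundle")
    if len(rasters) == 0:
        raise ValidationError("empty training set")
    X = _cnn_input(rasters.X)
    y = rasters.y.astype(np.float32)
    loss = "bce" if bundle.kind == CNN_DETECTOR else "mse"
    history = nn.fit(
        bundle.model, X, y,
        epochs=config.epochs, batch_size=config.batch_size, lr=config.lr,
        loss=loss, seed=subseed(seed, "train", bundle.kind),
    )
    bundle.manifest.setdefault("loss_history", []).extend(history)
    bundle.manifest["case_ids"] = list(rasters.case_ids)
    bundle.manifest["seed"] = seed
    return bundle


def predict(bundle: ModelBundle, inputs: LabeledTable | np.ndarray) -> Prediction:
    """Deterministic, batch-order-invariant prediction."""
    if bundle.is_cnn:
        X = _cnn_input(inputs.X if isinstance(inputs, LabeledTable) else inputs)
        if X.ndim != 4:
            raise DimensionError("CNN input must be (n, h, w, c) rasters")
        out = nn.predict(bundle.model, X)
        if bundle.kind == CNN_DETECTOR:
            proba = 1.0 / (1.0 + np.exp(-out.astype(np.float64)))
            return Prediction(bundle.kind, proba=proba,
                              labels=(proba >= DETECTION_THRESHOLD).astype(int))
        return Prediction(bundle.kind, sizes_mm=out.astype(float))
    X = _as_matrix(inputs)
    n_expected = bundle.model.n_features_in_
    if X.shape[1] != n_expected:
        raise DimensionError(f"expected {n_expected} features, got {X.shape[1]}")
    if bundle.kind == XGB_DETECTOR:
        proba = bundle.model.predict_proba(X)[:, 1]
        return Prediction(bundle.kind, proba=proba,
                          labels=(proba >= DETECTION_THRESHOLD).astype(int))
    return Prediction(bundle.kind, sizes_mm=bundle.model.predict(X).astype(float))


# ---------------------------------------------------------------------------
# Noise fine-tuning


@dataclass
class ProcessedCase:
    """A case ready for representation: processed sweep + ground truth."""

    case_id: str
    sweep: SMatrixSweep  # calibrated + skin-removed
    diameter_mm: float
    label: int


def default_featurizer(sweep: SMatrixSweep) -> np.ndarray:
    """Band-averaged 128-feature representation (tabular route)."""
    return band_average_features(sweep).values


def _float_repr(x: np.ndarray) -> np.ndarray:
    """Model-input representation as floats (uint8 rasters scaled to [0,1])."""
    x = np.asarray(x)
    if x.dtype == np.uint8:
        return x.astype(np.float32) / 255.0
    return x.astype(float)


def perturb_values(x: np.ndarray, level: float, rng: np.random.Generator) -> np.ndarray:
    """Alter every value of a data record by up to ``level`` of itself.

    Multiplicative elementwise perturbation x * (1 + u), u ~ U(-p, +p) —
    the noise model of the robustness protocol, acting on the data record
    fed to a model (feature vector or normalized raster). Level 0 returns
    an identical copy.
    """
    if level < 0:
        raise ValidationError("noise level must be >= 0")
    if level == 0:
        return np.array(x, copy=True)
    return x * (1.0 + rng.uniform(-level, level, size=x.shape))


def finetune_split(
    n_cases: int, fraction: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split of case indices into (fine-tune subset, holdout)."""
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    rng = substream(seed, "finetune-sample")
    n_pick = max(1, int(round(fraction * n_cases)))
    picked = np.sort(rng.choice(n_cases, size=n_pick, replace=False))
    holdout = np.setdiff1d(np.arange(n_cases), picked)
    return picked, holdout


def build_noisy_set(
    cases: Sequence[ProcessedCase],
    noise_levels: Sequence[float] = (0.01, 0.05, 0.10),
    fraction: float = 0.5,
    seed: int = 0,
    featurizer: Callable[[SMatrixSweep], np.ndarray] = default_featurizer,
    target: str = "label",
    indices: Optional[Sequence[int]] = None,
) -> LabeledTable:
    """Sample a fraction of cases and emit one noisy copy per noise level."""
    if not cases:
        raise ValidationError("no cases supplied")
    if indices is None:
        indices, _ = finetune_split(len(cases), fraction, seed)
    rows, ys, ids = [], [], []
    for idx in indices:
        case = cases[idx]
        x0 = _float_repr(featurizer(case.sweep))
        for level in noise_levels:
            rng = substream(subseed(seed, "noise", case.case_id), str(level))
            rows.append(perturb_values(x0, level, rng))
            ys.append(case.label if target == "label" else case.diameter_mm / 2.0)
            ids.append(f"{case.case_id}-n{level:g}")
    return LabeledTable(np.asarray(rows), np.asarray(ys), ids,
                        provenance=["original"] * len(ids))


def finetune_with_noise(
    bundle: ModelBundle,
    cases: Sequence[ProcessedCase],
    noise_levels: Sequence[float] = (0.01, 0.05, 0.10),
    fraction: float = 0.5,
    seed: int = 0,
    featurizer: Callable[[SMatrixSweep], np.ndarray] = default_featurizer,
    cnn_config: CnnConfig = CnnConfig(),
    n_extra_trees: int | None = None,
    indices: Optional[Sequence[int]] = None,
) -> ModelBundle:
    """Continue training a fitted bundle on a noise-infused subset.

    Returns a new bundle; the input bundle is left untouched so naive and
    fine-tuned models can be compared side by side.
    """
    target = "label" if bundle.is_detector else "radius"
    noisy = build_noisy_set(cases, noise_levels, fraction, seed, featurizer,
                            target, indices=indices)
    manifest = dict(bundle.manifest)
    manifest["finetune"] = {"noise_levels": list(noise_levels),
                            "fraction": fraction, "seed": seed}

    if bundle.is_cnn:
        new_model = nn.SmallCNN(
            channels=bundle.model.channels,
            dense_units=bundle.model.dense_units,
            in_channels=bundle.model.in_channels,
            seed=0,
        )
        new_model.set_weights(bundle.model.get_weights())
        new_bundle = ModelBundle(bundle.kind, new_model, manifest)
        loss = "bce" if bundle.kind == CNN_DETECTOR else "mse"
        history = nn.fit(
            new_model, _cnn_input(noisy.X), noisy.y.astype(np.float32),
            epochs=cnn_config.finetune_epochs, batch_size=cnn_config.batch_size,
            lr=cnn_config.lr, loss=loss, seed=subseed(seed, "finetune", bundle.kind),
        )
        manifest.setdefault("loss_history", []).extend(history)
        return new_bundle

    default_trees, cont_lr = FINETUNE_XGB[bundle.kind]
    n_extra = n_extra_trees if n_extra_trees is not None else default_trees
    X, y = _as_matrix(noisy), noisy.y
    base = bundle.model
    cls = xgb.XGBClassifier if bundle.kind == XGB_DETECTOR else xgb.XGBRegressor
    params = base.get_params()
    params.update(n_estimators=n_extra, learning_rate=cont_lr,
                  random_state=subseed(seed, "finetune"))
    cont = cls(**params)
    cont.fit(X, y.astype(int) if bundle.is_detector else y.astype(float),
             xgb_model=base.get_booster())
    return ModelBundle(bundle.kind, cont, manifest)


# ---------------------------------------------------------------------------
# Persistence


def save_bundle(bundle: ModelBundle, directory: str | Path) -> Path:
    """Save a bundle as a directory: manifest.json + weights blob."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"kind": bundle.kind, "manifest": bundle.manifest}
    if bundle.is_cnn:
        meta["arch"] = {
            "channels": list(bundle.model.channels),
            "dense_units": bundle.model.dense_units,
            "in_channels": bundle.model.in_channels,
        }
        np.savez(directory / "weights.npz",
                 **{f"p{i}": w for i, w in enumerate(bundle.model.get_weights())})
    else:
        # persist at booster level; the sklearn wrapper is rebuilt on load
        bundle.model.get_booster().save_model(directory / "model.ubj")
    (directory / "manifest.json").write_text(json.dumps(meta, default=str, indent=1))
    return directory


def load_bundle(directory: str | Path) -> ModelBundle:
    directory = Path(directory)
    meta = json.loads((directory / "manifest.json").read_text())
    kind = meta["kind"]
    if kind in (CNN_DETECTOR, CNN_SIZE):
        arch = meta["arch"]
        model = nn.SmallCNN(
            channels=tuple(arch["channels"]),
            dense_units=arch["dense_units"],
            in_channels=arch["in_channels"],
            seed=0,
        )
        with np.load(directory / "weights.npz") as blob:
            model.set_weights([blob[f"p{i}"] for i in range(len(blob.files))])
    else:
        cls = xgb.XGBClassifier if kind == XGB_DETECTOR else xgb.XGBRegressor
        model = cls()
        model.load_model(directory / "model.ubj")
    return ModelBundle(kind, model, meta.get("manifest", {}))
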