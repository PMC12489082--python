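"""Train the tabular detector and size regressor on a small synthetic study.

Generates a reduced study (20 on-plane cases per lung), trains the
gradient-boosted detector on balanced features and the size regressor on
radius targets, and evaluates both on held-out cases.
"""

import numpy as np

import beltscan as bs
from beltscan import models as M
from beltscan.phantom import DatasetDesign
from beltscan.pipeline import RunConfig, process_study, _detector_split
from beltscan.resampling import LabeledTable, balance_dataset

design = DatasetDesign(
    grid=bs.FrequencyGrid(0.5e9, 3.5e9, 128),
    sizes_a_mm=tuple(np.linspace(2.0, 60.0, 20)),
)
config = RunConfig(seed=0, design=design)
study = process_study(config, with_images=False)
print(f"{len(study.processed)} cases "
      f"({study.manifest['label'].eq(0).sum()} class 0, "
      f"{study.manifest['label'].eq(1).sum()} class 1)")

train_idx, test_idx = _detector_split(study, config)
balanced = balance_dataset(study.features.subset(train_idx), seed=0)
detector = M.train_xgb_detector(balanced, seed=0)
pred = M.predict(detector, study.features.subset(test_idx))
acc = np.mean(pred.labels == study.features.subset(test_idx).y)
print(f"detector held-out accuracy: {acc:.2f} on {len(test_idx)} cases")

a_idx = np.flatnonzero(study.manifest["simulation_set"] == "A")
test = a_idx[::5]
train = np.setdiff1d(a_idx, test)
t = study.features.subset(train)
regressor = M.train_xgb_size(LabeledTable(t.X, study.radii[train], t.case_ids),
                             seed=0)
sizes = M.predict(regressor, study.features.subset(test)).sizes_mm
mse = np.mean((sizes - study.radii[test]) ** 2)
print(f"size regressor held-out MSE: {mse:.2f} mm^2 "
      f"(target variance {np.var(study.radii[a_idx]):.1f} mm^2)")
for r_true, r_pred in list(zip(study.radii[test], sizes))[:4]:
    print(f"  true radius {r_true:5.1f} mm -> predicted {r_pred:5.1f} mm, "
          f"stage {bs.assign_stage(2 * r_pred).value}")
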