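"""Band-averaged features and ADASYN class rebalancing.

Each processed sweep is summarized as 128 values: the mean amplitude and
mean unwrapped phase of each of the 64 channels over 1.5-3 GHz. The
detection dataset is imbalanced (few tumors <= 8 mm), so ADASYN
synthesizes minority points near the class boundary until the classes
match.
"""

import numpy as np

import beltscan as bs
from beltscan.resampling import LabeledTable, balance_dataset

rng = np.random.default_rng(0)

# one real feature vector, to show the representation
scenario = bs.TorsoScenario(tumor=bs.Tumor(center=(-0.06, 0, 0),
                                           diameter_mm=12.0))
body, empty = bs.simulate_sweep(scenario, grid=bs.FrequencyGrid(0.5e9, 3.5e9, 128))
fv = bs.band_average_features(bs.preprocess_case(body, empty))
print(f"feature vector length: {len(fv.values)} "
      f"(64 amplitude means + 64 phase means over "
      f"{fv.band[0] / 1e9:.1f}-{fv.band[1] / 1e9:.1f} GHz)")

# the study's imbalance: 26 small-tumor cases vs 134 larger ones
X = np.vstack([rng.normal(size=(26, 128)), rng.normal(loc=3.0, size=(134, 128))])
y = np.array([0] * 26 + [1] * 134)
table = LabeledTable(X, y, [f"case{i:03d}" for i in range(160)])
balanced = balance_dataset(table, k=5, beta=1.0, seed=0)

n_syn = balanced.provenance.count("synthetic")
print(f"before balancing: {table.class_counts()}")
print(f"ADASYN synthesized {n_syn} minority points "
      f"-> {balanced.class_counts()}, {len(balanced)} rows total")
# 26 + 108 = 134 per class: every synthetic point is a convex combination
# of two small-tumor cases, concentrated near the decision boundary.
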