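"""Class rebalancing (ADASYN), image augmentation and leakage-safe splits.

ADASYN synthesizes minority-class points preferentially near the class
boundary: each minority point is weighted by the fraction of majority
points among its k nearest neighbours in the combined set, the synthesis
budget G = round(beta * (majority - minority)) is allocated by
largest-remainder rounding (so the total is hit exactly), and each
synthetic point is a convex combination of two minority points.

Augmentation quadruples an image set with horizontal flip, vertical flip
and 180-degree rotation (= both flips). Splits are performed by *case*,
with every synthetic/augmented descendant excluded from training whenever
its parent is held out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ._rng import substream
from .errors import LeakageError, ValidationError

ORIGINAL = "original"
SYNTHETIC = "synthetic"
AUGMENTED = "augmented"


@dataclass
class LabeledTable:
    """Rows of (features or images, label/target, case id, provenance).

    X has shape (n, ...) — (n, 128) for feature vectors, (n, h, w, c) for
    rasters. ``parents`` carries the originating case ids of synthetic and
    augmented rows (empty for originals).
    """

    X: np.ndarray
    y: np.ndarray
    case_ids: list[str]
    provenance: list[str] = field(default_factory=list)
    parents: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        n = self.X.shape[0]
        if not self.provenance:
            self.provenance = [ORIGINAL] * n
        if not self.parents:
            self.parents = [()] * n
        if not (len(self.y) == len(self.case_ids) == len(self.provenance)
                == len(self.parents) == n):
            raise ValidationError("inconsistent row counts in LabeledTable")

    def __len__(self) -> int:
        return int(self.X.shape[0])

    def subset(self, idx: np.ndarray | list[int]) -> "LabeledTable":
        idx = np.asarray(idx, dtype=int)
        return LabeledTable(
            X=self.X[idx],
            y=self.y[idx],
            case_ids=[self.case_ids[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
            parents=[self.parents[i] for i in idx],
        )

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y.astype(int), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``quotas``.

    Floors each quota, then distributes the remaining units to the largest
    fractional parts (ties broken by index). The result sums to ``total``
    exactly.
    """
    base = np.floor(quotas).astype(int)
    remainder = int(total) - int(base.sum())
    if remainder > 0:
        frac = quotas - base
        order = np.lexsort((np.arange(len(quotas)), -frac))
        base[order[:remainder]] += 1
    return base


def adasyn(
    minority: np.ndarray,
    majority: np.ndarray,
    k: int = 5,
    beta: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Generate synthetic minority points; returns (points, parent index pairs).

    Each parent pair (i, z) indexes into ``minority``: the synthetic point
    lies on the segment between minority[i] and minority[z].
    """
    minority = np.asarray(minority, dtype=float)
    majority = np.asarray(majority, dtype=float)
    if minority.ndim != 2 or majority.ndim != 2:
        raise ValidationError("minority/majority must be 2-D arrays")
    m, M = len(minority), len(majority)
    if m < 2:
        raise ValidationError("need at least 2 minority points to interpolate")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not (0 < beta <= 1):
        raise ValidationError("beta must lie in (0, 1]")

    G = int(round(beta * (M - m)))
    if G <= 0:
        return np.empty((0, minority.shape[1])), []

    combined = np.vstack([minority, majority])
    k_eff = min(k, len(combined) - 1)
    nn_all = NearestNeighbors(n_neighbors=k_eff + 1).fit(combined)
    _, idx_all = nn_all.kneighbors(minority)
    delta = np.empty(m)
    for i in range(m):
        neigh = [j for j in idx_all[i] if j != i][:k_eff]
        delta[i] = sum(1 for j in neigh if j >= m)
    r = delta / k_eff
    total_r = r.sum()
    r_hat = np.full(m, 1.0 / m) if total_r == 0 else r / total_r
    g = largest_remainder(r_hat * G, G)

    k_min = min(k, m - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(minority)
    _, idx_min = nn_min.kneighbors(minority)

    rng = substream(seed, "adasyn")
    out = np.empty((G, minority.shape[1]))
    parents: list[tuple[int, int]] = []
    pos = 0
    for i in range(m):
        neigh = [j for j in idx_min[i] if j != i][:k_min]
        for _ in range(g[i]):
            z = neigh[rng.integers(len(neigh))]
            lam = rng.uniform()
            out[pos] = minority[i] + lam * (minority[z] - minority[i])
            parents.append((i, int(z)))
            pos += 1
    assert pos == G
    return out, parents


def balance_dataset(
    table: LabeledTable, k: int = 5, beta: float = 1.0, seed: int = 0
) -> LabeledTable:
    """Append ADASYN synthetic rows so both binary classes have equal counts."""
    counts = table.class_counts()
    if len(counts) < 2:
        raise ValidationError("cannot balance a single-class dataset")
    if len(counts) != 2:
        raise ValidationError("balance_dataset expects binary labels")
    (l0, n0), (l1, n1) = sorted(counts.items(), key=lambda kv: kv[1])
    if n0 == n1:
        return table
    minority_label, majority_label = l0, l1
    y_int = table.y.astype(int)
    min_idx = np.flatnonzero(y_int == minority_label)
    maj_idx = np.flatnonzero(y_int == majority_label)
    shape = table.X.shape[1:]
    Xmin = table.X[min_idx].reshape(len(min_idx), -1).astype(float)
    Xmaj = table.X[maj_idx].reshape(len(maj_idx), -1).astype(float)
    synth, parent_pairs = adasyn(Xmin, Xmaj, k=k, beta=beta, seed=seed)
    if len(synth) == 0:
        return table
    synth = synth.reshape((len(synth),) + shape).astype(table.X.dtype, copy=False)
    new_ids = [f"syn-{i:04d}" for i in range(len(synth))]
    new_parents = [
        (table.case_ids[min_idx[i]], table.case_ids[min_idx[z]])
        for i, z in parent_pairs
    ]
    return LabeledTable(
        X=np.concatenate([table.X, synth]),
        y=np.concatenate([table.y, np.full(len(synth), minority_label, table.y.dtype)]),
        case_ids=table.case_ids + new_ids,
        provenance=table.provenance + [SYNTHETIC] * len(synth),
        parents=table.parents + new_parents,
    )


def hflip(images: np.ndarray) -> np.ndarray:
    """Flip across the vertical axis (reverse columns)."""
    return np.flip(images, axis=-2)


def vflip(images: np.ndarray) -> np.ndarray:
    """Flip across the horizontal axis (reverse rows)."""
    return np.flip(images, axis=-3)


def rot180(images: np.ndarray) -> np.ndarray:
    """180-degree rotation = horizontal then vertical flip."""
    return vflip(hflip(images))


def augment_images(table: LabeledTable) -> LabeledTable:
    """Quadruple an image table: original, h-flip, v-flip, 180 rotation."""
    if len(table) == 0:
        raise ValidationError("cannot augment an empty image set")
    if table.X.ndim < 3:
        raise ValidationError("augment_images expects image rasters")
    ops = {"hflip": hflip, "vflip": vflip, "rot180": rot180}
    xs = [table.X]
    ids = list(table.case_ids)
    prov = list(table.provenance)
    parents = list(table.parents)
    for name, op in ops.items():
        xs.append(op(table.X))
        ids.extend(f"{cid}-{name}" for cid in table.case_ids)
        prov.extend([AUGMENTED] * len(table))
        parents.extend((cid,) for cid in table.case_ids)
    return LabeledTable(
        X=np.concatenate(xs),
        y=np.tile(table.y, 4),
        case_ids=ids,
        provenance=prov,
        parents=parents,
    )


def _root_cases(table: LabeledTable, i: int) -> set[str]:
    """Originating case ids of row i (itself, if an original)."""
    if table.provenance[i] == ORIGINAL:
        return {table.case_ids[i]}
    return set(table.parents[i])


def leakage_safe_split(
    table: LabeledTable,
    test_ids: set[str] | list[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[LabeledTable, LabeledTable, LabeledTable]:
    """Split into (train, validation, test) with no case-level leakage.

    The test partition contains only the *original* rows whose case ids are
    in ``test_ids``; every synthetic/augmented descendant of a test case is
    excluded from train and validation. The remaining original cases are
    split train/validation by case (seeded); descendants follow their
    parents, and a descendant whose parents straddle the two partitions is
    dropped rather than leaked.
    """
    test_ids = set(test_ids)
    original_ids = [
        table.case_ids[i] for i in range(len(table)) if table.provenance[i] == ORIGINAL
    ]
    unknown = test_ids - set(original_ids)
    if unknown:
        raise ValidationError(f"test_ids not in table originals: {sorted(unknown)}")

    pool_ids = [cid for cid in original_ids if cid not in test_ids]
    rng = substream(seed, "split")
    perm = rng.permutation(len(pool_ids))
    n_train = int(round(train_fraction * len(pool_ids)))
    train_cases = {pool_ids[i] for i in perm[:n_train]}
    val_cases = {pool_ids[i] for i in perm[n_train:]}

    train_rows, val_rows, test_rows = [], [], []
    for i in range(len(table)):
        roots = _root_cases(table, i)
        if roots & test_ids:
            if table.provenance[i] == ORIGINAL:
                test_rows.append(i)
            continue  # descendants of test cases are discarded entirely
        in_train = roots <= train_cases
        in_val = roots <= val_cases
        if in_train:
            train_rows.append(i)
        elif in_val:
            val_rows.append(i)
        # parents straddle partitions: drop the row

    train, val, test = (table.subset(r) for r in (train_rows, val_rows, test_rows))
    for a, b in ((train, val), (train, test), (val, test)):
        overlap = {c for i in range(len(a)) for c in _root_cases(a, i)} & {
            c for i in range(len(b)) for c in _root_cases(b, i)
        }
        if overlap:
            raise LeakageError(f"case ids on both sides of a split: {sorted(overlap)}")
    return train, val, test
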