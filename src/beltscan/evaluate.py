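"""Multi-position fusion, staging, and evaluation statistics.

Because the belt's vertical position relative to an (unknown) tumor plane
attenuates the tumor signature, measurements are taken at several belt
positions: a tumor is declared present if *any* position detects one (OR
fusion), and the size estimate is the *maximum* over positions (off-plane
positions systematically under-estimate).

Statistics follow the study protocol: plain accuracy for detection, mean
squared error for size (reported in mm^2 — the squared-radius scale), and
an unpaired two-sample Student t-test with pooled variance comparing the
actual and predicted size distributions (Welch available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LeakageError, ValidationError
from .types import StageLabel, assign_stage


@dataclass
class PositionRecord:
    """One belt position's outputs for a case."""

    belt_offset_mm: float
    detected: int
    size_mm: Optional[float] = None
    probability: Optional[float] = None


@dataclass
class PositionSeries:
    """Per-position records for one subject."""

    records: list[PositionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("a position series needs at least one record")


def fuse_detection(series: PositionSeries) -> int:
    """Logical OR over per-position detection labels."""
    return int(any(r.detected for r in series.records))


def fuse_size(series: PositionSeries) -> float:
    """Maximum size prediction over positions."""
    sizes = [r.size_mm for r in series.records if r.size_mm is not None]
    if not sizes:
        raise ValidationError("no size predictions in the series")
    return float(max(sizes))


def fused_stage(series: PositionSeries) -> StageLabel:
    """Stage assigned from the fused (max) size, if a tumor is detected."""
    if not fuse_detection(series):
        return StageLabel.NONE
    return assign_stage(fuse_size(series))


def accuracy(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> float:
    """Fraction of correct predictions."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValidationError("label vectors must have equal length")
    if t.size == 0:
        raise ValidationError("empty label vectors")
    return float(np.mean(t == p))


def mean_squared_error(true_values: Sequence[float],
                       predicted_values: Sequence[float]) -> float:
    """Mean of squared differences."""
    t = np.asarray(true_values, dtype=float)
    p = np.asarray(predicted_values, dtype=float)
    if t.shape != p.shape:
        raise ValidationError("value vectors must have equal length")
    if t.size == 0:
        raise ValidationError("empty value vectors")
    return float(np.mean((t - p) ** 2))


def two_sample_ttest(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t statistic and two-tailed p.

    Default is the pooled-variance Student test with df = n_a + n_b - 2;
    ``welch=True`` drops the equal-variance assumption. If both samples are
    constant with unequal means the statistic is infinite and p = 0 (a
    documented edge); identical constant samples give t = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def evaluation_report(
    manifest: pd.DataFrame,
    predictions: dict[str, pd.DataFrame],
    train_case_ids: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, str]:
    """Per-model metrics on in-domain (set A/B) and cross-phantom (set C) cases.

    ``manifest`` must carry case_id, simulation_set, label and radius_mm
    columns for the held-out cases; ``predictions`` maps a model name to a
    frame with case_id plus either a ``label`` or ``size_mm`` column.
    Returns (metric table, human-readable summary).
    """
    if train_case_ids:
        overlap = set(manifest["case_id"]) & set(train_case_ids)
        if overlap:
            raise LeakageError(f"held-out cases seen in training: {sorted(overlap)}")
    rows = []
    for model_name, pred in predictions.items():
        merged = manifest.merge(pred, on="case_id", suffixes=("", "_pred"))
        if len(merged) != len(pred):
            raise ValidationError(f"{model_name}: predictions for unknown cases")
        for domain, sel in (
            ("in_domain", merged["simulation_set"].isin(["A", "B"])),
            ("cross_phantom", merged["simulation_set"] == "C"),
        ):
            part = merged[sel]
            if len(part) == 0:
                continue
            if "label_pred" in part.columns and part["label_pred"].notna().any():
                rows.append({
                    "model": model_name, "domain": domain, "metric": "accuracy",
                    "value": accuracy(part["label"], part["label_pred"]),
                    "n": len(part),
                })
            if "size_mm" in part.columns and part["size_mm"].notna().any():
                rows.append({
                    "model": model_name, "domain": domain, "metric": "mse_mm2",
                    "value": mean_squared_error(part["radius_mm"], part["size_mm"]),
                    "n": len(part),
                })
    report = pd.DataFrame(rows)
    lines = ["# Evaluation report", ""]
    for _, r in report.iterrows():
        lines.append(
            f"- {r['model']} [{r['domain']}] {r['metric']} = {r['value']:.4g} "
            f"(n={r['n']})"
        )
    lines.append("")
    lines.append(
        "MSE values are squared radius errors (mm^2); size predictions and "
        "targets are tumor radii in mm."
    )
    return report, "\n".join(lines)
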