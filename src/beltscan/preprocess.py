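"""Two-step calibration and band-averaged feature construction.

Step 1 (``calibrate``) subtracts the empty-domain sweep from the body
sweep, removing antenna coupling and fixed clutter. Step 2
(``remove_skin_artifact``) subtracts, at each frequency, the complex mean
over all channels, suppressing the common-mode skin reflection.

Features: each of the 64 channels contributes its mean amplitude and mean
(frequency-unwrapped) phase over the operating band, 1.5--3 GHz by
default — 128 real values per case. Channel order is row-major
(1,1),(1,2),...,(1,8),(2,1),...,(8,8); amplitudes fill slots 0..63 and
phases slots 64..127. Amplitudes are averaged in linear units, not dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .types import SMatrixSweep, SweepKind

DEFAULT_BAND = (1.5e9, 3.0e9)


@dataclass(frozen=True)
class FeatureVector:
    """128 band-averaged values: 64 amplitude means then 64 phase means."""

    values: np.ndarray
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (128,):
            raise ValidationError(f"feature vector must have length 128, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


def calibrate(body: SMatrixSweep, empty: SMatrixSweep) -> SMatrixSweep:
    """Element-wise complex difference body - empty (clutter removal)."""
    if body.grid != empty.grid:
        raise AlignmentError("body and empty sweeps are on different grids")
    if body.n_ports != empty.n_ports:
        raise AlignmentError("body and empty sweeps have different port counts")
    return SMatrixSweep(body.grid, body.values - empty.values, SweepKind.CALIBRATED)


def remove_skin_artifact(calibrated: SMatrixSweep) -> SMatrixSweep:
    """Subtract the per-frequency complex channel mean from every channel.

    After this step the channel mean at every frequency is zero to
    numerical precision; the operation is idempotent.
    """
    mean = calibrated.values.mean(axis=(1, 2), keepdims=True)
    return SMatrixSweep(calibrated.grid, calibrated.values - mean, SweepKind.CALIBRATED)


def preprocess_case(body: SMatrixSweep, empty: SMatrixSweep) -> SMatrixSweep:
    """Full two-step chain: calibrate then remove the skin artifact."""
    return remove_skin_artifact(calibrate(body, empty))


def band_average_features(
    sweep: SMatrixSweep, band: tuple[float, float] = DEFAULT_BAND
) -> FeatureVector:
    """Band-averaged amplitude/phase features over the closed band.

    The phase of each channel is unwrapped along frequency before
    averaging (averaging wrapped phase is meaningless near the branch
    cut).
    """
    f_lo, f_hi = band
    if not (sweep.grid.f_start <= f_lo < f_hi <= sweep.grid.f_stop):
        raise ValidationError("band must lie within the sweep grid")
    mask = sweep.grid.band_mask(f_lo, f_hi)
    if mask.sum() < 2:
        raise ValidationError("band contains fewer than 2 frequency samples")
    sub = sweep.values[mask]  # (nb, n, n)
    amp = np.abs(sub).mean(axis=0)
    phase = np.unwrap(np.angle(sub), axis=0).mean(axis=0)
    return FeatureVector(np.concatenate([amp.ravel(), phase.ravel()]), band=band)


FEATURE_COLUMNS = (
    [f"amp_S{i + 1}{j + 1}" for i in range(8) for j in range(8)]
    + [f"phase_S{i + 1}{j + 1}" for i in range(8) for j in range(8)]
)


def features_frame(
    case_ids: list[str], vectors: list[FeatureVector]
) -> pd.DataFrame:
    """Feature table: one row per case, 128 named columns plus case_id."""
    if len(case_ids) != len(vectors):
        raise ValidationError("case_ids and vectors must have equal length")
    df = pd.DataFrame([v.values for v in vectors], columns=FEATURE_COLUMNS)
    df.insert(0, "case_id", case_ids)
    return df
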