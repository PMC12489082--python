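"""Domain data model shared by all pipeline stages.

The sensing record is an 8-port complex scattering matrix swept over a
uniform frequency grid; the phantom is a parametric torso cross-section
(ellipse + two circular lungs + optional spherical tumor); labels are
derived, never stored as authoritative.

Units: frequencies in Hz, lengths in meters internally, tumor sizes and
belt offsets in millimeters at the data-model boundary (they are quoted in
mm throughout the manifest), phases in radians.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import DimensionError, ValidationError

C0 = 299_792_458.0  # vacuum speed of light, m/s
CLASS_BOUNDARY_MM = 8.0  # class 0: tumor absent or diameter <= 8 mm


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency sweep grid.

    Defaults to the 500-point sweep over 0.5--3.5 GHz used throughout the
    pipeline.
    """

    f_start: float = 0.5e9
    f_stop: float = 3.5e9
    n_points: int = 500

    def __post_init__(self) -> None:
        if not (self.f_start < self.f_stop):
            raise ValidationError("f_start must be < f_stop")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")

    @property
    def frequencies(self) -> np.ndarray:
        return np.linspace(self.f_start, self.f_stop, self.n_points)

    def band_mask(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Boolean mask of grid points in the closed band [f_lo, f_hi]."""
        f = self.frequencies
        return (f >= f_lo) & (f <= f_hi)


@dataclass(frozen=True)
class AntennaBelt:
    """Antenna positions (m) on the belt plane.

    positions has shape (n_antennas, 3); all antennas share the belt plane
    height (z coordinate).
    """

    positions: np.ndarray
    belt_plane_height: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise DimensionError("positions must have shape (n, 3)")
        if pos.shape[0] < 1:
            raise ValidationError("at least one antenna required")
        if not np.allclose(pos[:, 2], self.belt_plane_height, atol=1e-12):
            raise ValidationError("all antennas must lie on the belt plane")
        # pairwise distinct
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.min(d) <= 0:
            raise ValidationError("antenna positions must be pairwise distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_antennas(self) -> int:
        return self.positions.shape[0]


class SweepKind(str, Enum):
    BODY = "body"
    EMPTY = "empty"
    CALIBRATED = "calibrated"


@dataclass
class SMatrixSweep:
    """Complex S-matrix over a frequency grid.

    values is complex with shape (n_points, n_ports, n_ports), indexed
    (frequency, transmit port, receive port).
    """

    grid: FrequencyGrid
    values: np.ndarray
    kind: SweepKind = SweepKind.BODY

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise DimensionError(
                f"values must be (n_freq, n_ports, n_ports), got {v.shape}"
            )
        if v.shape[0] != self.grid.n_points:
            raise DimensionError(
                f"frequency extent {v.shape[0]} != grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(v.view(float))):
            raise ValidationError("sweep contains non-finite values")
        self.values = v
        self.kind = SweepKind(self.kind)

    @property
    def n_ports(self) -> int:
        return self.values.shape[1]

    def is_reciprocal(self, rtol: float = 1e-9) -> bool:
        vt = np.swapaxes(self.values, 1, 2)
        scale = np.max(np.abs(self.values)) or 1.0
        return bool(np.all(np.abs(self.values - vt) <= rtol * scale))


@dataclass(frozen=True)
class TissueDielectric:
    """Relative permittivity and conductivity (S/m) of a tissue."""

    eps_r: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_r < 1:
            raise ValidationError("eps_r must be >= 1")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


# Default dielectrics: chosen to respect the qualitative ordering
# tumor >> background > lung that drives the scattering contrast.
BACKGROUND_TISSUE = TissueDielectric(eps_r=35.0, sigma=0.5)
LUNG_TISSUE = TissueDielectric(eps_r=20.0, sigma=0.3)
TUMOR_TISSUE = TissueDielectric(eps_r=55.0, sigma=1.5)


@dataclass(frozen=True)
class Tumor:
    """Spherical tumor: center (m, 3-D), diameter (mm), tissue."""

    center: tuple[float, float, float]
    diameter_mm: float
    tissue: TissueDielectric = TUMOR_TISSUE

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValidationError("tumor diameter must be > 0 mm")

    @property
    def volume_m3(self) -> float:
        r = self.diameter_mm * 1e-3 / 2.0
        return 4.0 / 3.0 * np.pi * r**3


@dataclass(frozen=True)
class TorsoScenario:
    """Parametric torso phantom for one measurement.

    The tumor plane is z = 0; the belt sits at z = belt_offset_mm, so a
    nonzero offset increases every antenna-to-tumor distance.
    """

    phantom_id: str = "phantom-A"
    torso_semi_axes: tuple[float, float] = (0.15, 0.10)
    background_tissue: TissueDielectric = BACKGROUND_TISSUE
    lung_centers: tuple[tuple[float, float], ...] = ((-0.06, 0.0), (0.06, 0.0))
    lung_radius: float = 0.05
    tumor: Optional[Tumor] = None
    belt_offset_mm: float = 0.0
    clutter_seed: int = 0
    skin_amplitude: float = 1.0

    def __post_init__(self) -> None:
        a, b = self.torso_semi_axes
        if a <= 0 or b <= 0:
            raise ValidationError("torso semi-axes must be positive")
        if self.lung_radius <= 0:
            raise ValidationError("lung radius must be positive")
        if self.tumor is not None:
            if self.tumor.diameter_mm > 2 * self.lung_radius * 1000:
                raise ValidationError("tumor larger than the lung region")
            cx, cy = self.tumor.center[0], self.tumor.center[1]
            inside = any(
                (cx - lx) ** 2 + (cy - ly) ** 2 <= self.lung_radius**2
                for lx, ly in self.lung_centers
            )
            if not inside:
                raise ValidationError("tumor center lies outside both lungs")

    @property
    def belt_plane_height(self) -> float:
        return self.belt_offset_mm * 1e-3

    def lung_side(self) -> str:
        """Which lung holds the tumor: 'left', 'right' or 'none'.

        'left' is the patient's left, i.e. negative x in belt coordinates.
        """
        if self.tumor is None:
            return "none"
        return "left" if self.tumor.center[0] < 0 else "right"


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative measurement-noise specification.

    relative_level is the maximum fractional perturbation p: magnitudes are
    scaled by (1+u) and phases shifted by u'*|phase| with u, u' ~ U(-p, p).
    Canonical protocols use p in {0, 0.01, 0.05, 0.10}.
    """

    relative_level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_level <= 1.0):
            raise ValidationError("noise level must lie in [0, 1]")


class StageLabel(str, Enum):
    NONE = "none"
    IA = "IA"
    IB = "IB"
    IIA = "IIA"
    IIB = "IIB"


def assign_stage(size_mm: float) -> StageLabel:
    """Early-stage NSCLC bin from tumor size (largest dimension, mm).

    Bins: IA <= 30 < IB <= 40 < IIA <= 50 < IIB; anything above 50 mm is
    reported as IIB by this lookup (true stage may be beyond IIB). Size 0
    means no tumor. Boundary points 40 and 50 are assigned to the earlier
    stage (right-closed intervals), giving a gapless partition.
    """
    if size_mm < 0:
        raise ValidationError("tumor size must be >= 0 mm")
    if size_mm == 0:
        return StageLabel.NONE
    if size_mm <= 30:
        return StageLabel.IA
    if size_mm <= 40:
        return StageLabel.IB
    if size_mm <= 50:
        return StageLabel.IIA
    return StageLabel.IIB


def class_label(tumor_diameter_mm: float) -> int:
    """Binary detection label: 0 if absent or <= 8 mm, else 1."""
    if tumor_diameter_mm < 0:
        raise ValidationError("tumor diameter must be >= 0 mm")
    return 0 if tumor_diameter_mm <= CLASS_BOUNDARY_MM else 1


@dataclass
class CaseManifestRow:
    """One simulated measurement and its ground truth."""

    case_id: str
    phantom_id: str
    tumor_diameter_mm: float
    lung_side: str
    belt_offset_mm: float
    body_sweep_path: str
    empty_sweep_path: str
    simulation_set: str

    def __post_init__(self) -> None:
        if self.tumor_diameter_mm < 0:
            raise ValidationError("tumor diameter must be >= 0 mm")
        if self.lung_side not in ("left", "right", "none"):
            raise ValidationError(f"bad lung_side {self.lung_side!r}")
        if (self.tumor_diameter_mm == 0) != (self.lung_side == "none"):
            raise ValidationError("diameter 0 iff lung_side 'none'")
        if self.simulation_set not in ("A", "B", "C"):
            raise ValidationError(f"bad simulation_set {self.simulation_set!r}")

    @property
    def label(self) -> int:
        return class_label(self.tumor_diameter_mm)

    @property
    def radius_mm(self) -> float:
        return self.tumor_diameter_mm / 2.0
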