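"""Frequency-domain multistatic backprojection imaging.

For each pixel p the calibrated channel data are summed coherently with
the phase compensated for the two-way background propagation::

    I(p) = | sum_i sum_j sum_q S_ij(f_q) exp(+j k(f_q) (|p - r_i| + |p - r_j|)) |

with k(f) = 2 pi f sqrt(eps_bg) / c. Uniform pair weights, monostatic
(i = j) pairs included by default, magnitude output (a flag gives
magnitude squared). Images are normalized to the maximum of a healthy
reference case and rendered through a fixed perceptual colormap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .errors import ValidationError
from .types import C0, AntennaBelt, SMatrixSweep, TissueDielectric

DEFAULT_RENDER_SIZE = (634, 496)  # (width, height) of the rendered raster
DEFAULT_CNN_SIZE = (400, 400)


@dataclass(frozen=True)
class PixelGrid:
    """Rectangular pixel grid over the torso cross-section (meters).

    extent = (xmin, xmax, ymin, ymax); pixel centers are cell centers, so
    a symmetric extent yields a grid symmetric under x -> -x.
    """

    nx: int = 64
    ny: int = 64
    extent: tuple[float, float, float, float] = (-0.16, 0.16, -0.11, 0.11)

    def __post_init__(self) -> None:
        if self.nx * self.ny < 4:
            raise ValidationError("pixel grid too small")
        xmin, xmax, ymin, ymax = self.extent
        if not (xmin < xmax and ymin < ymax):
            raise ValidationError("degenerate pixel extent")

    @property
    def x_centers(self) -> np.ndarray:
        xmin, xmax, _, _ = self.extent
        dx = (xmax - xmin) / self.nx
        return xmin + dx * (0.5 + np.arange(self.nx))

    @property
    def y_centers(self) -> np.ndarray:
        _, _, ymin, ymax = self.extent
        dy = (ymax - ymin) / self.ny
        return ymin + dy * (0.5 + np.arange(self.ny))

    def pixel_coords(self) -> np.ndarray:
        """(ny*nx, 2) array of pixel-center coordinates, row-major."""
        X, Y = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([X.ravel(), Y.ravel()])

    def encloses(self, points_xy: np.ndarray) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return bool(
            np.all(points_xy[:, 0] >= xmin)
            and np.all(points_xy[:, 0] <= xmax)
            and np.all(points_xy[:, 1] >= ymin)
            and np.all(points_xy[:, 1] <= ymax)
        )


@dataclass
class ReconstructedImage:
    """Non-negative intensity map plus its healthy-reference normalizer."""

    grid: PixelGrid
    intensity: np.ndarray  # (ny, nx), >= 0
    normalization_ref: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (self.grid.ny, self.grid.nx):
            raise ValidationError("intensity shape does not match pixel grid")
        if np.any(arr < 0):
            raise ValidationError("intensity must be non-negative")
        if self.normalization_ref <= 0:
            raise ValidationError("normalization reference must be positive")
        self.intensity = arr

    @property
    def normalized(self) -> np.ndarray:
        """Intensity / healthy reference; may exceed 1 for tumor cases."""
        return self.intensity / self.normalization_ref

    @property
    def peak(self) -> float:
        return float(self.intensity.max())

    def argmax_xy(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(int(np.argmax(self.intensity)), self.intensity.shape)
        return float(self.grid.x_centers[ix]), float(self.grid.y_centers[iy])


_PHASE_CACHE: dict[tuple, np.ndarray] = {}


def _phase_factors(dist: np.ndarray, k: np.ndarray) -> np.ndarray:
    """exp(+j k_f |p - r_i|) as (nf, n_ant, npix); cached.

    The factors depend only on the belt/pixel geometry and the frequency
    grid, which the study re-uses across every case of a phantom, so a
    tiny cache removes the dominant cost of batch reconstruction.
    """
    key = (dist.tobytes(), k.tobytes())
    E = _PHASE_CACHE.get(key)
    if E is None:
        E = np.exp(1j * k[:, None, None] * dist[None, :, :])
        if len(_PHASE_CACHE) >= 4:
            _PHASE_CACHE.pop(next(iter(_PHASE_CACHE)))
        _PHASE_CACHE[key] = E
    return E


def reconstruct_image(
    calibrated: SMatrixSweep,
    belt: AntennaBelt,
    pixels: PixelGrid | None = None,
    background: TissueDielectric | None = None,
    include_monostatic: bool = True,
    power: bool = False,
    freq_chunk: int = 64,
) -> ReconstructedImage:
    """Coherent multistatic backprojection of a calibrated sweep.

    The inner double sum over antennas is factorized per frequency
    (sum_ij S_ij E_i E_j = sum_i E_i (sum_j S_ij E_j)), evaluated in
    frequency chunks to bound memory.
    """
    from .types import BACKGROUND_TISSUE

    pixels = pixels or PixelGrid()
    background = background or BACKGROUND_TISSUE
    ant_xy = belt.positions[:, :2]
    if not pixels.encloses(ant_xy):
        raise ValidationError("pixel grid does not enclose the antenna belt")

    pts = pixels.pixel_coords()  # (npix, 2)
    dist = np.linalg.norm(pts[None, :, :] - ant_xy[:, None, :], axis=2)  # (n, npix)
    k = 2 * np.pi * calibrated.grid.frequencies * np.sqrt(background.eps_r) / C0

    S = calibrated.values
    if not include_monostatic:
        S = S.copy()
        idx = np.arange(S.shape[1])
        S[:, idx, idx] = 0.0

    npix = pts.shape[0]
    acc = np.zeros(npix, dtype=complex)
    E_full = _phase_factors(dist, k)  # (nf, n, npix), cached per geometry
    for q0 in range(0, len(k), freq_chunk):
        E = E_full[q0 : q0 + freq_chunk]
        inner = S[q0 : q0 + freq_chunk] @ E  # (nfc, n, npix)
        inner *= E
        acc += inner.sum(axis=(0, 1))

    intensity = np.abs(acc)
    if power:
        intensity = intensity**2
    return ReconstructedImage(pixels, intensity.reshape(pixels.ny, pixels.nx))


def normalize_to_reference(
    image: ReconstructedImage, healthy_max: float
) -> ReconstructedImage:
    """Attach the healthy-case maximum as the normalization reference."""
    if healthy_max <= 0:
        raise ValidationError("healthy reference maximum must be positive")
    return replace(image, normalization_ref=float(healthy_max))


def render_image(
    image: ReconstructedImage,
    size: tuple[int, int] = DEFAULT_RENDER_SIZE,
    clip_max: float | None = None,
    cmap: str = "viridis",
) -> np.ndarray:
    """Render the normalized image as an 8-bit RGB raster of (width, height).

    Values are clipped to [0, clip_max] (clip_max defaults to the image's
    own normalized maximum), mapped through a fixed perceptual colormap,
    and bilinearly resized. Deterministic.
    """
    w, h = size
    if w < 1 or h < 1:
        raise ValidationError("raster size must be positive")
    vals = image.normalized
    if clip_max is None:
        clip_max = float(vals.max()) or 1.0
    if clip_max <= 0:
        clip_max = 1.0
    scaled = np.clip(vals / clip_max, 0.0, 1.0)
    rgba = colormaps[cmap](scaled)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    return resize_raster(rgb, (w, h))


def resize_raster(raster: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an (h, w, 3) uint8 raster to (width, height)."""
    w, h = size
    if w < 1 or h < 1:
        raise ValidationError("raster size must be positive")
    img = Image.fromarray(raster)
    return np.asarray(img.resize((w, h), Image.BILINEAR))


def save_png(raster: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(raster).save(path, format="PNG")
    return path
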