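"""Born-approximation forward model for the antenna-belt torso measurement.

Generates paired body / empty-domain S-parameter sweeps for a parametric
torso phantom. The model is deliberately structured so that the pipeline's
two calibration steps are exactly correct on its output:

* empty sweep  = antenna-coupling clutter ``C_ij(f)`` (deterministic in the
  clutter seed, the antenna separation and frequency);
* body sweep   = ``C_ij(f)`` + a skin-reflection term ``K(f)`` that is
  common-mode across channels (so the per-frequency channel-mean
  subtraction removes it exactly) + a tumor term present iff a tumor is.

The tumor term is a single Born point scatterer::

    T_ij(f) = kappa * V * dchi(f) * exp(-(alpha(f) + j k(f)) (d_i + d_j))
              / (d_i * d_j)

with ``V`` the tumor volume, ``dchi`` the complex dielectric contrast
against the background medium, ``k(f) = 2 pi f sqrt(eps_bg) / c`` the
background wavenumber, ``alpha`` the conductive attenuation, and ``d_i``
the 3-D antenna-to-tumor distance (a belt offset enlarges every ``d_i``).
Volume-, contrast- and distance-dependence — the structure the learning
stages exploit — therefore hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np

from ._rng import substream
from .errors import ValidationError
from .manifest import write_manifest
from .touchstone import write_sweep
from .types import (
    C0,
    AntennaBelt,
    CaseManifestRow,
    FrequencyGrid,
    NoiseSpec,
    SMatrixSweep,
    SweepKind,
    TissueDielectric,
    TorsoScenario,
    Tumor,
)

EPS0 = 8.8541878128e-12  # F/m
ETA0 = 376.730313668  # vacuum impedance, Ohm

# Overall scattering gain. Fixed so that the in-band tumor term of a 20 mm
# tumor at zero belt offset sits roughly 40 dB below the coupling clutter:
# the calibration chain has to do real work before the tumor is visible.
KAPPA = 180.0

SKIN_BASE = 0.02  # skin-reflection magnitude before the scenario's skin_amplitude


def make_belt(scenario: TorsoScenario, n_antennas: int = 8) -> AntennaBelt:
    """Place ``n_antennas`` on the torso ellipse at the belt plane.

    Antennas sit at equal parameter increments of the ellipse
    (x, y) = (a cos t, b sin t), first antenna on the +x axis,
    counter-clockwise.
    """
    a, b = scenario.torso_semi_axes
    if a <= 0 or b <= 0:
        raise ValidationError("degenerate torso ellipse")
    if n_antennas < 3:
        raise ValidationError("need at least 3 antennas")
    t = 2 * np.pi * np.arange(n_antennas) / n_antennas
    z = scenario.belt_plane_height
    pos = np.column_stack([a * np.cos(t), b * np.sin(t), np.full(n_antennas, z)])
    return AntennaBelt(positions=pos, belt_plane_height=z)


def _wavenumber(grid: FrequencyGrid, background: TissueDielectric) -> np.ndarray:
    """Real background wavenumber k(f) = 2 pi f sqrt(eps_r) / c, rad/m."""
    return 2 * np.pi * grid.frequencies * np.sqrt(background.eps_r) / C0


def _attenuation(background: TissueDielectric) -> float:
    """Conductive attenuation alpha = sigma * eta0 / (2 sqrt(eps_r)), Np/m."""
    return background.sigma * ETA0 / (2 * np.sqrt(background.eps_r))


def _contrast(grid: FrequencyGrid, tumor_tissue: TissueDielectric,
              background: TissueDielectric) -> np.ndarray:
    """Complex dielectric contrast dchi(f) of tumor against background."""
    w = 2 * np.pi * grid.frequencies
    eps_t = tumor_tissue.eps_r - 1j * tumor_tissue.sigma / (w * EPS0)
    eps_b = background.eps_r - 1j * background.sigma / (w * EPS0)
    return (eps_t - eps_b) / eps_b


@dataclass
class SweepComponents:
    """The generator's additive components, exposed for exactness tests."""

    grid: FrequencyGrid
    clutter: np.ndarray  # (nf, n, n) complex
    skin: np.ndarray
    tumor: np.ndarray

    @property
    def body(self) -> SMatrixSweep:
        return SMatrixSweep(self.grid, self.clutter + self.skin + self.tumor,
                            SweepKind.BODY)

    @property
    def empty(self) -> SMatrixSweep:
        return SMatrixSweep(self.grid, self.clutter.copy(), SweepKind.EMPTY)


def simulate_components(
    scenario: TorsoScenario,
    belt: AntennaBelt,
    grid: FrequencyGrid | None = None,
) -> SweepComponents:
    """Evaluate the forward model, returning clutter/skin/tumor separately."""
    grid = grid or FrequencyGrid()
    n = belt.n_antennas
    f = grid.frequencies
    pos = belt.positions

    # --- coupling clutter: seeded symmetric amplitudes, free-space phase ---
    rng = substream(scenario.clutter_seed, "clutter", n)
    amp = rng.uniform(0.05, 0.15, size=(n, n))
    phs = rng.uniform(-np.pi, np.pi, size=(n, n))
    amp = 0.5 * (amp + amp.T)
    phs = 0.5 * (phs + phs.T)
    amp[np.diag_indices(n)] = rng.uniform(0.25, 0.35, size=n)
    d_pair = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    d_eff = np.maximum(d_pair, 0.02)  # self terms reflect off the body surface
    k0 = 2 * np.pi * f / C0
    clutter = amp[None] * np.exp(1j * (phs[None] - k0[:, None, None] * d_eff[None]))

    # --- skin reflection: common-mode across all channels by construction ---
    k_bg = _wavenumber(grid, scenario.background_tissue)
    skin_f = scenario.skin_amplitude * SKIN_BASE * np.exp(-2j * k_bg * 0.01)
    skin = np.broadcast_to(skin_f[:, None, None], (grid.n_points, n, n)).copy()

    # --- tumor term: Born point scatterer ---
    tumor = np.zeros((grid.n_points, n, n), dtype=complex)
    if scenario.tumor is not None:
        tum = scenario.tumor
        center = np.asarray(tum.center, dtype=float)
        d_i = np.linalg.norm(pos - center[None, :], axis=1)  # (n,)
        if np.any(d_i <= 0):
            raise ValidationError("tumor coincides with an antenna")
        alpha = _attenuation(scenario.background_tissue)
        dchi = _contrast(grid, tum.tissue, scenario.background_tissue)
        gamma = alpha + 1j * k_bg  # (nf,)
        dsum = d_i[:, None] + d_i[None, :]  # (n, n)
        dprod = d_i[:, None] * d_i[None, :]
        tumor = (
            KAPPA
            * tum.volume_m3
            * dchi[:, None, None]
            * np.exp(-gamma[:, None, None] * dsum[None])
            / dprod[None]
        )

    return SweepComponents(grid=grid, clutter=clutter, skin=skin, tumor=tumor)


def simulate_sweep(
    scenario: TorsoScenario,
    belt: AntennaBelt | None = None,
    grid: FrequencyGrid | None = None,
) -> tuple[SMatrixSweep, SMatrixSweep]:
    """Simulate one measurement: (body sweep, empty-domain sweep)."""
    belt = belt or make_belt(scenario)
    comp = simulate_components(scenario, belt, grid)
    return comp.body, comp.empty


def add_noise(sweep: SMatrixSweep, noise: NoiseSpec) -> SMatrixSweep:
    """Multiplicative measurement noise at relative level p.

    Each entry's magnitude is scaled by (1+u) and its phase shifted by
    u' * |phase|, u, u' ~ U(-p, p), drawn independently per (frequency,
    i <= j) and mirrored so reciprocity is preserved. Deterministic under
    the NoiseSpec seed; p = 0 returns the sweep unchanged (bit-identical).
    """
    p = noise.relative_level
    if p == 0:
        return SMatrixSweep(sweep.grid, sweep.values.copy(), sweep.kind)
    rng = substream(noise.seed, "noise")
    nf, n, _ = sweep.values.shape
    iu, ju = np.triu_indices(n)
    u_mag = rng.uniform(-p, p, size=(nf, len(iu)))
    u_phs = rng.uniform(-p, p, size=(nf, len(iu)))
    mag = np.abs(sweep.values[:, iu, ju])
    phs = np.angle(sweep.values[:, iu, ju])
    new = mag * (1 + u_mag) * np.exp(1j * (phs + u_phs * np.abs(phs)))
    out = np.empty_like(sweep.values)
    out[:, iu, ju] = new
    out[:, ju, iu] = new
    return SMatrixSweep(sweep.grid, out, sweep.kind)


# ---------------------------------------------------------------------------
# Dataset designs


@dataclass(frozen=True)
class DatasetDesign:
    """Study design for the three simulation sets.

    Defaults emulate the study conditions: set A = 70 tumor diameters per
    lung, uniform over 2--60 mm, belt on the tumor plane; set B = 20
    off-plane cases (10 per lung, half of them <= 8 mm); set C = 10 cases
    on a second, differently shaped phantom with a different background
    medium. The default A grid puts 8 diameters <= 8 mm in each lung, so A
    and B together contain 26 class-0 cases against 134 class-1 cases.
    """

    grid: FrequencyGrid = FrequencyGrid()
    sizes_a_mm: tuple[float, ...] = tuple(np.linspace(2.0, 60.0, 70))
    b_cases: tuple[tuple[float, float], ...] = tuple(
        (d, o)
        for d, o in zip(
            (4.0, 5.0, 6.0, 7.0, 8.0, 15.0, 25.0, 35.0, 45.0, 55.0),
            (20.0, -20.0, 30.0, -30.0, 40.0, -40.0, 20.0, -30.0, 40.0, -20.0),
        )
    )
    c_sizes_mm: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
    include_b: bool = True
    include_c: bool = True

    def class0_count(self) -> int:
        """Class-0 rows in the A+B pool for this size grid (both lungs)."""
        n_a = 2 * sum(1 for d in self.sizes_a_mm if d <= 8.0)
        n_b = 2 * sum(1 for d, _ in self.b_cases if d <= 8.0) if self.include_b else 0
        return n_a + n_b


# The second phantom (set C): smaller torso, different background medium.
C_PHANTOM_SEMI_AXES = (0.13, 0.09)
C_PHANTOM_BACKGROUND = TissueDielectric(eps_r=42.0, sigma=0.6)
C_PHANTOM_LUNG_CENTERS = ((-0.05, 0.0), (0.05, 0.0))
C_PHANTOM_LUNG_RADIUS = 0.042


@dataclass
class GeneratedCase:
    """One generated measurement: manifest row + scenario + sweeps."""

    row: CaseManifestRow
    scenario: TorsoScenario
    body: SMatrixSweep
    empty: SMatrixSweep


def _tumor_scenario(
    base: TorsoScenario,
    side: str,
    diameter_mm: float,
    offset_mm: float,
    rng: np.random.Generator,
) -> TorsoScenario:
    """Scenario with a tumor jittered inside the requested lung."""
    lung = base.lung_centers[0] if side == "left" else base.lung_centers[1]
    slack = max(base.lung_radius - diameter_mm * 1e-3 / 2.0, 0.0)
    r = 0.5 * slack * np.sqrt(rng.uniform())
    theta = rng.uniform(0, 2 * np.pi)
    center = (lung[0] + r * np.cos(theta), lung[1] + r * np.sin(theta), 0.0)
    return replace(
        base,
        tumor=Tumor(center=center, diameter_mm=diameter_mm),
        belt_offset_mm=offset_mm,
    )


def generate_dataset(
    design: DatasetDesign | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[GeneratedCase]:
    """Generate the full synthetic study.

    Returns one :class:`GeneratedCase` per measurement; if ``out_dir`` is
    given, paired body/empty Touchstone files and ``manifest.csv`` are also
    written there. Fully reproducible from ``seed``.
    """
    design = design or DatasetDesign()
    if not design.sizes_a_mm:
        raise ValidationError("empty set-A size list")
    base_a = TorsoScenario(phantom_id="phantom-A", clutter_seed=seed)
    base_c = TorsoScenario(
        phantom_id="phantom-C",
        torso_semi_axes=C_PHANTOM_SEMI_AXES,
        background_tissue=C_PHANTOM_BACKGROUND,
        lung_centers=C_PHANTOM_LUNG_CENTERS,
        lung_radius=C_PHANTOM_LUNG_RADIUS,
        clutter_seed=seed + 1,
    )

    specs: list[tuple[str, str, TorsoScenario, float, float]] = []
    for side in ("left", "right"):
        for d in design.sizes_a_mm:
            specs.append((f"A-{side}-d{d:.2f}", "A", base_a, d, 0.0))
    if design.include_b:
        for side in ("left", "right"):
            for d, off in design.b_cases:
                specs.append((f"B-{side}-d{d:.2f}-o{off:g}", "B", base_a, d, off))
    if design.include_c:
        for side in ("left", "right"):
            for d in design.c_sizes_mm:
                specs.append((f"C-{side}-d{d:.2f}", "C", base_c, d, 0.0))

    ids = [s[0] for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate case_id in dataset design")

    cases: list[GeneratedCase] = []
    rows: list[CaseManifestRow] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for case_id, sim_set, base, d, off in specs:
        side = case_id.split("-")[1]
        rng = substream(seed, "placement", case_id)
        scen = _tumor_scenario(base, side, d, off, rng)
        body, empty = simulate_sweep(scen, grid=design.grid)
        body_path = empty_path = ""
        if out_path is not None:
            body_path = str(out_path / f"{case_id}-body.s8p")
            empty_path = str(out_path / f"{case_id}-empty.s8p")
            write_sweep(body, body_path)
            write_sweep(empty, empty_path)
        row = CaseManifestRow(
            case_id=case_id,
            phantom_id=scen.phantom_id,
            tumor_diameter_mm=d,
            lung_side=side,
            belt_offset_mm=off,
            body_sweep_path=body_path,
            empty_sweep_path=empty_path,
            simulation_set=sim_set,
        )
        rows.append(row)
        cases.append(GeneratedCase(row=row, scenario=scen, body=body, empty=empty))
    if out_path is not None:
        write_manifest(rows, out_path / "manifest.csv")
    return cases
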