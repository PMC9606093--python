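"""Ground-truthed synthetic phantoms for the virtual-histology pipeline.

No public volume data accompany the study design this package implements, so
every downstream stage is exercised on phantoms with known ground truth:

* 3-D density volumes containing cell-shaped hyperdense particles in three
  size populations — nucleoli of normal neurons (~2 µm), hyperdense glia
  (~4 µm) and ICHD-bearing neurons (~8 µm) — plus optional plaque-like
  clusters (~100 µm), hypodense vasculature, detector blur and noise, at the
  study's voxel scales (3.0, 0.7, 0.3, 0.1 µm);
* 2-D elemental area-density maps (ng/mm²) with labeled normal/ICHD cells;
* a four-group × four-region animal study with a configurable planted load
  elevation.

Rasterisation is voxel-centre-in-sphere (no partial-volume anti-aliasing):
that keeps an exact enumeration oracle available for every planted particle.
All generators are deterministic given their config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import PlacementError, VoxelVolume
from .xfm import CellMask, ElementalMap

__all__ = [
    "PopulationSpec",
    "PhantomConfig",
    "GroundTruth",
    "PlantedParticle",
    "ElementalPhantomConfig",
    "StudyConfig",
    "rasterize_sphere",
    "generate_phantom",
    "resample_volume",
    "generate_xfm_maps",
    "generate_group_study",
    "default_phantom_config",
    "default_xfm_config",
    "default_study_config",
]

POPULATION_NAMES = ("nucleoli", "glia", "ichd", "plaque")


@dataclass(frozen=True)
class PopulationSpec:
    """One particle population: size and intensity distribution.

    Diameters are sampled from a normal truncated at ±2.5 SD (and > 0.1 µm)
    so single extreme draws cannot leave the population's size regime.
    """

    name: str
    expected_count: int
    diameter_mean_um: float
    diameter_sd_um: float
    intensity_mean: float
    intensity_sd: float

    def __post_init__(self) -> None:
        if self.name not in POPULATION_NAMES:
            raise ValueError(f"population name must be one of {POPULATION_NAMES}")
        if not self.diameter_mean_um > 0:
            raise ValueError("diameter_mean_um must be > 0")
        if self.diameter_sd_um < 0 or self.intensity_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.expected_count < 0:
            raise ValueError("expected_count must be >= 0")

    @property
    def mean_volume_um3(self) -> float:
        """E[pi/6 d^3] for d ~ N(mean, sd) (untruncated moment formula)."""
        m, s = self.diameter_mean_um, self.diameter_sd_um
        return np.pi / 6.0 * (m**3 + 3 * m * s**2)


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of a 3-D phantom volume of interest."""

    shape: tuple[int, int, int] = (256, 256, 256)
    voxel_size_um: float = 0.3
    background_mean: float = 100.0
    background_sd: float = 2.0
    populations: tuple[PopulationSpec, ...] = ()
    vessel_fraction: float = 0.0
    vessel_contrast: float = 30.0
    blur_sigma_um: float = 0.2
    noise_sd: float = 5.0
    exact_counts: bool = False
    min_gap_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("all axis lengths must be >= 8")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")
        if not 0 <= self.vessel_fraction < 1:
            raise ValueError("vessel_fraction must be in [0, 1)")
        for p in self.populations:
            if p.name != "plaque" and p.expected_count > 0:
                if p.intensity_mean <= self.background_mean:
                    raise ValueError(
                        f"hyperdense population {p.name!r} must exceed background intensity"
                    )
        if self.vessel_fraction + self.particle_volume_fraction() >= 1.0:
            raise ValueError("vessel + particle volume fraction must be < 1")

    def particle_volume_fraction(self) -> float:
        total = float(np.prod(self.shape)) * self.voxel_size_um**3
        pv = sum(p.expected_count * p.mean_volume_um3 for p in self.populations)
        return pv / total

    @property
    def gap_um(self) -> float:
        """Minimum surface-to-surface gap between particles.

        Defaults to 2·blur_sigma + one voxel: the PSF blur must not bridge
        neighbouring particles, or connected-component labeling could not
        recover the planted count.
        """
        if self.min_gap_um is not None:
            return self.min_gap_um
        return 2.0 * self.blur_sigma_um + self.voxel_size_um

    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_um for s in self.shape)  # type: ignore[return-value]


def default_phantom_config(
    seed: int = 0,
    shape: tuple[int, int, int] = (256, 256, 256),
    voxel_size_um: float = 0.3,
    count_scale: float = 1.0,
    **overrides: Any,
) -> PhantomConfig:
    """Default transgenic-like VOI phantom.

    Three hyperdense populations with mean diameters 8 / 4 / 2 µm
    (SD 1.0 / 0.6 / 0.4 µm) in proportions 0.2 / 0.3 / 0.5, with counts set so
    the planted hyperdense tissue load lands in the 1–5 % band typical of
    AD-lesion load estimates; mild hypodense vasculature; Gaussian PSF blur
    and additive detector noise (particle contrast ≈ 50 density units over
    background, noise SD 5 → SNR ≈ 10).
    """
    vol_um3 = float(np.prod(shape)) * voxel_size_um**3
    # counts for the reference VOI (~76.8 um cube at 0.3 um) scale with volume
    ref = 256**3 * 0.3**3
    s = count_scale * vol_um3 / ref
    # PSF at the sampling limit: sigma = voxel/3 (FWHM ~ 0.8 voxel) at every scale
    overrides.setdefault("blur_sigma_um", voxel_size_um / 3.0)
    pops = (
        PopulationSpec("ichd", max(1, round(60 * s)), 8.0, 1.0, 145.0, 5.0),
        PopulationSpec("glia", max(1, round(90 * s)), 4.0, 0.6, 150.0, 5.0),
        PopulationSpec("nucleoli", max(1, round(150 * s)), 2.0, 0.4, 155.0, 5.0),
    )
    cfg = dict(
        shape=shape,
        voxel_size_um=voxel_size_um,
        populations=pops,
        vessel_fraction=0.01,
        seed=seed,
    )
    cfg.update(overrides)
    return PhantomConfig(**cfg)


@dataclass
class PlantedParticle:
    center_um: tuple[float, float, float]  # (z, y, x)
    diameter_um: float
    population: str
    intensity: float
    voxel_count: int


@dataclass
class GroundTruth:
    """Planted-particle catalog and analytic loads for one phantom."""

    particles: list[PlantedParticle]
    true_load_percent: dict[str, float]  # per population + 'total'
    config: PhantomConfig
    seed: int

    def count(self, population: str | None = None) -> int:
        if population is None:
            return len(self.particles)
        return sum(1 for p in self.particles if p.population == population)

    def diameters(self, population: str | None = None) -> np.ndarray:
        return np.array(
            [p.diameter_um for p in self.particles
             if population is None or p.population == population]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            dict(
                id=i + 1,
                z_um=p.center_um[0], y_um=p.center_um[1], x_um=p.center_um[2],
                diameter_um=p.diameter_um, population=p.population,
                intensity=p.intensity, voxel_count=p.voxel_count,
            )
            for i, p in enumerate(self.particles)
        ]
        cols = ["id", "z_um", "y_um", "x_um", "diameter_um", "population",
                "intensity", "voxel_count"]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        d = {
            "seed": self.seed,
            "n_particles": len(self.particles),
            "counts": {name: self.count(name) for name in POPULATION_NAMES
                       if self.count(name)},
            "true_load_percent": self.true_load_percent,
        }
        Path(path).write_text(json.dumps(d, indent=2))


def rasterize_sphere(
    center_um: Sequence[float],
    diameter_um: float,
    shape: tuple[int, int, int],
    voxel_size_um: float,
) -> np.ndarray:
    """Voxel-centre-in-sphere rasterisation over a full grid.

    A voxel is foreground iff its centre ``(index + 0.5) * voxel_size`` lies
    within (<=) ``diameter/2`` of the centre.  A sphere entirely outside the
    grid yields an empty mask.
    """
    if not diameter_um > 0:
        raise ValueError("diameter must be > 0")
    mask = np.zeros(shape, dtype=bool)
    patch = _sphere_patch(center_um, diameter_um / 2.0, shape, voxel_size_um)
    if patch is not None:
        slices, local = patch
        mask[slices] = local
    return mask


def _sphere_patch(
    center_um: Sequence[float],
    radius_um: float,
    shape: tuple[int, int, int],
    voxel_size_um: float,
) -> tuple[tuple[slice, slice, slice], np.ndarray] | None:
    """Bounding-box slices + local boolean sphere mask, or None if off-grid."""
    lo_idx = []
    hi_idx = []
    for ax in range(3):
        c = center_um[ax]
        lo = int(np.floor((c - radius_um) / voxel_size_um - 0.5))
        hi = int(np.ceil((c + radius_um) / voxel_size_um - 0.5)) + 1
        lo, hi = max(lo, 0), min(hi, shape[ax])
        if hi <= lo:
            return None
        lo_idx.append(lo)
        hi_idx.append(hi)
    axes = [
        ((np.arange(lo_idx[ax], hi_idx[ax]) + 0.5) * voxel_size_um - center_um[ax]) ** 2
        for ax in range(3)
    ]
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    local = d2 <= radius_um**2
    if not local.any():
        return None
    slices = tuple(slice(lo_idx[ax], hi_idx[ax]) for ax in range(3))
    return slices, local  # type: ignore[return-value]


def _carve_vessels(
    scene: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    """Carve hypodense cylindrical vessels until the target voxel fraction."""
    target = int(round(cfg.vessel_fraction * scene.size))
    occupied = np.zeros(scene.shape, dtype=bool)
    if target == 0:
        return occupied
    ez, ey, ex = cfg.extent_um()
    zc = ((np.arange(cfg.shape[0]) + 0.5) * cfg.voxel_size_um).astype(np.float32)
    yc = ((np.arange(cfg.shape[1]) + 0.5) * cfg.voxel_size_um).astype(np.float32)
    xc = ((np.arange(cfg.shape[2]) + 0.5) * cfg.voxel_size_um).astype(np.float32)
    for _ in range(64):
        if occupied.sum() >= target:
            break
        p0 = rng.uniform([0, 0, 0], [ez, ey, ex]).astype(np.float32)
        d = rng.normal(size=3).astype(np.float32)
        d /= np.linalg.norm(d)
        radius = rng.uniform(1.0, 3.0) * max(cfg.voxel_size_um, 1.0)
        # squared distance from the line x = p0 + t*d
        rz = zc - p0[0]
        ry = yc - p0[1]
        rx = xc - p0[2]
        t = (rz[:, None, None] * d[0] + ry[None, :, None] * d[1]
             + rx[None, None, :] * d[2])
        d2 = ((rz[:, None, None] - t * d[0]) ** 2
              + (ry[None, :, None] - t * d[1]) ** 2
              + (rx[None, None, :] - t * d[2]) ** 2)
        occupied |= d2 <= radius**2
    scene[occupied] = cfg.background_mean - cfg.vessel_contrast
    return occupied


def generate_phantom(config: PhantomConfig) -> tuple[VoxelVolume, GroundTruth]:
    """Render a phantom VOI and its ground-truth catalog.

    Pipeline: uniform background → hypodense vessels → hyperdense particles
    (rejection-sampled, non-overlapping with a surface gap, whole spheres
    inside the VOI) → pre-blur tissue texture → Gaussian PSF blur → additive
    detector noise.  Deterministic given config + seed.

    Raises :class:`PlacementError` when the requested particles cannot be
    placed without violating the packing bound.
    """
    rng = np.random.default_rng(config.seed)
    scene = np.full(config.shape, config.background_mean, dtype=np.float32)
    occupied = _carve_vessels(scene, config, rng)

    extent = np.array(config.extent_um())
    vox = config.voxel_size_um
    gap = config.gap_um
    particles: list[PlantedParticle] = []

    # draw per-population counts and size/intensity samples (fixed order)
    draws: list[tuple[PopulationSpec, np.ndarray, np.ndarray]] = []
    for pop in config.populations:
        n = pop.expected_count if config.exact_counts else int(rng.poisson(pop.expected_count))
        dia = rng.normal(pop.diameter_mean_um, pop.diameter_sd_um, size=n)
        lo = max(0.1, pop.diameter_mean_um - 2.5 * pop.diameter_sd_um)
        hi = pop.diameter_mean_um + 2.5 * pop.diameter_sd_um
        dia = np.clip(dia, lo, hi)
        inten = rng.normal(pop.intensity_mean, pop.intensity_sd, size=n)
        draws.append((pop, dia, inten))

    # place largest-diameter populations first: packing is easier
    order = np.argsort([-d[0].diameter_mean_um for d in draws], kind="stable")
    max_attempts = 500
    for oi in order:
        pop, dia, inten = draws[oi]
        for j in range(len(dia)):
            r = dia[j] / 2.0
            placed = False
            for _ in range(max_attempts):
                margin = r + gap
                if np.any(extent - 2 * margin <= 0):
                    break
                center = rng.uniform(margin, extent - margin)
                cand = _sphere_patch(center, r, config.shape, vox)
                if cand is None:
                    continue
                slices, local = cand
                if occupied[slices][local].any():
                    continue
                scene[slices][local] = inten[j]
                grown = _sphere_patch(center, r + gap, config.shape, vox)
                assert grown is not None
                occupied[grown[0]][grown[1]] = True
                particles.append(
                    PlantedParticle(
                        center_um=tuple(float(c) for c in center),
                        diameter_um=float(dia[j]),
                        population=pop.name,
                        intensity=float(inten[j]),
                        voxel_count=int(local.sum()),
                    )
                )
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place particle {j + 1}/{len(dia)} of population "
                    f"{pop.name!r} (d={dia[j]:.2f} um) after {max_attempts} attempts; "
                    "volume too small or too crowded"
                )

    if config.background_sd > 0:
        scene += config.background_sd * rng.standard_normal(
            config.shape, dtype=np.float32
        )
    if config.blur_sigma_um > 0:
        ndimage.gaussian_filter(scene, sigma=config.blur_sigma_um / vox, output=scene)
    if config.noise_sd > 0:
        scene += config.noise_sd * rng.standard_normal(config.shape, dtype=np.float32)

    total_vox = float(np.prod(config.shape))
    load: dict[str, float] = {}
    for name in POPULATION_NAMES:
        vc = sum(p.voxel_count for p in particles if p.population == name)
        if vc:
            load[name] = 100.0 * vc / total_vox
    load["total"] = 100.0 * sum(p.voxel_count for p in particles) / total_vox
    truth = GroundTruth(particles=particles, true_load_percent=load,
                        config=config, seed=config.seed)
    volume = VoxelVolume(
        scene, voxel_size=vox,
        meta={"kind": "synthetic-phantom", "seed": config.seed},
    )
    return volume, truth


def resample_volume(volume: VoxelVolume, new_voxel_size_um: float) -> VoxelVolume:
    """Block-mean downsample to a coarser voxel grid.

    The block edge is the nearest integer to ``new/old``; trailing voxels that
    do not fill a whole block are cropped (recorded in metadata).  Total
    integrated density over the cropped region is conserved to float64
    rounding, emulating coarser-resolution acquisition of the same tissue.
    """
    if new_voxel_size_um < volume.voxel_size:
        raise ValueError("new voxel size must be >= the original")
    ratio = new_voxel_size_um / volume.voxel_size
    m = max(1, int(round(ratio)))
    if m == 1:
        return VoxelVolume(volume.values.copy(), volume.voxel_size, dict(volume.meta))
    nz, ny, nx = (s // m for s in volume.shape)
    if min(nz, ny, nx) < 1:
        raise ValueError("volume too small for the requested voxel size")
    cropped = volume.values[: nz * m, : ny * m, : nx * m]
    blocks = cropped.reshape(nz, m, ny, m, nx, m)
    values = blocks.mean(axis=(1, 3, 5), dtype=np.float64)
    meta = dict(volume.meta)
    meta.update(
        resample_block=m,
        resample_requested_um=float(new_voxel_size_um),
        resample_cropped_voxels=[int(s - n * m) for s, n in
                                 zip(volume.shape, (nz, ny, nx))],
    )
    return VoxelVolume(values, voxel_size=volume.voxel_size * m, meta=meta)


# ---------------------------------------------------------------------------
# 2-D elemental phantoms
# ---------------------------------------------------------------------------

_DEFAULT_CLASS_MEANS = {
    # ng/mm2; ICHD-bearing cells accumulate P, S, Ca and Fe ~3x over normal
    "P": {"normal": 150.0, "ichd": 450.0},
    "S": {"normal": 100.0, "ichd": 300.0},
    "Ca": {"normal": 20.0, "ichd": 60.0},
    "Fe": {"normal": 30.0, "ichd": 90.0},
}


@dataclass(frozen=True)
class ElementalPhantomConfig:
    """Synthetic XFM section: labeled cells on a low-density background."""

    map_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    elements: tuple[str, ...] = ("P", "S", "Ca", "Fe")
    n_normal_cells: int = 22
    n_ichd_cells: int = 11
    class_density_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {e: dict(v) for e, v in _DEFAULT_CLASS_MEANS.items()}
    )
    density_sd: float = 5.0
    between_cell_cv: float = 0.0
    background_density: float = 2.0
    cell_diameter_mean_um: float = 12.0
    cell_diameter_sd_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal_cells + self.n_ichd_cells < 2:
            raise ValueError("need at least 2 cells in total")
        for e in self.elements:
            means = self.class_density_means.get(e)
            if means is None:
                raise ValueError(f"no class density means for element {e!r}")
            if any(v < 0 for v in means.values()):
                raise ValueError("densities must be >= 0")
        if self.density_sd < 0 or self.background_density < 0:
            raise ValueError("density_sd and background_density must be >= 0")


def default_xfm_config(seed: int = 0, ichd_ratio: float = 3.0,
                       **overrides: Any) -> ElementalPhantomConfig:
    """Default two-class elemental phantom (22 normal vs 11 ICHD cells)."""
    means = {
        e: {"normal": v["normal"], "ichd": v["normal"] * ichd_ratio}
        for e, v in _DEFAULT_CLASS_MEANS.items()
    }
    cfg = dict(class_density_means=means, seed=seed)
    cfg.update(overrides)
    return ElementalPhantomConfig(**cfg)


def generate_xfm_maps(
    config: ElementalPhantomConfig,
) -> tuple[dict[str, ElementalMap], CellMask, pd.DataFrame]:
    """Render per-element area-density maps with a labeled two-class cell mask.

    Cells are non-overlapping disks (normal cells first, then ICHD, labels in
    placement order).  Each cell's planted per-element mean is the class mean,
    optionally scattered between cells by ``between_cell_cv``; pixel noise is
    additive Gaussian, clipped at zero.  Returns (maps, mask, truth table with
    one row per cell × element: cell_id, cell_class, element, planted_mean).
    """
    rng = np.random.default_rng(config.seed)
    ny, nx = config.map_shape
    px = config.pixel_size_um
    extent = np.array([ny * px, nx * px])
    labels = np.zeros((ny, nx), dtype=np.uint16)
    classes: dict[int, str] = {}
    yy = (np.arange(ny) + 0.5) * px
    xx = (np.arange(nx) + 0.5) * px
    plan = ["normal"] * config.n_normal_cells + ["ichd"] * config.n_ichd_cells
    lab = 0
    max_attempts = 500
    for cls in plan:
        lab += 1
        dia = float(np.clip(
            rng.normal(config.cell_diameter_mean_um, config.cell_diameter_sd_um),
            4 * px, None,
        ))
        r = dia / 2.0
        placed = False
        for _ in range(max_attempts):
            margin = r + px
            if np.any(extent - 2 * margin <= 0):
                break
            cy, cx = rng.uniform(margin, extent - margin)
            d2 = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2
            disk = d2 <= r**2
            # one-pixel gap: reject if the dilated disk touches an existing cell
            grown = d2 <= (r + px) ** 2
            if labels[grown].any():
                continue
            labels[disk] = lab
            classes[lab] = cls
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {lab} ({cls}) after {max_attempts} attempts"
            )
    mask = CellMask(labels=labels, classes=classes)  # type: ignore[arg-type]

    truth_rows = []
    maps: dict[str, ElementalMap] = {}
    for element in config.elements:
        class_means = config.class_density_means[element]
        img = np.full((ny, nx), config.background_density, dtype=float)
        for lab_id in mask.label_ids:
            cls = classes[lab_id]
            planted = class_means[cls]
            if config.between_cell_cv > 0:
                planted = float(planted * rng.lognormal(
                    -0.5 * np.log(1 + config.between_cell_cv**2),
                    np.sqrt(np.log(1 + config.between_cell_cv**2)),
                ))
            img[labels == lab_id] = planted
            truth_rows.append(dict(cell_id=lab_id, cell_class=cls,
                                   element=element, planted_mean=planted))
        if config.density_sd > 0:
            img += rng.normal(0.0, config.density_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)
        maps[element] = ElementalMap(img, element=element, pixel_size_um=px,
                                     meta={"seed": config.seed, "synthetic": True})
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "cell_class",
                                              "element", "planted_mean"])
    return maps, mask, truth


# ---------------------------------------------------------------------------
# Group study
# ---------------------------------------------------------------------------

from .stats import GROUPS, REGIONS  # noqa: E402  (shared label vocabularies)

DEFAULT_GROUP_SIZES = {"WT-saline": 4, "WT-LY": 4, "TG-saline": 3, "TG-LY": 4}


@dataclass(frozen=True)
class StudyConfig:
    """Four-group × four-region study with a planted load effect.

    ``effects`` maps (group, region) to a multiplier on the mean hyperdense
    load; per-VOI loads scatter lognormally around the group×region mean with
    coefficient of variation ``between_voi_cv`` (load varies conspicuously
    between sample volumes of the same animal).  ``n_extra_dorsal`` appends
    additional dorsal VOIs round-robin across animals, which reproduces a
    66-VOI design from the 60-VOI base.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    regions: tuple[str, ...] = REGIONS
    vois_per_animal_region: int = 1
    n_extra_dorsal: int = 0
    base_load_percent: float = 2.0
    between_voi_cv: float = 0.25
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        for r in self.regions:
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}; expected one of {REGIONS}")
        for (g, r), mult in self.effects.items():
            if g not in GROUPS or r not in REGIONS:
                raise ValueError(f"unknown effect cell ({g!r}, {r!r})")
            if mult <= 0:
                raise ValueError("effect multipliers must be > 0")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("each group needs >= 1 animal")


def default_study_config(seed: int = 0, elevation: float = 2.5,
                         **overrides: Any) -> StudyConfig:
    """Default drug-study emulation: elevated load in untreated transgenic
    ventral cortex (TG-saline × vCTX), the study's one significant cell."""
    cfg = dict(
        effects={("TG-saline", "vCTX"): elevation} if elevation != 1.0 else {},
        seed=seed,
    )
    cfg.update(overrides)
    return StudyConfig(**cfg)


def generate_group_study(
    config: StudyConfig,
    render: bool = False,
    phantom_template: PhantomConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Generate the study table and per-VOI ground truth.

    Returns ``(table, artifacts)``.  The table has one row per VOI:
    ``voi_id, animal_id, group, region, true_load_percent``.  With
    ``render=False`` (default) artifacts map each voi_id to the
    :class:`PhantomConfig` that would realise it (counts scaled to the drawn
    load); with ``render=True`` they map to ``(VoxelVolume, GroundTruth)``
    pairs and the table's load column holds the rasterised truth load.
    """
    rng = np.random.default_rng(config.seed)
    if phantom_template is None:
        phantom_template = default_phantom_config(shape=(64, 64, 64),
                                                  voxel_size_um=0.7)
    sigma2 = np.log(1.0 + config.between_voi_cv**2)
    rows = []
    artifacts: dict[str, Any] = {}

    voi_plan: list[tuple[str, str, str]] = []  # (animal_id, group, region)
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        for a in range(1, n + 1):
            animal = f"{group}-a{a}"
            for region in config.regions:
                for _ in range(config.vois_per_animal_region):
                    voi_plan.append((animal, group, region))
    # extra dorsal VOIs, round-robin over animals x (dCTX, dHIP)
    animals = [f"{g}-a{a}" for g in GROUPS
               for a in range(1, config.group_sizes.get(g, 0) + 1)]
    dorsal = [r for r in ("dCTX", "dHIP") if r in config.regions] or ["dCTX"]
    for i in range(config.n_extra_dorsal):
        animal = animals[i % len(animals)]
        group = "-".join(animal.split("-")[:-1])
        voi_plan.append((animal, group, dorsal[i % len(dorsal)]))

    for idx, (animal, group, region) in enumerate(voi_plan, start=1):
        mult = config.effects.get((group, region), 1.0)
        mean_load = config.base_load_percent * mult
        drawn = float(rng.lognormal(np.log(mean_load) - sigma2 / 2.0,
                                    np.sqrt(sigma2)))
        voi_id = f"voi{idx:03d}"
        # scale planted particle counts so the expected load matches the draw
        base_frac = phantom_template.particle_volume_fraction() * 100.0
        scale = drawn / base_frac if base_frac > 0 else 0.0
        pops = tuple(
            replace(p, expected_count=max(0, round(p.expected_count * scale)))
            for p in phantom_template.populations
        )
        voi_cfg = replace(phantom_template, populations=pops,
                          seed=int(rng.integers(0, 2**31 - 1)))
        if render:
            vol, truth = generate_phantom(voi_cfg)
            artifacts[voi_id] = (vol, truth)
            load = truth.true_load_percent["total"]
        else:
            artifacts[voi_id] = voi_cfg
            load = drawn
        rows.append(dict(voi_id=voi_id, animal_id=animal, group=group,
                         region=region, true_load_percent=load))
    table = pd.DataFrame(rows, columns=["voi_id", "animal_id", "group",
                                        "region", "true_load_percent"])
    return table, artifacts
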