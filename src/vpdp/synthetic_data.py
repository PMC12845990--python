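"""Synthetic forest scenes, virtual LiDAR scans, and a satellite stand-in.

The generator emulates the acquisition setting the package targets: a gently
sloped plantation plot (default 150 x 70 m, ~730 stems/ha, mean slope 3
degrees) with tall conifer crowns above largely bare stems and a broadleaf
shrub understory; an aerial nadir scan with a limited number of returns per
pulse (so deep canopy is occluded from above); a ground (handheld/SLAM-style)
scan whose point density decays with distance from the operator's walking
trajectory and whose upper-canopy retention is suppressed by the material
below each target (so the top of the canopy is occluded from below); and a
10 m "observed" reflectance raster produced by running the package's own
radiative forward model on the ground-truth cloud at known coefficients
(alpha*, beta*) and adding Gaussian noise.

Because the satellite stand-in is generated by the same forward model,
parameter/correlation recovery on synthetic scenes is an internal-consistency
check, not an independent physical validation; see the methods note.

Every output is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .calibration_validation import ObservedRaster
from .point_cloud_io import PointCloud, ValidationError, concatenate
from .rt_simulator import RTParams, aggregate_mean, column_radiance
from .voxelizer import VoxelGrid, shared_lattice, voxelize

__all__ = [
    "SceneConfig",
    "ScanConfig",
    "Stand",
    "TruthBundle",
    "generate_stand",
    "sample_surface_points",
    "simulate_aerial_scan",
    "simulate_ground_scan",
    "synthesize_satellite",
    "default_trajectory",
    "StandardScene",
    "make_standard_scene",
]


@dataclass(frozen=True)
class SceneConfig:
    """Forest stand configuration (defaults emulate a mature larch plantation).

    extent
        Plot size (x, y) in meters; default 150 x 70 m.
    stem_density_ha
        Overstory trees per hectare; default 730.
    tree_height / crown_radius / crown_depth
        Uniform ranges (m) for tree size; crown base = height - crown depth,
        leaving a sparse bare-stem zone in the mid canopy.
    shrub_density_ha, shrub_height, shrub_radius
        Understory shrub layer (small low crowns).
    slope_deg
        Planar terrain slope (degrees, dipping along +x); default 3.0.
    seed
        Mandatory RNG seed; the stand is a pure function of config + seed.
    """

    extent: tuple[float, float] = (150.0, 70.0)
    stem_density_ha: float = 730.0
    tree_height: tuple[float, float] = (25.0, 38.0)
    crown_radius: tuple[float, float] = (1.5, 3.5)
    crown_depth: tuple[float, float] = (6.0, 12.0)
    shrub_density_ha: float = 400.0
    shrub_height: tuple[float, float] = (1.0, 4.0)
    shrub_radius: tuple[float, float] = (0.5, 1.5)
    slope_deg: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValidationError("plot extent must be positive in both axes")
        if self.stem_density_ha <= 0:
            raise ValidationError("stem density must be positive")


@dataclass(frozen=True)
class ScanConfig:
    """Virtual scan configuration for one platform.

    Aerial scans emit nadir pulses on a ``pulse_spacing`` grid and keep the
    highest ``max_returns`` truth points per pulse footprint (default 5, a
    typical UAV sensor return multiplicity; high-end units reach 32). Ground
    scans retain each truth point with probability
    ``exp(-d / range_decay) * exp(-occlusion_coeff * n_below)`` where d is the
    horizontal distance to the walking trajectory and n_below the number of
    truth points beneath the target in its vertical column. Gaussian
    coordinate noise of ``noise_sd`` meters is added to kept points.
    """

    platform: str = "aerial"
    max_returns: int = 5
    pulse_spacing: float = 0.5
    trajectory: np.ndarray | None = None
    range_decay: float = 6.0
    occlusion_coeff: float = 0.15
    column_width: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in ("aerial", "ground"):
            raise ValidationError("platform must be 'aerial' or 'ground'")
        if self.max_returns < 1:
            raise ValidationError("max_returns must be >= 1")
        if self.pulse_spacing <= 0 or self.range_decay <= 0:
            raise ValidationError("pulse spacing and range decay must be positive")


@dataclass
class Stand:
    """Tree/shrub lists plus the terrain surface of a synthetic plot."""

    config: SceneConfig
    trees: dict = field(repr=False)  # x, y, height, crown_radius, crown_base
    shrubs: dict = field(repr=False)

    def ground_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Planar sloped terrain height (dips along +x)."""
        return np.tan(np.radians(self.config.slope_deg)) * np.asarray(x)


@dataclass
class TruthBundle:
    """Provenance of a synthetic satellite image: everything needed to redo it."""

    alpha_star: float
    beta_star: float
    noise_sd: float
    affine: tuple[float, float]
    shift: tuple[float, float]
    pixel_size: float
    voxel_size: float
    seed: int

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)


def generate_stand(config: SceneConfig) -> Stand:
    """Draw tree and shrub positions/sizes from a seeded Poisson process."""
    rng = np.random.default_rng(config.seed)
    area_ha = config.extent[0] * config.extent[1] / 1e4
    n_trees = rng.poisson(config.stem_density_ha * area_ha)
    trees = {
        "x": rng.uniform(0, config.extent[0], n_trees),
        "y": rng.uniform(0, config.extent[1], n_trees),
        "height": rng.uniform(*config.tree_height, n_trees),
        "crown_radius": rng.uniform(*config.crown_radius, n_trees),
    }
    depth = rng.uniform(*config.crown_depth, n_trees)
    trees["crown_base"] = trees["height"] - depth
    n_shrubs = rng.poisson(config.shrub_density_ha * area_ha)
    shrubs = {
        "x": rng.uniform(0, config.extent[0], n_shrubs),
        "y": rng.uniform(0, config.extent[1], n_shrubs),
        "height": rng.uniform(*config.shrub_height, n_shrubs),
        "crown_radius": rng.uniform(*config.shrub_radius, n_shrubs),
    }
    shrubs["crown_base"] = 0.3 * shrubs["height"]
    return Stand(config, trees, shrubs)


def _spheroid_area(a: float | np.ndarray, c: float | np.ndarray) -> np.ndarray:
    """Approximate ellipsoid surface area (Thomsen's formula, p = 1.6075)."""
    p = 1.6075
    a, c = np.asarray(a, dtype=float), np.asarray(c, dtype=float)
    return 4 * np.pi * (((a * a) ** p + 2 * (a * c) ** p) / 3) ** (1 / p)


def _sample_spheroid_shell(
    n: np.ndarray, cx, cy, cz, a, c, rng
) -> np.ndarray:
    """Points on axis-aligned spheroid shells (one spheroid per element)."""
    total = int(n.sum())
    rep = np.repeat(np.arange(len(n)), n)
    u = rng.standard_normal((total, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = np.column_stack(
        [
            cx[rep] + a[rep] * u[:, 0],
            cy[rep] + a[rep] * u[:, 1],
            cz[rep] + c[rep] * u[:, 2],
        ]
    )
    return pts


def _sample_spheroid_volume(n, cx, cy, cz, a, c, rng) -> np.ndarray:
    total = int(n.sum())
    rep = np.repeat(np.arange(len(n)), n)
    u = rng.standard_normal((total, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(0, 1, total) ** (1 / 3)
    return np.column_stack(
        [
            cx[rep] + a[rep] * r * u[:, 0],
            cy[rep] + a[rep] * r * u[:, 1],
            cz[rep] + c[rep] * r * u[:, 2],
        ]
    )


def sample_surface_points(
    stand: Stand,
    crown_shell_density: float = 6.0,
    crown_volume_density: float = 1.2,
    stem_surface_density: float = 20.0,
    terrain_density: float = 2.0,
    stem_radius: float = 0.11,
    seed: int | None = None,
) -> PointCloud:
    """Sample a ground-truth point cloud from the stand's geometric elements.

    Crowns are spheroids sampled both on the shell (densities in points/m^2)
    and uniformly in the volume (points/m^3); stems are vertical cylinders
    below the crown base; terrain is a plane. Per-element point counts are
    Poisson with mean area (or volume) x density, so doubling a density
    doubles the expected count. Points carry a ``source_id`` element label.
    """
    for d in (crown_shell_density, crown_volume_density, stem_surface_density, terrain_density):
        if d < 0:
            raise ValidationError("densities must be non-negative")
    cfg = stand.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    def add(pts: np.ndarray, label: str) -> None:
        if len(pts):
            chunks.append(pts)
            labels.append(np.full(len(pts), label, dtype=object))

    for group, tag in ((stand.trees, "crown"), (stand.shrubs, "shrub")):
        if len(group["x"]) == 0:
            continue
        a = group["crown_radius"]
        c = (group["height"] - group["crown_base"]) / 2.0
        cz = stand.ground_z(group["x"], group["y"]) + group["crown_base"] + c
        n_shell = rng.poisson(crown_shell_density * _spheroid_area(a, c))
        add(_sample_spheroid_shell(n_shell, group["x"], group["y"], cz, a, c, rng), tag)
        vol = 4.0 / 3.0 * np.pi * a * a * c
        n_vol = rng.poisson(crown_volume_density * vol)
        add(_sample_spheroid_volume(n_vol, group["x"], group["y"], cz, a, c, rng), tag)

    t = stand.trees
    if len(t["x"]):
        lateral = 2 * np.pi * stem_radius * np.maximum(t["crown_base"], 0.0)
        n_stem = rng.poisson(stem_surface_density * lateral)
        rep = np.repeat(np.arange(len(n_stem)), n_stem)
        theta = rng.uniform(0, 2 * np.pi, rep.size)
        zfrac = rng.uniform(0, 1, rep.size)
        add(
            np.column_stack(
                [
                    t["x"][rep] + stem_radius * np.cos(theta),
                    t["y"][rep] + stem_radius * np.sin(theta),
                    stand.ground_z(t["x"][rep], t["y"][rep])
                    + zfrac * np.maximum(t["crown_base"][rep], 0.0),
                ]
            ),
            "stem",
        )

    n_terrain = rng.poisson(terrain_density * cfg.extent[0] * cfg.extent[1])
    tx = rng.uniform(0, cfg.extent[0], n_terrain)
    ty = rng.uniform(0, cfg.extent[1], n_terrain)
    add(
        np.column_stack([tx, ty, stand.ground_z(tx, ty) + rng.uniform(0, 0.05, n_terrain)]),
        "terrain",
    )

    if not chunks:
        return PointCloud(np.empty((0, 3)))
    pts = np.vstack(chunks)
    # clip points blown outside the plot by crown overhang
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < cfg.extent[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < cfg.extent[1])
    )
    return PointCloud(pts[inside], np.concatenate(labels)[inside], "synthetic plot meters")


# ---------------------------------------------------------------------------
# Virtual scans
# ---------------------------------------------------------------------------


def _column_rank_from_top(pts: np.ndarray, cell: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-point rank from the top of its (x, y) column and points-below count."""
    ij = np.floor(pts[:, :2] / cell).astype(np.int64)
    ij -= ij.min(axis=0)
    flat = ij[:, 0] * (ij[:, 1].max() + 1) + ij[:, 1]
    order = np.lexsort((-pts[:, 2], flat))
    sorted_flat = flat[order]
    group_start = np.flatnonzero(np.r_[True, sorted_flat[1:] != sorted_flat[:-1]])
    sizes = np.diff(np.r_[group_start, sorted_flat.size])
    rank_sorted = np.arange(sorted_flat.size) - np.repeat(group_start, sizes)
    rank = np.empty(flat.size, dtype=np.int64)
    rank[order] = rank_sorted
    n_in_col = np.repeat(sizes, sizes)[np.argsort(order, kind="stable")]
    n_below = n_in_col - 1 - rank
    return rank, n_below


def simulate_aerial_scan(truth_cloud: PointCloud, config: ScanConfig) -> PointCloud:
    """Nadir pulse scan: keep the highest ``max_returns`` hits per pulse cell.

    Pulses lie on a horizontal grid of ``pulse_spacing`` meters; candidate
    hits in a pulse footprint are the truth points in that grid cell, ordered
    top-down, and everything deeper than the return limit is occluded.
    """
    if config.platform != "aerial":
        raise ValidationError("config.platform must be 'aerial'")
    if len(truth_cloud) == 0:
        return PointCloud(np.empty((0, 3)))
    rng = np.random.default_rng(config.seed)
    rank, _ = _column_rank_from_top(truth_cloud.points, config.pulse_spacing)
    keep = rank < config.max_returns
    pts = truth_cloud.points[keep] + rng.normal(0, config.noise_sd, (int(keep.sum()), 3))
    return PointCloud(pts, np.full(len(pts), "aerial", dtype=object), truth_cloud.crs_note)


def default_trajectory(
    extent: tuple[float, float], line_spacing: float = 25.0, step: float = 2.0
) -> np.ndarray:
    """Serpentine walking path: parallel lines along x, spaced in y."""
    ys = np.arange(line_spacing / 2.0, extent[1], line_spacing)
    vertices = []
    for i, y in enumerate(ys):
        xs = np.arange(0, extent[0] + step / 2, step)
        if i % 2:
            xs = xs[::-1]
        vertices.append(np.column_stack([xs, np.full(xs.size, y)]))
    return np.vstack(vertices)


def simulate_ground_scan(truth_cloud: PointCloud, config: ScanConfig) -> PointCloud:
    """Ground (handheld-style) scan with range decay and upward occlusion.

    Retention probability of each truth point is
    ``exp(-d / range_decay) * exp(-occlusion_coeff * n_below)`` with d the
    horizontal distance to the nearest trajectory vertex and n_below the
    number of truth points beneath it in its vertical column — the canopy
    blocks the view from below, reproducing the characteristic loss of upper
    canopy in ground scans.
    """
    if config.platform != "ground":
        raise ValidationError("config.platform must be 'ground'")
    if config.trajectory is None or len(np.atleast_2d(config.trajectory)) == 0:
        raise ValidationError("ground scan requires a non-empty trajectory")
    if len(truth_cloud) == 0:
        return PointCloud(np.empty((0, 3)))
    rng = np.random.default_rng(config.seed)
    traj = np.atleast_2d(np.asarray(config.trajectory, dtype=float))
    tree = cKDTree(traj)
    d, _ = tree.query(truth_cloud.points[:, :2])
    _, n_below = _column_rank_from_top(truth_cloud.points, config.column_width)
    p = np.exp(-d / config.range_decay) * np.exp(-config.occlusion_coeff * n_below)
    keep = rng.random(len(truth_cloud)) < p
    pts = truth_cloud.points[keep] + rng.normal(0, config.noise_sd, (int(keep.sum()), 3))
    return PointCloud(pts, np.full(len(pts), "ground", dtype=object), truth_cloud.crs_note)


def retention_probability(
    truth_cloud: PointCloud, config: ScanConfig
) -> np.ndarray:
    """Per-point ground-scan retention probability (for diagnostics/tests)."""
    traj = np.atleast_2d(np.asarray(config.trajectory, dtype=float))
    d, _ = cKDTree(traj).query(truth_cloud.points[:, :2])
    _, n_below = _column_rank_from_top(truth_cloud.points, config.column_width)
    return np.exp(-d / config.range_decay) * np.exp(-config.occlusion_coeff * n_below)


# ---------------------------------------------------------------------------
# Satellite stand-in
# ---------------------------------------------------------------------------


def synthesize_satellite(
    truth_cloud: PointCloud,
    voxel_size: float = 0.5,
    alpha_star: float = 0.05,
    beta_star: float = 0.05,
    pixel_size: float = 10.0,
    noise_sd: float | None = None,
    noise_factor: float = 0.6,
    seed: int = 0,
    origin: tuple[float, float, float] | None = None,
    dims: tuple[int, int, int] | None = None,
    shift: tuple[float, float] = (0.0, 0.0),
    affine: tuple[float, float] = (8.0, 0.18),
    reflectance: float = 0.05,
) -> tuple[ObservedRaster, TruthBundle]:
    """Generate the coarse "observed" reflectance raster from the truth cloud.

    The truth cloud is voxelized, run through the column radiance model at the
    known coefficients (alpha*, beta*), aggregated to ``pixel_size`` (after an
    optional planted horizontal ``shift`` of the fine map), mapped through the
    positive affine transform ``a * radiance + b`` to a reflectance-like
    scale, and perturbed with i.i.d. Gaussian noise. When ``noise_sd`` is not
    given it is ``noise_factor`` times the spatial standard deviation of the
    noise-free signal (default 0.6, i.e. a moderately noisy satellite signal).
    """
    if pixel_size <= 0 or voxel_size <= 0:
        raise ValidationError("pixel and voxel sizes must be positive")
    grid = voxelize(truth_cloud, voxel_size, origin=origin, dims=dims)
    params = RTParams(alpha_star, beta_star, reflectance=reflectance)
    fine = column_radiance(grid, params).fine
    n_coarse = (
        int(np.ceil(grid.dims[0] * voxel_size / pixel_size)),
        int(np.ceil(grid.dims[1] * voxel_size / pixel_size)),
    )
    coarse = aggregate_mean(
        fine, voxel_size, pixel_size, n_coarse, offset=(-shift[0], -shift[1])
    )
    a, b = affine
    signal = a * coarse + b
    if noise_sd is None:
        noise_sd = float(noise_factor * np.nanstd(signal))
    rng = np.random.default_rng(seed)
    observed_vals = signal + rng.normal(0, noise_sd, signal.shape)
    mask = np.isfinite(observed_vals)
    observed = ObservedRaster(
        np.where(mask, observed_vals, np.nan), mask, grid.origin[:2], pixel_size
    )
    bundle = TruthBundle(
        alpha_star, beta_star, noise_sd, affine, shift, pixel_size, voxel_size, seed
    )
    return observed, bundle


# ---------------------------------------------------------------------------
# Standard scene
# ---------------------------------------------------------------------------


@dataclass
class StandardScene:
    """The bundled end-to-end synthetic study: one plot, two platforms, one image."""

    truth: PointCloud
    aerial: PointCloud
    ground: PointCloud
    merged: PointCloud
    lattice_origin: tuple[float, float, float]
    lattice_dims: tuple[int, int, int]
    voxel_size: float
    truth_grid: VoxelGrid
    aerial_grid: VoxelGrid
    ground_grid: VoxelGrid
    merged_grid: VoxelGrid
    observed: ObservedRaster
    bundle: TruthBundle


def make_standard_scene(
    seed: int = 0,
    voxel_size: float = 0.5,
    scene_config: SceneConfig | None = None,
    noise_sd: float | None = None,
    noise_factor: float = 0.6,
    satellite_shift: tuple[float, float] = (0.0, 0.0),
) -> StandardScene:
    """Build the default study scene: stand, truth cloud, both scans, image.

    All randomness derives from ``seed``. The aerial and ground scans use the
    default platform configurations; every cloud is voxelized on one shared
    lattice derived from the union bounding box so occupancy comparisons are
    meaningful.
    """
    cfg = scene_config or SceneConfig(seed=seed)
    if scene_config is not None and scene_config.seed != seed:
        cfg = SceneConfig(**{**scene_config.__dict__, "seed": seed})
    stand = generate_stand(cfg)
    truth = sample_surface_points(stand)
    aerial = simulate_aerial_scan(truth, ScanConfig(platform="aerial", seed=cfg.seed + 101))
    ground = simulate_ground_scan(
        truth,
        ScanConfig(
            platform="ground",
            trajectory=default_trajectory(cfg.extent),
            seed=cfg.seed + 202,
        ),
    )
    merged = concatenate([aerial, ground])
    origin, dims = shared_lattice([truth, aerial, ground], voxel_size)
    truth_grid = voxelize(truth, voxel_size, origin, dims)
    aerial_grid = voxelize(aerial, voxel_size, origin, dims)
    ground_grid = voxelize(ground, voxel_size, origin, dims)
    merged_grid = voxelize(merged, voxel_size, origin, dims)
    observed, bundle = synthesize_satellite(
        truth,
        voxel_size=voxel_size,
        seed=cfg.seed + 303,
        origin=origin,
        dims=dims,
        noise_sd=noise_sd,
        noise_factor=noise_factor,
        shift=satellite_shift,
    )
    return StandardScene(
        truth,
        aerial,
        ground,
        merged,
        origin,
        dims,
        voxel_size,
        truth_grid,
        aerial_grid,
        ground_grid,
        merged_grid,
        observed,
        bundle,
    )
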