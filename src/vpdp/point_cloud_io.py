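"""Point-cloud reading/writing, cleaning, and planar diagnostics.

Point clouds are plain ``(n, 3)`` float arrays of x/y/z in meters wrapped in
:class:`PointCloud`. The primary interchange format is whitespace-separated
ASCII XYZ (``x y z`` per line, ``#`` comments allowed); LAS/LAZ is supported
when :mod:`laspy` is installed.

Two diagnostic products mirror the standard visual checks on multi-platform
forest scans: vertical cross-section slabs and planar (top-down) point-density
rasters on a fine grid (0.5 m by default).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("vpdp")

__all__ = [
    "PointCloud",
    "DensityRaster",
    "FormatError",
    "ValidationError",
    "read_point_cloud",
    "write_point_cloud",
    "remove_isolated_outliers",
    "extract_cross_section",
    "planar_density_map",
]


class FormatError(ValueError):
    """Unreadable or unsupported point-cloud file."""


class ValidationError(ValueError):
    """Input violates a structural invariant (e.g. non-finite coordinate)."""


@dataclass
class PointCloud:
    """A set of 3D points in meters, optionally labelled by origin sensor.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of x, y, z coordinates in meters. All values
        must be finite. An empty cloud (``n = 0``) is legal.
    source_id
        Optional per-point label (sensor/platform of origin), length ``n``.
    crs_note
        Free-text tag describing the (shared, projected) coordinate system.
    """

    points: np.ndarray
    source_id: np.ndarray | None = None
    crs_note: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (n, 3), got {pts.shape}")
        bad = ~np.isfinite(pts).all(axis=1)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"non-finite coordinate at point record {idx}: {pts[idx]}"
            )
        self.points = pts
        if self.source_id is not None:
            sid = np.asarray(self.source_id)
            if sid.shape[0] != pts.shape[0]:
                raise ValidationError(
                    f"source_id length {sid.shape[0]} != point count {pts.shape[0]}"
                )
            self.source_id = sid

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_xyz, max_xyz); raises on an empty cloud."""
        if len(self) == 0:
            raise ValidationError("empty cloud has no bounds")
        return self.points.min(axis=0), self.points.max(axis=0)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        sid = self.source_id[mask] if self.source_id is not None else None
        return PointCloud(self.points[mask], sid, self.crs_note)


def concatenate(clouds: list[PointCloud]) -> PointCloud:
    """Concatenate clouds, preserving order and per-point source labels."""
    if not clouds:
        return PointCloud(np.empty((0, 3)))
    pts = np.vstack([c.points for c in clouds])
    if any(c.source_id is not None for c in clouds):
        sid = np.concatenate(
            [
                c.source_id
                if c.source_id is not None
                else np.full(len(c), "", dtype=object)
                for c in clouds
            ]
        )
    else:
        sid = None
    return PointCloud(pts, sid, clouds[0].crs_note)


@dataclass
class DensityRaster:
    """Top-down per-cell point counts on a regular 2D grid.

    ``counts[i, j]`` is the number of points whose x falls in cell i and y in
    cell j under half-open binning from ``origin``. The sum of all cells
    equals the number of in-bounds points.
    """

    origin: tuple[float, float]
    cell_size: float
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValidationError("cell size must be > 0")
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValidationError("density counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | os.PathLike) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")

    def to_tiff(self, path: str | os.PathLike) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            self.counts.astype(np.int32),
            metadata={
                "origin_x": self.origin[0],
                "origin_y": self.origin[1],
                "cell_size": self.cell_size,
            },
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

_FORMATS = {"las", "laz", "xyz-ascii"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("las", "laz"):
        return suffix
    return "xyz-ascii"


def read_point_cloud(path: str | os.PathLike, format: str | None = None) -> PointCloud:
    """Read a point cloud from LAS/LAZ or ASCII XYZ.

    Only x, y, z are consumed from LAS records. ASCII XYZ is whitespace
    separated, one point per line, ``#`` starts a comment. Input order is
    preserved. Non-finite coordinates raise :class:`ValidationError` naming
    the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    if fmt in ("las", "laz"):
        try:
            import laspy
        except ImportError as exc:  # pragma: no cover - laspy optional
            raise FormatError(
                "reading LAS/LAZ requires the optional 'laspy' dependency "
                "(pip install vpdp[las]); convert to ASCII XYZ otherwise"
            ) from exc
        with laspy.open(path) as reader:  # pragma: no cover - laspy optional
            las = reader.read()
            pts = np.column_stack([las.x, las.y, las.z]).astype(np.float64)
        return PointCloud(pts, crs_note=str(path))
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*no data.*")
            raw = np.loadtxt(path, comments="#", ndmin=2, dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"could not parse {path} as ASCII XYZ: {exc}") from exc
    if raw.size == 0:
        return PointCloud(np.empty((0, 3)))
    if raw.shape[1] < 3:
        raise FormatError(
            f"{path}: expected >= 3 whitespace-separated columns, got {raw.shape[1]}"
        )
    return PointCloud(raw[:, :3])


def write_point_cloud(
    cloud: PointCloud, path: str | os.PathLike, format: str = "xyz-ascii", precision: int = 6
) -> None:
    """Write a cloud as ASCII XYZ (the text interchange dialect)."""
    if format != "xyz-ascii":
        raise FormatError(f"writing supports xyz-ascii only, got {format!r}")
    np.savetxt(path, cloud.points, fmt=f"%.{precision}f")


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def remove_isolated_outliers(
    cloud: PointCloud, k_neighbors: int = 5, distance_factor: float = 3.0
) -> PointCloud:
    """Drop isolated points by a statistical k-nearest-neighbour rule.

    For each point the mean distance to its ``k_neighbors`` nearest
    neighbours is computed; points whose statistic exceeds
    ``global mean + distance_factor * global std`` are removed. This is a
    deterministic stand-in for the manual removal of isolated returns that is
    customary when preparing multi-sensor forest scans; results on real data
    depend on (k, factor), defaults k=5, factor=3.
    """
    if len(cloud) == 0:
        raise ValidationError("cannot filter an empty cloud")
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    if distance_factor <= 0:
        raise ValidationError("distance_factor must be > 0")
    if len(cloud) < k_neighbors + 1:
        logger.warning(
            "cloud of %d points smaller than k_neighbors+1=%d: returned unchanged",
            len(cloud),
            k_neighbors + 1,
        )
        return cloud
    tree = cKDTree(cloud.points)
    # k+1 because the first neighbour of each point is itself (distance 0)
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + distance_factor * mean_d.std()
    keep = mean_d <= threshold
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d isolated points (threshold %.3f m)", n_removed, threshold)
    return cloud.subset(keep)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def extract_cross_section(
    cloud: PointCloud,
    axis: str,
    center: float,
    width: float,
    length: tuple[float, float] | None = None,
) -> PointCloud:
    """Extract a vertical slab of points (a cross-section transect).

    ``axis`` names the slab-normal horizontal axis ('x' or 'y'); points with
    that coordinate in the half-open interval
    ``[center - width/2, center + width/2)`` are kept. ``length`` optionally
    bounds the along-slab coordinate (half-open as well). An empty result is
    legal.
    """
    if width <= 0:
        raise ValidationError("width must be > 0")
    if axis not in ("x", "y"):
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")
    normal = 0 if axis == "x" else 1
    along = 1 - normal
    coords = cloud.points
    lo, hi = center - width / 2.0, center + width / 2.0
    mask = (coords[:, normal] >= lo) & (coords[:, normal] < hi)
    if length is not None:
        mask &= (coords[:, along] >= length[0]) & (coords[:, along] < length[1])
    return cloud.subset(mask)


def planar_density_map(
    cloud: PointCloud,
    cell_size: float = 0.5,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> DensityRaster:
    """Bin points top-down into a per-cell count raster.

    Cells are half-open ``[lo, hi)`` with floor indexing; a point exactly on a
    boundary belongs to the higher-index cell. Out-of-bounds points (possible
    only when origin/shape are supplied) are excluded, so the raster total
    equals the in-bounds point count.
    """
    if cell_size <= 0:
        raise ValidationError("cell_size must be > 0")
    pts = cloud.points
    if origin is None:
        if len(cloud) == 0:
            return DensityRaster((0.0, 0.0), cell_size, np.zeros((1, 1), dtype=np.int64))
        origin = (float(pts[:, 0].min()), float(pts[:, 1].min()))
    if shape is None:
        if len(cloud) == 0:
            shape = (1, 1)
        else:
            span = pts[:, :2].max(axis=0) - np.asarray(origin)
            shape = tuple(int(np.floor(s / cell_size)) + 1 for s in span)
    ij = np.floor((pts[:, :2] - np.asarray(origin)) / cell_size).astype(np.int64)
    inb = (
        (ij[:, 0] >= 0)
        & (ij[:, 0] < shape[0])
        & (ij[:, 1] >= 0)
        & (ij[:, 1] < shape[1])
    )
    flat = ij[inb, 0] * shape[1] + ij[inb, 1]
    counts = np.bincount(flat, minlength=shape[0] * shape[1]).reshape(shape)
    return DensityRaster(tuple(map(float, origin)), float(cell_size), counts)
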