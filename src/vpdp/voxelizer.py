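"""Voxelization of point clouds onto a shared 3D lattice.

A :class:`VoxelGrid` stores per-voxel point counts ``P[i, j, k]`` on a regular
isotropic lattice; ``k`` increases upward from the grid origin. All binning is
half-open ``[lo, hi)`` with floor indexing, the single convention used across
the package, so that occupancy comparisons between sensors are meaningful:
whenever several clouds are compared they are voxelized on ONE lattice derived
from the union bounding box (:func:`shared_lattice`).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .point_cloud_io import PointCloud, ValidationError

__all__ = [
    "VoxelGrid",
    "LayerProfile",
    "LatticeMismatchError",
    "shared_lattice",
    "voxelize",
    "merge_grids",
    "aggregate_voxels",
    "vertical_profile",
]


class LatticeMismatchError(ValueError):
    """Two grids do not share origin / voxel size / dimensions."""


@dataclass
class VoxelGrid:
    """Regular 3D lattice of per-voxel point counts.

    Attributes
    ----------
    origin
        (x0, y0, z0) of the lattice corner, meters.
    voxel_size
        Isotropic edge length s > 0, meters.
    counts
        ``(nx, ny, nz)`` non-negative integer array; ``counts[i, j, k]`` is
        the number of points in cell ``[i, j, k]``; k indexes height upward.
    n_out_of_bounds
        Points of the source cloud that fell outside the lattice (counted,
        not stored).
    """

    origin: tuple[float, float, float]
    voxel_size: float
    counts: np.ndarray = field(repr=False)
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValidationError("voxel size must be > 0")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or min(self.counts.shape) < 1:
            raise ValidationError(f"counts must be 3D with dims >= 1, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("voxel counts must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def same_lattice(self, other: "VoxelGrid") -> bool:
        return (
            np.allclose(self.origin, other.origin)
            and self.voxel_size == other.voxel_size
            and self.dims == other.dims
        )

    def save(self, path: str | os.PathLike) -> None:
        """Serialize as a sparse (i, j, k, count) CSV plus a JSON header."""
        path = str(path)
        i, j, k = np.nonzero(self.counts)
        pd.DataFrame(
            {"i": i, "j": j, "k": k, "count": self.counts[i, j, k]}
        ).to_csv(path, index=False)
        header = {
            "origin": list(self.origin),
            "voxel_size": self.voxel_size,
            "dims": list(self.dims),
            "n_out_of_bounds": self.n_out_of_bounds,
        }
        with open(path + ".json", "w") as fh:
            json.dump(header, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "VoxelGrid":
        path = str(path)
        with open(path + ".json") as fh:
            header = json.load(fh)
        table = pd.read_csv(path)
        counts = np.zeros(tuple(header["dims"]), dtype=np.int64)
        counts[table["i"], table["j"], table["k"]] = table["count"]
        return cls(
            tuple(header["origin"]),
            header["voxel_size"],
            counts,
            header["n_out_of_bounds"],
        )


@dataclass
class LayerProfile:
    """Per-height-layer medians of voxel point counts.

    Layers are contiguous slabs of ``layer_height`` meters above the grid's
    minimum z. The median is taken over OCCUPIED voxels (count >= 1) in the
    slab; a slab with no occupied voxel has median NaN (undefined), never 0.
    """

    layer_bounds: list[tuple[float, float]]
    medians: np.ndarray
    voxel_tallies: np.ndarray

    def __post_init__(self) -> None:
        for (lo1, hi1), (lo2, hi2) in zip(self.layer_bounds, self.layer_bounds[1:]):
            if not np.isclose(hi1, lo2) or hi2 <= lo2:
                raise ValidationError("layers must be contiguous, ordered bottom-up")
        med = np.asarray(self.medians, dtype=float)
        if np.nanmin(med, initial=0.0) < 0:
            raise ValidationError("medians must be non-negative")
        self.medians = med
        self.voxel_tallies = np.asarray(self.voxel_tallies)

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {
                "layer_lo_m": [b[0] for b in self.layer_bounds],
                "layer_hi_m": [b[1] for b in self.layer_bounds],
                "median_points_per_voxel": self.medians,
                "n_occupied_voxels": self.voxel_tallies,
            }
        ).to_csv(path, index=False)


def shared_lattice(
    clouds: list[PointCloud], voxel_size: float
) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    """Origin and dims covering the union bounding box of several clouds."""
    nonempty = [c for c in clouds if len(c)]
    if not nonempty:
        raise ValidationError("need at least one non-empty cloud to derive a lattice")
    lo = np.min([c.bounds[0] for c in nonempty], axis=0)
    hi = np.max([c.bounds[1] for c in nonempty], axis=0)
    dims = tuple(int(np.floor((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
    return tuple(map(float, lo)), dims


def voxelize(
    cloud: PointCloud,
    voxel_size: float,
    origin: tuple[float, float, float] | None = None,
    dims: tuple[int, int, int] | None = None,
) -> VoxelGrid:
    """Count points per voxel under half-open binning.

    When ``origin``/``dims`` are omitted they are derived from the cloud's
    bounding box. Points outside the lattice are tallied in
    ``n_out_of_bounds`` and excluded from the counts, so
    ``grid.total + grid.n_out_of_bounds == len(cloud)``.
    """
    if voxel_size <= 0:
        raise ValidationError("voxel size must be > 0")
    if origin is None or dims is None:
        o, d = shared_lattice([cloud], voxel_size)
        origin = origin if origin is not None else o
        dims = dims if dims is not None else d
    pts = cloud.points
    if len(cloud) == 0:
        return VoxelGrid(tuple(map(float, origin)), voxel_size, np.zeros(dims, dtype=np.int64))
    idx = np.floor((pts - np.asarray(origin)) / voxel_size).astype(np.int64)
    inb = np.all((idx >= 0) & (idx < np.asarray(dims)), axis=1)
    n_oob = int((~inb).sum())
    if n_oob == len(cloud):
        import logging

        logging.getLogger("vpdp").warning("lattice excludes all %d points", n_oob)
    flat = np.ravel_multi_index(tuple(idx[inb].T), dims)
    counts = np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)
    return VoxelGrid(tuple(map(float, origin)), float(voxel_size), counts, n_oob)


def merge_grids(grids: list[VoxelGrid]) -> VoxelGrid:
    """Element-wise sum of count grids that share one lattice."""
    if not grids:
        raise ValidationError("merge_grids requires at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        if not np.allclose(g.origin, ref.origin):
            raise LatticeMismatchError(f"origin mismatch: {g.origin} vs {ref.origin}")
        if g.voxel_size != ref.voxel_size:
            raise LatticeMismatchError(
                f"voxel_size mismatch: {g.voxel_size} vs {ref.voxel_size}"
            )
        if g.dims != ref.dims:
            raise LatticeMismatchError(f"dims mismatch: {g.dims} vs {ref.dims}")
    counts = np.sum([g.counts for g in grids], axis=0)
    n_oob = sum(g.n_out_of_bounds for g in grids)
    return VoxelGrid(ref.origin, ref.voxel_size, counts, n_oob)


def aggregate_voxels(grid: VoxelGrid, factor: int) -> VoxelGrid:
    """Re-bin counts into voxels ``factor`` times coarser (same origin).

    Equivalent to voxelizing the same cloud at ``factor * voxel_size`` when
    origins coincide; partial blocks at the high edge are kept.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError("factor must be a positive integer")
    factor = int(factor)
    nx, ny, nz = grid.dims
    new_dims = tuple(-(-n // factor) for n in grid.dims)
    padded = np.zeros(tuple(n * factor for n in new_dims), dtype=grid.counts.dtype)
    padded[:nx, :ny, :nz] = grid.counts
    counts = (
        padded.reshape(
            new_dims[0], factor, new_dims[1], factor, new_dims[2], factor
        )
        .sum(axis=(1, 3, 5))
    )
    return VoxelGrid(grid.origin, grid.voxel_size * factor, counts, grid.n_out_of_bounds)


def vertical_profile(grid: VoxelGrid, layer_height: float = 10.0) -> LayerProfile:
    """Median point count per voxel within horizontal height layers.

    Layers are ``[0, h), [h, 2h), ...`` meters above the grid's minimum z
    (the z origin), assigned by voxel-center height. Medians are over occupied
    voxels only; an all-empty layer yields NaN.
    """
    if layer_height <= 0:
        raise ValidationError("layer_height must be > 0")
    s = grid.voxel_size
    nz = grid.dims[2]
    centers = (np.arange(nz) + 0.5) * s
    layer_of_k = np.floor(centers / layer_height).astype(int)
    n_layers = int(layer_of_k.max()) + 1
    bounds, medians, tallies = [], [], []
    for layer in range(n_layers):
        ks = np.flatnonzero(layer_of_k == layer)
        slab = grid.counts[:, :, ks]
        occupied = slab[slab >= 1]
        bounds.append((layer * layer_height, (layer + 1) * layer_height))
        tallies.append(occupied.size)
        medians.append(float(np.median(occupied)) if occupied.size else np.nan)
    return LayerProfile(bounds, np.array(medians), np.array(tallies))
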