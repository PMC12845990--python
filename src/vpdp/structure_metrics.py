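"""Coverage gap ratio (CGR): relative occlusion of a scan vs. a reference.

The reference occupancy V_All is normally the union of every available scan's
occupied voxels (the "all-merged" model). For a dataset with occupancy V_c,
the voxels present only in the reference are

    V_All-only = { (i, j, k) : (i, j, k) in V_All and (i, j, k) not in V_c }

and per height bin z the coverage gap ratio is

    CGR_z = |V_All-only at z| / |V_All at z|,

a number in [0, 1]: 0 means the dataset sees everything the reference sees at
that height, 1 means it sees nothing there. Bins where the reference itself is
empty are undefined (NaN), never reported as 0. Because the reference is
itself sensor-derived, CGR measures relative completeness, not absolute
occlusion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .point_cloud_io import ValidationError
from .voxelizer import LatticeMismatchError, VoxelGrid

__all__ = ["OccupancySet", "CGRProfile", "occupancy_set", "merge_occupancy", "coverage_gap_ratio"]


@dataclass(frozen=True)
class OccupancySet:
    """Set of occupied voxel indices (count >= 1) on a shared lattice."""

    indices: frozenset
    origin: tuple[float, float, float]
    voxel_size: float
    dims: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.indices)

    def same_lattice(self, other: "OccupancySet") -> bool:
        return (
            np.allclose(self.origin, other.origin)
            and self.voxel_size == other.voxel_size
            and self.dims == other.dims
        )

    def union(self, other: "OccupancySet") -> "OccupancySet":
        if not self.same_lattice(other):
            raise LatticeMismatchError("cannot union occupancy sets on different lattices")
        return OccupancySet(self.indices | other.indices, self.origin, self.voxel_size, self.dims)


@dataclass
class CGRProfile:
    """Per-height-bin coverage gap ratio against a reference occupancy.

    ``cgr[z]`` is NaN where the reference has no voxels in bin z (undefined).
    """

    bin_height: float
    bin_lo: np.ndarray
    bin_hi: np.ndarray
    cgr: np.ndarray
    n_reference_voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cgr = np.asarray(self.cgr, dtype=float)
        defined = ~np.isnan(cgr)
        if ((cgr[defined] < 0) | (cgr[defined] > 1)).any():
            raise ValidationError("CGR values must lie in [0, 1]")
        if (np.asarray(self.n_reference_voxels)[~defined] != 0).any():
            raise ValidationError("NaN CGR only allowed where the reference bin is empty")
        self.cgr = cgr

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.cgr)

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {
                "bin_lo_m": self.bin_lo,
                "bin_hi_m": self.bin_hi,
                "cgr": self.cgr,
                "n_reference_voxels": self.n_reference_voxels,
            }
        ).to_csv(path, index=False)


def occupancy_set(grid: VoxelGrid) -> OccupancySet:
    """Materialize the set of voxel indices with at least one point."""
    i, j, k = np.nonzero(grid.counts)
    idx = frozenset(zip(i.tolist(), j.tolist(), k.tolist()))
    return OccupancySet(idx, grid.origin, grid.voxel_size, grid.dims)


def merge_occupancy(sets: list[OccupancySet]) -> OccupancySet:
    """Union of occupancy sets (the all-merged reference V_All)."""
    if not sets:
        raise ValidationError("merge_occupancy requires at least one set")
    out = sets[0]
    for s in sets[1:]:
        out = out.union(s)
    return out


def coverage_gap_ratio(
    v_all: OccupancySet, v_c: OccupancySet, bin_height: float = 0.5
) -> CGRProfile:
    """CGR of dataset occupancy ``v_c`` against reference ``v_all`` per height bin.

    Voxels are assigned to bins by voxel-center height above the lattice z
    origin; with bin_height equal to the voxel size each bin is exactly one
    voxel layer. The set difference is exact: a reference voxel counts as a
    gap iff its index triplet is absent from ``v_c``.
    """
    if bin_height <= 0:
        raise ValidationError("bin_height must be > 0")
    if not v_all.same_lattice(v_c):
        raise LatticeMismatchError("occupancy sets must share one lattice")
    s = v_all.voxel_size
    nz = v_all.dims[2]
    n_bins = int(np.floor((nz - 0.5) * s / bin_height)) + 1
    n_ref = np.zeros(n_bins, dtype=np.int64)
    n_gap = np.zeros(n_bins, dtype=np.int64)
    vc = v_c.indices
    for (i, j, k) in v_all.indices:
        b = int(((k + 0.5) * s) // bin_height)
        n_ref[b] += 1
        if (i, j, k) not in vc:
            n_gap[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        cgr = np.where(n_ref > 0, n_gap / np.maximum(n_ref, 1), np.nan)
    lo = np.arange(n_bins) * bin_height
    return CGRProfile(bin_height, lo, lo + bin_height, cgr, n_ref)
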