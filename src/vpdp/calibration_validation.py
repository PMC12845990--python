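"""Calibration of the radiative proxy against an observed reflectance raster.

The empirical coefficients (alpha, beta) are fitted by maximizing the Pearson
correlation between the simulated coarse radiance map and an observed
satellite NIR reflectance raster (10 m pixels), over a deterministic
coarse-to-fine log-spaced grid. Because satellite geolocation is only accurate
to a few meters, each candidate is scored at its best horizontal shift of the
fine map within +/- ``max_shift`` meters (default 3 m, step = one fine cell);
ties break to the smallest displacement, then lexicographically.

Overfitting is monitored with repeated random subsampling: masked-in pixels
are split 70/30 into calibration and validation sets (stratified by observed
reflectance quartiles by default), parameters are fitted on the calibration
set, and the held-out correlation is reported over 20 seeded iterations.

Correlation is invariant to the absolute scale of the simulation (linear in I
and R) and to positive affine maps of the observed raster, so the fitted r
reflects spatial pattern agreement only.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .point_cloud_io import ValidationError
from .rt_simulator import ColumnRadianceModel, RTParams, _overlap_weights
from .voxelizer import VoxelGrid

__all__ = [
    "ObservedRaster",
    "CalibrationResult",
    "ValidationSummary",
    "SearchSpec",
    "DegenerateInputError",
    "pearson_r",
    "shift_search",
    "fit_alpha_beta",
    "subsample_validate",
    "read_observed_ascii",
    "write_observed_ascii",
]


class DegenerateInputError(ValueError):
    """Correlation undefined: too few pixels or zero variance."""


@dataclass
class ObservedRaster:
    """Observed coarse reflectance raster with a pixel validity mask.

    ``values[i, j]`` is dimensionless reflectance for the pixel whose x-cell
    index is i and y-cell index j on a grid of ``cell`` meters anchored at
    ``origin``. The mask encodes pixel screening (e.g. exclusion of
    non-target-species pixels); masked-out pixels never enter a correlation.
    """

    values: np.ndarray = field(repr=False)
    mask: np.ndarray | None = field(default=None, repr=False)
    origin: tuple[float, float] = (0.0, 0.0)
    cell: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("observed raster must be 2D")
        if self.cell <= 0:
            raise ValidationError("pixel size must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape must match values shape")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class CalibrationResult:
    """Fitted attenuation coefficients, adopted shift, and achieved r."""

    alpha: float
    beta: float
    shift: tuple[float, float]
    r: float
    n_pixels: int

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "alpha": self.alpha,
                    "beta": self.beta,
                    "shift_x_m": self.shift[0],
                    "shift_y_m": self.shift[1],
                    "pearson_r": self.r,
                    "n_pixels": self.n_pixels,
                },
                fh,
                indent=2,
            )


@dataclass
class ValidationSummary:
    """Per-iteration held-out correlations of the subsampling validation."""

    r_values: np.ndarray
    n_iter: int
    base_seed: int

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def sd_r(self) -> float:
        if self.n_iter < 2:
            return float("nan")
        return float(np.std(self.r_values, ddof=1))

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {"iteration": np.arange(self.n_iter), "r": self.r_values}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SearchSpec:
    """Deterministic coarse-to-fine grid search configuration.

    A ``n_coarse`` x ``n_coarse`` log-spaced grid over the (alpha, beta)
    bounds is scanned first, then ``refine_passes`` local ``n_refine`` x
    ``n_refine`` grids spanning one coarse spacing around the incumbent
    (clipped to bounds); the objective never worsens between passes. With
    ``shift_inside`` each candidate is scored at its own best shift; otherwise
    parameters are fitted at zero shift and the shift is adopted afterwards.
    """

    alpha_bounds: tuple[float, float] = (1e-4, 1.0)
    beta_bounds: tuple[float, float] = (1e-4, 1.0)
    n_coarse: int = 17
    n_refine: int = 9
    refine_passes: int = 1
    max_shift: float = 3.0
    shift_step: float = 0.5
    shift_inside: bool = True
    reflect_empty: bool = False
    incident: float = 1.0
    reflectance: float = 0.05


def pearson_r(
    simulated: np.ndarray,
    observed: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson product-moment correlation over masked-in, finite pairs.

    Raises :class:`DegenerateInputError` (never returns NaN) when fewer than
    3 pairs remain or either side has zero variance.
    """
    sim = np.asarray(simulated, dtype=np.float64).ravel()
    obs = np.asarray(observed, dtype=np.float64).ravel()
    if sim.shape != obs.shape:
        raise ValidationError("simulated and observed must have the same shape")
    valid = np.isfinite(sim) & np.isfinite(obs)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool).ravel()
    x, y = sim[valid], obs[valid]
    if x.size < 3:
        raise DegenerateInputError(f"need >= 3 paired pixels, have {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        raise DegenerateInputError("zero variance on one side of the correlation")
    return float((xc @ yc) / np.sqrt(vx * vy))


# ---------------------------------------------------------------------------
# Shift search
# ---------------------------------------------------------------------------


def _shift_offsets(max_shift: float, step: float) -> np.ndarray:
    if max_shift < 0:
        raise ValidationError("max_shift must be >= 0")
    if step <= 0:
        raise ValidationError("step must be > 0")
    n = int(round(max_shift / step))
    return np.arange(-n, n + 1) * step


class _ShiftObjective:
    """Precomputed aggregation weights for every candidate shift.

    Shifting the fine map by +d meters means each coarse pixel averages the
    fine cells over its window displaced by -d relative to the fine grid, so
    one 1D overlap-weight matrix per axis offset covers all shift pairs. The
    aggregation is an area-weighted mean, NaN where a window misses the fine
    extent entirely.
    """

    def __init__(
        self,
        observed: ObservedRaster,
        fine_shape: tuple[int, int],
        fine_cell: float,
        fine_origin: tuple[float, float],
        offsets: np.ndarray,
    ):
        ncx, ncy = observed.values.shape
        base = (
            observed.origin[0] - fine_origin[0],
            observed.origin[1] - fine_origin[1],
        )
        self.offsets = offsets
        self._wx = [
            _overlap_weights(fine_shape[0], fine_cell, ncx, observed.cell, base[0] - d)
            for d in offsets
        ]
        self._wy = [
            _overlap_weights(fine_shape[1], fine_cell, ncy, observed.cell, base[1] - d)
            for d in offsets
        ]
        self._wx_stack = np.vstack(self._wx)  # (n_off * ncx, nx)
        self._den = [
            [np.outer(wx.sum(axis=1), wy.sum(axis=1)) for wy in self._wy]
            for wx in self._wx
        ]
        self._ncx = ncx
        self.observed = observed
        # deterministic tie-break: smallest |shift|, then lexicographic
        pairs = [(dx, dy) for dx in offsets for dy in offsets]
        self._order = sorted(
            range(len(pairs)), key=lambda t: (np.hypot(*pairs[t]), pairs[t][0], pairs[t][1])
        )
        self._pairs = pairs

    def coarse_at(self, fine: np.ndarray, ix: int, iy: int) -> np.ndarray:
        num = self._wx[ix] @ fine @ self._wy[iy].T
        den = self._den[ix][iy]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)

    def best_shift(
        self, fine: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[float, float, float]:
        mask = self.observed.mask if mask is None else mask
        n_off = len(self.offsets)
        stacked = self._wx_stack @ fine  # all x-offsets at once
        best = None
        for t in self._order:
            dx, dy = self._pairs[t]
            ix, iy = t // n_off, t % n_off
            num = stacked[ix * self._ncx : (ix + 1) * self._ncx] @ self._wy[iy].T
            den = self._den[ix][iy]
            with np.errstate(invalid="ignore", divide="ignore"):
                coarse = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
            try:
                r = pearson_r(coarse, self.observed.values, mask)
            except DegenerateInputError:
                continue
            if best is None or r > best[2]:
                best = (float(dx), float(dy), r)
        if best is None:
            raise DegenerateInputError("correlation degenerate at every shift")
        return best


def shift_search(
    fine_map,
    observed: ObservedRaster,
    max_shift: float = 3.0,
    step: float = 0.5,
    mask: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Exhaustive horizontal shift search maximizing Pearson correlation.

    Evaluates every (dx, dy) on the grid {-max_shift, ..., +max_shift}^2 at
    the given step, shifting the fine radiance map before average aggregation
    to the observed lattice. Returns ``(dx, dy, r)`` of the maximum, with ties
    broken to the smallest displacement then lexicographically.
    """
    offsets = _shift_offsets(max_shift, step)
    obj = _ShiftObjective(
        observed, fine_map.fine.shape, fine_map.fine_cell, fine_map.origin, offsets
    )
    return obj.best_shift(fine_map.fine, mask)


# ---------------------------------------------------------------------------
# (alpha, beta) grid search
# ---------------------------------------------------------------------------


def _log_grid(bounds: tuple[float, float], n: int) -> np.ndarray:
    if not (0 < bounds[0] <= bounds[1]):
        raise ValidationError("bounds must be positive and ordered")
    if n == 1 or bounds[0] == bounds[1]:
        return np.array([bounds[0]])
    return np.logspace(np.log10(bounds[0]), np.log10(bounds[1]), n)


def fit_alpha_beta(
    grid: VoxelGrid,
    observed: ObservedRaster,
    search_spec: SearchSpec | None = None,
    mask: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit (alpha, beta) by maximizing shift-optimized Pearson correlation.

    Deterministic two-stage log-grid search; each candidate pair is scored by
    simulating column radiance, aggregating to the observed lattice at every
    candidate shift, and keeping the best correlation. The returned result
    carries the adopted shift and the pixel count used.
    """
    spec = search_spec or SearchSpec()
    if grid.total == 0:
        raise ValidationError("cannot calibrate against an all-empty voxel grid")
    model = ColumnRadianceModel(grid, reflect_empty=spec.reflect_empty)
    offsets = (
        _shift_offsets(spec.max_shift, spec.shift_step)
        if spec.shift_inside
        else np.array([0.0])
    )
    obj = _ShiftObjective(
        observed, grid.dims[:2], grid.voxel_size, grid.origin[:2], offsets
    )
    mask = observed.mask if mask is None else mask

    def score(alpha: float, beta: float) -> tuple[float, float, float]:
        fine = model.evaluate(
            RTParams(alpha, beta, incident=spec.incident, reflectance=spec.reflectance)
        )
        return obj.best_shift(fine, mask)

    best: tuple[float, float, tuple[float, float, float]] | None = None
    alphas = _log_grid(spec.alpha_bounds, spec.n_coarse)
    betas = _log_grid(spec.beta_bounds, spec.n_coarse)
    n_scored = 0
    for a in alphas:
        for b in betas:
            try:
                res = score(a, b)
            except DegenerateInputError:
                continue
            n_scored += 1
            if best is None or res[2] > best[2][2]:
                best = (a, b, res)
    if best is None:
        raise DegenerateInputError("objective undefined everywhere on the search grid")

    spacing_a = (
        np.log10(alphas[1] / alphas[0]) if len(alphas) > 1 else 0.0
    )
    spacing_b = np.log10(betas[1] / betas[0]) if len(betas) > 1 else 0.0
    for _ in range(spec.refine_passes):
        la, lb = np.log10(best[0]), np.log10(best[1])
        ra = np.clip(
            np.linspace(la - spacing_a, la + spacing_a, spec.n_refine),
            np.log10(spec.alpha_bounds[0]),
            np.log10(spec.alpha_bounds[1]),
        )
        rb = np.clip(
            np.linspace(lb - spacing_b, lb + spacing_b, spec.n_refine),
            np.log10(spec.beta_bounds[0]),
            np.log10(spec.beta_bounds[1]),
        )
        for a in 10.0 ** ra:
            for b in 10.0 ** rb:
                try:
                    res = score(a, b)
                except DegenerateInputError:
                    continue
                if res[2] > best[2][2]:
                    best = (a, b, res)
        spacing_a /= max(spec.n_refine - 1, 1) / 2.0
        spacing_b /= max(spec.n_refine - 1, 1) / 2.0

    alpha, beta, (dx, dy, r) = best
    if not spec.shift_inside and spec.max_shift > 0:
        # alternative nesting: adopt the shift only after fitting parameters
        full = _ShiftObjective(
            observed,
            grid.dims[:2],
            grid.voxel_size,
            grid.origin[:2],
            _shift_offsets(spec.max_shift, spec.shift_step),
        )
        fine = model.evaluate(
            RTParams(alpha, beta, incident=spec.incident, reflectance=spec.reflectance)
        )
        dx, dy, r = full.best_shift(fine, mask)

    # pixel count at the adopted shift
    ix = int(np.argmin(np.abs(obj.offsets - dx))) if spec.shift_inside else 0
    iy = int(np.argmin(np.abs(obj.offsets - dy))) if spec.shift_inside else 0
    fine = model.evaluate(
        RTParams(alpha, beta, incident=spec.incident, reflectance=spec.reflectance)
    )
    coarse = obj.coarse_at(fine, ix, iy)
    n_pixels = int((np.isfinite(coarse) & mask & np.isfinite(observed.values)).sum())
    return CalibrationResult(float(alpha), float(beta), (dx, dy), float(r), n_pixels)


# ---------------------------------------------------------------------------
# Subsampling validation
# ---------------------------------------------------------------------------


def _stratified_split(
    values: np.ndarray,
    pixel_idx: np.ndarray,
    calib_fraction: float,
    rng: np.random.Generator,
    stratify: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if stratify:
        qs = np.quantile(values, [0.25, 0.5, 0.75])
        strata = np.digitize(values, qs)
    else:
        strata = np.zeros(values.size, dtype=int)
    calib, valid = [], []
    for s in np.unique(strata):
        members = pixel_idx[strata == s]
        perm = rng.permutation(members)
        n_cal = int(round(calib_fraction * len(members)))
        calib.append(perm[:n_cal])
        valid.append(perm[n_cal:])
    return np.concatenate(calib), np.concatenate(valid)


def subsample_validate(
    grid: VoxelGrid,
    observed: ObservedRaster,
    calib_fraction: float = 0.7,
    n_iter: int = 20,
    base_seed: int = 0,
    stratify: bool = True,
    search_spec: SearchSpec | None = None,
) -> ValidationSummary:
    """Repeated 70/30 split validation of the (alpha, beta) calibration.

    Each iteration splits the masked-in pixels into calibration and held-out
    sets (stratified by observed-reflectance quartiles by default), fits
    (alpha, beta) on the calibration pixels, and evaluates the Pearson
    correlation on the held-out pixels at the fitted parameters and adopted
    shift. Fully reproducible from ``base_seed``.
    """
    if not (0 < calib_fraction < 1):
        raise ValidationError("calib_fraction must be in (0, 1)")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    spec = search_spec or SearchSpec()
    flat_mask = observed.mask.ravel()
    pixel_idx = np.flatnonzero(flat_mask & np.isfinite(observed.values.ravel()))
    n_cal = int(round(calib_fraction * pixel_idx.size))
    if min(n_cal, pixel_idx.size - n_cal) < 3:
        raise DegenerateInputError(
            f"{pixel_idx.size} maskable pixels cannot be split with >= 3 per side"
        )
    model = ColumnRadianceModel(grid, reflect_empty=spec.reflect_empty)
    offsets = (
        _shift_offsets(spec.max_shift, spec.shift_step)
        if spec.shift_inside
        else np.array([0.0])
    )
    obj = _ShiftObjective(
        observed, grid.dims[:2], grid.voxel_size, grid.origin[:2], offsets
    )
    values = observed.values.ravel()[pixel_idx]
    rs = np.empty(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng([base_seed, it])
        cal_idx, val_idx = _stratified_split(
            values, pixel_idx, calib_fraction, rng, stratify
        )
        cal_mask = np.zeros(flat_mask.size, dtype=bool)
        cal_mask[cal_idx] = True
        val_mask = np.zeros(flat_mask.size, dtype=bool)
        val_mask[val_idx] = True
        fit = fit_alpha_beta(
            grid, observed, search_spec=spec, mask=cal_mask.reshape(observed.mask.shape)
        )
        fine = model.evaluate(
            RTParams(fit.alpha, fit.beta, incident=spec.incident, reflectance=spec.reflectance)
        )
        ix = int(np.argmin(np.abs(obj.offsets - fit.shift[0])))
        iy = int(np.argmin(np.abs(obj.offsets - fit.shift[1])))
        coarse = obj.coarse_at(fine, ix, iy)
        rs[it] = pearson_r(coarse, observed.values, val_mask.reshape(observed.mask.shape))
    return ValidationSummary(rs, n_iter, base_seed)


# ---------------------------------------------------------------------------
# Raster I/O (plain text)
# ---------------------------------------------------------------------------


def write_observed_ascii(raster: ObservedRaster, path: str | os.PathLike) -> None:
    """Write a coarse raster as a commented ASCII grid (text interchange)."""
    with open(path, "w") as fh:
        fh.write(
            f"# origin_x {raster.origin[0]} origin_y {raster.origin[1]} "
            f"cell {raster.cell} nx {raster.values.shape[0]} ny {raster.values.shape[1]}\n"
        )
        np.savetxt(fh, raster.values, fmt="%.8g")
        fh.write("# mask\n")
        np.savetxt(fh, raster.mask.astype(int), fmt="%d")


def read_observed_ascii(path: str | os.PathLike) -> ObservedRaster:
    with open(path) as fh:
        header = fh.readline().split()
    x0, y0 = float(header[2]), float(header[4])
    cell = float(header[6])
    nx = int(header[8])
    data = np.loadtxt(path, comments="#", ndmin=2)
    values = data[:nx]
    mask = data[nx:].astype(bool) if data.shape[0] > nx else None
    return ObservedRaster(values, mask, (x0, y0), cell)
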