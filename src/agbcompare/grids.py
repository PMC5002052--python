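"""Raster data model and grid operations.

The central currency is :class:`BiomassRaster`: a single-band continuous
raster of aboveground biomass density (Mg/ha) with an explicit validity mask
(the map's forest mask intersected with data availability).  Grids are plain
axis-aligned square-cell grids in one planar coordinate system; rows increase
southward, columns eastward, cells are half-open squares
``[x, x+cell) x (y-cell, y]`` and cell (0, 0) touches the grid origin at its
northwest corner.

Alignment of maps published at different grain sizes follows the two-step
recipe used throughout map intercomparison work: block-mean aggregation by an
integer factor, then nearest-neighbour resampling onto the exact target grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "BiomassRaster",
    "MaskRaster",
    "CategoricalRaster",
    "GridError",
    "ExtentError",
    "aggregate_mean",
    "aggregate_mode",
    "resample_nearest",
    "resample_nearest_categorical",
    "common_mask",
    "difference",
    "total_biomass",
    "choose_aggregation_factor",
    "align_to",
]

# Cell areas convert through (cell_size m / 100)^2 = hectares per cell.
M_PER_HM = 100.0


class GridError(ValueError):
    """Two rasters that must share a grid do not."""


class ExtentError(ValueError):
    """Source and target grids do not overlap."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned square-cell grid.

    Parameters
    ----------
    origin_x, origin_y : float
        Map coordinates (m) of the outer (northwest) corner of cell (0, 0).
    cell_size : float
        Cell edge length in metres, > 0.
    n_rows, n_cols : int
        Grid dimensions, >= 1.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_size / M_PER_HM) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates: (x of each column, y of each row)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def is_factor_related(self, other: "GridSpec") -> bool:
        """True when origins coincide and cell sizes differ by an integer factor."""
        if not (np.isclose(self.origin_x, other.origin_x)
                and np.isclose(self.origin_y, other.origin_y)):
            return False
        big, small = max(self.cell_size, other.cell_size), min(self.cell_size, other.cell_size)
        ratio = big / small
        return bool(np.isclose(ratio, round(ratio)))


@dataclass
class BiomassRaster:
    """Continuous biomass-density raster (Mg/ha) with validity mask.

    ``is_difference`` flags cellwise difference products, for which the
    nonnegativity invariant is waived.
    """

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray
    label: str = ""
    nominal_year: Optional[int] = None
    is_difference: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask shape must match values")
        v = self.values[self.valid]
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("non-finite values at valid cells")
        if not self.is_difference and v.size and np.any(v < 0):
            raise ValueError("negative biomass density at valid cells")

    def mask(self) -> "MaskRaster":
        return MaskRaster(self.grid, self.valid.copy())

    def copy(self) -> "BiomassRaster":
        return replace(self, values=self.values.copy(), valid=self.valid.copy())


@dataclass
class MaskRaster:
    """Binary validity/footprint raster."""

    grid: GridSpec
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.grid.shape:
            raise ValueError("mask shape must match grid")

    @property
    def area_ha(self) -> float:
        return float(self.valid.sum()) * self.grid.cell_area_ha


@dataclass
class CategoricalRaster:
    """Integer-coded partition (mapping regions, forest type, age/elevation/
    slope classes).  Code 0 means unclassified."""

    grid: GridSpec
    codes: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape must match grid")
        present = set(np.unique(self.codes).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            # Auto-label rather than reject: legends are convenience metadata.
            for c in sorted(missing):
                self.legend[int(c)] = f"class_{c}"

    def region_codes(self) -> list[int]:
        u = np.unique(self.codes)
        return [int(c) for c in u if c != 0]


def _require_same_grid(*grids: GridSpec) -> None:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridError(f"grid mismatch: {g} != {first}")


def aggregate_mean(r: BiomassRaster, factor: int,
                   min_valid_fraction: float = 0.5) -> BiomassRaster:
    """Block-mean aggregation by an integer factor.

    Each output cell is the mean of valid input cells in its factor x factor
    window; the output cell is valid iff the fraction of valid input cells in
    the (full-size) window is >= ``min_valid_fraction``.  Edge windows use
    only cells that exist but are still judged against factor^2.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor > min(r.grid.n_rows, r.grid.n_cols):
        raise ValueError("factor exceeds raster dimensions")
    if not 0.0 <= min_valid_fraction <= 1.0:
        raise ValueError("min_valid_fraction must be in [0, 1]")
    if factor == 1:
        return r.copy()

    nr, nc = r.grid.shape
    out_rows = -(-nr // factor)
    out_cols = -(-nc // factor)
    pr, pc = out_rows * factor - nr, out_cols * factor - nc
    vals = np.where(r.valid, r.values, 0.0)
    vals = np.pad(vals, ((0, pr), (0, pc)))
    ok = np.pad(r.valid.astype(float), ((0, pr), (0, pc)))
    vsum = vals.reshape(out_rows, factor, out_cols, factor).sum(axis=(1, 3))
    vcnt = ok.reshape(out_rows, factor, out_cols, factor).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean = np.where(vcnt > 0, vsum / np.maximum(vcnt, 1), 0.0)
    frac = vcnt / float(factor * factor)
    # A zero threshold still requires at least one valid contributing cell.
    valid = (frac >= min_valid_fraction) & (vcnt > 0)
    out_grid = GridSpec(r.grid.origin_x, r.grid.origin_y,
                        r.grid.cell_size * factor, out_rows, out_cols)
    return BiomassRaster(out_grid, mean, valid, label=r.label,
                         nominal_year=r.nominal_year, is_difference=r.is_difference)


def aggregate_mode(c: CategoricalRaster, factor: int) -> CategoricalRaster:
    """Degrade a categorical raster by modal code per window (ties -> smallest
    code); windows with no classified cell get code 0."""
    if not float(factor).is_integer() or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return CategoricalRaster(c.grid, c.codes.copy(), dict(c.legend))
    nr, nc = c.grid.shape
    out_rows = -(-nr // factor)
    out_cols = -(-nc // factor)
    pr, pc = out_rows * factor - nr, out_cols * factor - nc
    codes = np.pad(c.codes, ((0, pr), (0, pc)))
    windows = codes.reshape(out_rows, factor, out_cols, factor)
    windows = windows.transpose(0, 2, 1, 3).reshape(out_rows, out_cols, -1)
    out = np.zeros((out_rows, out_cols), dtype=np.int64)
    for i in range(out_rows):
        for j in range(out_cols):
            w = windows[i, j]
            w = w[w != 0]
            if w.size:
                vals, counts = np.unique(w, return_counts=True)
                out[i, j] = vals[np.argmax(counts)]  # unique() sorts: ties -> smallest
    out_grid = GridSpec(c.grid.origin_x, c.grid.origin_y,
                        c.grid.cell_size * factor, out_rows, out_cols)
    return CategoricalRaster(out_grid, out, dict(c.legend))


def _nearest_indices(source: GridSpec, target: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Row/col index arrays mapping each target cell to its nearest source
    cell center (ties toward smaller index)."""
    txs, tys = target.cell_centers()
    # Continuous source index of each target center; nearest integer cell.
    fi = (source.origin_y - tys) / source.cell_size - 0.5
    fj = (txs - source.origin_x) / source.cell_size - 0.5
    # round-half-down implements the smaller-(row,col) tie break
    ri = np.ceil(fi - 0.5).astype(int)
    cj = np.ceil(fj - 0.5).astype(int)
    if ri.max() < 0 or cj.max() < 0 or ri.min() >= source.n_rows or cj.min() >= source.n_cols:
        raise ExtentError("target extent is disjoint from source")
    ri = np.clip(ri, 0, source.n_rows - 1)
    cj = np.clip(cj, 0, source.n_cols - 1)
    return ri, cj


def resample_nearest(r: BiomassRaster, target: GridSpec) -> BiomassRaster:
    """Nearest-neighbour resampling onto ``target``; value and validity are
    taken from the source cell whose center is nearest each target center."""
    if target == r.grid:
        return r.copy()
    ri, cj = _nearest_indices(r.grid, target)
    vals = r.values[np.ix_(ri, cj)]
    valid = r.valid[np.ix_(ri, cj)]
    return BiomassRaster(target, vals, valid, label=r.label,
                         nominal_year=r.nominal_year, is_difference=r.is_difference)


def resample_nearest_categorical(c: CategoricalRaster, target: GridSpec) -> CategoricalRaster:
    if target == c.grid:
        return CategoricalRaster(c.grid, c.codes.copy(), dict(c.legend))
    ri, cj = _nearest_indices(c.grid, target)
    return CategoricalRaster(target, c.codes[np.ix_(ri, cj)], dict(c.legend))


def common_mask(masks: Sequence[MaskRaster]) -> MaskRaster:
    """Cellwise AND of masks on one grid — the footprint common to all maps."""
    if not masks:
        raise ValueError("need at least one mask")
    _require_same_grid(*[m.grid for m in masks])
    out = np.ones(masks[0].grid.shape, dtype=bool)
    for m in masks:
        out &= m.valid
    return MaskRaster(masks[0].grid, out)


def difference(a: BiomassRaster, b: BiomassRaster) -> BiomassRaster:
    """Cellwise a − b; valid where both are valid.  Output is flagged as a
    difference product (may be negative)."""
    _require_same_grid(a.grid, b.grid)
    valid = a.valid & b.valid
    vals = np.where(valid, a.values - b.values, 0.0)
    label = f"{a.label}-{b.label}" if a.label or b.label else ""
    return BiomassRaster(a.grid, vals, valid, label=label, is_difference=True)


def total_biomass(r: BiomassRaster,
                  within: Optional[MaskRaster] = None) -> tuple[float, float]:
    """Total mass (Mg) and footprint area (ha) over valid (and ``within``)
    cells: sum of density x cell area."""
    if within is not None:
        _require_same_grid(r.grid, within.grid)
        sel = r.valid & within.valid
    else:
        sel = r.valid
    area = r.grid.cell_area_ha
    total = float(r.values[sel].sum()) * area
    return total, float(sel.sum()) * area


def choose_aggregation_factor(source_cell: float, target_cell: float) -> int:
    """Nearest-integer aggregation factor for the mean-then-nearest recipe."""
    if source_cell <= 0 or target_cell <= 0:
        raise ValueError("cell sizes must be positive")
    return max(1, round(target_cell / source_cell))


def align_to(r: BiomassRaster, target: GridSpec,
             min_valid_fraction: float = 0.5) -> BiomassRaster:
    """Align a map to a target grid: block-mean by the rounded factor, then
    nearest-neighbour snap onto the exact target grid."""
    factor = choose_aggregation_factor(r.grid.cell_size, target.cell_size)
    agg = aggregate_mean(r, factor, min_valid_fraction) if factor > 1 else r
    return resample_nearest(agg, target)
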