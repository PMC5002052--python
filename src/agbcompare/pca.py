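"""Simultaneous comparison of co-registered maps by R-mode PCA.

In R-mode the maps are the statistical variables and the shared valid pixels
are the observations.  When the maps broadly agree, the first principal
component captures the shared biomass pattern and absorbs most of the
variance; the second component, orthogonal to the first, then exposes the
dominant pattern of *disagreement* — a map whose score correlation with PC2
stands out is the map that departs from the consensus.  Running the same
decomposition per mapping region reveals regional outliers that a
whole-extent analysis averages away.

The decomposition is an eigen-analysis of the correlation matrix by default
(maps enter on equal footing regardless of their variance); covariance mode
is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import BiomassRaster, CategoricalRaster, GridError, MaskRaster

__all__ = [
    "PCAResult",
    "InsufficientDataError",
    "DegenerateVariableError",
    "stack_pixels",
    "rmode_pca",
    "pca_by_region",
    "scores_to_rasters",
]

MIN_SHARED_PIXELS = 10
DEFAULT_MIN_REGION_PIXELS = 30


class InsufficientDataError(ValueError):
    """Too few shared valid pixels for a meaningful decomposition."""


class DegenerateVariableError(ValueError):
    """A map is constant over the shared pixels; correlation-mode PCA undefined."""


@dataclass
class PCAResult:
    """Eigen-decomposition of a pixel-by-map stack.

    ``map_correlations[i, k]`` is the Pearson correlation between raw map i
    and the score series of component k.
    """

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    loadings: np.ndarray            # (n_maps, n_components)
    map_correlations: np.ndarray    # (n_maps, n_components)
    scores: np.ndarray              # (n_pixels, n_components)
    n_pixels: int
    map_labels: list[str] = field(default_factory=list)

    def outlier_map(self, component: int = 1) -> int:
        """Index of the map with the largest |correlation| with the given
        component (default PC2, the dominant disagreement axis)."""
        return int(np.argmax(np.abs(self.map_correlations[:, component])))


def stack_pixels(
    maps: Sequence[BiomassRaster],
    mask: MaskRaster,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the pixel-by-map table over pixels valid in the mask AND every
    map.  Returns (table, pixel_index) where pixel_index is (n, 2) (row, col).
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    for m in maps:
        if m.grid != mask.grid:
            raise GridError("map grid differs from mask grid")
    shared = mask.valid.copy()
    for m in maps:
        shared &= m.valid
    idx = np.argwhere(shared)
    if len(idx) < MIN_SHARED_PIXELS:
        raise InsufficientDataError(
            f"only {len(idx)} shared valid pixels (need >= {MIN_SHARED_PIXELS})")
    table = np.column_stack([m.values[shared] for m in maps])
    return table, idx


def rmode_pca(table: np.ndarray, standardize: bool = True,
              map_labels: Sequence[str] | None = None) -> PCAResult:
    """Eigen-decomposition of the correlation (default) or covariance matrix
    of the pixel-by-map table.

    Eigenvector signs are fixed so each component's largest-magnitude loading
    is positive (eigenvector sign is otherwise arbitrary).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2-D with >= 2 columns")
    n, p = table.shape
    if n <= p:
        raise InsufficientDataError("need more pixels than maps")
    sd = table.std(axis=0, ddof=1)
    if standardize and np.any(sd == 0):
        raise DegenerateVariableError("constant map column under standardization")
    centered = table - table.mean(axis=0)
    data = centered / sd if standardize else centered
    c = (data.T @ data) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(c)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|loading| positive per component
    for k in range(p):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = data @ eigvecs
    corr = np.zeros((p, p))
    for k in range(p):
        s = scores[:, k]
        if s.std() == 0:
            corr[:, k] = 0.0
        else:
            for i in range(p):
                if sd[i] == 0:
                    corr[i, k] = 0.0
                else:
                    corr[i, k] = np.corrcoef(table[:, i], s)[0, 1]
    total = eigvals.sum()
    return PCAResult(
        eigenvalues=eigvals,
        variance_fraction=eigvals / total if total > 0 else eigvals,
        loadings=eigvecs,
        map_correlations=corr,
        scores=scores,
        n_pixels=n,
        map_labels=list(map_labels) if map_labels else [f"map_{i}" for i in range(p)],
    )


def pca_by_region(
    maps: Sequence[BiomassRaster],
    mask: MaskRaster,
    partition: CategoricalRaster,
    min_pixels: int = DEFAULT_MIN_REGION_PIXELS,
    standardize: bool = True,
) -> tuple[dict[int, PCAResult], list[int]]:
    """Independent R-mode PCA per region of the partition.

    Regions with fewer than ``min_pixels`` shared valid pixels (or a
    degenerate map column) are reported in the skipped list.
    """
    if partition.grid != mask.grid:
        raise GridError("partition grid differs from mask grid")
    shared = mask.valid.copy()
    for m in maps:
        if m.grid != mask.grid:
            raise GridError("map grid differs from mask grid")
        shared &= m.valid
    labels = [m.label or f"map_{i}" for i, m in enumerate(maps)]
    results: dict[int, PCAResult] = {}
    skipped: list[int] = []
    for code in partition.region_codes():
        sel = shared & (partition.codes == code)
        if sel.sum() < max(min_pixels, MIN_SHARED_PIXELS):
            skipped.append(code)
            continue
        table = np.column_stack([m.values[sel] for m in maps])
        try:
            results[code] = rmode_pca(table, standardize=standardize, map_labels=labels)
        except (DegenerateVariableError, InsufficientDataError):
            skipped.append(code)
    return results, skipped


def scores_to_rasters(result: PCAResult, pixel_index: np.ndarray,
                      grid, n_components: int | None = None) -> list[BiomassRaster]:
    """Spatialise score columns back onto the grid as difference-flagged
    rasters (scores may be negative), valid only on the stacked pixels."""
    p = result.scores.shape[1] if n_components is None else n_components
    out = []
    for k in range(p):
        vals = np.zeros(grid.shape)
        valid = np.zeros(grid.shape, dtype=bool)
        vals[pixel_index[:, 0], pixel_index[:, 1]] = result.scores[:, k]
        valid[pixel_index[:, 0], pixel_index[:, 1]] = True
        out.append(BiomassRaster(grid, vals, valid, label=f"PC{k + 1}",
                                 is_difference=True))
    return out
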