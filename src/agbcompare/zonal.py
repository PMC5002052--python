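"""Region-partition summaries and the multi-resolution agreement ladder.

Per-region distributional summaries (mean, p10/p50/p90, totals) characterise
each map inside ecologically coherent mapping regions; cross-map scatter of
those statistics exposes systematic range compression (saturation,
shrinkage, coarse resolution).  The multiscale ladder aggregates map pairs
through a sequence of grain sizes and recomputes Willmott's d per region at
each: agreement that improves with aggregation points to fine-scale
(registration/noise) disagreement, while agreement that stays flat points to
disagreement structured at the region scale or beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import DegenerateFitError, ols_fit, willmott_d
from .grids import (BiomassRaster, CategoricalRaster, GridError,
                    aggregate_mean, aggregate_mode, total_biomass, MaskRaster)

__all__ = [
    "RegionSummary",
    "MultiscaleAgreement",
    "percentile",
    "region_summaries",
    "summaries_frame",
    "percentile_pairs",
    "multiscale_agreement",
]

STATISTICS = ("mean", "p10", "p50", "p90")
DEFAULT_MIN_PAIR_PIXELS = 30


@dataclass
class RegionSummary:
    region: int
    n_valid: int
    mean: Optional[float]
    p10: Optional[float]
    p50: Optional[float]
    p90: Optional[float]
    total: float
    area_ha: float

    @property
    def defined(self) -> bool:
        return self.n_valid > 0

    @property
    def interdecile_range(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.p90 - self.p10


@dataclass
class MultiscaleAgreement:
    """Willmott d per (region, aggregation factor) for one ordered map pair,
    with per-factor median and range (max − min) across regions."""

    pair: tuple[str, str]
    per_region: pd.DataFrame          # columns: factor, region, n, d
    summary: pd.DataFrame             # columns: factor, median_d, range_d, n_regions
    skipped: list[tuple[int, int]] = field(default_factory=list)  # (factor, region)


def percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation percentile (p50 of [1,2,3,4] is 2.5)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    return float(np.percentile(values, q, method="linear"))


def region_summaries(m: BiomassRaster,
                     partition: CategoricalRaster) -> list[RegionSummary]:
    """One summary per region code over the map's valid cells; regions with
    zero valid cells are emitted with undefined statistics."""
    if partition.grid != m.grid:
        raise GridError("partition grid differs from map grid")
    area = m.grid.cell_area_ha
    out = []
    for code in partition.region_codes():
        sel = m.valid & (partition.codes == code)
        n = int(sel.sum())
        if n == 0:
            out.append(RegionSummary(code, 0, None, None, None, None, 0.0, 0.0))
            continue
        v = m.values[sel]
        out.append(RegionSummary(
            region=code, n_valid=n,
            mean=float(v.mean()),
            p10=percentile(v, 10), p50=percentile(v, 50), p90=percentile(v, 90),
            total=float(v.sum()) * area, area_ha=n * area))
    return out


def summaries_frame(maps: Sequence[BiomassRaster],
                    partition: CategoricalRaster) -> pd.DataFrame:
    """Long-format per-map, per-region statistics table."""
    rows = []
    for i, m in enumerate(maps):
        label = m.label or f"map_{i}"
        for s in region_summaries(m, partition):
            for stat in STATISTICS:
                rows.append({"map": label, "region": s.region,
                             "stat": stat, "value": getattr(s, stat),
                             "n_valid": s.n_valid})
    return pd.DataFrame(rows)


def percentile_pairs(maps: Sequence[BiomassRaster],
                     partition: CategoricalRaster) -> pd.DataFrame:
    """Per-region paired statistics for every unordered map pair.

    Returns a long table with one row per (pair, statistic): the per-region
    scatter (x = first map, y = second), the OLS fit, and the count of
    regions dropped for an undefined statistic.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    labels = [m.label or f"map_{i}" for i, m in enumerate(maps)]
    per_map = {lab: {s.region: s for s in region_summaries(m, partition)}
               for lab, m in zip(labels, maps)}
    rows = []
    for (la, lb) in combinations(labels, 2):
        for stat in STATISTICS:
            xs, ys, regions, dropped = [], [], [], 0
            for code in per_map[la]:
                sa, sb = per_map[la][code], per_map[lb].get(code)
                if sb is None or not sa.defined or not sb.defined:
                    dropped += 1
                    continue
                xs.append(getattr(sa, stat))
                ys.append(getattr(sb, stat))
                regions.append(code)
            try:
                slope, intercept, r2 = ols_fit(xs, ys) if len(xs) >= 2 else (None, None, None)
            except DegenerateFitError:
                slope = intercept = r2 = None
            rows.append({"map_x": la, "map_y": lb, "stat": stat,
                         "n_regions": len(xs), "n_dropped": dropped,
                         "slope": slope, "intercept": intercept, "r2": r2,
                         "x": xs, "y": ys, "regions": regions})
    return pd.DataFrame(rows)


def _per_region_d(a: BiomassRaster, b: BiomassRaster,
                  partition: CategoricalRaster,
                  min_pixels: int) -> tuple[list[dict], list[int]]:
    shared = a.valid & b.valid
    rows, skipped = [], []
    for code in partition.region_codes():
        sel = shared & (partition.codes == code)
        n = int(sel.sum())
        if n < min_pixels:
            skipped.append(code)
            continue
        rows.append({"region": code, "n": n,
                     "d": willmott_d(a.values[sel], b.values[sel])})
    return rows, skipped


def multiscale_agreement(
    a: BiomassRaster,
    b: BiomassRaster,
    partition: CategoricalRaster,
    factors: Sequence[int] = (1, 2, 3, 4),
    min_pixels: int = DEFAULT_MIN_PAIR_PIXELS,
    min_valid_fraction: float = 0.5,
) -> MultiscaleAgreement:
    """Willmott d of (a, b) per region across an aggregation ladder.

    ``a`` occupies the truth slot X; since no map is truth, callers should
    also run the reversed ordering.  At each factor both maps are block-mean
    aggregated, the partition degraded by modal code, and d computed per
    region on the jointly valid pixel pairs.
    """
    if a.grid != b.grid or partition.grid != a.grid:
        raise GridError("maps and partition must share one grid")
    for f in factors:
        if not float(f).is_integer() or f < 1:
            raise ValueError(f"factors must be positive integers, got {f}")
        if f > min(a.grid.n_rows, a.grid.n_cols):
            raise ValueError(f"factor {f} exceeds raster dimensions")
    per_rows, summary_rows, skipped = [], [], []
    for f in sorted(set(int(f) for f in factors)):
        if f == 1:
            aa, bb, pp = a, b, partition
        else:
            aa = aggregate_mean(a, f, min_valid_fraction)
            bb = aggregate_mean(b, f, min_valid_fraction)
            pp = aggregate_mode(partition, f)
        # require pixels per region to scale down with aggregation
        eff_min = max(2, min_pixels // (f * f))
        rows, skip = _per_region_d(aa, bb, pp, eff_min)
        for r in rows:
            r["factor"] = f
        per_rows.extend(rows)
        skipped.extend((f, code) for code in skip)
        ds = [r["d"] for r in rows]
        summary_rows.append({
            "factor": f,
            "median_d": float(np.median(ds)) if ds else np.nan,
            "range_d": float(max(ds) - min(ds)) if ds else np.nan,
            "n_regions": len(ds)})
    pair = (a.label or "a", b.label or "b")
    return MultiscaleAgreement(
        pair=pair,
        per_region=pd.DataFrame(per_rows,
                                columns=["factor", "region", "n", "d"]),
        summary=pd.DataFrame(summary_rows),
        skipped=skipped)
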