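"""Pairwise agreement statistics.

Willmott's index of agreement (Willmott 1981) compares a series Y against a
reference X::

    d = 1 - sum_i (X_i - Y_i)^2 / sum_i (|X_i - Xbar| + |Y_i - Xbar|)^2

with Xbar the mean of the reference.  d is bounded in [0, 1]; 1 means perfect
agreement.  The denominator is the "potential error" — the largest squared
error the pair could exhibit given their deviations from the reference mean —
so d does not over-penalise disagreement the way unbounded metrics (MSE,
RMSE) do.  X is always the truth slot; for map-vs-map comparisons where no
map is the truth, both orderings should be computed.

The module also provides ordinary-least-squares comparison diagnostics and
the per-unit aggregation pipeline comparing map totals against a reference
table of unit totals (emulating plot-based state inventory estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import BiomassRaster, CategoricalRaster, GridError, MaskRaster, total_biomass

__all__ = [
    "AgreementResult",
    "ReferenceTable",
    "DegenerateFitError",
    "willmott_d",
    "ols_fit",
    "compare_to_reference",
]


class DegenerateFitError(ValueError):
    """OLS requested on a constant predictor."""


@dataclass
class AgreementResult:
    """One map-vs-reference (or map-vs-map) comparison.

    mean_bias is mean(Y − X) in the input units.
    """

    d: float
    n: int
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r2: Optional[float] = None
    mean_bias: float = 0.0
    label: str = ""


@dataclass
class ReferenceTable:
    """Per-unit reference biomass totals, keyed by partition code."""

    totals: dict[int, float]
    units: str = "Mg"
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.totals) != len(set(self.totals)):
            raise ValueError("duplicate unit ids")
        for k, v in self.totals.items():
            if v < 0:
                raise ValueError(f"negative reference total for unit {k}")

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path)
        units = str(df["units"].iloc[0]) if "units" in df else "Mg"
        names = ({int(r.unit_code): str(r.unit_name) for r in df.itertuples()}
                 if "unit_name" in df else {})
        return cls({int(r.unit_code): float(r.total_biomass) for r in df.itertuples()},
                   units=units, names=names)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "unit_code": list(self.totals),
            "unit_name": [self.names.get(k, "") for k in self.totals],
            "total_biomass": list(self.totals.values()),
            "units": self.units,
        }).to_csv(path, index=False)


def willmott_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Willmott's index of agreement of y against reference x.

    Degenerate convention: when the potential-error denominator is zero (both
    series constant and equal to the reference mean), d = 1 if the numerator
    is also zero, else 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    xbar = x.mean()
    sse = float(np.sum((x - y) ** 2))
    pe = float(np.sum((np.abs(x - xbar) + np.abs(y - xbar)) ** 2))
    if pe == 0.0:
        return 1.0 if sse == 0.0 else 0.0
    # sse <= pe holds termwise, so clamp only guards float rounding
    return min(1.0, max(0.0, 1.0 - sse / pe))


def ols_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS of y on x; returns (slope, intercept, r2) with r2 the squared
    Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def compare_to_reference(
    m: BiomassRaster,
    partition: CategoricalRaster,
    ref: ReferenceTable,
) -> tuple[AgreementResult, pd.DataFrame]:
    """Aggregate a map to per-unit totals over its own validity mask and
    compare against reference unit totals (reference in the truth slot).

    Returns the agreement result and a per-unit table with columns
    unit_code, reference, map_total, included; units present in the partition
    but absent from the reference (and vice versa) are excluded from the fit
    and flagged.  The national sum over included units is stored in the
    table's ``attrs['national_total']``.
    """
    if partition.grid != m.grid:
        raise GridError("partition grid differs from map grid")
    rows = []
    for code in partition.region_codes():
        sel = MaskRaster(m.grid, partition.codes == code)
        tot, _ = total_biomass(m, within=sel)
        rows.append({"unit_code": code,
                     "reference": ref.totals.get(code, np.nan),
                     "map_total": tot,
                     "included": code in ref.totals})
    table = pd.DataFrame(rows)
    used = table[table["included"]]
    if len(used) < 2:
        raise ValueError("fewer than 2 units shared between partition and reference")
    x = used["reference"].to_numpy()
    y = used["map_total"].to_numpy()
    d = willmott_d(x, y)
    try:
        slope, intercept, r2 = ols_fit(x, y)
    except DegenerateFitError:
        slope = intercept = r2 = None
    result = AgreementResult(d=d, n=len(used), slope=slope, intercept=intercept,
                             r2=r2, mean_bias=float(np.mean(y - x)), label=m.label)
    table.attrs["national_total"] = float(y.sum())
    table.attrs["skipped_units"] = [int(c) for c in table.loc[~table["included"], "unit_code"]]
    return result, table
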