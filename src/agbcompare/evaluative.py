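"""Hypothesis-driven tests of disagreement sources.

Each test formalises one hypothesised methodological source of inter-map
disagreement as an explicit decision rule over targeted contrasts:

mask
    Maps with conservative forest masks should report lower national totals;
    the verdict checks rank concordance between mask footprint area and
    national total.
resolution
    Coarse-grain maps cannot resolve landscape extremes, so their per-region
    interdecile ranges (p90 − p10) should be compressed relative to
    fine-grain maps.
sensor
    Optical (passive) sensors saturate at lower biomass than radar/lidar
    (active), depressing p90 in high-biomass regions.
extrapolation
    Parametric extrapolation regresses toward the mean, compressing both
    tails (higher p10 AND lower p90) relative to non-parametric techniques.
year
    Maps of different nominal years differ through real growth and
    disturbance; an independent proxy change raster should explain a
    substantial share of the inter-map difference variance.
allometry
    The nationally consistent component-ratio method (CRM) yields
    systematically lower estimates than regional allometric equations.

Verdicts are ``consistent`` (the data show the hypothesised signature),
``inconsistent`` (the data show the reverse), or ``inconclusive``
(ties, mixed outcomes, or no contrast).  Strict inequalities are used
throughout, so identical inputs are always inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import DegenerateFitError
from .grids import BiomassRaster, CategoricalRaster, GridError
from .zonal import region_summaries

__all__ = [
    "StratumDifference",
    "EvaluativeFinding",
    "stratified_difference",
    "test_forest_mask",
    "test_resolution",
    "test_sensor_saturation",
    "test_extrapolation",
    "test_year_effect",
    "test_allometry",
]

DEFAULT_YEAR_EFFECT_FRACTION = 0.4
DEFAULT_HIGH_BIOMASS_QUANTILE = 75.0


@dataclass
class StratumDifference:
    """Order statistics of a difference map within one ancillary stratum."""

    code: int
    label: str
    n: int
    median_diff: float
    p10_diff: float
    p90_diff: float

    @property
    def range(self) -> float:
        return self.p90_diff - self.p10_diff


@dataclass
class EvaluativeFinding:
    test: str
    hypothesis: str
    metrics: pd.DataFrame
    verdict: str               # consistent | inconsistent | inconclusive
    rationale: str
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in ("consistent", "inconsistent", "inconclusive"):
            raise ValueError(f"invalid verdict {self.verdict!r}")
        if self.metrics.empty:
            raise ValueError("metrics table must be nonempty")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "hypothesis": self.hypothesis,
            "verdict": self.verdict,
            "rationale": self.rationale,
            "thresholds": self.thresholds,
            "metrics": self.metrics.to_dict(orient="records"),
        }


def stratified_difference(
    diff: BiomassRaster,
    ancillary: CategoricalRaster,
) -> tuple[list[StratumDifference], dict]:
    """Order statistics of a difference map per ancillary stratum.

    Code 0 (unclassified) is excluded but counted; strata with no jointly
    valid pixels are omitted and listed in the returned bookkeeping dict
    (keys ``skipped``, ``n_unclassified``).
    """
    if ancillary.grid != diff.grid:
        raise GridError("ancillary grid differs from difference grid")
    if not diff.is_difference:
        raise ValueError("input raster is not flagged as a difference product")
    out: list[StratumDifference] = []
    skipped: list[int] = []
    n_unclassified = int((diff.valid & (ancillary.codes == 0)).sum())
    for code in ancillary.region_codes():
        sel = diff.valid & (ancillary.codes == code)
        n = int(sel.sum())
        if n == 0:
            skipped.append(code)
            continue
        v = diff.values[sel]
        out.append(StratumDifference(
            code=code, label=ancillary.legend.get(code, str(code)), n=n,
            median_diff=float(np.percentile(v, 50)),
            p10_diff=float(np.percentile(v, 10)),
            p90_diff=float(np.percentile(v, 90))))
    return out, {"skipped": skipped, "n_unclassified": n_unclassified}


def _labels(maps: Sequence[BiomassRaster], prefix: str = "map") -> list[str]:
    return [m.label or f"{prefix}_{i}" for i, m in enumerate(maps)]


def test_forest_mask(maps: Sequence[BiomassRaster]) -> EvaluativeFinding:
    """Rank concordance between mask footprint area and national total."""
    from .grids import total_biomass
    if len(maps) < 1:
        raise ValueError("need at least one map")
    labels = _labels(maps)
    rows = []
    for lab, m in zip(labels, maps):
        total, area = total_biomass(m)
        rows.append({"map": lab, "mask_area_ha": area, "national_total_Mg": total})
    metrics = pd.DataFrame(rows)
    hyp = ("A more conservative (smaller) forest mask yields a lower national "
           "biomass total: totals rank-order with mask areas.")
    if len(maps) < 2:
        return EvaluativeFinding("mask", hyp, metrics, "inconclusive",
                                 "single map, no contrast")
    areas = metrics["mask_area_ha"].to_numpy()
    totals = metrics["national_total_Mg"].to_numpy()
    if np.ptp(areas) == 0 or np.ptp(totals) == 0:
        return EvaluativeFinding("mask", hyp, metrics, "inconclusive",
                                 "tied mask areas or totals, no rank contrast")
    rho = float(stats.spearmanr(areas, totals).statistic)
    smallest = int(np.argmin(areas))
    if np.isclose(rho, 1.0):
        verdict, why = "consistent", "total rank order matches mask-area rank order"
    elif smallest == int(np.argmax(totals)):
        verdict = "inconsistent"
        why = (f"map {labels[smallest]!r} has the smallest mask but the "
               "largest national total")
    else:
        verdict, why = "inconclusive", f"partial rank concordance (spearman rho={rho:.2f})"
    return EvaluativeFinding("mask", hyp, metrics, verdict, why,
                             thresholds={"spearman_rho": rho})


def _region_stat_medians(maps: Sequence[BiomassRaster],
                         partition: CategoricalRaster,
                         stat) -> dict[str, float]:
    """Median across regions of a per-region statistic, per map."""
    out = {}
    for lab, m in zip(_labels(maps), maps):
        vals = [stat(s) for s in region_summaries(m, partition) if s.defined]
        out[lab] = float(np.median(vals)) if vals else np.nan
    return out


def _dominance_verdict(low_group: dict[str, float], high_group: dict[str, float],
                       ) -> tuple[str, str]:
    """Strict group dominance: consistent iff every low-group value is below
    every high-group value; inconsistent iff the reverse; else inconclusive,
    naming the offending maps."""
    lo = np.array(list(low_group.values()))
    hi = np.array(list(high_group.values()))
    if np.all(lo[:, None] < hi[None, :]):
        return "consistent", "strict group dominance holds"
    if np.all(lo[:, None] > hi[None, :]):
        return "inconsistent", "group dominance is reversed"
    offenders = [k for k, v in low_group.items()
                 if not np.all(v < hi)]
    return "inconclusive", f"mixed ordering; maps not fitting the pattern: {offenders}"


def test_resolution(fine_maps: Sequence[BiomassRaster],
                    coarse_maps: Sequence[BiomassRaster],
                    partition: CategoricalRaster) -> EvaluativeFinding:
    """Coarse-grain maps should show compressed per-region interdecile
    ranges relative to fine-grain maps."""
    if not fine_maps or not coarse_maps:
        raise ValueError("both groups must be nonempty")
    idr = lambda s: s.p90 - s.p10
    fine = _region_stat_medians(fine_maps, partition, idr)
    coarse = _region_stat_medians(coarse_maps, partition, idr)
    metrics = pd.DataFrame(
        [{"map": k, "group": "fine", "median_interdecile_range": v} for k, v in fine.items()]
        + [{"map": k, "group": "coarse", "median_interdecile_range": v} for k, v in coarse.items()])
    verdict, why = _dominance_verdict(coarse, fine)
    hyp = ("Coarse-resolution maps under-resolve landscape extremes: their "
           "region-wise median interdecile range (p90−p10) is below every "
           "fine-resolution map's.")
    return EvaluativeFinding("resolution", hyp, metrics, verdict, why)


def test_sensor_saturation(
    active_maps: Sequence[BiomassRaster],
    passive_maps: Sequence[BiomassRaster],
    partition: CategoricalRaster,
    high_biomass_quantile: float = DEFAULT_HIGH_BIOMASS_QUANTILE,
) -> EvaluativeFinding:
    """Passive-optical maps should show depressed p90 in high-biomass regions.

    High-biomass regions are those whose across-map mean of per-region median
    biomass is at or above the given quantile (default: top quartile).  A
    passive map carries the saturation signature when its p90 falls below
    every active map's p90 in a majority (> 50 %) of those regions.
    """
    if not active_maps or not passive_maps:
        raise ValueError("both groups must be nonempty")
    all_maps = list(active_maps) + list(passive_maps)
    groups = ["active"] * len(active_maps) + ["passive"] * len(passive_maps)
    labels = _labels(all_maps)
    p90 = {}      # label -> {region: p90}
    med = {}
    for lab, m in zip(labels, all_maps):
        summ = {s.region: s for s in region_summaries(m, partition) if s.defined}
        p90[lab] = {r: s.p90 for r, s in summ.items()}
        med[lab] = {r: s.p50 for r, s in summ.items()}
    shared = set.intersection(*(set(v) for v in p90.values()))
    if not shared:
        raise ValueError("no region defined in every map")
    region_level = {r: float(np.mean([med[lab][r] for lab in labels])) for r in shared}
    cut = np.percentile(list(region_level.values()), high_biomass_quantile)
    high = [r for r in shared if region_level[r] >= cut]
    act_labels = [l for l, g in zip(labels, groups) if g == "active"]
    pas_labels = [l for l, g in zip(labels, groups) if g == "passive"]
    rows, verdicts = [], {}
    for pl in pas_labels:
        below = sum(1 for r in high
                    if all(p90[pl][r] < p90[al][r] for al in act_labels))
        above = sum(1 for r in high
                    if all(p90[pl][r] > p90[al][r] for al in act_labels))
        frac_below = below / len(high)
        if frac_below > 0.5:
            verdicts[pl] = "consistent"
        elif above / len(high) > 0.5:
            verdicts[pl] = "inconsistent"
        else:
            verdicts[pl] = "inconclusive"
        rows.append({"map": pl, "group": "passive",
                     "n_high_biomass_regions": len(high),
                     "fraction_p90_below_all_active": frac_below,
                     "map_verdict": verdicts[pl]})
    for al in act_labels:
        rows.append({"map": al, "group": "active",
                     "n_high_biomass_regions": len(high),
                     "fraction_p90_below_all_active": np.nan,
                     "map_verdict": ""})
    metrics = pd.DataFrame(rows)
    vset = set(verdicts.values())
    if vset == {"consistent"}:
        verdict, why = "consistent", "every passive map shows the saturation signature"
    elif vset == {"inconsistent"}:
        verdict, why = "inconsistent", "every passive map shows elevated p90 instead"
    else:
        verdict = "inconclusive"
        why = f"per-map outcomes mixed: {verdicts}"
    hyp = ("Optical-sensor saturation depresses the 90th-percentile biomass "
           "of passive maps below active-sensor maps in high-biomass regions.")
    return EvaluativeFinding("sensor", hyp, metrics, verdict, why,
                             thresholds={"high_biomass_quantile": high_biomass_quantile,
                                         "majority": 0.5})


def test_extrapolation(parametric_maps: Sequence[BiomassRaster],
                       nonparametric_maps: Sequence[BiomassRaster],
                       partition: CategoricalRaster) -> EvaluativeFinding:
    """Parametric extrapolation should compress both tails: region-wise
    median p10 higher AND median p90 lower than every non-parametric map."""
    if not parametric_maps or not nonparametric_maps:
        raise ValueError("both groups must be nonempty")
    par_p10 = _region_stat_medians(parametric_maps, partition, lambda s: s.p10)
    par_p90 = _region_stat_medians(parametric_maps, partition, lambda s: s.p90)
    non_p10 = _region_stat_medians(nonparametric_maps, partition, lambda s: s.p10)
    non_p90 = _region_stat_medians(nonparametric_maps, partition, lambda s: s.p90)
    rows = ([{"map": k, "group": "parametric", "median_p10": par_p10[k],
              "median_p90": par_p90[k]} for k in par_p10]
            + [{"map": k, "group": "nonparametric", "median_p10": non_p10[k],
                "median_p90": non_p90[k]} for k in non_p10])
    metrics = pd.DataFrame(rows)
    # compressed: parametric p10 above all nonparametric AND p90 below all
    v10, _ = _dominance_verdict(non_p10, par_p10)   # nonpar p10 < par p10
    v90, _ = _dominance_verdict(par_p90, non_p90)   # par p90 < nonpar p90
    if v10 == "consistent" and v90 == "consistent":
        verdict, why = "consistent", "parametric envelopes compressed on both tails"
    elif v10 == "inconsistent" and v90 == "inconsistent":
        verdict, why = "inconsistent", "parametric envelopes wider on both tails"
    else:
        verdict = "inconclusive"
        why = f"tail orderings mixed (lower tail {v10}, upper tail {v90})"
    hyp = ("Parametric extrapolation regresses toward the mean, raising p10 "
           "and lowering p90 relative to non-parametric maps.")
    return EvaluativeFinding("extrapolation", hyp, metrics, verdict, why)


def test_year_effect(
    diff: BiomassRaster,
    proxy_change: BiomassRaster,
    fraction_threshold: float = DEFAULT_YEAR_EFFECT_FRACTION,
) -> EvaluativeFinding:
    """Share of inter-map difference variance explained by a proxy change map.

    OLS of diff on proxy over jointly valid cells; the "consistency
    fraction" is the regression r² — the fraction of difference variance
    attributable to real growth/disturbance.  Consistent iff the slope is
    positive and the fraction meets the threshold.
    """
    if proxy_change.grid != diff.grid:
        raise GridError("proxy grid differs from difference grid")
    sel = diff.valid & proxy_change.valid
    x = proxy_change.values[sel]
    y = diff.values[sel]
    if x.size < 3:
        raise ValueError("too few jointly valid cells")
    if np.ptp(x) == 0:
        raise DegenerateFitError("proxy change map is constant over the shared cells")
    res = stats.linregress(x, y)
    frac = float(res.rvalue ** 2)
    metrics = pd.DataFrame([{
        "n_pixels": int(x.size), "slope": float(res.slope),
        "intercept": float(res.intercept), "r2": frac,
        "consistency_fraction": frac}])
    if res.slope > 0 and frac >= fraction_threshold:
        verdict = "consistent"
        why = (f"proxy change explains {frac:.1%} of the difference variance "
               f"with positive slope")
    else:
        verdict = "inconsistent"
        why = (f"slope {res.slope:.3f}, fraction {frac:.3f} below threshold "
               f"{fraction_threshold}")
    hyp = ("Differences between maps of different nominal years reflect real "
           "growth and disturbance captured by the proxy change map.")
    return EvaluativeFinding("year", hyp, metrics, verdict, why,
                             thresholds={"fraction_threshold": fraction_threshold})


def test_allometry(crm_maps: Sequence[BiomassRaster],
                   regional_maps: Sequence[BiomassRaster],
                   partition: CategoricalRaster) -> EvaluativeFinding:
    """CRM-based maps should sit below regional-equation maps: region-wise
    median of per-region means strictly lower for every CRM map."""
    if not crm_maps or not regional_maps:
        raise ValueError("both groups must be nonempty")
    crm_mean = _region_stat_medians(crm_maps, partition, lambda s: s.mean)
    reg_mean = _region_stat_medians(regional_maps, partition, lambda s: s.mean)
    crm_med = _region_stat_medians(crm_maps, partition, lambda s: s.p50)
    reg_med = _region_stat_medians(regional_maps, partition, lambda s: s.p50)
    rows = ([{"map": k, "group": "crm", "median_of_region_means": crm_mean[k],
              "median_of_region_medians": crm_med[k]} for k in crm_mean]
            + [{"map": k, "group": "regional", "median_of_region_means": reg_mean[k],
                "median_of_region_medians": reg_med[k]} for k in reg_mean])
    metrics = pd.DataFrame(rows)
    verdict, why = _dominance_verdict(crm_mean, reg_mean)
    hyp = ("Component-ratio-method maps are systematically lower than maps "
           "built on regional allometric equations.")
    return EvaluativeFinding("allometry", hyp, metrics, verdict, why)
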