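"""Raster and table I/O, run configuration, and the two pipeline phases.

Rasters are exchanged as single-band GeoTIFFs with a plain (non-rotated)
geotransform encoded in the ModelPixelScale/ModelTiepoint tags and invalid
cells encoded by a nodata value (default −9999, carried in the GDAL_NODATA
tag).  Categorical layers are integer bands with a ``<name>.legend.csv``
sidecar (columns code,label).  Tables are RFC-4180 CSV.

The two pipeline entry points mirror the framework's phases:

``run_describe``
    alignment → common mask → reference comparison → global and regional
    R-mode PCA → multiscale pairwise agreement, all products written to the
    output directory.
``run_evaluate``
    the six hypothesis tests, driven by per-map group tags, each emitted as
    a JSON finding plus a combined text report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .agreement import (AgreementResult, DegenerateFitError, ReferenceTable,
                        compare_to_reference)
from .evaluative import (EvaluativeFinding, test_allometry, test_extrapolation,
                         test_forest_mask, test_resolution,
                         test_sensor_saturation, test_year_effect,
                         DEFAULT_YEAR_EFFECT_FRACTION)
from .grids import (BiomassRaster, CategoricalRaster, GridSpec, MaskRaster,
                    align_to, common_mask, difference,
                    resample_nearest_categorical)
from .pca import pca_by_region, rmode_pca, scores_to_rasters, stack_pixels
from .zonal import multiscale_agreement, summaries_frame

logger = logging.getLogger("agbcompare")

DEFAULT_NODATA = -9999.0
TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_MODEL_TRANSFORMATION = 34264
TAG_GDAL_NODATA = 42113

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_COMPUTATION = 3


class FormatError(ValueError):
    """Unsupported raster file property."""


# ---------------------------------------------------------------- raster I/O

def _geo_extratags(grid: GridSpec, nodata: Optional[float]) -> list:
    tags = [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
    ]
    if nodata is not None:
        s = repr(float(nodata)).encode() + b"\x00"
        tags.append((TAG_GDAL_NODATA, "s", len(s), s))
    return tags


def write_raster(path, r: BiomassRaster, nodata: float = DEFAULT_NODATA) -> None:
    """Single-band float GeoTIFF; invalid cells hold the nodata value."""
    data = np.where(r.valid, r.values, nodata).astype(np.float64)
    tifffile.imwrite(path, data, extratags=_geo_extratags(r.grid, nodata))


def write_mask(path, m: MaskRaster) -> None:
    tifffile.imwrite(path, m.valid.astype(np.uint8),
                     extratags=_geo_extratags(m.grid, None))


def write_categorical(path, c: CategoricalRaster) -> None:
    tifffile.imwrite(path, c.codes.astype(np.int32),
                     extratags=_geo_extratags(c.grid, None))
    legend = pd.DataFrame({"code": list(c.legend), "label": list(c.legend.values())})
    legend.to_csv(Path(str(path)).with_suffix(".legend.csv"), index=False)


def _read_page(path):
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise FormatError(f"{path}: expected a single-band raster, "
                              f"found {len(tf.pages)} pages")
        page = tf.pages[0]
        tags = {t.code: t.value for t in page.tags.values()}
        data = page.asarray()
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single band, got shape {data.shape}")
    if TAG_MODEL_TRANSFORMATION in tags:
        t = tags[TAG_MODEL_TRANSFORMATION]
        if t[1] != 0 or t[4] != 0:
            raise FormatError(f"{path}: rotated/sheared geotransform is unsupported")
        scale = (t[0], -t[5])
        origin = (t[3], t[7])
    elif TAG_MODEL_PIXEL_SCALE in tags and TAG_MODEL_TIEPOINT in tags:
        ps = tags[TAG_MODEL_PIXEL_SCALE]
        tp = tags[TAG_MODEL_TIEPOINT]
        scale = (ps[0], ps[1])
        origin = (tp[3] - tp[0] * ps[0], tp[4] + tp[1] * ps[1])
    else:
        raise FormatError(f"{path}: no geotransform tags "
                          "(ModelPixelScale/ModelTiepoint)")
    if not np.isclose(scale[0], scale[1]):
        raise FormatError(f"{path}: non-square cells {scale} are unsupported")
    grid = GridSpec(origin[0], origin[1], float(scale[0]),
                    data.shape[0], data.shape[1])
    nodata = None
    if TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[TAG_GDAL_NODATA]).rstrip("\x00"))
    return grid, data, nodata


def read_raster(path, label: str = "",
                nominal_year: Optional[int] = None) -> BiomassRaster:
    """Read a continuous biomass raster; nodata cells become invalid."""
    grid, data, nodata = _read_page(path)
    data = data.astype(float)
    if nodata is None:
        nodata = DEFAULT_NODATA
    valid = np.isfinite(data) & (data != nodata)
    data = np.where(valid, data, 0.0)
    return BiomassRaster(grid, data, valid, label=label or Path(str(path)).stem,
                         nominal_year=nominal_year)


def read_mask(path) -> MaskRaster:
    grid, data, _ = _read_page(path)
    return MaskRaster(grid, data.astype(bool))


def read_categorical(path) -> CategoricalRaster:
    grid, data, _ = _read_page(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: categorical raster must hold an integer band")
    legend_path = Path(str(path)).with_suffix(".legend.csv")
    legend = {}
    if legend_path.exists():
        df = pd.read_csv(legend_path)
        legend = {int(r.code): str(r.label) for r in df.itertuples()}
    return CategoricalRaster(grid, data.astype(np.int64), legend)


# ------------------------------------------------------------- configuration

@dataclass
class MapEntry:
    path: str
    label: str
    nominal_year: Optional[int] = None
    sensor: Optional[str] = None        # active | passive
    technique: Optional[str] = None     # parametric | nonparametric
    allometry: Optional[str] = None     # crm | regional
    grain: Optional[str] = None         # fine | coarse


@dataclass
class RunConfig:
    """Declarative description of one intercomparison run."""

    maps: list[MapEntry]
    partition: Optional[str] = None
    reference: Optional[str] = None
    proxy_change: Optional[str] = None
    ancillary: dict[str, str] = field(default_factory=dict)
    output_dir: str = "agbcompare_out"
    seed: int = 0
    min_valid_fraction: float = 0.5
    min_pixels: int = 30
    year_effect_fraction: float = DEFAULT_YEAR_EFFECT_FRACTION
    multiscale_factors: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        labels = [m.label for m in self.maps]
        if len(labels) != len(set(labels)):
            raise ValueError("map labels must be unique")
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in [0, 1]")
        if not 0.0 <= self.year_effect_fraction <= 1.0:
            raise ValueError("year_effect_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        maps = [MapEntry(**m) for m in raw.pop("maps")]
        factors = tuple(raw.pop("multiscale_factors", None) or (1, 2, 3, 4))
        return cls(maps=maps, multiscale_factors=factors, **raw)

    def digest(self) -> str:
        blob = json.dumps({
            "maps": [vars(m) for m in self.maps],
            "partition": self.partition, "reference": self.reference,
            "proxy_change": self.proxy_change, "ancillary": self.ancillary,
            "seed": self.seed, "min_valid_fraction": self.min_valid_fraction,
            "min_pixels": self.min_pixels,
            "year_effect_fraction": self.year_effect_fraction,
            "multiscale_factors": list(self.multiscale_factors),
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunData:
    """Loaded inputs for one run (also constructible from a synthetic
    scenario without touching disk)."""

    maps: list[BiomassRaster]
    entries: list[MapEntry]
    partition: Optional[CategoricalRaster] = None
    reference: Optional[ReferenceTable] = None
    proxy_change: Optional[BiomassRaster] = None
    ancillary: dict[str, CategoricalRaster] = field(default_factory=dict)


def load_run(cfg: RunConfig) -> RunData:
    maps = [read_raster(e.path, label=e.label, nominal_year=e.nominal_year)
            for e in cfg.maps]
    partition = read_categorical(cfg.partition) if cfg.partition else None
    reference = ReferenceTable.from_csv(cfg.reference) if cfg.reference else None
    proxy = None
    if cfg.proxy_change:
        proxy = read_raster(cfg.proxy_change, label="proxy_change")
        proxy.is_difference = True
    ancillary = {name: read_categorical(p) for name, p in cfg.ancillary.items()}
    return RunData(maps=maps, entries=list(cfg.maps), partition=partition,
                   reference=reference, proxy_change=proxy, ancillary=ancillary)


def data_from_scenario(scenario, grain_threshold: float = 2.0) -> RunData:
    """Adapt a synthetic scenario bundle to the pipeline input form."""
    entries = []
    for ms in scenario.map_specs:
        coarse = any(p.kind == "coarsen" for p in ms.perturbations)
        entries.append(MapEntry(path="", label=ms.label,
                                nominal_year=ms.nominal_year,
                                sensor=ms.sensor, technique=ms.technique,
                                allometry=ms.allometry,
                                grain="coarse" if coarse else "fine"))
    return RunData(maps=[m.copy() for m in scenario.maps], entries=entries,
                   partition=scenario.partition, reference=scenario.reference,
                   proxy_change=scenario.proxy_change,
                   ancillary=dict(scenario.ancillary))


# ------------------------------------------------------------------ pipeline

def _write_manifest(out: Path, cfg: Optional[RunConfig], stage: str) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config_hash": cfg.digest() if cfg else None,
        "seed": cfg.seed if cfg else None,
        "thresholds": {
            "min_valid_fraction": cfg.min_valid_fraction if cfg else None,
            "min_pixels": cfg.min_pixels if cfg else None,
            "year_effect_fraction": cfg.year_effect_fraction if cfg else None,
        },
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _agreement_row(res: AgreementResult, national: float) -> dict:
    return {"map": res.label, "n": res.n, "d": res.d, "slope": res.slope,
            "intercept": res.intercept, "r2": res.r2,
            "mean_bias": res.mean_bias, "national_total": national}


def run_describe(data: RunData, out_dir, cfg: Optional[RunConfig] = None,
                 min_pixels: int = 30,
                 factors: Sequence[int] = (1, 2, 3, 4),
                 min_valid_fraction: float = 0.5,
                 write_rasters: bool = True) -> dict:
    """Descriptive phase; returns the result bundle and writes products."""
    if cfg is not None:
        min_pixels = cfg.min_pixels
        factors = cfg.multiscale_factors
        min_valid_fraction = cfg.min_valid_fraction
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(data.maps) < 2:
        raise ValueError("describe phase needs at least 2 maps")

    # alignment: coarsest cell size wins; mean-aggregate then snap
    target = max(data.maps, key=lambda m: m.grid.cell_size).grid
    logger.info("aligning %d maps to %.0f m grid", len(data.maps), target.cell_size)
    aligned = [align_to(m, target, min_valid_fraction) for m in data.maps]
    partition = data.partition
    if partition is not None and partition.grid != target:
        partition = resample_nearest_categorical(partition, target)
    shared = common_mask([m.mask() for m in aligned])

    results: dict = {"aligned_maps": aligned, "common_mask": shared,
                     "partition": partition}

    # reference comparison on each map's own mask / native grid
    if data.reference is not None and partition is not None:
        rows = []
        for m in aligned:
            res, table = compare_to_reference(m, partition, data.reference)
            rows.append(_agreement_row(res, table.attrs["national_total"]))
        ref_df = pd.DataFrame(rows)
        ref_df.to_csv(out / "reference_agreement.csv", index=False)
        results["reference_agreement"] = ref_df
    else:
        logger.info("no reference table: reference comparison skipped")
        results["reference_agreement"] = None

    # global + regional R-mode PCA
    table, idx = stack_pixels(aligned, shared)
    labels = [m.label for m in aligned]
    global_pca = rmode_pca(table, map_labels=labels)
    results["global_pca"] = global_pca
    pca_df = pd.DataFrame({
        "component": [f"PC{k+1}" for k in range(len(global_pca.eigenvalues))],
        "eigenvalue": global_pca.eigenvalues,
        "variance_fraction": global_pca.variance_fraction})
    pca_df.to_csv(out / "pca_variance.csv", index=False)
    corr_rows = [{"map": lab, "component": f"PC{k+1}",
                  "loading": global_pca.loadings[i, k],
                  "correlation": global_pca.map_correlations[i, k]}
                 for i, lab in enumerate(labels)
                 for k in range(len(labels))]
    pd.DataFrame(corr_rows).to_csv(out / "pca_map_correlations.csv", index=False)
    if write_rasters:
        for r in scores_to_rasters(global_pca, idx, target, n_components=2):
            write_raster(out / f"{r.label}.tif", r)

    if partition is not None:
        regional, skipped = pca_by_region(aligned, shared, partition,
                                          min_pixels=min_pixels)
        results["regional_pca"] = regional
        results["regional_pca_skipped"] = skipped
        reg_rows = [{"region": code, "map": lab, "component": f"PC{k+1}",
                     "correlation": res.map_correlations[i, k]}
                    for code, res in regional.items()
                    for i, lab in enumerate(labels) for k in range(2)]
        pd.DataFrame(reg_rows).to_csv(out / "pca_regional_correlations.csv",
                                      index=False)

        # per-map per-region statistics + multiscale ladder, both orderings
        summaries_frame(aligned, partition).to_csv(
            out / "region_statistics.csv", index=False)
        ms_rows, ms_summary = [], []
        for a, b in combinations(aligned, 2):
            for x, y in ((a, b), (b, a)):
                ms = multiscale_agreement(x, y, partition, factors=factors,
                                          min_pixels=min_pixels,
                                          min_valid_fraction=min_valid_fraction)
                per = ms.per_region.copy()
                per["map_x"], per["map_y"] = x.label, y.label
                ms_rows.append(per)
                s = ms.summary.copy()
                s["map_x"], s["map_y"] = x.label, y.label
                ms_summary.append(s)
        results["multiscale_per_region"] = pd.concat(ms_rows, ignore_index=True)
        results["multiscale_summary"] = pd.concat(ms_summary, ignore_index=True)
        results["multiscale_per_region"].to_csv(out / "multiscale_d.csv", index=False)
        results["multiscale_summary"].to_csv(out / "multiscale_summary.csv",
                                             index=False)
    _write_manifest(out, cfg, "describe")
    return results


def run_evaluate(data: RunData, out_dir, cfg: Optional[RunConfig] = None,
                 year_effect_fraction: float = DEFAULT_YEAR_EFFECT_FRACTION,
                 min_valid_fraction: float = 0.5) -> dict:
    """Evaluative phase: run every test whose inputs and group tags exist.

    Tests lacking inputs are reported as skipped; degenerate contrasts
    (e.g. a constant proxy change map) yield an inconclusive finding rather
    than an error, so a null scenario runs clean end to end.
    """
    if cfg is not None:
        year_effect_fraction = cfg.year_effect_fraction
        min_valid_fraction = cfg.min_valid_fraction
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = max(data.maps, key=lambda m: m.grid.cell_size).grid
    aligned = [align_to(m, target, min_valid_fraction) for m in data.maps]
    partition = data.partition
    if partition is not None and partition.grid != target:
        partition = resample_nearest_categorical(partition, target)

    findings: dict[str, EvaluativeFinding] = {}
    skipped: dict[str, str] = {}

    findings["mask"] = test_forest_mask(aligned)

    def group(attr, value):
        return [m for m, e in zip(aligned, data.entries)
                if getattr(e, attr, None) == value]

    if partition is None:
        for t in ("resolution", "sensor", "extrapolation", "allometry"):
            skipped[t] = "no region partition supplied"
    else:
        fine, coarse = group("grain", "fine"), group("grain", "coarse")
        if fine and coarse:
            findings["resolution"] = test_resolution(fine, coarse, partition)
        else:
            skipped["resolution"] = "need both fine and coarse grain tags"
        active, passive = group("sensor", "active"), group("sensor", "passive")
        if active and passive:
            findings["sensor"] = test_sensor_saturation(active, passive, partition)
        else:
            skipped["sensor"] = "need both active and passive sensor tags"
        par = group("technique", "parametric")
        non = group("technique", "nonparametric")
        if par and non:
            findings["extrapolation"] = test_extrapolation(par, non, partition)
        else:
            skipped["extrapolation"] = "need both technique tags"
        crm, reg = group("allometry", "crm"), group("allometry", "regional")
        if crm and reg:
            findings["allometry"] = test_allometry(crm, reg, partition)
        else:
            skipped["allometry"] = "need both allometry tags"

    if data.proxy_change is None:
        skipped["year"] = "no proxy change raster supplied"
    else:
        dated = [m for m in aligned if m.nominal_year is not None]
        if len(dated) < 2:
            skipped["year"] = "need two maps with nominal years"
        else:
            early = min(dated, key=lambda m: m.nominal_year)
            late = max(dated, key=lambda m: m.nominal_year)
            diff = difference(early, late)
            proxy = data.proxy_change
            if proxy.grid != target:
                proxy = align_to(proxy, target, min_valid_fraction)
                proxy.is_difference = True
            try:
                findings["year"] = test_year_effect(
                    diff, proxy, fraction_threshold=year_effect_fraction)
            except DegenerateFitError as exc:
                findings["year"] = EvaluativeFinding(
                    "year",
                    "Inter-map differences reflect real growth/disturbance.",
                    pd.DataFrame([{"note": str(exc)}]),
                    "inconclusive", f"degenerate contrast: {exc}")

    report = {"findings": {k: f.to_dict() for k, f in findings.items()},
              "skipped": skipped}
    (out / "findings.json").write_text(json.dumps(report, indent=2, default=str))
    lines = ["Evaluative phase report", "======================="]
    for name, f in findings.items():
        lines += [f"\n[{name}] verdict: {f.verdict}",
                  f"  hypothesis: {f.hypothesis}", f"  rationale: {f.rationale}"]
    for name, why in skipped.items():
        lines.append(f"\n[{name}] skipped: {why}")
    (out / "findings.txt").write_text("\n".join(lines) + "\n")
    _write_manifest(out, cfg, "evaluate")
    return {"findings": findings, "skipped": skipped}
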