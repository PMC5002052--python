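"""Synthetic scenario generator.

Produces complete, fully deterministic test scenarios: a spatially
autocorrelated nonnegative biomass truth field, a set of maps derived from
the truth by composable perturbations that mimic the methodological error
sources of real national biomass products (mask differences, grain size,
sensor saturation, parametric shrinkage, allometry scaling, nominal-year
disturbance), a contiguous region partition, categorical ancillary layers,
a per-region reference table, and a proxy change raster.

Every random draw is governed by the scenario seed; identical configuration
plus seed yields a bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .agreement import ReferenceTable
from .grids import (BiomassRaster, CategoricalRaster, GridSpec, MaskRaster,
                    aggregate_mean, resample_nearest, total_biomass)

__all__ = [
    "PerturbationSpec",
    "MapSpec",
    "ScenarioConfig",
    "Scenario",
    "gaussian_random_field",
    "perturb",
    "make_regions",
    "make_categorical_field",
    "make_scenario",
    "preset_map_specs",
]

PERTURBATION_KINDS = ("bias", "scale", "saturate", "noise", "coarsen",
                      "mask_morph", "shrinkage", "disturbance")


@dataclass(frozen=True)
class PerturbationSpec:
    """One error mechanism applied to a truth field.

    kind / parameters:
      bias         b (Mg/ha), added then floored at 0
      scale        factor k > 0
      saturate     cap s > 0 (Mg/ha), optional noise_sd on top
      noise        noise_sd (Mg/ha), iid Gaussian, floored at 0
      coarsen      factor (integer): block mean then snap back to the grid
      mask_morph   radius (cells): >0 grows the validity mask, <0 shrinks it
      shrinkage    lam in [0, 1]: x -> mean + lam*(x - mean)
      disturbance  n_patches, patch_radius (cells), loss_fraction in [0, 1]
    """

    kind: str
    b: float = 0.0
    k: float = 1.0
    s: float = np.inf
    noise_sd: float = 0.0
    factor: int = 1
    radius: int = 0
    lam: float = 1.0
    n_patches: int = 0
    patch_radius: float = 3.0
    loss_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "scale" and self.k <= 0:
            raise ValueError("scale factor must be > 0")
        if self.kind == "saturate" and self.s <= 0:
            raise ValueError("saturation cap must be > 0")
        if self.kind == "shrinkage" and not 0.0 <= self.lam <= 1.0:
            raise ValueError("shrink coefficient must be in [0, 1]")
        if self.kind == "disturbance" and not 0.0 <= self.loss_fraction <= 1.0:
            raise ValueError("loss fraction must be in [0, 1]")


@dataclass(frozen=True)
class MapSpec:
    """One synthetic map: label, ordered perturbations, metadata for the
    evaluative groupings (sensor, technique, allometry) and nominal year."""

    label: str
    perturbations: tuple[PerturbationSpec, ...] = ()
    nominal_year: Optional[int] = None
    sensor: str = "active"          # active | passive
    technique: str = "nonparametric"  # parametric | nonparametric
    allometry: str = "regional"     # crm | regional

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbations", tuple(self.perturbations))


@dataclass(frozen=True)
class ScenarioConfig:
    grid: GridSpec = GridSpec(0.0, 0.0, 240.0, 120, 120)
    mean: float = 100.0             # Mg/ha, typical temperate-forest density
    sd: float = 35.0
    corr_length: float = 8.0        # cells
    n_regions: int = 9
    maps: tuple[MapSpec, ...] = ()
    seed: int = 0
    reference_noise_sd: float = 0.02   # relative sd on per-region truth totals
    n_forest_types: int = 4
    n_age_classes: int = 4

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.corr_length <= 0:
            raise ValueError("correlation length must be > 0")
        object.__setattr__(self, "maps", tuple(self.maps))


@dataclass
class Scenario:
    """Full input bundle for one intercomparison run."""

    config: ScenarioConfig
    truth: BiomassRaster
    maps: list[BiomassRaster]
    map_specs: list[MapSpec]
    partition: CategoricalRaster
    ancillary: dict[str, CategoricalRaster]
    reference: ReferenceTable
    proxy_change: Optional[BiomassRaster]

    @property
    def masks(self) -> list[MaskRaster]:
        return [m.mask() for m in self.maps]


def gaussian_random_field(grid: GridSpec, mean: float, sd: float,
                          corr_length: float, seed) -> BiomassRaster:
    """Stationary random field with Gaussian-shaped spatial autocovariance.

    White noise is convolved with a Gaussian kernel of sigma
    corr_length/sqrt(2), giving autocorrelation exp(-h^2 / (2 L^2)) at lag h;
    the field is then rescaled to the target mean and sd and truncated at 0.
    """
    if corr_length <= 0:
        raise ValueError("correlation length must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if sd == 0:
        vals = np.full(grid.shape, float(mean))
    else:
        white = rng.standard_normal(grid.shape)
        sigma = corr_length / np.sqrt(2.0)
        smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
        smooth = (smooth - smooth.mean()) / smooth.std()
        vals = mean + sd * smooth
    vals = np.clip(vals, 0.0, None)
    return BiomassRaster(grid, vals, np.ones(grid.shape, dtype=bool), label="truth")


def _disk(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2) <= radius ** 2


def disturbance_footprint(grid: GridSpec, n_patches: int, patch_radius: float,
                          seed) -> np.ndarray:
    """Boolean footprint of seeded random disk patches."""
    rng = np.random.default_rng(seed)
    fp = np.zeros(grid.shape, dtype=bool)
    disk = _disk(patch_radius)
    r = disk.shape[0] // 2
    for _ in range(n_patches):
        ci = int(rng.integers(0, grid.n_rows))
        cj = int(rng.integers(0, grid.n_cols))
        i0, i1 = max(0, ci - r), min(grid.n_rows, ci + r + 1)
        j0, j1 = max(0, cj - r), min(grid.n_cols, cj + r + 1)
        di0, dj0 = i0 - (ci - r), j0 - (cj - r)
        fp[i0:i1, j0:j1] |= disk[di0:di0 + (i1 - i0), dj0:dj0 + (j1 - j0)]
    return fp


def perturb(r: BiomassRaster, spec: PerturbationSpec, seed=0) -> BiomassRaster:
    """Apply one perturbation; the input raster is not modified."""
    vals = r.values.copy()
    valid = r.valid.copy()
    rng = np.random.default_rng(seed)
    if spec.kind == "bias":
        vals = np.clip(vals + spec.b, 0.0, None)
    elif spec.kind == "scale":
        vals = vals * spec.k
    elif spec.kind == "saturate":
        vals = np.minimum(vals, spec.s)
        if spec.noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, spec.noise_sd, vals.shape), 0.0, None)
    elif spec.kind == "noise":
        vals = np.clip(vals + rng.normal(0.0, spec.noise_sd, vals.shape), 0.0, None)
    elif spec.kind == "coarsen":
        agg = aggregate_mean(r, spec.factor, min_valid_fraction=0.0)
        back = resample_nearest(agg, r.grid)
        vals, valid = back.values, back.valid & r.valid
    elif spec.kind == "mask_morph":
        if spec.radius != 0:
            struct = _disk(abs(spec.radius))
            if spec.radius > 0:
                valid = ndimage.binary_dilation(valid, structure=struct)
            else:
                valid = ndimage.binary_erosion(valid, structure=struct)
    elif spec.kind == "shrinkage":
        xbar = vals[valid].mean() if valid.any() else 0.0
        vals = np.clip(xbar + spec.lam * (vals - xbar), 0.0, None)
    elif spec.kind == "disturbance":
        fp = disturbance_footprint(r.grid, spec.n_patches, spec.patch_radius, seed)
        vals = np.where(fp, vals * (1.0 - spec.loss_fraction), vals)
    else:  # pragma: no cover - guarded by PerturbationSpec
        raise ValueError(spec.kind)
    return BiomassRaster(r.grid, vals, valid, label=r.label,
                         nominal_year=r.nominal_year)


def make_regions(grid: GridSpec, n_regions: int, seed) -> CategoricalRaster:
    """Contiguous partition by nearest seeded center (Voronoi on cell
    centers); codes 1..n_regions, every region nonempty."""
    n_cells = grid.n_rows * grid.n_cols
    if not 1 <= n_regions <= n_cells:
        raise ValueError("n_regions must be in [1, cell count]")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_regions, replace=False)
    ci, cj = np.unravel_index(flat, grid.shape)
    ii, jj = np.mgrid[0:grid.n_rows, 0:grid.n_cols]
    d2 = ((ii[..., None] - ci) ** 2 + (jj[..., None] - cj) ** 2)
    codes = np.argmin(d2, axis=-1) + 1
    legend = {k + 1: f"region_{k + 1}" for k in range(n_regions)}
    return CategoricalRaster(grid, codes, legend)


def make_categorical_field(grid: GridSpec, n_classes: int, corr_length: float,
                           seed, labels: Sequence[str] | None = None) -> CategoricalRaster:
    """Ancillary layer: a seeded autocorrelated field quantile-binned into
    n_classes equal-area classes (codes 1..n)."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_length / np.sqrt(2.0),
                                     mode="wrap")
    qs = np.quantile(smooth, np.linspace(0, 1, n_classes + 1)[1:-1])
    codes = np.digitize(smooth, qs) + 1
    legend = {k + 1: (labels[k] if labels else f"class_{k + 1}")
              for k in range(n_classes)}
    return CategoricalRaster(grid, codes, legend)


def _pert_seed(base_seed: int, map_index: int, pert_index: int):
    # stable per-(map, perturbation) seed stream
    return [int(base_seed) & 0x7FFFFFFF, map_index, pert_index]


def make_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate the full bundle.

    Each map applies its perturbation list, in order, to the truth field.
    The reference table holds per-region truth totals with seeded relative
    noise.  The proxy change raster is emitted (truth minus disturbed truth)
    when any map carries a disturbance perturbation; otherwise it is None.
    """
    truth = gaussian_random_field(cfg.grid, cfg.mean, cfg.sd,
                                  cfg.corr_length, [cfg.seed, 0])
    partition = make_regions(cfg.grid, cfg.n_regions, [cfg.seed, 1])
    age_labels = ["young", "immature", "mature", "old"][:cfg.n_age_classes]
    ancillary = {
        "forest_type": make_categorical_field(cfg.grid, cfg.n_forest_types,
                                              cfg.corr_length * 1.5,
                                              [cfg.seed, 2]),
        "age_class": make_categorical_field(cfg.grid, cfg.n_age_classes,
                                            cfg.corr_length, [cfg.seed, 3],
                                            labels=age_labels),
        "elevation_class": make_categorical_field(cfg.grid, 3,
                                                  cfg.corr_length * 2,
                                                  [cfg.seed, 4],
                                                  labels=["lt500m", "500to1500m", "gt1500m"]),
        "slope_class": make_categorical_field(cfg.grid, 2, cfg.corr_length,
                                              [cfg.seed, 5],
                                              labels=["benign", "extreme"]),
    }

    maps: list[BiomassRaster] = []
    any_disturbance = False
    for i, ms in enumerate(cfg.maps):
        m = replace(truth.copy(), label=ms.label, nominal_year=ms.nominal_year)
        for j, p in enumerate(ms.perturbations):
            m = perturb(m, p, seed=_pert_seed(cfg.seed, i, j))
            if p.kind == "disturbance":
                any_disturbance = True
        maps.append(m)

    # reference: per-region truth totals + seeded relative noise
    rng_ref = np.random.default_rng([cfg.seed, 6])
    totals: dict[int, float] = {}
    for code in partition.region_codes():
        sel = MaskRaster(cfg.grid, partition.codes == code)
        tot, _ = total_biomass(truth, within=sel)
        noisy = tot * (1.0 + rng_ref.normal(0.0, cfg.reference_noise_sd))
        totals[code] = max(0.0, float(noisy))
    reference = ReferenceTable(totals, units="Mg",
                               names=dict(partition.legend))

    proxy = None
    if any_disturbance:
        lost = np.zeros(cfg.grid.shape)
        for i, ms in enumerate(cfg.maps):
            for j, p in enumerate(ms.perturbations):
                if p.kind == "disturbance":
                    fp = disturbance_footprint(cfg.grid, p.n_patches,
                                               p.patch_radius,
                                               _pert_seed(cfg.seed, i, j))
                    lost = np.where(fp, np.maximum(lost, truth.values * p.loss_fraction),
                                    lost)
        proxy = BiomassRaster(cfg.grid, lost, np.ones(cfg.grid.shape, dtype=bool),
                              label="proxy_change", is_difference=True)

    return Scenario(config=cfg, truth=truth, maps=maps,
                    map_specs=list(cfg.maps), partition=partition,
                    ancillary=ancillary, reference=reference,
                    proxy_change=proxy)


def preset_map_specs() -> tuple[MapSpec, ...]:
    """Four map archetypes echoing the error taxonomy of the real national
    products:

    S-like  fine grid, active sensor, parametric, CRM allometry (scale 0.95)
    K-like  fine grid, active sensor, non-parametric, mild saturation
    B-like  coarse grid, passive sensor, non-parametric, positive bias,
            conservative (eroded) mask
    W-like  coarse grid, passive sensor, parametric shrinkage, CRM allometry
    """
    return (
        MapSpec("S-like", (
            PerturbationSpec("scale", k=0.95),
            PerturbationSpec("noise", noise_sd=8.0),
        ), nominal_year=2005, sensor="active", technique="parametric",
            allometry="crm"),
        MapSpec("K-like", (
            PerturbationSpec("saturate", s=160.0),
            PerturbationSpec("noise", noise_sd=8.0),
        ), nominal_year=2000, sensor="active", technique="nonparametric",
            allometry="regional"),
        MapSpec("B-like", (
            PerturbationSpec("coarsen", factor=4),
            PerturbationSpec("bias", b=15.0),
            PerturbationSpec("mask_morph", radius=-3),
            PerturbationSpec("noise", noise_sd=8.0),
        ), nominal_year=2003, sensor="passive", technique="nonparametric",
            allometry="regional"),
        MapSpec("W-like", (
            PerturbationSpec("coarsen", factor=4),
            PerturbationSpec("shrinkage", lam=0.7),
            PerturbationSpec("scale", k=0.97),
            PerturbationSpec("noise", noise_sd=8.0),
        ), nominal_year=2009, sensor="passive", technique="parametric",
            allometry="crm"),
    )
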