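"""The six hypothesis tests and ancillary-stratified difference summaries."""

import numpy as np
import pytest

from agbcompare import difference, stratified_difference, make_regions
from agbcompare import evaluative as ev
from agbcompare.agreement import DegenerateFitError
from agbcompare.grids import GridSpec
from agbcompare.synthetic import (PerturbationSpec, gaussian_random_field,
                                  perturb)

from conftest import make_partition, make_raster


def _landscape(seed=0, shape=(60, 60), mean=100, sd=35, corr=3):
    grid = GridSpec(0, 0, 240.0, *shape)
    truth = gaussian_random_field(grid, mean, sd, corr, seed=seed)
    partition = make_regions(grid, 6, seed=seed + 5000)
    return truth, partition


class TestStratifiedDifference:
    def test_zero_difference_everywhere(self):
        a = make_raster(np.full((4, 4), 50.0))
        diff = difference(a, a)
        anc = make_partition([[1, 1, 2, 2]] * 4)
        strata, info = stratified_difference(diff, anc)
        assert all(s.median_diff == 0 and s.range == 0 for s in strata)
        assert info["skipped"] == []

    def test_planted_offsets_recovered(self):
        codes = np.array([[1, 1], [2, 2]])
        a = make_raster([[10.0, 10.0], [10.0, 10.0]])
        b = make_raster([[5.0, 5.0], [15.0, 15.0]])
        strata, _ = stratified_difference(difference(a, b),
                                          make_partition(codes))
        by_code = {s.code: s for s in strata}
        assert by_code[1].median_diff == 5.0
        assert by_code[2].median_diff == -5.0

    def test_empty_stratum_skipped_and_counts_conserve(self):
        diff = difference(make_raster([[1.0, 2.0, 3.0]], valid=[[1, 0, 1]]),
                          make_raster([[0.0, 0.0, 0.0]]))
        anc = make_partition([[1, 2, 0]])  # code 2 has no valid pixel; one cell unclassified
        strata, info = stratified_difference(diff, anc)
        assert info["skipped"] == [2]
        assert sum(s.n for s in strata) + info["n_unclassified"] == 2

    def test_requires_difference_flag(self):
        r = make_raster([[1.0]])
        with pytest.raises(ValueError):
            stratified_difference(r, make_partition([[1]]))


class TestForestMask:
    def test_nested_mask_lowers_total(self):
        truth, _ = _landscape(seed=1)
        small = perturb(truth, PerturbationSpec("mask_morph", radius=-3))
        small.label, truth.label = "small", "full"
        finding = ev.test_forest_mask([truth, small])
        assert finding.verdict == "consistent"

    def test_small_mask_high_bias_is_inconsistent(self):
        truth, _ = _landscape(seed=2)
        biased = perturb(perturb(truth, PerturbationSpec("mask_morph", radius=-3)),
                         PerturbationSpec("bias", b=30.0))
        biased.label, truth.label = "biased_small", "full"
        finding = ev.test_forest_mask([truth, biased])
        assert finding.verdict == "inconsistent"
        assert "biased_small" in finding.rationale

    def test_single_map_inconclusive(self):
        truth, _ = _landscape(seed=3)
        assert ev.test_forest_mask([truth]).verdict == "inconclusive"

    def test_identical_maps_inconclusive(self):
        truth, _ = _landscape(seed=4)
        assert ev.test_forest_mask([truth, truth.copy()]).verdict == "inconclusive"


class TestResolution:
    def test_aggregated_copy_is_compressed(self):
        truth, partition = _landscape(seed=5)
        coarse = perturb(truth, PerturbationSpec("coarsen", factor=8))
        coarse.label, truth.label = "coarse", "fine"
        finding = ev.test_resolution([truth], [coarse], partition)
        assert finding.verdict == "consistent"

    def test_identical_groups_inconclusive(self):
        truth, partition = _landscape(seed=6)
        assert ev.test_resolution([truth], [truth.copy()],
                               partition).verdict == "inconclusive"

    def test_reversed_grouping_inconsistent(self):
        truth, partition = _landscape(seed=7)
        coarse = perturb(truth, PerturbationSpec("coarsen", factor=8))
        finding = ev.test_resolution([coarse], [truth], partition)
        assert finding.verdict == "inconsistent"


class TestSensorSaturation:
    def test_capped_copy_is_consistent(self):
        truth, partition = _landscape(seed=8)
        capped = perturb(truth, PerturbationSpec("saturate", s=125.0))
        capped.label, truth.label = "passive", "active"
        finding = ev.test_sensor_saturation([truth], [capped], partition)
        assert finding.verdict == "consistent"

    def test_identical_groups_inconclusive(self):
        truth, partition = _landscape(seed=9)
        finding = ev.test_sensor_saturation([truth], [truth.copy()], partition)
        assert finding.verdict == "inconclusive"

    def test_mixed_active_group_detail(self):
        """One active map with elevated upper tail leaves the group verdict
        inconclusive while the per-map table distinguishes the outcomes."""
        truth, partition = _landscape(seed=10)
        elevated = perturb(truth, PerturbationSpec("scale", k=1.3))
        capped = perturb(truth, PerturbationSpec("saturate", s=125.0))
        elevated.label, truth.label, capped.label = "act_hi", "act_lo", "pas"
        finding = ev.test_sensor_saturation([elevated, truth], [capped], partition)
        assert "fraction_p90_below_all_active" in finding.metrics.columns


class TestExtrapolation:
    def test_shrunk_copy_is_consistent(self):
        truth, partition = _landscape(seed=11)
        shrunk = perturb(truth, PerturbationSpec("shrinkage", lam=0.7))
        finding = ev.test_extrapolation([shrunk], [truth], partition)
        assert finding.verdict == "consistent"

    def test_identical_groups_inconclusive(self):
        truth, partition = _landscape(seed=12)
        assert ev.test_extrapolation([truth], [truth.copy()],
                                  partition).verdict == "inconclusive"

    def test_shrunk_map_in_wrong_group_inconsistent(self):
        truth, partition = _landscape(seed=13)
        shrunk = perturb(truth, PerturbationSpec("shrinkage", lam=0.7))
        finding = ev.test_extrapolation([truth], [shrunk], partition)
        assert finding.verdict == "inconsistent"


class TestYearEffect:
    def _proxy(self, seed=14, shape=(80, 80)):
        grid = GridSpec(0, 0, 240.0, *shape)
        field = gaussian_random_field(grid, 0, 10, 4, seed=seed)
        proxy = make_raster(field.values - field.values.mean(),
                            cell_size=240.0, is_difference=True)
        return grid, proxy

    def test_exact_proxy_fully_consistent(self):
        grid, proxy = self._proxy()
        diff = proxy.copy()
        finding = ev.test_year_effect(diff, proxy)
        assert finding.verdict == "consistent"
        assert finding.metrics["consistency_fraction"].iloc[0] == pytest.approx(1.0)
        assert finding.metrics["slope"].iloc[0] == pytest.approx(1.0)

    def test_independent_difference_inconsistent(self):
        grid, proxy = self._proxy(seed=15, shape=(100, 100))
        rng = np.random.default_rng(16)
        diff = make_raster(rng.normal(0, 10, grid.shape), cell_size=240.0,
                           is_difference=True)
        finding = ev.test_year_effect(diff, proxy)
        assert finding.verdict == "inconsistent"
        assert finding.metrics["consistency_fraction"].iloc[0] < 0.05

    def test_variance_partition_arithmetic(self):
        grid, proxy = self._proxy(seed=17, shape=(100, 100))
        rng = np.random.default_rng(18)
        noise_sd = float(proxy.values.std()) * np.sqrt(1.2)
        diff = make_raster(proxy.values + rng.normal(0, noise_sd, grid.shape),
                           cell_size=240.0, is_difference=True)
        finding = ev.test_year_effect(diff, proxy)
        frac = finding.metrics["consistency_fraction"].iloc[0]
        assert frac == pytest.approx(1 / 2.2, abs=0.03)

    def test_constant_proxy_rejected(self):
        diff = make_raster(np.random.default_rng(0).normal(0, 5, (10, 10)),
                           is_difference=True)
        proxy = make_raster(np.zeros((10, 10)), is_difference=True)
        with pytest.raises(DegenerateFitError):
            ev.test_year_effect(diff, proxy)


class TestAllometry:
    def test_uniform_scaling_consistent(self):
        truth, partition = _landscape(seed=19)
        crm = perturb(truth, PerturbationSpec("scale", k=0.9))
        finding = ev.test_allometry([crm], [truth], partition)
        assert finding.verdict == "consistent"

    def test_offending_map_named(self):
        truth, partition = _landscape(seed=20)
        low = perturb(truth, PerturbationSpec("scale", k=0.9))
        high = perturb(truth, PerturbationSpec("scale", k=1.1))
        low.label, high.label, truth.label = "crm_lo", "crm_hi", "reg"
        finding = ev.test_allometry([low, high], [truth], partition)
        assert finding.verdict == "inconclusive"
        assert "crm_hi" in finding.rationale

    def test_identical_groups_inconclusive(self):
        truth, partition = _landscape(seed=21)
        assert ev.test_allometry([truth], [truth.copy()],
                              partition).verdict == "inconclusive"


class TestVerdictStability:
    def test_map_order_does_not_change_verdicts(self):
        truth, partition = _landscape(seed=22)
        coarse = perturb(truth, PerturbationSpec("coarsen", factor=4))
        other = perturb(truth, PerturbationSpec("noise", noise_sd=5.0), seed=1)
        v1 = ev.test_resolution([truth, other], [coarse], partition).verdict
        v2 = ev.test_resolution([other, truth], [coarse], partition).verdict
        assert v1 == v2
        m1 = ev.test_forest_mask([truth, other, coarse]).verdict
        m2 = ev.test_forest_mask([coarse, truth, other]).verdict
        assert m1 == m2
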