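"""Synthetic scenario generator: plume structure, counties, determinism."""

import dataclasses
import math

import numpy as np
import pytest

from airburden.exposure import average_rates
from airburden.grid import PrecursorPollutantPair, SourceDefinition, make_grid
from airburden.synthetic import (
    DispersionSpec,
    default_config,
    default_seasonal_profiles,
    generate_counties,
    generate_plume,
    generate_scenario,
    scale_state_emissions,
)


def point_source(tons=100.0, cell=(5, 5), sector="RC", precursor="POC"):
    return SourceDefinition("S1", sector,
                            {"JAN": {precursor: tons}, "JUL": {precursor: tons}},
                            {cell: 1.0})


class TestGeneratePlume:
    def test_zero_emissions_give_zero_field(self, small_grid, pm_pair):
        src = point_source(tons=0.0)
        f = generate_plume(small_grid, src, "JAN", pm_pair, DispersionSpec(72.0), 1.0)
        assert np.abs(f.values).max() == 0.0

    def test_amplitude_linear_in_emissions(self, small_grid, pm_pair):
        f1 = generate_plume(small_grid, point_source(100.0), "JAN", pm_pair,
                            DispersionSpec(72.0), 2.0)
        f2 = generate_plume(small_grid, point_source(200.0), "JAN", pm_pair,
                            DispersionSpec(72.0), 2.0)
        np.testing.assert_array_equal(f2.values, 2.0 * f1.values)

    @pytest.mark.parametrize("sigma", [40.0, 72.0, 150.0])
    def test_gaussian_falloff_matches_closed_form(self, small_grid, pm_pair, sigma):
        # center-to-neighbor ratio of an isotropic Gaussian one cell (36 km) away
        src = point_source(cell=(5, 5))
        f = generate_plume(small_grid, src, "JAN", pm_pair, DispersionSpec(sigma), 1.0)
        ratio = f.values[5, 5] / f.values[5, 6]
        assert ratio == pytest.approx(math.exp(36.0 ** 2 / (2 * sigma ** 2)), rel=1e-12)

    def test_negative_multiplier_flips_whole_field(self, small_grid, o3_pair):
        src = point_source(precursor="NOX")
        f = generate_plume(small_grid, src, "JAN", o3_pair, DispersionSpec(72.0), -0.5)
        assert (f.values <= 0).all()
        assert f.values.min() < 0

    def test_advection_displaces_peak(self, pm_pair):
        g = make_grid(20, 20, 36.0)
        src = point_source(cell=(10, 10))
        f = generate_plume(g, src, "JAN", pm_pair,
                           DispersionSpec(50.0, advect_km=(72.0, 36.0)), 1.0)
        i, j = np.unravel_index(np.argmax(f.values), f.values.shape)
        assert (i, j) == (11, 12)


class TestGenerateCounties:
    def test_single_county_covers_domain(self, small_grid):
        counties = generate_counties(small_grid, 1, (100, 100), (0.01, 0.01), seed=0)
        assert len(counties) == 1
        xmin, ymin, xmax, ymax = small_grid.extent
        assert counties[0].polygon.area == pytest.approx((xmax - xmin) * (ymax - ymin))

    @pytest.mark.parametrize("n", [1, 4, 6, 7, 48])
    def test_tiling_partitions_domain(self, small_grid, n):
        counties = generate_counties(small_grid, n, (1e3, 1e6), (0.008, 0.015), seed=3)
        assert len(counties) == n
        total = sum(c.polygon.area for c in counties)
        xmin, ymin, xmax, ymax = small_grid.extent
        assert total == pytest.approx((xmax - xmin) * (ymax - ymin), rel=1e-9)
        # pairwise non-overlapping (positive-area intersections only)
        for a in range(n):
            for b in range(a + 1, n):
                inter = counties[a].polygon.intersection(counties[b].polygon)
                assert inter.area == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_reproduces_table(self, small_grid):
        a = generate_counties(small_grid, 6, (1e3, 1e6), (0.008, 0.015), seed=11)
        b = generate_counties(small_grid, 6, (1e3, 1e6), (0.008, 0.015), seed=11)
        for ca, cb in zip(a, b):
            assert ca.adult_population == cb.adult_population
            assert ca.yearly_mortality_rates == cb.yearly_mortality_rates
            assert ca.polygon.equals(cb.polygon)

    def test_rates_and_pops_within_ranges(self, small_grid):
        counties = generate_counties(small_grid, 12, (1e3, 1e6), (0.008, 0.015), seed=5)
        for c in counties:
            assert 1e3 <= c.adult_population <= 1e6
            assert 0.008 <= average_rates(c) <= 0.015

    def test_invalid_ranges_rejected(self, small_grid):
        with pytest.raises(ValueError):
            generate_counties(small_grid, 4, (0.0, 10.0), (0.01, 0.02), seed=0)
        with pytest.raises(ValueError):
            generate_counties(small_grid, 0, (1e3, 1e6), (0.01, 0.02), seed=0)


class TestSeasonalProfiles:
    def test_rc_primary_pm_winter_dominant(self):
        prof = default_seasonal_profiles()
        for prec in ("PEC", "POC", "PSO4"):
            jan, jul = prof[("RC", f"{prec}->PM25")]
            assert jan / jul > 1

    def test_egu_so2_summer_enhanced(self):
        jan, jul = default_seasonal_profiles()[("EGU", "SO2->PM25")]
        assert jul > jan > 0

    def test_nox_o3_january_negative_both_sectors(self):
        prof = default_seasonal_profiles()
        for sector in ("RC", "EGU"):
            jan, jul = prof[(sector, "NOX->O3")]
            assert jan < 0 < jul

    def test_all_multipliers_finite_and_nonzero(self):
        for (sector, key), (jan, jul) in default_seasonal_profiles().items():
            assert math.isfinite(jan) and math.isfinite(jul)
            assert jan != 0 and jul != 0


class TestGenerateScenario:
    def test_composite_is_exact_superposition(self):
        scen = generate_scenario(default_config(seed=2))
        for group in scen.run_groups:
            for month in ("JAN", "JUL"):
                for pair in PrecursorPollutantPair.all_pairs():
                    comp = scen.composites[(group.run_id, month, pair.key)]
                    total = sum(scen.ground_truth[(sid, group.sector, month, pair.key)]
                                .values for sid in group.state_ids)
                    np.testing.assert_array_equal(comp.values, total)

    def test_singleton_group_composite_equals_ground_truth(self):
        cfg = default_config(seed=2)
        cfg = dataclasses.replace(cfg, groupings=[("G1", ["S1"])])
        scen = generate_scenario(cfg)
        for month in ("JAN", "JUL"):
            comp = scen.composites[("G1-RC", month, "POC->PM25")]
            gt = scen.ground_truth[("S1", "RC", month, "POC->PM25")]
            np.testing.assert_array_equal(comp.values, gt.values)

    def test_regeneration_is_bit_identical(self):
        a = generate_scenario(default_config(seed=42))
        b = generate_scenario(default_config(seed=42))
        for key in a.ground_truth:
            np.testing.assert_array_equal(a.ground_truth[key].values,
                                          b.ground_truth[key].values)
        assert a.emissions.equals(b.emissions)
        for ca, cb in zip(a.counties, b.counties):
            assert ca.adult_population == cb.adult_population

    def test_emission_scaling_scales_ground_truth_exactly(self):
        cfg = default_config(seed=3)
        scen = generate_scenario(cfg)
        scen2 = generate_scenario(scale_state_emissions(cfg, "S1", 3.0))
        for month in ("JAN", "JUL"):
            for pair in PrecursorPollutantPair.all_pairs():
                base = scen.ground_truth[("S1", "RC", month, pair.key)].values
                scaled = scen2.ground_truth[("S1", "RC", month, pair.key)].values
                np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-12)
                other = scen2.ground_truth[("S2", "RC", month, pair.key)].values
                np.testing.assert_array_equal(
                    other, scen.ground_truth[("S2", "RC", month, pair.key)].values)

    def test_run_group_sector_mismatch_rejected(self):
        cfg = default_config(seed=0)
        with pytest.raises(ValueError, match="undefined states"):
            dataclasses.replace(cfg, groupings=[("G1", ["S1", "NOPE"])])
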