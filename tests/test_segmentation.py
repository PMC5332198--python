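"""Seeded best-first region growing: seeds, growth, splitting, QA accounting."""

import dataclasses
import itertools

import numpy as np
import pytest

from airburden.exposure import ExposureGrid
from airburden.grid import (
    PrecursorPollutantPair,
    SensitivityField,
    SourceDefinition,
    make_grid,
)
from airburden.health import PM25_CRF, annualized_mortality, crf_for
from airburden.segmentation import (
    BACKGROUND,
    OMITTED,
    qa_run,
    read_label_map,
    region_grow,
    select_seeds,
    split_run,
    write_label_map,
)
from airburden.synthetic import (
    DispersionSpec,
    default_config,
    generate_plume,
    generate_scenario,
)


PAIR = PrecursorPollutantPair("POC", "PM25")


def source_at(cell, state_id="S1", tons=100.0):
    return SourceDefinition(state_id, "RC",
                            {"JAN": {"POC": tons}, "JUL": {"POC": tons}},
                            {cell: 1.0})


def two_plume_field(grid, cell_a, cell_b, sigma_km=72.0, tons_a=100.0, tons_b=100.0,
                    sign=1.0, run_id="G"):
    sa, sb = source_at(cell_a, "SA", tons_a), source_at(cell_b, "SB", tons_b)
    fa = generate_plume(grid, sa, "JAN", PAIR, DispersionSpec(sigma_km), sign)
    fb = generate_plume(grid, sb, "JAN", PAIR, DispersionSpec(sigma_km), sign)
    comp = SensitivityField(grid, run_id, "JAN", PAIR, fa.values + fb.values)
    return comp, (sa, fa), (sb, fb)


def uniform_exposure(grid, pop=1e5, rate=0.01):
    return ExposureGrid(grid, np.full(grid.shape, pop), np.full(grid.shape, rate))


class TestSelectSeeds:
    def test_single_member_peak_cell(self):
        g = make_grid(12, 12, 36.0)
        src = source_at((6, 6))
        f = generate_plume(g, src, "JAN", PAIR, DispersionSpec(72.0), 1.0)
        assert select_seeds(f, [src]) == {"S1": (6, 6)}

    def test_disjoint_plumes_seed_at_own_peaks(self):
        g = make_grid(12, 30, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (6, 5), (6, 24))
        seeds = select_seeds(comp, [sa, sb])
        assert seeds == {"SA": (6, 5), "SB": (6, 24)}

    def test_tie_breaks_to_lexicographically_smaller_cell(self):
        g = make_grid(4, 4, 36.0)
        vals = np.zeros(g.shape)
        vals[1, 1] = vals[2, 2] = 5.0
        f = SensitivityField(g, "R", "JAN", PAIR, vals)
        src = SourceDefinition("S1", "RC", {}, {(1, 1): 0.5, (2, 2): 0.5})
        assert select_seeds(f, [src]) == {"S1": (1, 1)}

    def test_zero_field_falls_back_to_max_weight_cell(self):
        g = make_grid(4, 4, 36.0)
        f = SensitivityField.zeros(g, "R", "JAN", PAIR)
        src = SourceDefinition("S1", "RC", {}, {(1, 1): 0.3, (2, 2): 0.7})
        assert select_seeds(f, [src]) == {"S1": (2, 2)}

    def test_negative_peak_found_by_magnitude(self):
        g = make_grid(12, 12, 36.0)
        src = source_at((6, 6), tons=100.0)
        f = generate_plume(g, src, "JAN", PrecursorPollutantPair("NOX", "O3"),
                           DispersionSpec(72.0), -1.0)
        src_nox = SourceDefinition("S1", "RC", {"JAN": {"NOX": 100.0}}, {(6, 6): 1.0})
        assert select_seeds(f, [src_nox]) == {"S1": (6, 6)}


class TestRegionGrow:
    def test_single_plume_fully_claimed_no_omission(self):
        g = make_grid(14, 14, 36.0)
        src = source_at((7, 7))
        f = generate_plume(g, src, "JAN", PAIR, DispersionSpec(60.0), 1.0)
        lm = region_grow(f, {"S1": (7, 7)})
        above = np.abs(f.values) >= 1e-6 * np.abs(f.values).max()
        assert (lm.labels[above] == 0).all()
        assert not lm.omitted_mask.any()

    def test_separated_plumes_match_dominant_contributor_oracle(self):
        g = make_grid(14, 40, 36.0)
        # separation far beyond the above-floor radius at this floor
        comp, (sa, fa), (sb, fb) = two_plume_field(g, (7, 6), (7, 33), sigma_km=40.0)
        floor = 1e-4 * np.abs(comp.values).max()
        lm = region_grow(comp, select_seeds(comp, [sa, sb]), background_floor=floor)
        assert not lm.omitted_mask.any()
        oracle = np.where(np.abs(fa.values) >= np.abs(fb.values), "SA", "SB")
        for sid in ("SA", "SB"):
            assert (oracle[lm.state_mask(sid)] == sid).all()
        # both regions non-trivial
        assert lm.state_mask("SA").sum() > 10 and lm.state_mask("SB").sum() > 10

    def test_all_negative_plume_labeled_like_positive_mirror(self):
        g = make_grid(14, 14, 36.0)
        src = source_at((7, 7))
        pos = generate_plume(g, src, "JAN", PAIR, DispersionSpec(60.0), 1.0)
        neg = pos.with_values(-pos.values)
        lm_pos = region_grow(pos, {"S1": (7, 7)})
        lm_neg = region_grow(neg, {"S1": (7, 7)})
        np.testing.assert_array_equal(lm_pos.labels, lm_neg.labels)

    def test_contested_midline_between_equal_plumes_is_omitted(self):
        g = make_grid(11, 21, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (5, 6), (5, 14), sigma_km=80.0)
        lm = region_grow(comp, select_seeds(comp, [sa, sb]))
        assert lm.omitted_mask.any()
        # omitted cells sit between the two regions, not inside either core
        omitted_cols = np.where(lm.omitted_mask.any(axis=0))[0]
        assert omitted_cols.min() > 6 and omitted_cols.max() < 14

    def test_member_order_invariance(self):
        g = make_grid(11, 21, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (5, 6), (5, 14), sigma_km=80.0,
                                                 tons_b=70.0)
        seeds = select_seeds(comp, [sa, sb])
        for perm in itertools.permutations(seeds.items()):
            lm = region_grow(comp, dict(perm))
            np.testing.assert_array_equal(
                lm.labels, region_grow(comp, seeds).labels)

    def test_regions_are_connected_and_contain_seed(self):
        from scipy.ndimage import label as cc_label
        g = make_grid(11, 21, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (5, 6), (5, 14), sigma_km=80.0,
                                                 tons_b=60.0)
        seeds = select_seeds(comp, [sa, sb])
        lm = region_grow(comp, seeds)
        for sid in ("SA", "SB"):
            mask = lm.state_mask(sid)
            n_components = cc_label(mask, structure=np.ones((3, 3)))[1]
            assert n_components == 1
            assert mask[seeds[sid]]

    def test_duplicate_seeds_rejected(self):
        g = make_grid(5, 5, 36.0)
        f = SensitivityField(g, "R", "JAN", PAIR, np.ones(g.shape))
        with pytest.raises(ValueError, match="duplicate seed"):
            region_grow(f, {"A": (2, 2), "B": (2, 2)})

    def test_background_floor_excludes_weak_cells(self):
        g = make_grid(14, 14, 36.0)
        src = source_at((7, 7))
        f = generate_plume(g, src, "JAN", PAIR, DispersionSpec(45.0), 1.0)
        floor = 0.1 * f.values.max()
        lm = region_grow(f, {"S1": (7, 7)}, background_floor=floor)
        weak = np.abs(f.values) < floor
        weak[7, 7] = False  # the seed itself is always attributed
        assert (lm.labels[weak] == BACKGROUND).all()


class TestSplitRun:
    def test_masking_partition_resums_exactly(self):
        g = make_grid(11, 21, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (5, 6), (5, 14), sigma_km=80.0)
        lm = region_grow(comp, select_seeds(comp, [sa, sb]))
        parts = split_run(comp, lm)
        resum = sum(p.values for p in parts.values())
        resum = resum + np.where(lm.omitted_mask, comp.values, 0.0)
        resum = resum + np.where(lm.background_mask, comp.values, 0.0)
        np.testing.assert_allclose(resum, comp.values, rtol=1e-12, atol=0)

    def test_singleton_run_keeps_all_non_background(self):
        g = make_grid(14, 14, 36.0)
        src = source_at((7, 7))
        f = generate_plume(g, src, "JAN", PAIR, DispersionSpec(60.0), 1.0)
        lm = region_grow(f, {"S1": (7, 7)})
        part = split_run(f, lm)["S1"]
        np.testing.assert_array_equal(
            part.values[~lm.background_mask], f.values[~lm.background_mask])

    def test_metadata_mismatch_rejected(self):
        g = make_grid(11, 21, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (5, 6), (5, 14))
        lm = region_grow(comp, select_seeds(comp, [sa, sb]))
        other = SensitivityField(g, "OTHER", "JAN", PAIR, comp.values)
        with pytest.raises(ValueError, match="does not match"):
            split_run(other, lm)

    def test_attributed_impacts_close_to_ground_truth(self):
        g = make_grid(16, 34, 36.0)
        comp, (sa, fa), (sb, fb) = two_plume_field(g, (8, 8), (8, 25), sigma_km=72.0,
                                                   tons_b=80.0)
        exp = uniform_exposure(g)
        lm = region_grow(comp, select_seeds(comp, [sa, sb]))
        parts = split_run(comp, lm)
        for sid, gt in (("SA", fa), ("SB", fb)):
            attributed = annualized_mortality(parts[sid], exp, PM25_CRF)
            truth = annualized_mortality(gt, exp, PM25_CRF)
            assert attributed == pytest.approx(truth, rel=0.15)


class TestQaRun:
    def _segmented(self, sep=8, sigma=80.0):
        g = make_grid(11, 21, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (5, 6), (5, 6 + sep), sigma_km=sigma)
        lm = region_grow(comp, select_seeds(comp, [sa, sb]))
        return comp, lm, uniform_exposure(g)

    def test_no_omitted_cells_gives_zero_fraction(self):
        g = make_grid(14, 14, 36.0)
        src = source_at((7, 7))
        f = generate_plume(g, src, "JAN", PAIR, DispersionSpec(60.0), 1.0)
        lm = region_grow(f, {"S1": (7, 7)})
        report = qa_run(lm, f, uniform_exposure(g), PM25_CRF)
        assert report.omission_fraction == 0.0 and report.passed

    def test_full_omission_fails(self):
        g = make_grid(3, 3, 36.0)
        f = SensitivityField(g, "R", "JAN", PAIR, np.ones(g.shape))
        lm = region_grow(f, {"A": (0, 0)})
        lm.labels[lm.labels == 0] = OMITTED
        report = qa_run(lm, f, uniform_exposure(g), PM25_CRF)
        assert report.omission_fraction == pytest.approx(1.0)
        assert not report.passed
        assert report.fallback_required == ["A"]

    def test_overlapping_default_separation_below_10_percent(self):
        comp, lm, exp = self._segmented()
        report = qa_run(lm, comp, exp, PM25_CRF)
        assert 0 < report.omission_fraction < 0.10
        assert report.passed

    def test_degenerate_zero_impact_flagged(self):
        g = make_grid(3, 3, 36.0)
        f = SensitivityField(g, "R", "JAN", PAIR, np.ones(g.shape))
        lm = region_grow(f, {"A": (0, 0)})
        zero_exp = ExposureGrid(g, np.zeros(g.shape), np.zeros(g.shape))
        report = qa_run(lm, f, zero_exp, PM25_CRF)
        assert report.degenerate and report.omission_fraction == 0.0

    def test_omission_monotone_in_separation(self):
        # widening the gap between plumes never increases omitted impact share
        g = make_grid(13, 40, 36.0)
        exp = uniform_exposure(g)
        fractions = []
        for sep in (6, 10, 14, 18, 22):
            comp, (sa, _), (sb, _) = two_plume_field(g, (6, 7), (6, 7 + sep),
                                                     sigma_km=80.0)
            lm = region_grow(comp, select_seeds(comp, [sa, sb]))
            fractions.append(qa_run(lm, comp, exp, PM25_CRF).omission_fraction)
        assert all(a >= b - 1e-12 for a, b in zip(fractions, fractions[1:]))
        assert fractions[0] > fractions[-1]


class TestScenarioSegmentation:
    def test_default_scenario_runs_all_pass_qa(self):
        from airburden.exposure import intersect_to_grid
        scen = generate_scenario(default_config(seed=5))
        exp = intersect_to_grid(scen.counties, scen.grid)
        group = scen.run_groups[0]
        for month in ("JAN", "JUL"):
            comp = scen.composites[(group.run_id, month, "POC->PM25")]
            lm = region_grow(comp, select_seeds(comp, group.members))
            report = qa_run(lm, comp, exp, PM25_CRF)
            assert report.passed


class TestLabelMapIO:
    def test_raster_round_trip(self, tmp_path):
        g = make_grid(11, 21, 36.0)
        comp, (sa, _), (sb, _) = two_plume_field(g, (5, 6), (5, 14), sigma_km=80.0)
        lm = region_grow(comp, select_seeds(comp, [sa, sb]))
        write_label_map(lm, str(tmp_path / "l.csv"), str(tmp_path / "l.json"))
        back = read_label_map(str(tmp_path / "l.csv"), str(tmp_path / "l.json"))
        np.testing.assert_array_equal(back.labels, lm.labels)
        assert back.states == lm.states
        assert back.seeds == lm.seeds
        assert (back.run_id, back.month, back.pair_key) == (lm.run_id, lm.month,
                                                            lm.pair_key)
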