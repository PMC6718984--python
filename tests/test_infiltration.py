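"""Infiltration distance binning, enrichment trend and composition."""

import numpy as np
import pandas as pd
import pytest

from cimquant import synthetic
from cimquant.infiltration import (SectionPointPattern, bin_distances,
                                   cell_distances, composition_timecourse,
                                   enrichment_profile, section_counts)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def make_section(xy, pops, rim=UNIT_SQUARE, **kw):
    return SectionPointPattern(section_id="s", xy=np.asarray(xy, float),
                               population=np.asarray(pops, object),
                               rim_polygon=rim, **kw)


class TestCellDistances:
    def test_axis_aligned_offset(self):
        sec = make_section([[2.0, 0.5]], ["control"])
        d, _inc, _n = cell_distances(sec)
        assert d[0] == pytest.approx(1.0)

    def test_on_rim_is_zero_and_included(self):
        sec = make_section([[1.0, 0.5]], ["control"])
        d, included, n_excl = cell_distances(sec)
        assert d[0] == 0.0 and included.all() and n_excl == 0

    def test_corner_distance(self):
        sec = make_section([[2.0, 2.0]], ["silenced"])
        d, _inc, _n = cell_distances(sec)
        assert d[0] == pytest.approx(np.sqrt(2.0))

    def test_interior_cells_excluded(self):
        sec = make_section([[0.5, 0.5], [2.0, 0.5]], ["silenced", "silenced"])
        d, included, n_excl = cell_distances(sec)
        assert n_excl == 1 and included.tolist() == [False, True]

    def test_separate_needle_track(self):
        needle = UNIT_SQUARE * 0.5 + 2.0  # square away from the rim
        sec = make_section([[2.25, 2.25], [3.0, 0.5]],
                           ["silenced", "control"],
                           exclusion_polygon=needle)
        _d, included, n_excl = cell_distances(sec)
        assert included.tolist() == [False, True] and n_excl == 1

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_section([[1.0, 1.0]], ["control"],
                         rim=np.array([[0, 0], [1, 1], [2, 2]]))


class TestBinDistances:
    def test_arithmetic_example(self):
        # with D = 100 a cell at 55 um lands in bin 6
        bins = bin_distances([55.0, 100.0])
        assert bins[0] == 6

    def test_right_edge_closed_and_zero(self):
        bins = bin_distances([0.0, 100.0])
        assert bins.tolist() == [1, 10]

    def test_ceil_formula_matches_edge_enumeration(self, rng):
        """Brute-force bin lookup against explicit bin edges."""
        d = rng.uniform(0, 1, 10_000) * rng.uniform(50, 200)
        d[0] = d.max()  # make the max explicit
        D = d.max()
        bins = bin_distances(d)
        edges = np.linspace(0, D, 11)
        for x, b in zip(d, bins):
            # bin b covers (edges[b-1], edges[b]], with 0 in bin 1
            brute = 1 if x == 0 else int(np.searchsorted(edges, x, side="left"))
            assert b == brute

    def test_scale_invariance(self, rng):
        d = rng.uniform(0, 300, 500)
        assert np.array_equal(bin_distances(d), bin_distances(d * 7.3))

    def test_all_on_rim_warns_bin_one(self):
        with pytest.warns(UserWarning):
            bins = bin_distances([0.0, 0.0])
        assert bins.tolist() == [1, 1]


def sections_from_generator(seed, ls=0.02, lc=0.005, n_s=970, n_c=352, k=4):
    pats = []
    for i in range(k):
        cfg = synthetic.SectionGenConfig(n_silenced=n_s, n_control=n_c,
                                         decay_silenced=ls, decay_control=lc,
                                         section_id=f"s{i}", seed=seed * 1000 + i)
        pats.append(synthetic.gen_section(cfg)[0])
    return pats


class TestEnrichmentProfile:
    def test_ratio_arithmetic(self):
        # hand-placed cells: 2 bins used out of 10 is below the defined-bin
        # minimum, so build a spread pattern and check count pooling instead
        secs = sections_from_generator(1)
        enr = enrichment_profile(secs)
        assert enr.counts_silenced.sum() == 4 * 970
        assert enr.counts_control.sum() == 4 * 352
        defined = ~np.isnan(enr.ratio)
        np.testing.assert_allclose(
            enr.ratio[defined],
            enr.counts_silenced[defined] / enr.counts_control[defined])

    def test_depleted_population_gives_negative_trend(self):
        enr = enrichment_profile(sections_from_generator(2))
        assert enr.pearson_r < 0 and enr.p_value < 0.01
        assert enr.abs_r == -enr.pearson_r

    def test_exchangeable_populations_not_significant(self):
        """With identical decay rates the trend test should rarely reject:
        calibration at alpha=0.01 over seeds."""
        rejections = 0
        for seed in range(40):
            enr = enrichment_profile(
                sections_from_generator(seed + 100, ls=0.005, lc=0.005))
            rejections += enr.p_value < 0.01
        assert rejections <= 2

    def test_section_order_invariance(self):
        secs = sections_from_generator(3)
        a = enrichment_profile(secs)
        b = enrichment_profile(secs[::-1])
        assert a.pearson_r == b.pearson_r
        np.testing.assert_array_equal(a.counts_silenced, b.counts_silenced)

    def test_rigid_transform_per_section_invariance(self):
        secs = sections_from_generator(4)
        moved = []
        for i, s in enumerate(secs):
            ang = 0.7 * (i + 1)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            t = np.array([50.0 * i, -30.0 * i])
            moved.append(SectionPointPattern(
                section_id=s.section_id, xy=s.xy @ R.T + t,
                population=s.population, rim_polygon=s.rim_polygon @ R.T + t))
        a, b = enrichment_profile(secs), enrichment_profile(moved)
        assert a.pearson_r == pytest.approx(b.pearson_r, abs=1e-9)

    def test_count_conservation_with_exclusions(self):
        secs = sections_from_generator(5)
        # push a few cells inside the rim so they get excluded
        secs[0].xy[:7] = 0.0
        enr = enrichment_profile(secs)
        for pop, total in (("silenced", 4 * 970), ("control", 4 * 352)):
            counts = getattr(enr, f"counts_{pop}").sum()
            assert counts + enr.excluded[pop] == total

    def test_constant_ratio_undefined_correlation(self):
        # equal counts in every bin: ratio constant -> r undefined, p = 1
        xy, pops = [], []
        for b in range(10):
            d = 5.0 + 10.0 * b  # distances strictly inside each bin
            for pop in ("silenced", "control"):
                xy.append([1.0 + d, 0.5])
                pops.append(pop)
        xy.append([101.0, 0.5])  # pin D = 100 with one extra control pair
        pops.append("control")
        xy.append([101.0, 0.4])
        pops.append("silenced")
        sec = make_section(xy, pops)
        enr = enrichment_profile([sec])
        assert np.isnan(enr.pearson_r) and enr.p_value == 1.0

    def test_no_control_cells_propagates_error(self):
        secs = sections_from_generator(6, n_c=0)
        with pytest.raises(ValueError, match="defined ratio"):
            enrichment_profile(secs)

    def test_pseudocount_defines_empty_bins(self):
        secs = sections_from_generator(7)
        enr = enrichment_profile(secs, pseudocount=0.5)
        assert enr.n_defined_bins == 10


class TestCompositionTimecourse:
    def test_reported_schedule_gives_negative_trend(self):
        table = pd.DataFrame({
            "tumor_id": ["a", "b", "c"], "day": [18.0, 89.0, 179.0],
            "n_silenced": [67, 33, 8], "n_control": [33, 67, 92]})
        points, r, p = composition_timecourse(table)
        assert r < 0
        assert [pt.fraction_silenced_mean for pt in points] == \
            pytest.approx([0.67, 0.33, 0.08])

    def test_constant_fraction_r_undefined(self):
        table = pd.DataFrame({
            "tumor_id": list("abc"), "day": [10.0, 50.0, 90.0],
            "n_silenced": [50] * 3, "n_control": [50] * 3})
        _pts, r, p = composition_timecourse(table)
        assert np.isnan(r) and p == 1.0

    def test_generator_recovery_within_three_se(self):
        sched = [(18, 0.67), (89, 0.33), (179, 0.08)]
        table = synthetic.gen_timecourse(sched, cells_per_section=500,
                                         sections_per_tumor=3, seed=9)
        points, r, _p = composition_timecourse(table)
        assert r < 0
        for pt, (_day, f) in zip(sorted(points, key=lambda q: q.day), sched):
            se = np.sqrt(f * (1 - f) / (500 * 3))
            assert abs(pt.fraction_silenced_mean - f) < 3 * se
            assert pt.fraction_silenced_sem >= 0

    def test_zero_cell_tumor_rejected(self):
        table = pd.DataFrame({
            "tumor_id": list("abc"), "day": [1.0, 2.0, 3.0],
            "n_silenced": [5, 0, 5], "n_control": [5, 0, 5]})
        with pytest.raises(ValueError):
            composition_timecourse(table)

    def test_too_few_tumors_rejected(self):
        table = pd.DataFrame({
            "tumor_id": ["a", "b"], "day": [1.0, 2.0],
            "n_silenced": [5, 6], "n_control": [5, 4]})
        with pytest.raises(ValueError, match="3 tumors"):
            composition_timecourse(table)

    def test_section_counts_roundtrip(self):
        pats = []
        for i, day in enumerate((18.0, 89.0, 179.0)):
            cfg = synthetic.SectionGenConfig(
                n_silenced=100, n_control=50, section_id=f"s{i}",
                day=day, tumor_id=f"t{i}", seed=i)
            pats.append(synthetic.gen_section(cfg)[0])
        table = section_counts(pats)
        assert (table["n_silenced"] == 100).all()
        assert (table["n_control"] == 50).all()
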