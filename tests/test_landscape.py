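"""Patch construction, resource calendars, composition, synthetic inputs."""

import numpy as np
import pytest

from beescape.landscape import (
    PIXEL_AREA_M2,
    TASSELING_WINDOW,
    LandCoverGrid,
    Landscape,
    Patch,
    build_landscape,
    build_patches,
    composition_metrics,
    day_length_hours,
    default_class_table,
    resource_calendar,
    synthesize_landscape,
    synthesize_weather,
)


def grid_of(codes, colony=None, central=None):
    codes = np.asarray(codes)
    if colony is None:
        colony = (codes.shape[0] // 2, codes.shape[1] // 2)
    return LandCoverGrid(codes=codes, colony_rc=colony, central_mask=central)


class TestBuildPatches:
    def test_uniform_grid_single_patch(self):
        g = grid_of(np.full((3, 3), 176))
        patches = build_patches(g, min_area_m2=0)
        assert len(patches) == 1
        assert patches[0].area_m2 == pytest.approx(9 * PIXEL_AREA_M2)

    def test_diagonal_pixels_are_separate_under_rook_adjacency(self):
        codes = np.full((4, 4), 122)
        codes[0, 0] = 176
        codes[1, 1] = 176
        g = grid_of(codes)
        patches = build_patches(g, min_area_m2=0)
        assert len(patches) == 2
        merged = build_patches(g, min_area_m2=0, connectivity=8)
        assert len(merged) == 1

    def test_central_field_is_own_patch_at_distance_zero(self):
        codes = np.full((5, 5), 1)  # all corn
        central = np.zeros((5, 5), dtype=bool)
        central[2, 2] = True
        g = grid_of(codes, central=central)
        patches = build_patches(g, min_area_m2=0)
        centrals = [p for p in patches if p.is_central]
        assert len(centrals) == 1
        assert centrals[0].distance_m == 0.0
        # adjacent corn pixels form their own patch despite touching it
        assert any(not p.is_central and p.code == 1 for p in patches)

    def test_excluded_classes_dropped_and_unknown_codes_raise(self):
        g = grid_of(np.array([[111, 176], [176, 176]]))
        patches = build_patches(g, min_area_m2=0)
        assert all(p.code != 111 for p in patches)
        bad = grid_of(np.array([[999]]))
        with pytest.raises(ValueError, match="999"):
            build_patches(bad)

    def test_min_area_filter(self):
        codes = np.full((3, 3), 122)
        codes[0, 0] = 176
        g = grid_of(codes)
        assert build_patches(g, min_area_m2=10_000) == []
        assert len(build_patches(g, min_area_m2=0)) == 1

    def test_areas_are_pixel_multiples_and_bounded_by_circle(self):
        grid = synthesize_landscape(3, {"semi_natural": 0.5, "other_crop": 0.4})
        patches = build_patches(grid)
        for p in patches:
            assert p.area_m2 % PIXEL_AREA_M2 == pytest.approx(0.0)
        assert sum(p.area_m2 for p in patches) <= np.pi * 1500**2


class TestResourceCalendar:
    def test_corn_is_pollen_only_within_tasseling(self):
        p = Patch(0, 1, "corn", "crop", "other_crop", 0.25, 1e5, 0.0)
        nectar, pollen, _ = resource_calendar(p)
        assert nectar.sum() == 0.0
        lo, hi = TASSELING_WINDOW
        assert np.all(pollen[lo - 1 : hi] > 0)
        assert pollen[lo - 2] == 0.0 and pollen[hi] == 0.0

    def test_daily_pollen_scales_linearly_with_area(self):
        small = Patch(0, 1, "corn", "crop", "other_crop", 0.25, 1e4, 0.0)
        large = Patch(1, 1, "corn", "crop", "other_crop", 0.25, 2e4, 0.0)
        _, p_small, _ = resource_calendar(small)
        _, p_large, _ = resource_calendar(large)
        assert p_large.sum() == pytest.approx(2 * p_small.sum())

    def test_semi_natural_uniform_within_month(self):
        p = Patch(0, 176, "pasture", "semi_natural", "semi_natural", 1.0, 1e5, 500.0)
        _, pollen, _ = resource_calendar(p)
        june = pollen[151:181]  # days 152..181
        assert np.allclose(june, june[0])
        assert pollen[0] == 0.0  # january

    def test_central_residue_schedule_constant_over_tasseling(self):
        grid = synthesize_landscape(3, {"semi_natural": 0.5, "other_crop": 0.4})
        scape = build_landscape(grid)
        assert scape.residue_ng_g(210, 2800.0)[scape.central_index] == 2800.0
        assert scape.residue_ng_g(202, 2800.0).sum() == 0.0
        assert scape.residue_ng_g(217, 2800.0).sum() == 0.0
        conc = scape.residue_ng_g(210, 39.9)
        assert np.count_nonzero(conc) == 1  # only the test field carries residue


class TestComposition:
    def test_all_crop_circle(self):
        grid = grid_of(np.full((101, 101), 1))
        comp = composition_metrics(grid)
        assert comp["other_crop"] == pytest.approx(100.0)
        assert comp["semi_natural"] == 0.0

    def test_half_and_half_fixture(self):
        codes = np.full((101, 101), 1)
        codes[:, 50:] = 176  # right half pasture
        comp = composition_metrics(grid_of(codes))
        assert comp["other_crop"] == pytest.approx(50.0, abs=1.0)
        assert comp["semi_natural"] == pytest.approx(50.0, abs=1.0)

    def test_categories_partition_at_most_everything(self):
        grid = synthesize_landscape(5, {"semi_natural": 0.3, "other_crop": 0.5})
        comp = composition_metrics(grid)
        assert sum(comp.values()) <= 100.0 + 1e-9


class TestSynthesizeLandscape:
    def test_composition_hits_targets(self):
        targets = {"semi_natural": 0.63, "other_crop": 0.30}
        grid = synthesize_landscape(9, targets)
        comp = composition_metrics(grid)
        assert comp["semi_natural"] == pytest.approx(63.0, abs=3.0)
        assert comp["other_crop"] == pytest.approx(30.0, abs=3.0)

    def test_deterministic_under_seed(self):
        targets = {"semi_natural": 0.4, "other_crop": 0.5}
        a = synthesize_landscape(21, targets)
        b = synthesize_landscape(21, targets)
        assert np.array_equal(a.codes, b.codes)
        c = synthesize_landscape(22, targets)
        assert not np.array_equal(a.codes, c.codes)

    def test_central_field_size_and_contiguity(self):
        from scipy import ndimage

        grid = synthesize_landscape(4, {"semi_natural": 0.5, "other_crop": 0.4},
                                    central_field_ha=10.0)
        n_pixels = int(grid.central_mask.sum())
        assert n_pixels == round(10.0 * 10_000 / PIXEL_AREA_M2)  # ~111 pixels
        _, n_components = ndimage.label(grid.central_mask)
        assert n_components == 1
        assert grid.central_mask[grid.colony_rc]

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            synthesize_landscape(1, {"semi_natural": 0.8, "other_crop": 0.5})


class TestSynthesizeWeather:
    def test_deterministic_and_seasonal(self):
        a = synthesize_weather(7)
        b = synthesize_weather(7)
        assert all(x == y for x, y in zip(a, b))
        july = np.mean([w.tmax for w in a[181:212]])
        january = np.mean([w.tmax for w in a[:31]])
        assert july > january + 10

    def test_wet_day_fraction_near_configured_probability(self):
        days = synthesize_weather(11)
        wet = np.mean([w.precip > 0 for w in days])
        # binomial 95% interval around 0.3 at n=365
        assert abs(wet - 0.3) < 2 * np.sqrt(0.3 * 0.7 / 365) + 0.01

    def test_day_length_bounds_and_solstice_ordering(self):
        dl = [day_length_hours(d, 44.0) for d in range(1, 366)]
        assert all(0 <= h <= 24 for h in dl)
        assert dl[171] > dl[354]  # summer solstice day longer than winter
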