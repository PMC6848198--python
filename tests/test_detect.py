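"""SHAPES delineation, linking, Diner correction and krill classification."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_grid, shapes_bruteforce
from krillhab.detect import (
    KRILL_DB_WINDOW,
    BeamGeometry,
    ShapesParams,
    classify_krill,
    db_difference,
    detect_swarms,
    diner_correct,
)
from krillhab.grids import SENTINEL


def blob(sv, i0, i1, j0, j1, value=-60.0):
    sv[i0:i1, j0:j1] = value
    return sv


DX, DZ = 5.0, 2.0


def run_detect(sv, **kw):
    params = ShapesParams(**kw) if kw else ShapesParams()
    return detect_swarms(make_grid(sv, dx=DX, dz=DZ), params)


class TestDetect:
    def test_single_blob_measured_length(self):
        # a 30 m x 10 m blob -> one region, length within one sample width
        sv = np.full((40, 30), -90.0)
        blob(sv, 10, 16, 10, 15)  # 6 pings * 5 m = 30 m; 5 bins * 2 m = 10 m
        regions = run_detect(sv)
        assert len(regions) == 1
        assert abs(regions[0].length_m - 30.0) <= DX
        assert abs(regions[0].height_m - 10.0) <= DZ

    def test_two_blobs_link_by_gap(self):
        # 20 m gap with 15 m max linking -> 2 regions; 10 m gap -> 1 region
        sv = np.full((40, 30), -90.0)
        blob(sv, 5, 10, 10, 14)
        blob(sv, 14, 19, 10, 14)  # gap = (14-9-1)*5 = 20 m
        assert len(run_detect(sv)) == 2
        sv = np.full((40, 30), -90.0)
        blob(sv, 5, 10, 10, 14)
        blob(sv, 12, 17, 10, 14)  # gap = (12-9-1)*5 = 10 m
        assert len(run_detect(sv)) == 1

    def test_min_length_filter(self):
        sv = np.full((40, 30), -90.0)
        blob(sv, 10, 12, 10, 14)  # 10 m long < 15 m minimum
        assert run_detect(sv) == []

    def test_empty_grid_no_regions(self):
        assert run_detect(np.full((20, 20), -90.0)) == []

    def test_regions_in_ping_order(self):
        sv = np.full((60, 30), -90.0)
        blob(sv, 40, 46, 5, 10)
        blob(sv, 5, 11, 20, 25)
        regions = run_detect(sv)
        assert [r.ping_idx.min() for r in regions] == sorted(r.ping_idx.min() for r in regions)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_grids(self, seed):
        # randomized property: production detection == exhaustive
        # threshold/4-component/pairwise-link search on small grids
        rng = np.random.default_rng(seed)
        n_p, n_d = rng.integers(10, 50), rng.integers(10, 50)
        sv = np.where(rng.random((n_p, n_d)) < 0.12, -60.0, -90.0)
        params = ShapesParams(min_length_m=5.0, min_height_m=2.0,
                              max_link_horizontal_m=12.0, max_link_vertical_m=4.0)
        regions = run_detect(sv, min_length_m=5.0, min_height_m=2.0,
                             max_link_horizontal_m=12.0, max_link_vertical_m=4.0)
        got = {frozenset(zip(r.ping_idx.tolist(), r.depth_idx.tolist())) for r in regions}
        expected = shapes_bruteforce(sv, params.sv_threshold_db, DX, DZ,
                                     params.min_length_m, params.min_height_m,
                                     params.max_link_horizontal_m, params.max_link_vertical_m)
        assert got == expected

    def test_mvbs_is_linear_mean(self):
        sv = np.full((40, 30), -90.0)
        blob(sv, 10, 16, 10, 15, -60.0)
        blob(sv, 10, 13, 10, 15, -50.0)  # half the samples 10 dB hotter
        region = run_detect(sv)[0]
        expected = 10 * np.log10((1e-5 + 1e-6) / 2)
        assert region.mvbs_120 == pytest.approx(expected, abs=1e-9)


class TestDinerCorrection:
    def region_at(self, depth_bins, length_pings=30):
        sv = np.full((length_pings + 20, max(depth_bins) + 10), -90.0)
        sv[10:10 + length_pings, depth_bins[0]:depth_bins[1]] = -60.0
        return run_detect(sv)[0]

    def test_corrected_length_formula(self):
        # beam diameter at 100 m for a 7 deg beam: 2*100*tan(3.5 deg) = 12.23 m
        assert 2 * 100 * np.tan(np.radians(3.5)) == pytest.approx(12.23, abs=0.01)
        region = self.region_at((48, 53))
        corr = diner_correct(region, BeamGeometry(beam_width_deg=7.0))
        d_b = 2 * region.mean_depth_m * np.tan(np.radians(3.5))
        assert corr.corrected_length_m == pytest.approx(region.length_m - d_b, abs=1e-9)

    def test_zero_beam_width_identity(self):
        region = self.region_at((20, 25))
        corr = diner_correct(region, BeamGeometry(beam_width_deg=0.0))
        assert corr.corrected_length_m == region.length_m
        assert corr.corrected_area_m2 == pytest.approx(region.area_m2, rel=1e-9)
        assert corr.corrected_perimeter_m == pytest.approx(region.perimeter_m, rel=1e-9)

    def test_sub_beam_region_flagged(self):
        # 200 m deep, 20 m long: beam diameter 24.5 m exceeds the length
        region = self.region_at((98, 103), length_pings=4)
        corr = diner_correct(region, BeamGeometry(beam_width_deg=7.0))
        assert corr.corrected_length_m <= 0
        assert corr.sub_beam_resolution

    def test_corrected_never_exceeds_measured(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            j0 = int(rng.integers(5, 80))
            region = self.region_at((j0, j0 + int(rng.integers(3, 10))), int(rng.integers(4, 40)))
            corr = diner_correct(region, BeamGeometry(beam_width_deg=7.0))
            assert corr.corrected_length_m < region.length_m
            assert corr.corrected_area_m2 <= region.area_m2 + 1e-9

    def test_rectangle_corrected_geometry_closed_form(self):
        # rectangular blob: erosion by h on each side shrinks every row equally
        region = self.region_at((30, 35), length_pings=30)
        corr = diner_correct(region, BeamGeometry(beam_width_deg=7.0))
        h = region.mean_depth_m * np.tan(np.radians(3.5))
        n_rows = 5
        width = region.length_m - 2 * h
        assert corr.corrected_area_m2 == pytest.approx(width * n_rows * DZ, rel=1e-9)
        assert corr.corrected_perimeter_m == pytest.approx(2 * width + 2 * n_rows * DZ, rel=1e-9)


class TestKrillClassification:
    def make_region(self, diff):
        sv = np.full((40, 30), -90.0)
        blob(sv, 10, 16, 10, 15, -60.0)
        grid = make_grid(sv, np.where(sv > -80, sv - diff, sv), dx=DX, dz=DZ)
        return detect_swarms(grid)[0]

    def test_db_difference_recovers_planted(self):
        region = self.make_region(9.0)
        assert db_difference(region) == pytest.approx(9.0, abs=1e-6)

    @pytest.mark.parametrize("diff,expected", [
        (1.04, True), (14.80, True),  # closed window includes both bounds
        (0.90, False), (15.0, False), (1.03, False), (14.81, False),
        (9.0, True),
    ])
    def test_window_boundaries_inclusive(self, diff, expected):
        # boundary semantics checked on exact dB differences (MVBS set
        # directly; the log/exp round trip through a grid would perturb the
        # boundary by ~1e-14 dB)
        base = self.make_region(9.0)
        base.mvbs_120 = diff
        base.mvbs_38 = 0.0
        assert classify_krill(base) is expected

    def test_masked_38_channel_raises(self):
        sv = np.full((40, 30), -90.0)
        blob(sv, 10, 16, 10, 15, -60.0)
        grid = make_grid(sv, np.full_like(sv, SENTINEL), dx=DX, dz=DZ)
        region = detect_swarms(grid)[0]
        with pytest.raises(ValueError, match="fully masked"):
            db_difference(region)
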