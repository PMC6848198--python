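"""The synthetic survey generator: determinism, planted ground truth,
whale placement link, effort structure."""

import numpy as np
import pandas as pd
import pytest

from krillhab.clean import tvg_db
from krillhab.grids import SENTINEL
from krillhab.simulate import (
    EffortSchedule,
    PlantedAggregation,
    SimConfig,
    WhalePlacement,
    ground_truth_table,
    simulate_echogram,
    simulate_whales_and_effort,
)


def tiny_config(aggs=(), seed=0, n_pings=600, **kw):
    return SimConfig(n_pings=n_pings, aggregations=list(aggs), seed=seed, **kw)


class TestEchogram:
    def test_no_aggregations_pure_background(self):
        cfg = tiny_config(noise_jitter_db=0.0)
        grid, aggs = simulate_echogram(cfg)
        assert aggs == []
        expected = cfg.noise_floor_db[120] + tvg_db(grid.depth, cfg.alpha_db_per_m[120])
        np.testing.assert_allclose(grid.sv_120, np.broadcast_to(expected, grid.sv_120.shape), atol=1e-9)

    def test_planted_mask_equals_ellipse_when_noise_negligible(self):
        agg = PlantedAggregation(300, 100.0, 40.0, 10.0, -60.0, 9.0)
        cfg = tiny_config([agg], noise_floor_db={38: -999.0, 120: -999.0},
                          noise_jitter_db=0.0, shape_irregularity=0.0)
        grid, _ = simulate_echogram(cfg)
        hot = grid.sv_120 > -70.0
        xs = (np.arange(cfg.n_pings) + 0.5) * cfg.dx_m
        zs = cfg.depth_centres()
        x0 = (agg.centroid_ping + 0.5) * cfg.dx_m
        ellipse = ((xs[:, None] - x0) / 40.0) ** 2 + ((zs[None, :] - 100.0) / 10.0) ** 2 <= 1.0
        np.testing.assert_array_equal(hot, ellipse)
        # planted Sv recovered on the mask, at both frequencies
        assert grid.sv_120[ellipse].max() == pytest.approx(-60.0, abs=0.01)
        assert (grid.sv_120[ellipse] - grid.sv_038[ellipse]).mean() == pytest.approx(9.0, abs=0.01)

    def test_same_seed_identical_different_seed_not(self):
        agg = PlantedAggregation(300, 100.0, 40.0, 10.0, -60.0, 9.0)
        g1, _ = simulate_echogram(tiny_config([agg], seed=5))
        g2, _ = simulate_echogram(tiny_config([agg], seed=5))
        g3, _ = simulate_echogram(tiny_config([agg], seed=6))
        np.testing.assert_array_equal(g1.sv_120, g2.sv_120)
        assert not np.array_equal(g1.sv_120, g3.sv_120)

    @pytest.mark.parametrize("agg", [
        PlantedAggregation(5, 100.0, 200.0, 10.0, -60.0, 9.0),    # off the track start
        PlantedAggregation(300, 245.0, 40.0, 10.0, -60.0, 9.0),   # below max depth
    ])
    def test_out_of_grid_aggregation_rejected(self, agg):
        with pytest.raises(ValueError, match="outside"):
            simulate_echogram(tiny_config([agg]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_echogram(SimConfig(n_pings=0))


class TestWhalePlacement:
    def test_null_betas_presence_independent_of_traits(self):
        cfg = SimConfig.survey(n_swarms=400, seed=3,
                               whale_placement=WhalePlacement(beta0=-1.0, beta_density=0, beta_depth=0, beta_height=0))
        truth, _, _ = simulate_whales_and_effort(cfg, cfg.aggregations)
        assert np.allclose(truth.placement_prob, truth.placement_prob[0])

    def test_density_link_raises_presence_in_top_tercile(self):
        # over >= 1000 swarms, a strong density coefficient concentrates
        # placement in the densest tercile
        cfg = SimConfig.survey(
            n_swarms=1200, seed=4,
            whale_placement=WhalePlacement(beta0=-1.0, beta_density=3.0, beta_depth=0.0, beta_height=0.0),
        )
        truth, _, _ = simulate_whales_and_effort(cfg, cfg.aggregations)
        sv = np.array([a.sv120_db for a in cfg.aggregations])
        terciles = np.quantile(sv, [1 / 3, 2 / 3])
        lo = truth.placed[sv <= terciles[0]].mean()
        hi = truth.placed[sv >= terciles[1]].mean()
        assert hi > lo + 0.2

    def test_zero_effort_zero_observations(self):
        cfg = SimConfig.survey(
            n_swarms=100, seed=2,
            effort=EffortSchedule(fraction_none=1.0, fraction_visual=0, fraction_acoustic=0, fraction_both=0),
        )
        _, obs, effort = simulate_whales_and_effort(cfg, cfg.aggregations)
        assert len(obs.sightings) == 0 and len(obs.bearing_pairs) == 0
        assert len(effort) == 0

    def test_determinism(self):
        cfg1 = SimConfig.survey(n_swarms=100, seed=8)
        cfg2 = SimConfig.survey(n_swarms=100, seed=8)
        t1, o1, e1 = simulate_whales_and_effort(cfg1, cfg1.aggregations)
        t2, o2, e2 = simulate_whales_and_effort(cfg2, cfg2.aggregations)
        pd.testing.assert_frame_equal(t1.whales, t2.whales)
        pd.testing.assert_frame_equal(o1.sightings_frame(), o2.sightings_frame())
        pd.testing.assert_frame_equal(e1, e2)


class TestEffortSchedule:
    def test_partition_proportions_reproduced(self):
        # effort fractions configured to the observed 559/667/125/337 partition
        cfg = SimConfig.voyage(seed=1)
        _, _, effort = simulate_whales_and_effort(cfg, cfg.aggregations)
        from krillhab.associate import effort_filter

        table = ground_truth_table(cfg.aggregations, cfg)
        tagged = effort_filter(table, effort)
        frac = tagged["effort_tag"].value_counts(normalize=True)
        targets = cfg.effort.fractions()
        for kind in ("none", "visual", "acoustic", "both"):
            assert frac.get(kind, 0.0) == pytest.approx(targets[kind], abs=0.06)

    def test_visual_effort_only_in_daylight(self):
        from krillhab.locate import solar_altitude

        cfg = SimConfig.voyage(seed=2)
        _, _, effort = simulate_whales_and_effort(cfg, cfg.aggregations)
        vis = effort[effort["kind"] == "visual"]
        mids = vis["start"] + (vis["end"] - vis["start"]) / 2
        for t in mids:
            lat, lon = cfg.position_at(t)
            assert solar_altitude(lat, lon, t) > -1.0  # block centres in daylight


class TestGroundTruth:
    def test_row_count_and_krill_flag(self):
        cfg = SimConfig.voyage(seed=0)
        table = ground_truth_table(cfg.aggregations, cfg)
        assert len(table) == len(cfg.aggregations)
        for _, row in table.sample(20, random_state=0).iterrows():
            assert row["is_krill"] == (1.04 <= row["db_difference"] <= 14.80)

    def test_joins_to_detected_swarms_by_centroid(self, small_survey):
        # nearest-centroid match links detected swarms back to planted truth
        truth = small_survey.truth_table
        detected = small_survey.swarm_table
        assert len(detected) > 0
        t_ping = truth["centroid_ping"].to_numpy()
        matched = 0
        for _, row in detected.iterrows():
            dt = (pd.Timestamp(row["time"]) - small_survey.config.start_time).total_seconds()
            ping = dt / small_survey.config.ping_interval_s
            if np.abs(t_ping - ping).min() < 60:
                matched += 1
        assert matched / len(detected) > 0.9


class TestRecoveryRate:
    def test_strong_plants_recovered(self, small_survey):
        # planted krill well above threshold and above minimum size are
        # recovered by the full detection chain
        truth = small_survey.truth_table
        detected = small_survey.swarm_table
        strong = truth[(truth["sv120_db"] >= -60.0) & (truth["length_m"] >= 40) & (truth["height_m"] >= 8)]
        cfg = small_survey.config
        det_pings = (
            (pd.DatetimeIndex(detected["time"]) - cfg.start_time).total_seconds() / cfg.ping_interval_s
        ).to_numpy()
        recovered = sum(np.abs(det_pings - p).min() < 30 for p in strong["centroid_ping"])
        assert recovered / len(strong) >= 0.95
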