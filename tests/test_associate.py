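"""Effort/heading filters, presence labels, outlier removal, split."""

import numpy as np
import pandas as pd
import pytest

from conftest import presence_bruteforce, quantile_outliers_bruteforce
from krillhab.associate import (
    SCALES,
    OutlierRule,
    ScaleThreshold,
    classify_presence,
    effort_filter,
    heading_filter,
    remove_outliers,
    stratified_split,
)
from krillhab.characterise import COVARIATES


def swarm_frame(times, lats=None, lons=None):
    n = len(times)
    return pd.DataFrame(
        {
            "time": pd.DatetimeIndex(times),
            "lat": lats if lats is not None else np.full(n, -65.5),
            "lon": lons if lons is not None else np.full(n, 174.0),
        }
    )


class TestHeadingFilter:
    def test_constant_heading_keeps_all(self):
        t = pd.date_range("2015-02-17", periods=3600, freq="s")
        records = swarm_frame(t[::600])
        out = heading_filter(records, t, np.full(3600, 90.0))
        assert len(out) == len(records)

    def test_alternating_heading_removed(self):
        t = pd.date_range("2015-02-17", periods=3600, freq="s")
        headings = np.where(np.arange(3600) % 2 == 0, 0.0, 180.0)
        out = heading_filter(swarm_frame([t[1800]]), t, headings)
        assert len(out) == 0

    def test_planted_turn_windows_removed_exactly(self):
        # swarms inside oscillating-heading windows drop; the rest stay
        t = pd.date_range("2015-02-17", periods=7200, freq="s")
        headings = np.full(7200, 90.0)
        headings[2000:3000] = 90 + 80 * np.sin(np.arange(1000) / 30.0)
        swarm_t = [t[500], t[2500], t[5000]]
        out = heading_filter(swarm_frame(swarm_t), t, headings)
        assert pd.DatetimeIndex(out["time"]).tolist() == [t[500], t[5000]]

    def test_no_coverage_kept_with_warning(self):
        t = pd.date_range("2015-02-17", periods=100, freq="s")
        with pytest.warns(UserWarning, match="heading coverage"):
            out = heading_filter(swarm_frame([pd.Timestamp("2015-03-01")]), t, np.full(100, 90.0))
        assert len(out) == 1


class TestEffortFilter:
    def intervals(self):
        return pd.DataFrame(
            {
                "start": pd.to_datetime(["2015-02-17T00:00", "2015-02-17T01:30"]),
                "end": pd.to_datetime(["2015-02-17T02:00", "2015-02-17T03:00"]),
                "kind": ["visual", "acoustic"],
            }
        )

    def test_tags(self):
        records = swarm_frame(pd.to_datetime([
            "2015-02-17T00:30",  # visual only
            "2015-02-17T01:45",  # both overlap
            "2015-02-17T02:30",  # acoustic only
            "2015-02-17T05:00",  # none
        ]))
        out = effort_filter(records, self.intervals())
        assert out["effort_tag"].tolist() == ["visual", "both", "acoustic", "none"]


class TestClassifyPresence:
    def detection(self, dt_minutes, dist_km, t0=pd.Timestamp("2015-02-17T12:00")):
        from krillhab.locate import destination_point

        lat, lon = destination_point(-65.5, 174.0, 45.0, dist_km * 1000)
        return pd.DataFrame({"time": [t0 + pd.Timedelta(minutes=dt_minutes)], "lat": [lat], "lon": [lon]})

    def test_within_both_thresholds_present(self):
        records = swarm_frame([pd.Timestamp("2015-02-17T12:00")])
        dets = self.detection(50, 11.0)
        assert classify_presence(records, dets, ScaleThreshold(12, 1, "12"))[0]

    def test_monotone_across_nested_scales(self):
        records = swarm_frame([pd.Timestamp("2015-02-17T12:00")])
        dets = self.detection(30, 15.0)  # 15 km & 30 min
        flags = [classify_presence(records, dets, s)[0] for s in SCALES]
        assert flags == [False, True, True]

    def test_empty_detections_all_absent(self):
        records = swarm_frame([pd.Timestamp("2015-02-17T12:00")])
        out = classify_presence(records, pd.DataFrame(columns=["time", "lat", "lon"]), SCALES[0])
        assert not out.any()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 60, 25
        t0 = pd.Timestamp("2015-02-17")
        records = swarm_frame(
            t0 + pd.to_timedelta(rng.integers(0, 86400, n), unit="s"),
            -66 + rng.random(n), 173 + rng.random(n) * 2,
        )
        dets = pd.DataFrame(
            {
                "time": t0 + pd.to_timedelta(rng.integers(0, 86400, m), unit="s"),
                "lat": -66 + rng.random(m),
                "lon": 173 + rng.random(m) * 2,
            }
        )
        for scale in SCALES:
            got = classify_presence(records, dets, scale)
            ref = presence_bruteforce(records, dets, scale.distance_km, scale.time_h)
            np.testing.assert_array_equal(got, ref)
        # nested-scale monotonicity on the same random data
        p12 = classify_presence(records, dets, SCALES[0])
        p20 = classify_presence(records, dets, SCALES[1])
        p40 = classify_presence(records, dets, SCALES[2])
        assert np.all(p12 <= p20) and np.all(p20 <= p40)


class TestRemoveOutliers:
    def table(self, values_by_col):
        n = len(next(iter(values_by_col.values())))
        df = pd.DataFrame({c: np.ones(n) for c in COVARIATES})
        for c, v in values_by_col.items():
            df[c] = v
        return df

    def test_single_covariate_matches_sort_oracle(self):
        df = self.table({"mean_depth": np.arange(1, 1001, dtype=float)})
        got = remove_outliers(df, OutlierRule())
        ref = quantile_outliers_bruteforce(df, COVARIATES, 0.995)
        pd.testing.assert_frame_equal(got, ref)
        assert len(got) < len(df)

    def test_constant_column_removes_nothing(self):
        df = self.table({"mean_depth": np.full(100, 7.0)})
        assert len(remove_outliers(df, OutlierRule())) == 100

    def test_order_independent_union_semantics(self):
        rng = np.random.default_rng(5)
        df = self.table({c: rng.lognormal(0, 1, 500) for c in COVARIATES})
        got = remove_outliers(df, OutlierRule())
        ref = quantile_outliers_bruteforce(df, COVARIATES, 0.995)
        pd.testing.assert_frame_equal(got, ref)
        got_rev = remove_outliers(df, OutlierRule(), covariates=list(reversed(COVARIATES)))
        pd.testing.assert_frame_equal(got, got_rev)

    def test_level_validation(self):
        with pytest.raises(ValueError):
            OutlierRule(level=0.4)


class TestStratifiedSplit:
    def table(self, n_pos, n_neg):
        return pd.DataFrame(
            {"whale_present": [1] * n_pos + [0] * n_neg, "x": np.arange(n_pos + n_neg)}
        )

    def test_balanced_100_100(self):
        train, test = stratified_split(self.table(100, 100), seed=0)
        assert len(train) == 150 and len(test) == 50
        assert train["whale_present"].sum() == 75
        assert test["whale_present"].sum() == 25

    def test_per_class_rounding_arithmetic(self):
        # class sizes 663/409: round-half-even gives 497 + 307 = 804 training rows
        train, test = stratified_split(self.table(663, 409), seed=0)
        assert train["whale_present"].sum() == 497
        assert (1 - train["whale_present"]).sum() == 307
        assert len(train) == 804 and len(test) == 268

    def test_partition_properties(self):
        df = self.table(37, 61)
        train, test = stratified_split(df, seed=3)
        merged = pd.concat([train, test]).sort_values("x").reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, df)
        assert set(train["x"]).isdisjoint(set(test["x"]))

    def test_same_seed_same_split(self):
        df = self.table(50, 50)
        t1, _ = stratified_split(df, seed=9)
        t2, _ = stratified_split(df, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(self.table(1, 50), seed=0)
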