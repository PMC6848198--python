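"""Swarm-whale association: effort and heading filters, presence labels at
three nested spatiotemporal scales, quantile outlier removal and the
stratified train/test split.

A krill swarm is "in the presence of whales" at a given scale when some whale
detection lies within the scale's distance AND time thresholds (both
inclusive) of the swarm; the three scales used are {12 km, 1 h}, {20 km, 2 h}
and {40 km, 4 h}, nested so presence labels are monotone non-decreasing
across them.  Only swarms detected during whale effort (periods when the
distance to whales was measurable, visually or by paired-sonobuoy
triangulation) enter the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circstd

from .characterise import COVARIATES
from .locate import great_circle_distance, solar_altitude

__all__ = [
    "ScaleThreshold",
    "OutlierRule",
    "SCALES",
    "heading_filter",
    "effort_filter",
    "classify_presence",
    "remove_outliers",
    "stratified_split",
    "annotate_day_night",
]


@dataclass(frozen=True)
class ScaleThreshold:
    """One spatiotemporal association scale."""

    distance_km: float
    time_h: float
    label: str

    def __post_init__(self):
        if self.distance_km <= 0 or self.time_h <= 0:
            raise ValueError("scale thresholds must be positive")


SCALES = (
    ScaleThreshold(12.0, 1.0, "12km_1h"),
    ScaleThreshold(20.0, 2.0, "20km_2h"),
    ScaleThreshold(40.0, 4.0, "40km_4h"),
)


@dataclass(frozen=True)
class OutlierRule:
    """Per-covariate upper-quantile outlier removal (single pass).

    A row is removed when any covariate exceeds that covariate's
    ``level`` quantile computed on the pre-removal table.  The quantile
    estimator is linear interpolation between order statistics (numpy's
    default); the removal count is sensitive to this convention, so it is
    recorded in output metadata.
    """

    level: float = 0.995
    method: str = "linear"

    def __post_init__(self):
        if not 0.5 < self.level < 1.0:
            raise ValueError("quantile level must be in (0.5, 1)")


def heading_filter(
    records: pd.DataFrame,
    heading_times: pd.DatetimeIndex,
    headings: np.ndarray,
    window_s: float = 600.0,
    max_circ_sd_deg: float = 30.0,
) -> pd.DataFrame:
    """Drop swarms detected while the ship's heading was highly variable.

    For each swarm the circular standard deviation of the heading series in a
    centred window is compared against ``max_circ_sd_deg``.  Swarms without
    heading coverage are kept with a warning.
    """
    if len(records) == 0:
        return records.copy()
    ht = heading_times.asi8
    keep = np.ones(len(records), dtype=bool)
    uncovered = 0
    for k, t in enumerate(pd.DatetimeIndex(records["time"]).asi8):
        half = int(window_s / 2 * 1e9)
        lo = np.searchsorted(ht, t - half, side="left")
        hi = np.searchsorted(ht, t + half, side="right")
        if hi - lo < 2:
            uncovered += 1
            continue
        sd = np.degrees(circstd(np.radians(headings[lo:hi])))
        if sd > max_circ_sd_deg:
            keep[k] = False
    if uncovered:
        warnings.warn(f"{uncovered} swarms had no heading coverage and were kept")
    return records.loc[keep].reset_index(drop=True)


def effort_filter(records: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Tag each swarm with the whale-effort kind at its detection time.

    ``intervals`` has columns (start, end, kind in {visual, acoustic}) with
    union semantics (overlapping rows of both kinds mean 'both').  Returns the
    table with an ``effort_tag`` column in {visual, acoustic, both, none};
    'none' rows are reported but excluded from modelling downstream.
    """
    out = records.copy()
    times = pd.DatetimeIndex(out["time"])
    tags = []
    vis = intervals[intervals["kind"] == "visual"]
    aco = intervals[intervals["kind"] == "acoustic"]

    def covered(t, df):
        return bool(((df["start"] <= t) & (t <= df["end"])).any()) if len(df) else False

    for t in times:
        v = covered(t, vis)
        a = covered(t, aco)
        tags.append("both" if v and a else "visual" if v else "acoustic" if a else "none")
    out["effort_tag"] = tags
    return out


def classify_presence(
    records: pd.DataFrame, detections: pd.DataFrame, scale: ScaleThreshold
) -> np.ndarray:
    """Binary presence label per swarm at one scale.

    Present iff some detection satisfies great-circle distance <=
    ``scale.distance_km`` AND |dt| <= ``scale.time_h`` (both inclusive).
    """
    n = len(records)
    if len(detections) == 0:
        return np.zeros(n, dtype=bool)
    s_t = pd.DatetimeIndex(records["time"]).asi8 / 1e9
    d_t = np.sort(pd.DatetimeIndex(detections["time"]).asi8 / 1e9)
    order = np.argsort(pd.DatetimeIndex(detections["time"]).asi8 / 1e9, kind="stable")
    d_lat = detections["lat"].to_numpy()[order]
    d_lon = detections["lon"].to_numpy()[order]
    s_lat = records["lat"].to_numpy()
    s_lon = records["lon"].to_numpy()

    max_dt = scale.time_h * 3600.0
    max_d = scale.distance_km * 1000.0
    present = np.zeros(n, dtype=bool)
    for k in range(n):
        lo = np.searchsorted(d_t, s_t[k] - max_dt, side="left")
        hi = np.searchsorted(d_t, s_t[k] + max_dt, side="right")
        if hi <= lo:
            continue
        d = great_circle_distance(s_lat[k], s_lon[k], d_lat[lo:hi], d_lon[lo:hi])
        present[k] = bool(np.any(np.atleast_1d(d) <= max_d))
    return present


def remove_outliers(
    table: pd.DataFrame, rule: OutlierRule | None = None, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Single-pass removal of extreme rows: drop row i when X_ij > Q_level(X_j)
    for ANY covariate j, quantiles computed on the pre-removal table."""
    rule = rule or OutlierRule()
    covariates = covariates or COVARIATES
    if len(table) < 2:
        raise ValueError("outlier removal needs at least two rows")
    keep = np.ones(len(table), dtype=bool)
    for c in covariates:
        x = table[c].to_numpy(dtype=float)
        q = np.quantile(x[np.isfinite(x)], rule.level, method=rule.method)
        keep &= ~(x > q)
    return table.loc[keep].reset_index(drop=True)


def stratified_split(
    table: pd.DataFrame,
    response: str = "whale_present",
    train_frac: float = 0.75,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportionally stratified train/test split.

    Within each response class, ``round(train_frac * n_class)`` rows
    (round-half-to-even) go to training after a seeded shuffle, keeping the
    presence/absence ratio equal between the two sets up to rounding.
    """
    y = table[response].astype(bool)
    classes = [True, False]
    if any((y == c).sum() < 2 for c in classes):
        raise ValueError("each response class needs at least two rows to split")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = table.index[y == c].to_numpy()
        rng.shuffle(idx)
        n_train = round(train_frac * len(idx))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train = table.loc[sorted(train_idx)].reset_index(drop=True)
    test = table.loc[sorted(test_idx)].reset_index(drop=True)
    return train, test


def annotate_day_night(records: pd.DataFrame) -> pd.DataFrame:
    """Annotate each swarm with solar altitude and a day flag (altitude > 0).

    The annotation is reported (day/night tabulations) but never used for
    filtering.
    """
    out = records.copy()
    alt = solar_altitude(out["lat"].to_numpy(), out["lon"].to_numpy(), pd.DatetimeIndex(out["time"]))
    out["solar_altitude"] = alt
    out["is_day"] = out["solar_altitude"] > 0.0
    return out
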