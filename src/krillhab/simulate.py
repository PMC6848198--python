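"""Synthetic dual-frequency survey generator with known ground truth.

Emulates the observational setup of an Antarctic blue whale / krill voyage:
a ship steaming at 10 knots pinging a 38/120 kHz echosounder once per second,
TVG-shaped background noise, elliptical krill (and non-krill) aggregations
with controlled Sv and dB-difference, whale placement near swarms through a
logistic link on swarm density, depth and height, and day/night-structured
visual + passive-acoustic effort.  Every downstream stage therefore has a
recoverable target.

Swarm traits are spatially autocorrelated along the track (Gaussian-smoothed
latent fields) because the surveyed prey field showed strong geographic
stratification; whale aggregations in the simulation inherit that structure,
which is what makes presence labels at the 12-40 km association scales
informative about individual swarm traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .characterise import TSModel, ts_per_kg
from .clean import DEFAULT_ALPHA_DB_PER_M, tvg_db
from .detect import KRILL_DB_WINDOW
from .grids import EchogramGrid, db_to_linear, linear_to_db
from .locate import (
    BearingPair,
    Sighting,
    destination_point,
    great_circle_distance,
    initial_bearing,
    solar_altitude,
)

KNOT_M_S = 1852.0 / 3600.0

__all__ = [
    "PlantedAggregation",
    "WhalePlacement",
    "EffortSchedule",
    "SimConfig",
    "WhaleTruth",
    "SurveyObservations",
    "simulate_echogram",
    "simulate_whales_and_effort",
    "ground_truth_table",
]


@dataclass(frozen=True)
class PlantedAggregation:
    """An elliptical aggregation planted in the echogram."""

    centroid_ping: int
    centroid_depth_m: float
    semi_axis_h_m: float
    semi_axis_v_m: float
    sv120_db: float
    db_difference: float

    @property
    def is_krill(self) -> bool:
        return KRILL_DB_WINDOW[0] <= self.db_difference <= KRILL_DB_WINDOW[1]

    @property
    def height_m(self) -> float:
        return 2.0 * self.semi_axis_v_m

    @property
    def length_m(self) -> float:
        return 2.0 * self.semi_axis_h_m


@dataclass(frozen=True)
class WhalePlacement:
    """Logistic link placing whales near swarms.

    ``P(whale | swarm) = logit^-1(b0 + b_density*z_rho + b_depth*z_z + b_height*z_h)``
    on z-scored log biomass density, mean depth and height of the planted
    swarms.  Placed whales sit at a uniform bearing and range
    (500 m .. max_offset_m) from the swarm, at the swarm passage time plus
    uniform jitter.
    """

    beta0: float = -2.0
    beta_density: float = 2.0
    beta_depth: float = -2.0
    beta_height: float = 2.5
    max_offset_m: float = 5_000.0
    time_jitter_s: float = 1_800.0


@dataclass(frozen=True)
class EffortSchedule:
    """Target proportions of track time per effort kind.

    Visual effort (and hence 'both') is only assignable during daylight;
    blocks are ``block_s`` long and assigned to kinds by seeded shuffle so the
    realised proportions approximate the targets given the day/night split.
    """

    block_s: float = 1800.0
    fraction_none: float = 559 / 1688
    fraction_visual: float = 667 / 1688
    fraction_acoustic: float = 125 / 1688
    fraction_both: float = 337 / 1688

    def fractions(self) -> dict[str, float]:
        f = {
            "none": self.fraction_none,
            "visual": self.fraction_visual,
            "acoustic": self.fraction_acoustic,
            "both": self.fraction_both,
        }
        total = sum(f.values())
        return {k: v / total for k, v in f.items()}


@dataclass
class SimConfig:
    """Full description of a synthetic survey."""

    n_pings: int
    n_depth: int = 125
    ping_interval_s: float = 1.0
    bin_size_m: float = 2.0
    speed_knots: float = 10.0
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2015-02-17T00:00:00"))
    start_lat: float = -65.5
    start_lon: float = 174.0
    course_deg: float = 90.0
    noise_floor_db: dict = field(default_factory=lambda: {38: -155.0, 120: -152.0})
    noise_jitter_db: float = 1.5
    alpha_db_per_m: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA_DB_PER_M))
    aggregations: list[PlantedAggregation] = field(default_factory=list)
    whale_placement: WhalePlacement = field(default_factory=WhalePlacement)
    effort: EffortSchedule = field(default_factory=EffortSchedule)
    turn_windows: list[tuple[int, int]] = field(default_factory=list)  # ping ranges of unstable heading
    shape_irregularity: float = 0.7  # max per-row half-width jitter; drawn per swarm
    seed: int = 0

    _track_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    # -- geometry -----------------------------------------------------------
    @property
    def dx_m(self) -> float:
        return self.speed_knots * KNOT_M_S * self.ping_interval_s

    @property
    def max_depth_m(self) -> float:
        return self.n_depth * self.bin_size_m

    def depth_centres(self) -> np.ndarray:
        return (np.arange(self.n_depth) + 0.5) * self.bin_size_m

    def track(self):
        """Per-ping (time, lat, lon, heading); straight line at constant speed."""
        if self._track_cache is None:
            t = self.start_time + pd.to_timedelta(np.arange(self.n_pings) * self.ping_interval_s, unit="s")
            dist = np.arange(self.n_pings) * self.dx_m
            lat, lon = destination_point(self.start_lat, self.start_lon, self.course_deg, dist)
            heading = np.full(self.n_pings, float(self.course_deg))
            for p0, p1 in self.turn_windows:
                idx = np.arange(max(p0, 0), min(p1, self.n_pings))
                # oscillating heading: 2-minute period, +-60 deg -> high circular SD
                heading[idx] = self.course_deg + 60.0 * np.sin(2 * np.pi * (idx - p0) / 120.0)
            object.__setattr__(self, "_track_cache", (pd.DatetimeIndex(t), np.atleast_1d(lat), np.atleast_1d(lon), heading))
        return self._track_cache

    def position_at(self, time) -> tuple[float, float]:
        """Ship position at an arbitrary time (clamped to the track)."""
        dt = (pd.Timestamp(time) - self.start_time).total_seconds()
        dt = min(max(dt, 0.0), (self.n_pings - 1) * self.ping_interval_s)
        dist = dt / self.ping_interval_s * self.dx_m
        return destination_point(self.start_lat, self.start_lon, self.course_deg, dist)

    # -- presets ------------------------------------------------------------
    @classmethod
    def survey(
        cls,
        n_swarms: int = 1000,
        seed: int = 0,
        spacing_pings: int = 60,
        whale_placement: WhalePlacement | None = None,
        effort: EffortSchedule | None = None,
        fraction_non_krill: float = 0.0,
        n_turn_swarms: int = 0,
        trait_correlation_m: float = 25_000.0,
        sv_mean_db: float = -62.0,
        sv_sd_db: float = 6.0,
        sv_clip_db: tuple[float, float] = (-78.0, -46.0),
        semi_h_clip_m: tuple[float, float] = (16.0, 600.0),
        semi_h_log_median_m: float = 55.0,
        semi_h_log_sd: float = 0.6,
    ) -> "SimConfig":
        """A survey preset with spatially autocorrelated planted swarm traits.

        Trait magnitudes emulate a Southern Ocean krill survey: Sv(120)
        around -62 dB, mean depths tens to hundreds of metres, heights of a
        few to tens of metres, lognormal lengths around 110 m, krill
        dB-differences centred near 9 dB.
        """
        rng = np.random.default_rng(seed)
        cfg = cls(n_pings=n_swarms * spacing_pings + 2 * spacing_pings, seed=seed)

        sigma = trait_correlation_m / (spacing_pings * cfg.dx_m)

        def latent(scale=sigma):
            z = gaussian_filter1d(rng.standard_normal(n_swarms), scale, mode="wrap")
            return (z - z.mean()) / max(z.std(), 1e-12)

        z_sv, z_depth, z_height = latent(), latent(), latent()
        sv120 = np.clip(sv_mean_db + sv_sd_db * z_sv, *sv_clip_db)
        depth = np.clip(64.0 + 45.0 * z_depth, 18.0, 235.0)
        semi_v = np.clip(6.5 + 5.0 * z_height, 3.0, 28.0)
        semi_h = np.clip(np.exp(rng.normal(math.log(semi_h_log_median_m), semi_h_log_sd, n_swarms)), *semi_h_clip_m)
        db_diff = np.clip(rng.normal(9.0, 2.5, n_swarms), 1.2, 14.6)
        if fraction_non_krill > 0:
            non_krill = rng.random(n_swarms) < fraction_non_krill
            db_diff[non_krill] = rng.choice([-2.0, 16.5], size=non_krill.sum()) + rng.normal(
                0, 0.8, non_krill.sum()
            )

        pings = spacing_pings + np.arange(n_swarms) * spacing_pings
        # keep vertical extent inside the analysed water column
        depth = np.clip(depth, semi_v + 12.0, cfg.max_depth_m - semi_v - 4.0)
        aggs = [
            PlantedAggregation(int(p), float(z), float(a), float(b), float(s), float(d))
            for p, z, a, b, s, d in zip(pings, depth, semi_h, semi_v, sv120, db_diff)
        ]
        cfg.aggregations = aggs
        if whale_placement is not None:
            cfg.whale_placement = whale_placement
        if effort is not None:
            cfg.effort = effort
        if n_turn_swarms > 0:
            # heading-instability windows covering blocks of 5 consecutive swarms
            n_windows = max(1, n_turn_swarms // 5)
            step = n_swarms // (n_windows + 1)
            windows = []
            for w in range(n_windows):
                first = (w + 1) * step
                last = min(first + (n_turn_swarms // n_windows) - 1, n_swarms - 1)
                windows.append((int(pings[first] - spacing_pings // 2), int(pings[last] + spacing_pings // 2)))
            cfg.turn_windows = windows
        return cfg

    @classmethod
    def recovery(cls, n_swarms: int = 1000, seed: int = 0, null: bool = False) -> "SimConfig":
        """Recovery-experiment preset: strong (or null) logistic whale placement
        on density/depth/height, continuous visual+acoustic effort."""
        if null:
            # rare uniform placement: after the 12 km / 1 h label dilation a
            # ~1% base rate keeps presence and absence both well represented;
            # spatially unstructured traits (correlation ~ one ping) keep the
            # random split free of location leakage, so traits carry no
            # information about the labels at all
            wp = WhalePlacement(beta0=-4.5, beta_density=0.0, beta_depth=0.0, beta_height=0.0)
        else:
            # strong placement concentrated in the best patches: whales are
            # rare outside aggregations, as observed at sea
            wp = WhalePlacement(beta0=-3.0, beta_density=2.2, beta_depth=-2.2, beta_height=2.2)
        eff = EffortSchedule(fraction_none=0.0, fraction_visual=0.0, fraction_acoustic=0.0, fraction_both=1.0)
        # strong, well-detectable swarms: every planted Sv sits >= 4 dB above
        # the delineation threshold so recovery failures reflect the chain,
        # not marginal detectability
        return cls.survey(
            n_swarms=n_swarms, seed=seed, whale_placement=wp, effort=eff,
            sv_mean_db=-58.0, sv_sd_db=5.0, sv_clip_db=(-66.0, -46.0),
            semi_h_clip_m=(12.0, 140.0), semi_h_log_median_m=40.0, semi_h_log_sd=0.8,
            trait_correlation_m=18_000.0 if not null else 1.0,
        )

    @classmethod
    def voyage(cls, seed: int = 0) -> "SimConfig":
        """Voyage-scale preset: 1728 planted krill swarms (40 of them inside
        heading-instability windows), ~7% non-krill aggregations, the observed
        effort partition, and sparse whale aggregations whose presence
        fractions at the three association scales fall in the observed
        one-third to three-quarters range."""
        return cls.survey(
            n_swarms=1728,
            seed=seed,
            spacing_pings=80,
            fraction_non_krill=0.07,
            n_turn_swarms=40,
            whale_placement=WhalePlacement(
                beta0=-4.8, beta_density=2.0, beta_depth=-2.0, beta_height=2.0
            ),
        )


def simulate_echogram(config: SimConfig) -> tuple[EchogramGrid, list[PlantedAggregation]]:
    """Render the two-frequency echogram: TVG-shaped background noise plus the
    planted aggregations, combined in the linear domain.

    Background per frequency is ``noise_floor + 20 log10 r + 2 a r`` with
    Gaussian dB jitter; each aggregation's samples carry its Sv at 120 kHz and
    ``Sv - dB_difference`` at 38 kHz.
    """
    if config.n_pings <= 0 or config.n_depth <= 0:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(config.seed)
    depth = config.depth_centres()
    time, lat, lon, heading = config.track()
    dx = config.dx_m

    x_centres = (np.arange(config.n_pings) + 0.5) * dx
    grids = {}
    for f in (38, 120):
        bg = config.noise_floor_db[f] + tvg_db(depth, config.alpha_db_per_m[f])
        jitter = rng.normal(0.0, config.noise_jitter_db, size=(config.n_pings, config.n_depth))
        grids[f] = db_to_linear(bg[None, :] + jitter)

    for agg in config.aggregations:
        x0 = (agg.centroid_ping + 0.5) * dx
        if x0 - agg.semi_axis_h_m < 0 or x0 + agg.semi_axis_h_m > config.n_pings * dx:
            raise ValueError(f"aggregation at ping {agg.centroid_ping} extends outside the grid horizontally")
        if agg.centroid_depth_m - agg.semi_axis_v_m < 0 or agg.centroid_depth_m + agg.semi_axis_v_m > config.max_depth_m:
            raise ValueError(f"aggregation at ping {agg.centroid_ping} extends outside the depth range")
        i0 = max(int((x0 - agg.semi_axis_h_m) / dx) - 1, 0)
        i1 = min(int((x0 + agg.semi_axis_h_m) / dx) + 2, config.n_pings)
        j0 = max(int((agg.centroid_depth_m - agg.semi_axis_v_m) / config.bin_size_m) - 1, 0)
        j1 = min(int((agg.centroid_depth_m + agg.semi_axis_v_m) / config.bin_size_m) + 2, config.n_depth)
        xs = x_centres[i0:i1]
        zs = depth[j0:j1]
        # irregular ellipse: per-row half-width jitter decouples perimeter
        # (hence roughness) from the planted height, as in real swarms
        frac = 1.0 - ((zs - agg.centroid_depth_m) / agg.semi_axis_v_m) ** 2
        half = agg.semi_axis_h_m * np.sqrt(np.clip(frac, 0.0, None))
        # shape complexity varies between swarms, so perimeter (and hence
        # roughness) carries swarm-level variation independent of height
        q = rng.uniform(0.05, config.shape_irregularity) if config.shape_irregularity > 0.05 else config.shape_irregularity
        jit_l = 1.0 + q * rng.uniform(-1.0, 1.0, len(zs))
        jit_r = 1.0 + q * rng.uniform(-1.0, 1.0, len(zs))
        mask = (xs[:, None] >= (x0 - half * jit_l)[None, :]) & (
            xs[:, None] <= (x0 + half * jit_r)[None, :]
        ) & (frac > 0.0)[None, :]
        grids[120][i0:i1, j0:j1] += mask * db_to_linear(np.float64(agg.sv120_db))
        grids[38][i0:i1, j0:j1] += mask * db_to_linear(np.float64(agg.sv120_db - agg.db_difference))

    grid = EchogramGrid(
        sv_038=linear_to_db(grids[38]),
        sv_120=linear_to_db(grids[120]),
        depth=depth,
        time=time,
        lat=lat,
        lon=lon,
        heading=heading,
    )
    return grid, list(config.aggregations)


@dataclass
class WhaleTruth:
    """Ground-truth whale placement: positions, link coefficients, per-swarm
    placement probabilities and outcomes."""

    whales: pd.DataFrame  # time, lat, lon, swarm_index
    coefficients: WhalePlacement
    placement_prob: np.ndarray
    placed: np.ndarray


@dataclass
class SurveyObservations:
    """Raw whale observations as logged at sea (pre-localisation)."""

    sightings: list[Sighting]
    bearing_pairs: list[BearingPair]

    def sightings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [s.time for s in self.sightings],
                "ship_lat": [s.ship_lat for s in self.sightings],
                "ship_lon": [s.ship_lon for s in self.sightings],
                "ship_heading": [s.ship_heading for s in self.sightings],
                "relative_angle": [s.relative_angle for s in self.sightings],
                "range_m": [s.range_m for s in self.sightings],
            }
        )

    def bearings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [b.time for b in self.bearing_pairs],
                "lat_a": [b.lat_a for b in self.bearing_pairs],
                "lon_a": [b.lon_a for b in self.bearing_pairs],
                "bearing_a": [b.bearing_a for b in self.bearing_pairs],
                "lat_b": [b.lat_b for b in self.bearing_pairs],
                "lon_b": [b.lon_b for b in self.bearing_pairs],
                "bearing_b": [b.bearing_b for b in self.bearing_pairs],
            }
        )


def _assign_effort_blocks(config: SimConfig, rng: np.random.Generator):
    """Assign effort kinds to half-hour blocks honouring day/night constraints."""
    total_s = config.n_pings * config.ping_interval_s
    n_blocks = max(1, int(np.ceil(total_s / config.effort.block_s)))
    starts = config.start_time + pd.to_timedelta(np.arange(n_blocks) * config.effort.block_s, unit="s")
    mids = starts + pd.to_timedelta(config.effort.block_s / 2, unit="s")
    pos = [config.position_at(t) for t in mids]
    alt = np.array([solar_altitude(la, lo, t) for (la, lo), t in zip(pos, mids)])
    is_day = alt > 0.0

    frac = config.effort.fractions()
    quota = {k: int(round(v * n_blocks)) for k, v in frac.items()}
    # fix rounding drift
    drift = n_blocks - sum(quota.values())
    quota["none"] += drift

    kinds = np.empty(n_blocks, dtype=object)
    night_idx = np.where(~is_day)[0]
    day_idx = np.where(is_day)[0]
    rng.shuffle(night_idx)
    rng.shuffle(day_idx)

    # night blocks can only be acoustic or no-effort (visual observation
    # needs daylight): spend the acoustic quota first, then the no-effort
    # quota; any remaining night blocks degrade 'both' (then 'visual')
    # scheduled effort to acoustic-only
    n_night = len(night_idx)
    n_ac_night = min(quota["acoustic"], n_night)
    n_no_night = min(quota["none"], n_night - n_ac_night)
    for k, i in enumerate(night_idx):
        kinds[i] = "none" if n_ac_night <= k < n_ac_night + n_no_night else "acoustic"
    quota["acoustic"] -= n_ac_night
    quota["none"] -= n_no_night
    n_rest = n_night - n_ac_night - n_no_night
    take_both = min(n_rest, quota["both"])
    quota["both"] -= take_both
    quota["visual"] = max(quota["visual"] - (n_rest - take_both), 0)

    tokens = (
        ["visual"] * quota["visual"]
        + ["both"] * quota["both"]
        + ["acoustic"] * max(quota["acoustic"], 0)
        + ["none"] * max(quota["none"], 0)
    )
    # pad/trim to the number of day blocks
    if len(tokens) < len(day_idx):
        tokens += ["none"] * (len(day_idx) - len(tokens))
    rng.shuffle(tokens)
    for i, tok in zip(day_idx, tokens):
        kinds[i] = tok

    rows = []
    for i in range(n_blocks):
        start = starts[i]
        end = start + pd.to_timedelta(config.effort.block_s, unit="s")
        if kinds[i] in ("visual", "both"):
            rows.append({"start": start, "end": end, "kind": "visual"})
        if kinds[i] in ("acoustic", "both"):
            rows.append({"start": start, "end": end, "kind": "acoustic"})
    effort = pd.DataFrame(rows, columns=["start", "end", "kind"])
    return kinds, starts, effort


def simulate_whales_and_effort(
    config: SimConfig, truth: Sequence[PlantedAggregation]
) -> tuple[WhaleTruth, SurveyObservations, pd.DataFrame]:
    """Place whales near planted krill swarms via the logistic link, then
    generate the raw observations the effort schedule allows: visual sightings
    (daylight visual effort, range <= 12 km) and sonobuoy bearing pairs
    (acoustic effort, both buoys within 40 km)."""
    rng = np.random.default_rng(config.seed + 1)
    wp = config.whale_placement
    kinds, block_starts, effort = _assign_effort_blocks(config, rng)

    krill = [a for a in truth if a.is_krill]
    if not krill:
        empty = pd.DataFrame(columns=["time", "lat", "lon", "swarm_index"])
        return WhaleTruth(empty, wp, np.array([]), np.array([], dtype=bool)), SurveyObservations([], []), effort

    tsm = TSModel()
    ts_g = ts_per_kg(tsm, 44.5) - 30.0
    log_rho = np.array([(a.sv120_db - ts_g) / 10.0 for a in krill])
    depth = np.array([a.centroid_depth_m for a in krill])
    height = np.array([a.height_m for a in krill])

    def z(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    eta = wp.beta0 + wp.beta_density * z(log_rho) + wp.beta_depth * z(depth) + wp.beta_height * z(height)
    prob = expit(eta)
    placed = rng.random(len(krill)) < prob

    time_idx, lat, lon, heading = config.track()
    dt_block = config.effort.block_s

    whales = []
    sightings: list[Sighting] = []
    pairs: list[BearingPair] = []
    for k, agg in enumerate(krill):
        if not placed[k]:
            continue
        p = int(np.clip(agg.centroid_ping, 0, config.n_pings - 1))
        t_swarm = time_idx[p]
        w_time = t_swarm + pd.to_timedelta(rng.uniform(-wp.time_jitter_s, wp.time_jitter_s), unit="s")
        brg = rng.uniform(0, 360)
        rng_m = rng.uniform(500.0, wp.max_offset_m)
        w_lat, w_lon = destination_point(lat[p], lon[p], brg, rng_m)
        whales.append({"time": w_time, "lat": w_lat, "lon": w_lon, "swarm_index": k})

        block = int(np.clip((w_time - config.start_time).total_seconds() // dt_block, 0, len(kinds) - 1))
        kind = kinds[block]
        s_lat, s_lon = config.position_at(w_time)
        ping_at = int(
            np.clip((w_time - config.start_time).total_seconds() / config.ping_interval_s, 0, config.n_pings - 1)
        )
        s_head = heading[ping_at]
        ship_range = great_circle_distance(s_lat, s_lon, w_lat, w_lon)
        day = solar_altitude(s_lat, s_lon, w_time) > 0

        if kind in ("visual", "both") and day and ship_range <= 12_000.0 and ship_range > 0:
            bearing = initial_bearing(s_lat, s_lon, w_lat, w_lon)
            sightings.append(
                Sighting(
                    time=w_time,
                    ship_lat=s_lat,
                    ship_lon=s_lon,
                    ship_heading=float(s_head),
                    relative_angle=(bearing - s_head) % 360.0,
                    range_m=float(ship_range),
                )
            )
        if kind in ("acoustic", "both"):
            buoy_times = (w_time - pd.Timedelta(seconds=600), w_time - pd.Timedelta(seconds=2400))
            (la_a, lo_a), (la_b, lo_b) = (config.position_at(t) for t in buoy_times)
            baseline = great_circle_distance(la_a, lo_a, la_b, lo_b)
            if (
                baseline > 1_000.0
                and great_circle_distance(la_a, lo_a, w_lat, w_lon) <= 40_000.0
                and great_circle_distance(la_b, lo_b, w_lat, w_lon) <= 40_000.0
            ):
                pairs.append(
                    BearingPair(
                        time=w_time,
                        lat_a=la_a,
                        lon_a=lo_a,
                        bearing_a=initial_bearing(la_a, lo_a, w_lat, w_lon),
                        lat_b=la_b,
                        lon_b=lo_b,
                        bearing_b=initial_bearing(la_b, lo_b, w_lat, w_lon),
                    )
                )

    whales_df = pd.DataFrame(whales, columns=["time", "lat", "lon", "swarm_index"])
    return WhaleTruth(whales_df, wp, prob, placed), SurveyObservations(sightings, pairs), effort


def ground_truth_table(
    truth: Sequence[PlantedAggregation],
    config: SimConfig,
    whale_truth: WhaleTruth | None = None,
) -> pd.DataFrame:
    """One row per planted aggregation: traits, position/time, krill flag and
    (when whale truth is supplied) placement probability/outcome."""
    time_idx, lat, lon, _ = config.track()
    rows = []
    for a in truth:
        p = int(np.clip(a.centroid_ping, 0, config.n_pings - 1))
        rows.append(
            {
                "centroid_ping": a.centroid_ping,
                "time": time_idx[p],
                "lat": float(lat[p]),
                "lon": float(lon[p]),
                "centroid_depth_m": a.centroid_depth_m,
                "length_m": a.length_m,
                "height_m": a.height_m,
                "sv120_db": a.sv120_db,
                "db_difference": a.db_difference,
                "is_krill": a.is_krill,
            }
        )
    df = pd.DataFrame(rows)
    if whale_truth is not None and len(df):
        krill_pos = df.index[df["is_krill"]].to_numpy()
        df["whale_prob"] = np.nan
        df["whale_placed"] = False
        df.loc[krill_pos, "whale_prob"] = whale_truth.placement_prob
        df.loc[krill_pos, "whale_placed"] = whale_truth.placed
    return df
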