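"""Two-frequency echogram container and its netCDF/CSV round trip.

An :class:`EchogramGrid` holds calibrated volume backscattering strength
Sv(ping, depth) at 38 and 120 kHz together with per-ping time/position/heading.
Missing or excluded samples carry the conventional no-data sentinel (−999 dB).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr

SENTINEL = -999.0

__all__ = ["EchogramGrid", "SENTINEL", "db_to_linear", "linear_to_db"]


def db_to_linear(sv_db: np.ndarray) -> np.ndarray:
    """dB -> linear (sentinel samples map to 0 intensity)."""
    out = np.where(sv_db <= SENTINEL, 0.0, np.power(10.0, sv_db / 10.0))
    return out


def linear_to_db(sv_lin: np.ndarray) -> np.ndarray:
    """linear -> dB (non-positive intensities map to the sentinel)."""
    with np.errstate(divide="ignore"):
        out = np.where(sv_lin > 0.0, 10.0 * np.log10(np.maximum(sv_lin, 1e-300)), SENTINEL)
    return out


@dataclass
class EchogramGrid:
    """Gridded Sv at 38 and 120 kHz with ping metadata.

    ``sv_038``/``sv_120`` are (n_ping, n_depth) arrays in dB re 1 m^-1;
    ``depth`` holds strictly increasing bin centres in metres.
    """

    sv_038: np.ndarray
    sv_120: np.ndarray
    depth: np.ndarray
    time: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    heading: np.ndarray
    sentinel: float = SENTINEL

    def __post_init__(self):
        self.sv_038 = np.asarray(self.sv_038, dtype=float)
        self.sv_120 = np.asarray(self.sv_120, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.sv_038.shape != self.sv_120.shape:
            raise ValueError("38 and 120 kHz grids must share shape")
        if self.sv_038.shape != (len(self.time), len(self.depth)):
            raise ValueError("grid shape must be (n_ping, n_depth)")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth bin centres must be strictly increasing")
        if np.any(np.diff(self.time.asi8) < 0):
            raise ValueError("ping times must be non-decreasing")

    # -- basic geometry -----------------------------------------------------
    @property
    def n_pings(self) -> int:
        return self.sv_120.shape[0]

    @property
    def n_depth(self) -> int:
        return self.sv_120.shape[1]

    @property
    def bin_size_m(self) -> float:
        return float(np.median(np.diff(self.depth)))

    def sv(self, freq_khz: int) -> np.ndarray:
        if int(freq_khz) == 38:
            return self.sv_038
        if int(freq_khz) == 120:
            return self.sv_120
        raise KeyError(f"no {freq_khz} kHz channel")

    def along_track_m(self) -> np.ndarray:
        """Cumulative along-track distance of each ping from GPS positions (m)."""
        from .locate import great_circle_distance

        if self.n_pings == 1:
            return np.zeros(1)
        step = great_circle_distance(self.lat[:-1], self.lon[:-1], self.lat[1:], self.lon[1:])
        return np.concatenate([[0.0], np.cumsum(step)])

    def copy(self) -> "EchogramGrid":
        return replace(
            self,
            sv_038=self.sv_038.copy(),
            sv_120=self.sv_120.copy(),
            depth=self.depth.copy(),
            lat=np.array(self.lat, dtype=float),
            lon=np.array(self.lon, dtype=float),
            heading=np.array(self.heading, dtype=float),
        )

    # -- IO -----------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            data_vars={
                "Sv_038": (("ping", "depth"), self.sv_038),
                "Sv_120": (("ping", "depth"), self.sv_120),
                "time": (("ping",), self.time.asi8 / 1e9),
                "lat": (("ping",), np.asarray(self.lat, dtype=float)),
                "lon": (("ping",), np.asarray(self.lon, dtype=float)),
                "heading": (("ping",), np.asarray(self.heading, dtype=float)),
            },
            coords={"depth": ("depth", self.depth)},
            attrs={"sentinel": self.sentinel, "time_units": "seconds since 1970-01-01T00:00:00Z"},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EchogramGrid":
        time = pd.to_datetime(np.asarray(ds["time"].values, dtype=float), unit="s")
        return cls(
            sv_038=np.asarray(ds["Sv_038"].values, dtype=float),
            sv_120=np.asarray(ds["Sv_120"].values, dtype=float),
            depth=np.asarray(ds["depth"].values, dtype=float),
            time=pd.DatetimeIndex(time),
            lat=np.asarray(ds["lat"].values, dtype=float),
            lon=np.asarray(ds["lon"].values, dtype=float),
            heading=np.asarray(ds["heading"].values, dtype=float),
            sentinel=float(ds.attrs.get("sentinel", SENTINEL)),
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EchogramGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())

    def to_long_csv(self, path) -> None:
        """Long-format CSV: one row per (ping, depth) sample."""
        n_p, n_d = self.sv_120.shape
        df = pd.DataFrame(
            {
                "ping": np.repeat(np.arange(n_p), n_d),
                "time": np.repeat(self.time.values, n_d),
                "lat": np.repeat(self.lat, n_d),
                "lon": np.repeat(self.lon, n_d),
                "heading": np.repeat(self.heading, n_d),
                "depth": np.tile(self.depth, n_p),
                "Sv_038": self.sv_038.ravel(),
                "Sv_120": self.sv_120.ravel(),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path) -> "EchogramGrid":
        df = pd.read_csv(path, parse_dates=["time"])
        pings = np.sort(df["ping"].unique())
        depth = np.sort(df["depth"].unique())
        df = df.sort_values(["ping", "depth"])
        n_p, n_d = len(pings), len(depth)
        per_ping = df.drop_duplicates("ping").sort_values("ping")
        return cls(
            sv_038=df["Sv_038"].to_numpy().reshape(n_p, n_d),
            sv_120=df["Sv_120"].to_numpy().reshape(n_p, n_d),
            depth=depth,
            time=pd.DatetimeIndex(per_ping["time"]),
            lat=per_ping["lat"].to_numpy(),
            lon=per_ping["lon"].to_numpy(),
            heading=per_ping["heading"].to_numpy(),
        )
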