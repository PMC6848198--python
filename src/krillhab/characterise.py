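"""The 11 krill-swarm descriptors feeding the habitat model.

Each krill-classified swarm is summarised by: corrected area, corrected
length, corrected perimeter, roughness (corrected perimeter / corrected
area), mean depth, mean height, dB difference, biomass density (wet weight,
g m^-3), swarm backscattering coefficient, nearest-neighbour distance, and
nearest-neighbour depth difference.

Biomass density converts acoustic energy to wet weight through the target
strength of 1 kg of krill:

    rho_v = 10 ** ((MVBS_120 - TS_kg) / 10)

where ``TS_kg = TS(L) - 10 log10(m(L) in kg)`` combines a per-individual
TS(L) parameterisation at 120 kHz with a Morris-type length/wet-mass
allometry ``m(mg) = a L^b``.  With TS_kg referenced to 1 kg the formula
yields kg m^-3; the swarm table reports g m^-3 by referencing TS to 1 g
(``TS_g = TS_kg - 30``), the scale on which the survey's densities span
roughly 2-1700 g m^-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import SwarmRegion, classify_krill, db_difference
from .locate import great_circle_distance

#: column names of the 11 model covariates, in reporting order
COVARIATES = [
    "corrected_area",
    "corrected_length",
    "corrected_perimeter",
    "roughness",
    "mean_depth",
    "mean_height",
    "db_difference",
    "biomass_density",
    "swarm_backscattering_coefficient",
    "nearest_neighbour_distance",
    "nearest_neighbour_depth",
]

NN_SENTINEL = np.nan

__all__ = [
    "TSModel",
    "COVARIATES",
    "ts_per_kg",
    "biomass_density",
    "swarm_backscatter",
    "nearest_neighbours",
    "build_swarm_table",
]


@dataclass(frozen=True)
class TSModel:
    """Krill target-strength parameterisation at 120 kHz plus mass allometry.

    ``TS(L) = ts_slope * log10(L_mm) + ts_intercept`` (dB re 1 m^2) is a
    log-linear fit spanning the simplified-SDWBA range for 26-60 mm krill;
    any published curve can be dropped in by subclass or by passing a custom
    instance.  Wet mass follows ``m(mg) = mass_a * L_mm ** mass_b``
    (Morris et al. 1988 style coefficients).
    """

    name: str = "loglinear-120khz"
    ts_slope: float = 27.5
    ts_intercept: float = -118.9
    mass_a_mg: float = 3.85e-3
    mass_b: float = 3.20
    valid_range_mm: tuple[float, float] = (20.0, 65.0)

    def ts_individual(self, length_mm: float) -> float:
        if length_mm <= 0:
            raise ValueError("krill length must be positive")
        return self.ts_slope * np.log10(length_mm) + self.ts_intercept

    def wet_mass_mg(self, length_mm: float) -> float:
        return self.mass_a_mg * length_mm ** self.mass_b

    def assert_monotone(self, lo: float = 26.0, hi: float = 60.0, n: int = 200) -> None:
        """TS must increase with length over the trawled size range."""
        ls = np.linspace(lo, hi, n)
        ts = self.ts_slope * np.log10(ls) + self.ts_intercept
        if np.any(np.diff(ts) <= 0):
            raise ValueError(f"TS model '{self.name}' is not monotone increasing over {lo}-{hi} mm")


def ts_per_kg(tsmodel: TSModel, length_mm: float) -> float:
    """Target strength of 1 kg of krill, dB re 1 kg.

    ``TS_kg = TS_individual(L) - 10 log10(m_individual(L) in kg)``.
    """
    lo, hi = tsmodel.valid_range_mm
    if not lo <= length_mm <= hi:
        warnings.warn(f"krill length {length_mm} mm outside the TS model's valid range {lo}-{hi} mm")
    mass_kg = tsmodel.wet_mass_mg(length_mm) * 1e-6
    if mass_kg <= 0:
        raise ValueError("non-positive individual mass")
    return tsmodel.ts_individual(length_mm) - 10.0 * np.log10(mass_kg)


def biomass_density(mvbs_120: float, ts_kg: float) -> float:
    """Wet-weight biomass density ``10 ** ((MVBS_120 - TS_kg) / 10)``.

    Units follow the TS reference: kg m^-3 when ``ts_kg`` is dB re 1 kg,
    g m^-3 when referenced to 1 g (``ts_kg - 30``).
    """
    return float(10.0 ** ((np.asarray(mvbs_120) - np.asarray(ts_kg)) / 10.0))


def swarm_backscatter(region: SwarmRegion) -> float:
    """Swarm backscattering coefficient (m): linear-mean s_v at 120 kHz times
    mean height times corrected length — acoustic energy proportional to
    swarm length."""
    if region.corrected_length_m is None:
        raise ValueError("region must be beam-corrected first")
    height = region.height_m
    if height <= 0:
        warnings.warn("degenerate zero-height swarm; backscattering coefficient set to 0")
        return 0.0
    sv_lin = 10.0 ** (region.mvbs_120 / 10.0)
    return float(sv_lin * height * max(region.corrected_length_m, 0.0))


def nearest_neighbours(table: pd.DataFrame) -> pd.DataFrame:
    """Attach nearest-neighbour distance and depth difference to a swarm table.

    The neighbour of each swarm is the other swarm minimising great-circle
    distance between centroids (horizontal-only search); the depth difference
    is taken to that same neighbour.  A single-swarm table gets sentinel
    (NaN) values with a warning.
    """
    out = table.copy()
    n = len(out)
    if n < 2:
        warnings.warn("fewer than two swarms: nearest-neighbour metrics undefined")
        out["nearest_neighbour_distance"] = NN_SENTINEL
        out["nearest_neighbour_depth"] = NN_SENTINEL
        return out
    lat = out["lat"].to_numpy()
    lon = out["lon"].to_numpy()
    depth = out["mean_depth"].to_numpy()
    d = great_circle_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    out["nearest_neighbour_distance"] = d[np.arange(n), nn]
    out["nearest_neighbour_depth"] = np.abs(depth - depth[nn])
    return out


def build_swarm_table(
    regions: list[SwarmRegion],
    tsmodel: TSModel | None = None,
    krill_length_mm: float = 44.5,
    exclude_sub_beam: bool = True,
) -> pd.DataFrame:
    """Assemble the krill swarm table: one row per krill-classified region
    with all 11 covariates plus id/time/position.

    Non-krill regions (dB-difference outside the window) are excluded, as are
    sub-beam-resolution regions when ``exclude_sub_beam``.  A single
    survey-wide krill length (default 44.5 mm, the trawled mean) feeds the TS
    model.
    """
    tsmodel = tsmodel or TSModel()
    tsmodel.assert_monotone()
    ts_kg = ts_per_kg(tsmodel, krill_length_mm)
    ts_g = ts_kg - 30.0  # reference the TS to 1 g so densities come out in g m^-3

    rows = []
    for k, region in enumerate(regions):
        if region.corrected_length_m is None:
            raise ValueError("regions must be beam-corrected (diner_correct) before tabulation")
        if region.sub_beam_resolution and exclude_sub_beam:
            continue
        if not np.isfinite(region.mvbs_38):
            continue  # cannot classify without both frequencies
        if not classify_krill(region):
            continue
        area = region.corrected_area_m2
        perim = region.corrected_perimeter_m
        rows.append(
            {
                "swarm_id": k,
                "time": region.time,
                "lat": region.lat,
                "lon": region.lon,
                "corrected_area": area,
                "corrected_length": region.corrected_length_m,
                "corrected_perimeter": perim,
                "roughness": perim / area if area > 0 else np.nan,
                "mean_depth": region.mean_depth_m,
                "mean_height": region.height_m,
                "db_difference": db_difference(region),
                "biomass_density": biomass_density(region.mvbs_120, ts_g),
                "swarm_backscattering_coefficient": swarm_backscatter(region),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return pd.DataFrame(columns=["swarm_id", "time", "lat", "lon", *COVARIATES])
    table = nearest_neighbours(table)
    return table[["swarm_id", "time", "lat", "lon", *COVARIATES]]
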