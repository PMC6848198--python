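"""SHAPES-style swarm delineation on the 120 kHz channel.

The shoal analysis and patch estimation system (SHAPES; Barange 1994, as
implemented in Echoview) delineates aggregations in three steps: threshold the
echogram, take 4-connected components as candidates, then merge candidates
whose edge-to-edge gaps are within the horizontal/vertical linking distances.
Merged regions failing the minimum length/height criteria are discarded.

Swarm morphology (length, height, area, perimeter) is measured on the
rectilinear sample footprint in (along-track m, depth m) coordinates and then
corrected for the transducer beam after Diner (2001): at mean swarm depth z the
beam subtends a diameter ``D_b = 2 z tan(theta/2)`` which inflates horizontal
dimensions; the corrected boundary is the measured one shrunk by ``D_b/2`` on
each horizontal side.

Species identification uses the dual-frequency dB-difference technique:
aggregations whose ``MVBS_120 - MVBS_38`` falls within the krill window
(1.04 to 14.80 dB) are classified as krill.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import SENTINEL, EchogramGrid, db_to_linear, linear_to_db

KRILL_DB_WINDOW = (1.04, 14.80)

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

__all__ = [
    "ShapesParams",
    "BeamGeometry",
    "SwarmRegion",
    "detect_swarms",
    "diner_correct",
    "db_difference",
    "classify_krill",
    "KRILL_DB_WINDOW",
]


@dataclass(frozen=True)
class ShapesParams:
    """SHAPES parameters (defaults follow the krill-swarm literature)."""

    sv_threshold_db: float = -70.0
    min_length_m: float = 15.0
    min_height_m: float = 5.0
    max_link_horizontal_m: float = 15.0
    max_link_vertical_m: float = 5.0

    def __post_init__(self):
        if self.sv_threshold_db <= SENTINEL:
            raise ValueError("Sv threshold must lie above the no-data sentinel")
        for name in ("min_length_m", "min_height_m", "max_link_horizontal_m", "max_link_vertical_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BeamGeometry:
    """Echosounder beam geometry used for the Diner correction."""

    beam_width_deg: float = 7.0
    pulse_duration_s: float = 1.024e-3
    sound_speed_m_s: float = 1450.0

    def __post_init__(self):
        if not 0 <= self.beam_width_deg < 90:
            raise ValueError("beam width must be in [0, 90) degrees")


@dataclass
class SwarmRegion:
    """One delineated aggregation.

    ``ping_idx``/``depth_idx`` are the sample coordinates of the mask;
    morphology is in metres with along-track position ``x = ping_idx * dx``.
    Corrected fields are filled by :func:`diner_correct`.
    """

    ping_idx: np.ndarray
    depth_idx: np.ndarray
    dx_m: float
    dz_m: float
    length_m: float
    height_m: float
    area_m2: float
    perimeter_m: float
    mean_depth_m: float
    mvbs_120: float
    mvbs_38: float
    time: pd.Timestamp
    lat: float
    lon: float
    corrected_length_m: Optional[float] = None
    corrected_area_m2: Optional[float] = None
    corrected_perimeter_m: Optional[float] = None
    sub_beam_resolution: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.ping_idx)

    def row_intervals(self) -> dict[int, list[tuple[float, float]]]:
        """Per depth-bin horizontal cover, metres: {depth_idx: [(x0, x1), ...]}."""
        rows: dict[int, list[tuple[float, float]]] = {}
        order = np.lexsort((self.ping_idx, self.depth_idx))
        ii = self.ping_idx[order]
        jj = self.depth_idx[order]
        if len(ii) == 0:
            return rows
        brk = np.nonzero((np.diff(jj) != 0) | (np.diff(ii) != 1))[0]
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk, [len(ii) - 1]])
        for s, e in zip(starts, ends):
            rows.setdefault(int(jj[s]), []).append((ii[s] * self.dx_m, (ii[e] + 1) * self.dx_m))
        return rows

    def boundary_geojson(self) -> dict:
        """Boundary polygon(s) in (along-track m, depth m), GeoJSON mapping."""
        from shapely.geometry import box, mapping
        from shapely.ops import unary_union

        cells = [
            box(i * self.dx_m, self.depth_idx_to_z(j) - self.dz_m / 2, (i + 1) * self.dx_m,
                self.depth_idx_to_z(j) + self.dz_m / 2)
            for i, j in zip(self.ping_idx, self.depth_idx)
        ]
        return mapping(unary_union(cells))

    def depth_idx_to_z(self, j: int) -> float:
        # depth of bin centre; regions only store indices, so reconstruct from dz
        dc = getattr(self, "_depth_centres", None)
        return float(dc[j]) if dc is not None else (j + 0.5) * self.dz_m


# -- interval-union sweep geometry -----------------------------------------

def _union_measure(runs: list[tuple[float, float]]) -> float:
    total, last = 0.0, -np.inf
    for a, b in sorted(runs):
        a = max(a, last)
        if b > a:
            total += b - a
            last = b
        last = max(last, b)
    return total


def _symmetric_difference_measure(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> float:
    """Measure of the set where exactly one of the two interval unions covers."""
    events = []
    for x0, x1 in a:
        events += [(x0, 0, 1), (x1, 0, -1)]
    for x0, x1 in b:
        events += [(x0, 1, 1), (x1, 1, -1)]
    events.sort()
    total, prev_x = 0.0, None
    ca = cb = 0
    for x, which, d in events:
        if prev_x is not None and ((ca > 0) != (cb > 0)):
            total += x - prev_x
        if which == 0:
            ca += d
        else:
            cb += d
        prev_x = x
    return total


def _area_perimeter(rows: dict[int, list[tuple[float, float]]], dz: float) -> tuple[float, float]:
    """Area and perimeter of a union-of-rows rectilinear polygon."""
    if not rows:
        return 0.0, 0.0
    area = sum(_union_measure(r) for r in rows.values()) * dz
    vertical = 2.0 * dz * sum(len(_merge(r)) for r in rows.values())
    horizontal = 0.0
    jmin, jmax = min(rows), max(rows)
    for j in range(jmin, jmax + 2):
        above = _merge(rows.get(j - 1, []))
        here = _merge(rows.get(j, []))
        horizontal += _symmetric_difference_measure(above, here)
    return area, vertical + horizontal


def _merge(runs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(runs):
        if out and a <= out[-1][1] + 1e-12:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return [r for r in out if r[1] > r[0]]


# -- detection --------------------------------------------------------------

def _link_components(labels: np.ndarray, n_labels: int, kh: int, kv: int):
    """Union-find merge of candidate components.

    Two candidates link when some sample pair satisfies |di| <= kh+1 and
    |dj| <= kv+1 (the integer form of edge-to-edge gaps within the linking
    distances).  Bounding boxes sorted along track prefilter the pair list.
    Returns (root label per label, samples per label).
    """
    parent = np.arange(n_labels + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    objs = ndimage.find_objects(labels)
    samples = {}
    for lbl in range(1, n_labels + 1):
        sl = objs[lbl - 1]
        ii, jj = np.nonzero(labels[sl] == lbl)
        samples[lbl] = (ii + sl[0].start, jj + sl[1].start)

    boxes = [
        (objs[l - 1][0].start, objs[l - 1][0].stop - 1, objs[l - 1][1].start, objs[l - 1][1].stop - 1, l)
        for l in range(1, n_labels + 1)
    ]
    boxes.sort()
    for a_idx in range(len(boxes)):
        i0a, i1a, j0a, j1a, la = boxes[a_idx]
        for b_idx in range(a_idx + 1, len(boxes)):
            i0b, i1b, j0b, j1b, lb = boxes[b_idx]
            if i0b - i1a > kh + 1:
                break  # boxes sorted by i0: all later pairs are further along track
            gap_j = max(j0b - j1a, j0a - j1b, 0)
            if gap_j > kv + 1:
                continue
            ia, ja = samples[la]
            ib, jb = samples[lb]
            di = np.abs(ia[:, None] - ib[None, :])
            dj = np.abs(ja[:, None] - jb[None, :])
            if np.any((di <= kh + 1) & (dj <= kv + 1)):
                union(la, lb)
    return np.array([find(l) for l in range(n_labels + 1)]), samples


def detect_swarms(grid: EchogramGrid, params: ShapesParams | None = None) -> list[SwarmRegion]:
    """Run the SHAPES threshold-link-filter chain on the 120 kHz channel."""
    params = params or ShapesParams()
    if grid.n_pings == 0 or grid.n_depth == 0:
        return []
    x = grid.along_track_m()
    if grid.n_pings > 1:
        dx = float(np.median(np.diff(x)))
    else:
        dx = np.nan
    if not np.isfinite(dx) or dx <= 0:
        raise ValueError("along-track sample spacing is unknown (need GPS positions or ship speed)")
    dz = grid.bin_size_m

    mask = grid.sv_120 >= params.sv_threshold_db
    labels, n = ndimage.label(mask, structure=FOUR_CONN)
    if n == 0:
        return []

    kh = int(np.floor(params.max_link_horizontal_m / dx + 1e-9))
    kv = int(np.floor(params.max_link_vertical_m / dz + 1e-9))
    roots, samples = _link_components(labels, n, kh, kv)

    merged: dict[int, list[int]] = {}
    for lbl in range(1, n + 1):
        merged.setdefault(int(roots[lbl]), []).append(lbl)

    lin120 = db_to_linear(grid.sv_120)
    lin038 = np.where(grid.sv_038 > SENTINEL, db_to_linear(grid.sv_038), np.nan)

    regions = []
    for group in merged.values():
        ii = np.concatenate([samples[l][0] for l in group])
        jj = np.concatenate([samples[l][1] for l in group])
        length = (ii.max() - ii.min() + 1) * dx
        height = (jj.max() - jj.min() + 1) * dz
        if length < params.min_length_m or height < params.min_height_m:
            continue
        mvbs120 = linear_to_db(np.asarray(lin120[ii, jj].mean()))
        v38 = lin038[ii, jj]
        mvbs38 = linear_to_db(np.asarray(np.nanmean(v38))) if np.any(np.isfinite(v38)) else np.nan
        region = SwarmRegion(
            ping_idx=ii,
            depth_idx=jj,
            dx_m=dx,
            dz_m=dz,
            length_m=length,
            height_m=height,
            area_m2=np.nan,
            perimeter_m=np.nan,
            mean_depth_m=float(grid.depth[jj].mean()),
            mvbs_120=float(mvbs120),
            mvbs_38=float(mvbs38),
            time=grid.time[int(round(ii.mean()))],
            lat=float(np.mean(grid.lat[ii])),
            lon=float(np.mean(grid.lon[ii])),
        )
        region._depth_centres = grid.depth  # type: ignore[attr-defined]
        area, perim = _area_perimeter(region.row_intervals(), dz)
        region.area_m2 = area
        region.perimeter_m = perim
        regions.append(region)
    regions.sort(key=lambda r: r.ping_idx.min())
    return regions


def diner_correct(region: SwarmRegion, beam: BeamGeometry | None = None) -> SwarmRegion:
    """Beam-geometry correction of horizontal swarm morphology after Diner.

    The beam diameter at mean swarm depth, ``D_b = 2 z tan(theta/2)``, is
    removed from the measured length, and the boundary is shrunk horizontally
    by ``D_b/2`` on each side before re-measuring area and perimeter.  Regions
    whose corrected length is non-positive are flagged sub-beam-resolution.
    Height is not corrected (only horizontal dimensions are beam-inflated).
    """
    beam = beam or BeamGeometry()
    if not region.mean_depth_m > 0:
        raise ValueError("region mean depth must be positive")
    d_beam = 2.0 * region.mean_depth_m * np.tan(np.radians(beam.beam_width_deg) / 2.0)
    out = replace(region)
    out._depth_centres = getattr(region, "_depth_centres", None)  # type: ignore[attr-defined]
    out.corrected_length_m = region.length_m - d_beam
    if out.corrected_length_m <= 0:
        out.sub_beam_resolution = True
        out.corrected_area_m2 = 0.0
        out.corrected_perimeter_m = 0.0
        return out
    h = d_beam / 2.0
    rows = {
        j: [(a + h, b - h) for a, b in runs if b - h > a + h]
        for j, runs in region.row_intervals().items()
    }
    rows = {j: r for j, r in rows.items() if r}
    area, perim = _area_perimeter(rows, region.dz_m)
    out.corrected_area_m2 = area
    out.corrected_perimeter_m = perim
    if area <= 0:  # every row narrower than the beam footprint
        out.sub_beam_resolution = True
    return out


def db_difference(region: SwarmRegion) -> float:
    """Frequency response fingerprint: MVBS_120 - MVBS_38 (dB)."""
    if not (np.isfinite(region.mvbs_120) and np.isfinite(region.mvbs_38)):
        raise ValueError("dB difference undefined: one frequency fully masked over the region")
    return region.mvbs_120 - region.mvbs_38


def classify_krill(region: SwarmRegion, window: tuple[float, float] = KRILL_DB_WINDOW) -> bool:
    """Krill iff the dB-difference lies within the closed window."""
    d = db_difference(region)
    return window[0] <= d <= window[1]
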