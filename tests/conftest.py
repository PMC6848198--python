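"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive each quantity with the dumbest
possible algorithm (exhaustive pair scans, sort-based quantiles, pixel BFS)
so they stay independent of the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from krillhab.grids import SENTINEL, EchogramGrid

EARTH_R = 6_371_008.8


def make_grid(sv120: np.ndarray, sv038: np.ndarray | None = None, dx: float = 5.0, dz: float = 2.0,
              lat0: float = -65.0) -> EchogramGrid:
    """Toy echogram on a straight east-west track with sample spacing dx."""
    sv120 = np.asarray(sv120, dtype=float)
    if sv038 is None:
        sv038 = sv120.copy()
    n_p, n_d = sv120.shape
    # longitude step giving a great-circle step of dx metres at lat0
    dlon = np.degrees(dx / (EARTH_R * np.cos(np.radians(lat0))))
    return EchogramGrid(
        sv_038=sv038,
        sv_120=sv120,
        depth=(np.arange(n_d) + 0.5) * dz,
        time=pd.date_range("2015-02-17", periods=n_p, freq="s"),
        lat=np.full(n_p, lat0),
        lon=174.0 + np.arange(n_p) * dlon,
        heading=np.full(n_p, 90.0),
    )


# -- brute-force oracles -----------------------------------------------------

def shapes_bruteforce(sv, threshold, dx, dz, min_len, min_h, link_h, link_v):
    """Threshold -> BFS 4-components -> exhaustive pairwise linking to a fixed
    point -> size filter.  Returns a set of frozensets of (i, j) samples."""
    n_p, n_d = sv.shape
    cells = {(i, j) for i in range(n_p) for j in range(n_d) if sv[i, j] >= threshold}
    comps = []
    todo = set(cells)
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i, j = frontier.pop()
            for ni, nj in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)):
                if (ni, nj) in todo:
                    todo.remove((ni, nj))
                    comp.add((ni, nj))
                    frontier.append((ni, nj))
        comps.append(comp)

    def linked(a, b):
        for (i1, j1) in a:
            for (i2, j2) in b:
                hgap = max(abs(i1 - i2) - 1, 0) * dx
                vgap = max(abs(j1 - j2) - 1, 0) * dz
                if hgap <= link_h and vgap <= link_v:
                    return True
        return False

    changed = True
    while changed:
        changed = False
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                if linked(comps[a], comps[b]):
                    comps[a] = comps[a] | comps[b]
                    del comps[b]
                    changed = True
                    break
            if changed:
                break

    out = set()
    for comp in comps:
        ii = [i for i, _ in comp]
        jj = [j for _, j in comp]
        length = (max(ii) - min(ii) + 1) * dx
        height = (max(jj) - min(jj) + 1) * dz
        if length >= min_len and height >= min_h:
            out.add(frozenset(comp))
    return out


def auc_bruteforce(scores, labels):
    """All positive/negative pairs; ties count half."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def haversine_scalar(lat1, lon1, lat2, lon2):
    from math import asin, cos, radians, sin, sqrt

    p1, p2 = radians(lat1), radians(lat2)
    dl = radians(lon2 - lon1)
    dp = p2 - p1
    a = sin(dp / 2) ** 2 + cos(p1) * cos(p2) * sin(dl / 2) ** 2
    return 2 * EARTH_R * asin(sqrt(a))


def nn_bruteforce(lat, lon, depth):
    """O(n^2) nearest-neighbour distances and depth differences."""
    n = len(lat)
    dist = []
    ddepth = []
    for i in range(n):
        best, bestj = float("inf"), -1
        for j in range(n):
            if i == j:
                continue
            d = haversine_scalar(lat[i], lon[i], lat[j], lon[j])
            if d < best:
                best, bestj = d, j
        dist.append(best)
        ddepth.append(abs(depth[i] - depth[bestj]))
    return np.array(dist), np.array(ddepth)


def presence_bruteforce(records, detections, dist_km, time_h):
    """O(n*m) spatiotemporal scan."""
    out = []
    for _, r in records.iterrows():
        hit = False
        for _, d in detections.iterrows():
            dt = abs((pd.Timestamp(r["time"]) - pd.Timestamp(d["time"])).total_seconds())
            if dt <= time_h * 3600 and haversine_scalar(r["lat"], r["lon"], d["lat"], d["lon"]) <= dist_km * 1000:
                hit = True
                break
        out.append(hit)
    return np.array(out)


def quantile_outliers_bruteforce(df, cols, level=0.995):
    """Sort-based linear-interpolation quantile, then single-pass row removal."""
    drop = set()
    for c in cols:
        x = sorted(df[c].tolist())
        h = (len(x) - 1) * level
        lo = int(np.floor(h))
        q = x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])
        for idx, v in zip(df.index, df[c]):
            if v > q:
                drop.add(idx)
    return df.drop(index=sorted(drop)).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_survey():
    """One small end-to-end survey (no model fit), shared across tests."""
    from krillhab.pipeline import run_pipeline
    from krillhab.simulate import SimConfig

    cfg = SimConfig.recovery(n_swarms=60, seed=7)
    return run_pipeline(cfg, fit=False)
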