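"""End-to-end orchestration: simulate -> clean -> detect -> characterise ->
locate -> associate -> fit, plus run-directory artefacts and summary tables."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associate import (
    SCALES,
    OutlierRule,
    ScaleThreshold,
    annotate_day_night,
    classify_presence,
    effort_filter,
    heading_filter,
    remove_outliers,
    stratified_split,
)
from .characterise import TSModel, build_swarm_table
from .clean import NoiseEstimate, apply_exclusions, remove_noise, smooth_7x7
from .detect import BeamGeometry, ShapesParams, detect_swarms, diner_correct
from .habitat import BRTConfig, WhaleHabitatBRT
from .locate import TriangulationFailure, detections_frame, sighting_position, triangulate
from .simulate import SimConfig, simulate_echogram, simulate_whales_and_effort, ground_truth_table

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_all", "summarise", "locate_observations"]


def locate_observations(obs) -> pd.DataFrame:
    """Convert raw sightings/bearing pairs into a whale-detection table,
    dropping triangulations that fail quality gates."""
    dets = [sighting_position(s) for s in obs.sightings]
    n_failed = 0
    for pair in obs.bearing_pairs:
        try:
            dets.append(triangulate(pair))
        except TriangulationFailure:
            n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed} bearing pairs failed triangulation gates")
    return detections_frame(dets)


@dataclass
class PipelineResult:
    """In-memory artefacts of one full synthetic run."""

    config: SimConfig
    truth_table: pd.DataFrame
    swarm_table: pd.DataFrame          # all krill swarms passing filters, tagged
    modelling_tables: dict             # scale label -> (train, test)
    detections: pd.DataFrame
    effort: pd.DataFrame
    fits: dict = field(default_factory=dict)   # scale label -> WhaleHabitatBRTResults
    aucs: dict = field(default_factory=dict)   # scale label -> held-out AUC
    counts: dict = field(default_factory=dict)


def run_pipeline(
    config: SimConfig,
    scales: tuple[ScaleThreshold, ...] = SCALES,
    brt_config: BRTConfig | None = None,
    fit: bool = True,
    shapes: ShapesParams | None = None,
    beam: BeamGeometry | None = None,
    noise: NoiseEstimate | None = None,
    tsmodel: TSModel | None = None,
    krill_length_mm: float = 44.5,
    surface_m: float = 10.0,
    max_depth_m: float = 250.0,
    keep_grid: bool = False,
) -> PipelineResult:
    """Run every stage on a synthetic survey and (optionally) fit the BRT at
    each association scale.  The split and every stochastic stage derive from
    ``config.seed``."""
    grid, aggs = simulate_echogram(config)
    whale_truth, obs, effort = simulate_whales_and_effort(config, aggs)
    truth = ground_truth_table(aggs, config, whale_truth)

    cleaned = remove_noise(grid, noise)
    cleaned = apply_exclusions(cleaned, surface_m=surface_m, max_depth_m=max_depth_m)
    cleaned = smooth_7x7(cleaned)

    regions = [diner_correct(r, beam) for r in detect_swarms(cleaned, shapes)]
    table = build_swarm_table(regions, tsmodel, krill_length_mm)

    detections = locate_observations(obs)

    counts = {"swarms_detected": len(table)}
    table = heading_filter(table, grid.time, grid.heading)
    counts["swarms_after_heading_filter"] = len(table)
    counts["swarms_heading_removed"] = counts["swarms_detected"] - len(table)

    table = effort_filter(table, effort)
    table = annotate_day_night(table)
    counts["effort_tags"] = table["effort_tag"].value_counts().to_dict()

    for scale in scales:
        table[f"present_{scale.label}"] = classify_presence(table, detections, scale)

    during = table[table["effort_tag"] != "none"].reset_index(drop=True)
    counts["swarms_during_effort"] = len(during)

    modelling_tables = {}
    fits = {}
    aucs = {}
    if len(during) >= 4:
        filtered = remove_outliers(during, OutlierRule())
        counts["swarms_after_outlier_removal"] = len(filtered)
        for scale in scales:
            lbl = scale.label
            filt = filtered.copy()
            filt["whale_present"] = filt[f"present_{lbl}"].astype(int)
            counts[f"presence_{lbl}"] = int(filt["whale_present"].sum())
            counts[f"absence_{lbl}"] = int((1 - filt["whale_present"]).sum())
            try:
                train, test = stratified_split(filt, seed=config.seed)
            except ValueError:
                continue
            modelling_tables[lbl] = (train, test)
            if fit:
                model = WhaleHabitatBRT.from_dataframe(train)
                res = model.fit(brt_config or BRTConfig(seed=config.seed))
                fits[lbl] = res
                aucs[lbl] = res.test_auc(test)

    result = PipelineResult(
        config=config,
        truth_table=truth,
        swarm_table=table,
        modelling_tables=modelling_tables,
        detections=detections,
        effort=effort,
        fits=fits,
        aucs=aucs,
        counts=counts,
    )
    if keep_grid:
        result.grid = grid  # type: ignore[attr-defined]
        result.cleaned = cleaned  # type: ignore[attr-defined]
    return result


# -- file-based runs --------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a file-based run (YAML-serialisable)."""

    out_dir: str = "krillhab_run"
    preset: str = "voyage"  # voyage | recovery | null
    n_swarms: int = 1000
    seed: int = 0
    surface_exclusion_m: float = 10.0
    max_depth_m: float = 250.0
    snr_threshold_db: float = 10.0
    krill_length_mm: float = 44.5
    sv_threshold_db: float = -70.0
    brt_grid: str = "fixed"  # fixed | quick | full
    scales_km_h: tuple = ((12.0, 1.0), (20.0, 2.0), (40.0, 4.0))
    write_echogram: bool = False

    def validate(self) -> None:
        if self.preset not in ("voyage", "recovery", "null"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.brt_grid not in ("fixed", "quick", "full"):
            raise ValueError(f"unknown brt grid {self.brt_grid!r}")
        if not self.surface_exclusion_m < self.max_depth_m:
            raise ValueError("surface exclusion must be above the maximum depth")
        for d, t in self.scales_km_h:
            if d <= 0 or t <= 0:
                raise ValueError("scales must be positive")

    def sim_config(self) -> SimConfig:
        if self.preset == "voyage":
            return SimConfig.voyage(seed=self.seed)
        return SimConfig.recovery(n_swarms=self.n_swarms, seed=self.seed, null=self.preset == "null")

    def scales(self) -> tuple[ScaleThreshold, ...]:
        return tuple(ScaleThreshold(d, t, f"{d:g}km_{t:g}h") for d, t in self.scales_km_h)

    def brt(self) -> BRTConfig:
        return {
            "fixed": BRTConfig.fixed(seed=self.seed),
            "quick": BRTConfig.quick_grid(seed=self.seed),
            "full": BRTConfig.full_grid(seed=self.seed),
        }[self.brt_grid]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["scales_km_h"] = [list(s) for s in self.scales_km_h]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "scales_km_h" in d:
            d["scales_km_h"] = tuple(tuple(s) for s in d["scales_km_h"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def run_all(cfg: RunConfig) -> Path:
    """Execute the full chain and write every stage artefact plus a manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim_config()
    res = run_pipeline(
        sim,
        scales=cfg.scales(),
        brt_config=cfg.brt(),
        surface_m=cfg.surface_exclusion_m,
        max_depth_m=cfg.max_depth_m,
        keep_grid=cfg.write_echogram,
    )
    if cfg.write_echogram:
        res.grid.to_netcdf(out / "echogram.nc")  # type: ignore[attr-defined]
    res.truth_table.to_csv(out / "truth.csv", index=False)
    res.swarm_table.to_csv(out / "swarms.csv", index=False)
    res.detections.to_csv(out / "detections.csv", index=False)
    res.effort.to_csv(out / "effort.csv", index=False)
    for lbl, (train, test) in res.modelling_tables.items():
        train.to_csv(out / f"train_{lbl}.csv", index=False)
        test.to_csv(out / f"test_{lbl}.csv", index=False)
    model_summary = {
        lbl: {**fitres.summary_dict(), "test_auc": res.aucs.get(lbl)} for lbl, fitres in res.fits.items()
    }
    (out / "model_summary.json").write_text(json.dumps(model_summary, indent=2))
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "preset": cfg.preset,
        "scales": [list(s) for s in cfg.scales_km_h],
        "grid_shape": [sim.n_pings, sim.n_depth],
        "counts": res.counts,
        "parameters": {
            "surface_exclusion_m": cfg.surface_exclusion_m,
            "max_depth_m": cfg.max_depth_m,
            "sv_threshold_db": cfg.sv_threshold_db,
            "krill_length_mm": cfg.krill_length_mm,
            "brt_grid": cfg.brt_grid,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def summarise(run_dir) -> dict:
    """Aggregate a completed run into effort counts, presence x day/night
    tables per scale, influence rankings and split sizes."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    swarms_path = run_dir / "swarms.csv"
    if not manifest_path.exists() or not swarms_path.exists():
        raise FileNotFoundError(f"incomplete run directory: {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    swarms = pd.read_csv(swarms_path)
    model_summary = {}
    ms_path = run_dir / "model_summary.json"
    if ms_path.exists():
        model_summary = json.loads(ms_path.read_text())

    effort_counts = swarms["effort_tag"].value_counts().to_dict()
    during = swarms[swarms["effort_tag"] != "none"]

    presence_tables = {}
    split_tables = {}
    for col in [c for c in swarms.columns if c.startswith("present_")]:
        lbl = col[len("present_"):]
        sub = during
        tab = {
            "present_total": int(sub[col].sum()),
            "present_day": int((sub[col] & sub["is_day"]).sum()),
            "present_night": int((sub[col] & ~sub["is_day"]).sum()),
            "absent_total": int((~sub[col].astype(bool)).sum()),
            "absent_day": int((~sub[col].astype(bool) & sub["is_day"]).sum()),
            "absent_night": int((~sub[col].astype(bool) & ~sub["is_day"]).sum()),
        }
        presence_tables[lbl] = tab
        train_p = run_dir / f"train_{lbl}.csv"
        test_p = run_dir / f"test_{lbl}.csv"
        if train_p.exists() and test_p.exists():
            tr = pd.read_csv(train_p)
            te = pd.read_csv(test_p)
            split_tables[lbl] = {
                "train_presence": int(tr["whale_present"].sum()),
                "train_absence": int((1 - tr["whale_present"]).sum()),
                "train_total": len(tr),
                "test_presence": int(te["whale_present"].sum()),
                "test_absence": int((1 - te["whale_present"]).sum()),
                "test_total": len(te),
                "train_ratio": round(tr["whale_present"].sum() / max((1 - tr["whale_present"]).sum(), 1), 2),
                "test_ratio": round(te["whale_present"].sum() / max((1 - te["whale_present"]).sum(), 1), 2),
            }

    influence = {lbl: ms.get("relative_influence", {}) for lbl, ms in model_summary.items()}
    return {
        "manifest": manifest,
        "effort_counts": effort_counts,
        "presence_tables": presence_tables,
        "split_tables": split_tables,
        "influence": influence,
        "aucs": {lbl: ms.get("test_auc") for lbl, ms in model_summary.items()},
    }
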