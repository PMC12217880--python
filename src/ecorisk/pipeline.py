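"""End-to-end orchestration: observed-date analysis, scenario simulation,
and carbon–risk conflict mapping, with every intermediate written to disk.

A run produces a :class:`RunManifest` (JSON) recording config, seeds and
every output path, so reruns with identical config and seeds reproduce the
rasters bit-for-bit.  Stage seeds are derived deterministically from one
master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import carbon as carbon_mod
from . import classify as classify_mod
from . import conflict as conflict_mod
from . import lucc, risk
from .geodata import (
    EvaluationGrid,
    LandClassTable,
    LandUseRaster,
    RunConfig,
    build_evaluation_grid,
    write_float_raster,
    write_landuse_raster,
)
from .presets import ERI_FIXED_BREAKS, RISK_LABELS

SCENARIOS = ("ND", "UD", "CP")
HORIZONS = 2  # successive one-step projections


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    timing_s: dict = field(default_factory=dict)

    def add(self, stage: str, key: str, path: Path) -> None:
        self.outputs.setdefault(stage, {})[key] = str(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _risk_breaks(values: np.ndarray, config: RunConfig):
    if config.classification_mode == "fixed":
        t = config.fixed_breaks or ERI_FIXED_BREAKS
        return classify_mod.fixed_breaks(t, RISK_LABELS)
    return classify_mod.jenks_breaks(values, k=5, seed=config.seed, labels=RISK_LABELS)


def run_observed(
    config: RunConfig,
    rasters: list[LandUseRaster],
    classes: LandClassTable,
    out_dir: str | Path,
    labels: list[str] | None = None,
) -> RunManifest:
    """Per-date ERI, carbon, five-class maps and class-area tables."""
    if not rasters:
        raise ValueError("need at least one land-use raster")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = labels or [f"t{i}" for i in range(len(rasters))]
    manifest = RunManifest(config=dict(config.__dict__), master_seed=config.seed)
    grid = build_evaluation_grid(rasters[0], config.unit_size)
    trend_rows = []
    for lab, ras in zip(labels, rasters):
        t0 = time.perf_counter()
        rasters[0].require_aligned(ras)
        _, eri = risk.eri_pipeline(
            ras, grid, classes,
            connectivity=config.connectivity,
            min_unit_area_fraction=config.min_unit_area_fraction,
        )
        eri_r = eri.as_raster()
        write_float_raster(eri_r, out / f"eri_{lab}.tif")
        manifest.add("eri", lab, out / f"eri_{lab}.tif")
        eri.to_frame().to_csv(out / f"eri_units_{lab}.csv", index=False)

        cs = carbon_mod.carbon_map(ras, classes)
        write_float_raster(cs.density, out / f"carbon_{lab}.tif")
        manifest.add("carbon", lab, out / f"carbon_{lab}.tif")
        manifest.metrics.setdefault("carbon_total_t", {})[lab] = cs.total_t

        vals = eri.values[np.isfinite(eri.values)]
        breaks = _risk_breaks(vals, config)
        eri_cls = classify_mod.apply_breaks(eri_r, breaks)
        eri_cls.areas.to_csv(out / f"eri_classes_{lab}.csv", index=False)
        manifest.add("eri_classes", lab, out / f"eri_classes_{lab}.csv")

        carbon_breaks = classify_mod.jenks_breaks(
            cs.density.grid[np.isfinite(cs.density.grid)], k=5, seed=config.seed
        )
        carbon_cls = classify_mod.apply_breaks(cs.density, carbon_breaks)
        carbon_cls.areas.to_csv(out / f"carbon_classes_{lab}.csv", index=False)
        manifest.add("carbon_classes", lab, out / f"carbon_classes_{lab}.csv")

        for code, area in ras.class_areas_km2().items():
            trend_rows.append({"date": lab, "class": code, "area_km2": area})
        manifest.timing_s[f"observed:{lab}"] = time.perf_counter() - t0
    pd.DataFrame(trend_rows).to_csv(out / "class_area_trend.csv", index=False)
    manifest.add("tables", "class_area_trend", out / "class_area_trend.csv")
    manifest.write(out / "manifest.json")
    return manifest


def run_scenarios(
    config: RunConfig,
    t0: LandUseRaster,
    t1: LandUseRaster,
    drivers: np.ndarray,
    classes: LandClassTable,
    out_dir: str | Path,
    scenarios: tuple[str, ...] = SCENARIOS,
    horizons: int = HORIZONS,
) -> RunManifest:
    """Project land use under each scenario and map carbon–risk conflict.

    For each scenario and horizon: allocate the scenario-adjusted Markov
    demand, compute ERI and carbon on the projected map, then the
    bivariate local Moran between per-unit carbon density and risk, its
    LISA labels and the conflict summary.  Water is frozen via the
    restriction mask throughout.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config.__dict__), master_seed=config.seed)
    t0.require_aligned(t1)
    grid = build_evaluation_grid(t0, config.unit_size)

    base = lucc.estimate_transition_matrix(t0, t1)
    suit_seed = derive_seed(config.seed, "suitability")
    manifest.stage_seeds["suitability"] = suit_seed
    suit = lucc.fit_suitability(t0, t1, drivers, seed=suit_seed)
    water_frozen = t1.grid == 2

    comparison = []
    for scen in scenarios:
        spec = lucc.ScenarioSpec.preset(scen)
        model = lucc.TransitionModel(
            P=base.P,
            transfer_cost=lucc.scenario_transfer_cost(scen),
            restriction_mask=water_frozen,
        )
        current = t1
        for h in range(1, horizons + 1):
            tag = f"{scen}_h{h}"
            tstart = time.perf_counter()
            seed_alloc = derive_seed(config.seed, f"allocate:{tag}")
            manifest.stage_seeds[f"allocate:{tag}"] = seed_alloc
            res = lucc.allocate(current, model, suit, spec, seed=seed_alloc)
            current = res.raster
            write_landuse_raster(current, out / f"landuse_{tag}.tif")
            manifest.add("landuse", tag, out / f"landuse_{tag}.tif")
            res.log.to_csv(out / f"allocation_log_{tag}.csv", index=False)
            manifest.metrics.setdefault("demand", {})[tag] = res.demand.tolist()
            manifest.metrics.setdefault("shortfall", {})[tag] = res.shortfall.tolist()

            _, eri = risk.eri_pipeline(
                current, grid, classes,
                connectivity=config.connectivity,
                min_unit_area_fraction=config.min_unit_area_fraction,
            )
            write_float_raster(eri.as_raster(), out / f"eri_{tag}.tif")
            manifest.add("eri", tag, out / f"eri_{tag}.tif")
            cs = carbon_mod.carbon_map(current, classes)
            write_float_raster(cs.density, out / f"carbon_{tag}.tif")
            manifest.add("carbon", tag, out / f"carbon_{tag}.tif")
            manifest.metrics.setdefault("carbon_total_t", {})[tag] = cs.total_t

            finite = np.isfinite(eri.values)
            weights = conflict_mod.build_weights(
                grid, scheme=config.weights_scheme,
                standardization=config.weights_standardization,
                retained=finite,
            )
            ids = weights.ids
            x_carbon = cs.unit_mean_density(grid)[ids]
            x_risk = eri.values[ids]
            seed_moran = derive_seed(config.seed, f"moran:{tag}")
            manifest.stage_seeds[f"moran:{tag}"] = seed_moran
            mres = conflict_mod.bivariate_moran(
                x_carbon, x_risk, weights,
                permutations=config.permutations, seed=seed_moran,
            )
            labels = conflict_mod.lisa_labels(mres, alpha=config.alpha)
            report = conflict_mod.conflict_summary(labels, mres, grid)
            write_float_raster(report.label_raster, out / f"lisa_{tag}.tif")
            manifest.add("lisa", tag, out / f"lisa_{tag}.tif")
            report.table.to_csv(out / f"conflict_{tag}.csv", index=False)
            manifest.metrics.setdefault("moran_I", {})[tag] = mres.I_global
            manifest.metrics.setdefault("moran_p", {})[tag] = mres.p_global
            manifest.metrics.setdefault("hotspot_share", {})[tag] = report.hotspot_share
            comparison.append(
                {
                    "scenario": scen,
                    "horizon": h,
                    "moran_I": mres.I_global,
                    "moran_p": mres.p_global,
                    "hotspot_percent": report.hotspot_share,
                    "carbon_total_t": cs.total_t,
                    "construction_km2": current.class_areas_km2()[1],
                    "cropland_km2": current.class_areas_km2()[5],
                }
            )
            manifest.timing_s[tag] = time.perf_counter() - tstart

    pd.DataFrame(comparison).to_csv(out / "scenario_comparison.csv", index=False)
    manifest.add("tables", "scenario_comparison", out / "scenario_comparison.csv")
    manifest.write(out / "manifest.json")
    return manifest
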