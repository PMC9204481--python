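"""End-to-end study runner.

Ties the stages into the full two-group analysis: simulate (or load) the
native and neoatherosclerotic cohorts, analyze every pullback, build the
three comparison tables (lesion geometry+morphology, frame-level
prevalences, rupture location), derive the mean lesion spec per group,
build the idealized geometries, and run the flow and wall-stress
surrogates.  Every run writes the resolved configuration next to its
outputs so it can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .annotation import Pullback, ThresholdConfig, read_pullback
from .geometry import LesionSpec, build_geometry, export_geometry, mean_lesion_spec
from .hemodynamics import FlowConditions, axisymmetric_ns_solve, quasi1d_flow
from .model import analyze_cohort
from .morphometry import FRAME_FEATURES, frame_prevalence
from .stats import TwoGroupComparison, format_p
from .structural import cap_stress_estimate
from .synthetic import group_params, simulate_cohort, synthesize_pullback

log = logging.getLogger("plaqrupt")

__all__ = ["RunConfig", "run_full_study"]

#: Lesion-table layout: (column, kind, decimals)
LESION_TABLE_VARIABLES = [
    ("lesion_length_mm", "continuous", 1),
    ("mla_mm2", "continuous", 2),
    ("prox_ref_area_mm2", "continuous", 2),
    ("dist_ref_area_mm2", "continuous", 2),
    ("area_stenosis_pct", "continuous", 1),
    ("rg_upstream", "continuous", 3),
    ("rg_downstream", "continuous", 3),
    ("tcfa", "binary"),
    ("thcfa", "binary"),
    ("min_fct_um", "continuous", 0),
    ("mean_fct_um", "continuous", 0),
    ("mean_lipid_arc_deg", "continuous", 1),
    ("lipid_length_mm", "continuous", 1),
    ("lipid_index", "continuous", 1),
    ("calcific_present", "binary"),
    ("mean_calcific_arc_deg", "continuous", 1),
    ("calcific_index", "continuous", 1),
    ("macrophages_present", "binary"),
    ("spotted_macrophages", "binary"),
    ("lined_macrophages", "binary"),
    ("lined_macrophage_index", "continuous", 1),
    ("crystal_present", "binary"),
    ("microchannel_present", "binary"),
    ("n_rupture_sites", "continuous", 1),
    ("rupture_length_mm", "continuous", 1),
    ("rupture_depth_mm", "continuous", 1),
    ("rupture_arc_deg", "continuous", 1),
    ("rupture_extent_index", "continuous", 1),
    ("thrombus_present", "binary"),
    ("thrombus_score_pct", "continuous", 1),
]


@dataclass
class RunConfig:
    """Fully serializable run configuration."""

    seed: int = 7
    n_prnv: int = 56
    n_prna: int = 24
    output_dir: str = "plaqrupt_run"
    input_dirs: Optional[dict] = None       # {"PR-NV": dir, "PR-NA": dir} of pullback JSONs
    thresholds: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)
    solver: str = "quasi1d"                 # or "axisym"
    grid: dict = field(default_factory=lambda: {"n_z": 121, "n_r": 21})
    export_stl: bool = False

    def resolved_thresholds(self) -> ThresholdConfig:
        return ThresholdConfig(**self.thresholds)

    def resolved_flow(self) -> FlowConditions:
        return FlowConditions(**self.flow)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _load_or_simulate(config: RunConfig, group: str, n: int, seed: int):
    """-> (pullbacks, truth table or None)"""
    if config.input_dirs and group in config.input_dirs:
        paths = sorted(Path(config.input_dirs[group]).glob("*.json"))
        if not paths:
            raise ValueError(f"no pullback JSONs found for group {group}")
        return [read_pullback(p) for p in paths], None
    if n <= 0:
        raise ValueError(f"empty group {group}")
    cohort = simulate_cohort(group_params(group, n=n, seed=seed))
    pullbacks = [
        synthesize_pullback(row, seed=seed + 1000 + i, group=group)
        for i, (_, row) in enumerate(cohort.iterrows())
    ]
    return pullbacks, cohort


def run_full_study(config: RunConfig) -> dict:
    """Run the full two-group study; returns the output bundle paths/objects."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.resolved_thresholds()
    conditions = config.resolved_flow()
    bundle: dict = {"output_dir": str(out)}

    stage = "simulate/load"
    try:
        pb_nv, truth_nv = _load_or_simulate(config, "PR-NV", config.n_prnv, config.seed)
        pb_na, truth_na = _load_or_simulate(config, "PR-NA", config.n_prna, config.seed + 1)
        log.info("stage %s: %d + %d pullbacks (%.1fs)", stage, len(pb_nv), len(pb_na),
                 time.time() - t0)

        stage = "per-lesion analysis"
        metrics_nv = analyze_cohort(pb_nv, thresholds)
        metrics_na = analyze_cohort(pb_na, thresholds)
        metrics_nv.to_csv(out / "lesions_prnv.csv")
        metrics_na.to_csv(out / "lesions_prna.csv")

        stage = "comparison tables"
        lesion_table = TwoGroupComparison(
            metrics_nv, metrics_na, LESION_TABLE_VARIABLES, labels=("PR-NV", "PR-NA")
        ).fit()
        lesion_table.to_frame().to_csv(out / "table_lesion_level.csv", index=False)

        frame_rows = []
        for feature in FRAME_FEATURES:
            c_nv, t_nv, p_nv = frame_prevalence(pb_nv, feature, thresholds)
            c_na, t_na, p_na = frame_prevalence(pb_na, feature, thresholds)
            from .stats import chi_square_2x2
            try:
                _, p = chi_square_2x2(c_nv, t_nv - c_nv, c_na, t_na - c_na)
            except ValueError:
                p = None
            frame_rows.append({
                "feature": feature,
                "PR-NV": f"{c_nv} ({p_nv})", "PR-NA": f"{c_na} ({p_na})",
                "p": format_p(p),
            })
        pd.DataFrame(frame_rows).to_csv(out / "table_frame_level.csv", index=False)

        loc_rows = []
        for grp, metrics in (("PR-NV", metrics_nv), ("PR-NA", metrics_na)):
            if "rupture_longitudinal_class" not in metrics:
                continue
            counts = metrics["rupture_longitudinal_class"].value_counts()
            total = int(counts.sum())
            for cls in ("upstream", "throat", "downstream"):
                n = int(counts.get(cls, 0))
                loc_rows.append({"group": grp, "class": cls, "n": n,
                                 "pct": round(100.0 * n / total, 1) if total else None})
        pd.DataFrame(loc_rows).to_csv(out / "table_rupture_location.csv", index=False)

        stage = "mean geometry"
        source_nv = truth_nv if truth_nv is not None else metrics_nv
        source_na = truth_na if truth_na is not None else metrics_na
        spec_nv = mean_lesion_spec(source_nv, "PR-NV")
        spec_na = mean_lesion_spec(source_na, "PR-NA")
        geom_nv = build_geometry(spec_nv)
        geom_na = build_geometry(spec_na)
        export_geometry(geom_nv, out / "geometry_prnv.csv", "profile-csv")
        export_geometry(geom_na, out / "geometry_prna.csv", "profile-csv")
        if config.export_stl:
            export_geometry(geom_nv, out / "geometry_prnv.stl", "stl")
            export_geometry(geom_na, out / "geometry_prna.stl", "stl")

        stage = "flow"
        solve = (
            (lambda g: axisymmetric_ns_solve(g, conditions, **config.grid))
            if config.solver == "axisym"
            else (lambda g: quasi1d_flow(g, conditions))
        )
        flow_nv, flow_na = solve(geom_nv), solve(geom_na)
        for name, sol in (("prnv", flow_nv), ("prna", flow_na)):
            pd.DataFrame({"z_mm": sol.z_mm, "wss_pa": sol.wss_pa,
                          "pressure_mmhg": sol.pressure_mmhg}).to_csv(
                out / f"flow_{name}.csv", index=False)

        stage = "wall stress"
        stress_nv = cap_stress_estimate(geom_nv, conditions, flow=flow_nv)
        stress_na = cap_stress_estimate(geom_na, conditions, flow=flow_na)

        summary = {
            "n_lesions": {"PR-NV": len(pb_nv), "PR-NA": len(pb_na)},
            "flow": {
                grp: {"tau_max_pa": s.tau_max_pa, "pressure_drop_mmhg": s.pressure_drop_mmhg,
                      "pct_area_high_ess": s.pct_area_high_ess}
                for grp, s in (("PR-NV", flow_nv), ("PR-NA", flow_na))
            },
            "stress": {
                grp: {"superficial_pss_kpa": s.superficial_pss_kpa,
                      "max_pss_kpa": s.max_pss_kpa,
                      "max_pss_location": s.max_pss_location}
                for grp, s in (("PR-NV", stress_nv), ("PR-NA", stress_na))
            },
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "physiology_summary.json").write_text(json.dumps(summary, indent=1))
        config.to_yaml(out / "resolved_config.yaml")
        bundle.update(
            summary=summary,
            lesion_table=lesion_table,
            metrics={"PR-NV": metrics_nv, "PR-NA": metrics_na},
            geometries={"PR-NV": geom_nv, "PR-NA": geom_na},
            flow={"PR-NV": flow_nv, "PR-NA": flow_na},
            stress={"PR-NV": stress_nv, "PR-NA": stress_na},
        )
        log.info("study complete in %.1fs", time.time() - t0)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"study failed at stage '{stage}': {exc}") from exc
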